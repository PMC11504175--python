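"""Shared fixtures: small deterministic phantoms and prepared samples."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octfluid.model import prepare_samples
from octfluid.phantom import PhantomSpec, generate_phantom

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def phantom_pair():
    """One 128x128 phantom with all three fluid classes present."""
    return generate_phantom(PhantomSpec(height=128, width=128, seed=3))


@pytest.fixture(scope="session")
def small_samples():
    """Four prepared 64x64 samples for quick training-loop tests."""
    pairs = [generate_phantom(PhantomSpec(height=64, width=64, seed=40 + s,
                                          fluids_per_class={"IRF": 1,
                                                            "SRF": 1,
                                                            "PED": 0}))
             for s in range(4)]
    return prepare_samples(pairs, target_size=(64, 64))
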