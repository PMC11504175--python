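"""Synthetic OCT B-scan phantoms with exact ground-truth fluid masks.

A phantom is a bright, gently curved retinal band on a darker background,
carrying three classes of darker-than-tissue fluid pockets:

* IRF (label 1): elliptical cysts in the inner half of the band,
* SRF (label 2): pockets hugging the band's lower boundary,
* PED (label 3): dome-shaped bumps that locally deform the lowest boundary
  downwards, as a detached pigment epithelium does.

Placement is positional, not intensity-coded: all three classes share the
same fluid intensity, so a segmenter has to exploit position and shape to
tell them apart.  Speckle is modelled as clipped multiplicative Gaussian
noise, the standard first-order surrogate for OCT speckle.  Identical
specs (including the seed) regenerate bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, PlacementError
from .io import read_image, read_mask, write_image, write_manifest, write_mask

CLASS_NAMES = {1: "IRF", 2: "SRF", 3: "PED"}
CLASS_IDS = {v: k for k, v in CLASS_NAMES.items()}

_MAX_TRIES = 100  # rejection-sampling budget per pocket


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic B-scan; a spec is its own seed."""

    height: int = 128
    width: int = 128
    n_layers: int = 4
    layer_curvature: float = 0.5
    fluids_per_class: dict = field(
        default_factory=lambda: {"IRF": 2, "SRF": 1, "PED": 1})
    fluid_size_range: tuple = (6, 14)
    speckle_sigma: float = 0.15
    background_level: float = 0.08
    tissue_level: float = 0.65
    seed: int = 0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ConfigError("phantom height and width must be >= 64")
        for cls, n in self.fluids_per_class.items():
            if cls not in CLASS_IDS:
                raise ConfigError(f"unknown fluid class {cls!r}")
            if n < 0:
                raise ConfigError(f"negative pocket count for {cls}")
        lo, hi = self.fluid_size_range
        if not (0 < lo <= hi):
            raise ConfigError("fluid_size_range must satisfy 0 < min <= max")
        if self.speckle_sigma < 0:
            raise ConfigError("speckle_sigma must be >= 0")
        if not (0 <= self.background_level < self.tissue_level <= 1):
            raise ConfigError("need 0 <= background_level < tissue_level <= 1")


@dataclass(frozen=True)
class PhantomPair:
    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8, values in {0, 1, 2, 3}
    spec: PhantomSpec


def _band_boundaries(spec: PhantomSpec, rng: np.random.Generator):
    """Sinusoidally bowed top/bottom rows of the tissue band, per column."""
    h, w = spec.height, spec.width
    x = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    centre = 0.45 * h + spec.layer_curvature * 0.10 * h * np.sin(
        np.pi * x / w + phase)
    thickness = 0.42 * h
    top = np.clip(centre - thickness / 2, 1, h - 2)
    bottom = np.clip(centre + thickness / 2, 1, h - 2)
    return top, bottom


def _ellipse(rows, cols, r0, c0, a_r, a_c):
    return ((rows - r0) / a_r) ** 2 + ((cols - c0) / a_c) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render one phantom image/mask pair deterministically from its spec."""
    image, mask, _, _ = _render(spec)
    return PhantomPair(image=image, mask=mask, spec=spec)


def band_extent(spec: PhantomSpec):
    """Per-column (top, bottom) rows of the tissue band, PED bumps included.

    Deterministic replay of the generator; used by co-registration checks.
    """
    _, _, top, bottom_def = _render(spec)
    return top, bottom_def


def _render(spec: PhantomSpec):
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rows, cols = np.ogrid[0:h, 0:w]
    top, bottom = _band_boundaries(spec, rng)
    lo, hi = spec.fluid_size_range

    mask = np.zeros((h, w), dtype=np.uint8)

    # ---- PED first: bumps deform the lowest boundary downwards
    bottom_def = bottom.copy()
    for _ in range(spec.fluids_per_class.get("PED", 0)):
        for attempt in range(_MAX_TRIES):
            a_c = rng.uniform(max(lo, 4), hi) * 1.5        # half-width, px
            depth = rng.uniform(max(lo * 0.6, 3), hi * 0.8)
            c0 = rng.uniform(a_c + 2, w - a_c - 3)
            span = np.abs(np.arange(w) - c0) < a_c
            bump = np.where(span,
                            depth * np.sqrt(np.clip(
                                1 - ((np.arange(w) - c0) / a_c) ** 2, 0, 1)),
                            0.0)
            new_bottom = bottom + bump
            region = (rows >= bottom[None, :]) & (rows < new_bottom[None, :])
            if new_bottom.max() >= h - 1:
                continue  # bump would leave the frame
            if (mask[region] != 0).any() or (bump > 0).sum() < 3:
                continue
            bottom_def = np.maximum(bottom_def, new_bottom)
            mask[region] = 3
            break
        else:
            raise PlacementError(
                "could not place a PED bump inside the phantom frame")

    band = (rows >= top[None, :]) & (rows < bottom_def[None, :])

    # ---- IRF: ellipses in the inner (upper-to-middle) half of the band
    def place_ellipses(cls_name, n, row_lo_frac, row_hi_frac):
        cls_id = CLASS_IDS[cls_name]
        for _ in range(n):
            for attempt in range(_MAX_TRIES):
                a_r = rng.uniform(lo, hi) * 0.6
                a_c = rng.uniform(lo, hi)
                c0 = rng.uniform(a_c + 1, w - a_c - 2)
                tcol, bcol = np.interp(c0, np.arange(w), top), \
                    np.interp(c0, np.arange(w), bottom)
                th = bcol - tcol
                r_min = tcol + row_lo_frac * th + a_r + 1
                r_max = tcol + row_hi_frac * th - a_r - 1
                if r_max <= r_min:
                    continue
                r0 = rng.uniform(r_min, r_max)
                ell = _ellipse(rows, cols, r0, c0, a_r, a_c)
                # 2-px inflated footprint keeps pockets separated so each
                # stays its own connected component
                halo = _ellipse(rows, cols, r0, c0, a_r + 2, a_c + 2)
                inside = (rows > top[None, :]) & (rows < bottom[None, :] - 0.5)
                if (ell & ~inside).any() or (mask[halo] != 0).any():
                    continue
                mask[ell] = cls_id
                break
            else:
                raise PlacementError(
                    f"could not place a {cls_name} pocket after "
                    f"{_MAX_TRIES} attempts (spec too small or too crowded)")

    place_ellipses("IRF", spec.fluids_per_class.get("IRF", 0), 0.05, 0.55)
    place_ellipses("SRF", spec.fluids_per_class.get("SRF", 0), 0.55, 0.97)

    # ---- render intensities
    image = np.full((h, w), spec.background_level)
    image[band] = spec.tissue_level
    # faint internal layering: n_layers horizontal sub-bands
    if spec.n_layers > 1:
        frac = (rows - top[None, :]) / np.maximum(bottom_def - top, 1)[None, :]
        layer_idx = np.floor(np.clip(frac, 0, 0.999) * spec.n_layers)
        mod = 0.06 * np.where(layer_idx % 2 == 0, 1.0, -1.0)
        image[band] += mod[band]
    fluid_level = spec.background_level + 0.10
    image[mask > 0] = fluid_level

    if spec.speckle_sigma > 0:
        noise = rng.standard_normal((h, w))
        image = image * (1.0 + spec.speckle_sigma * noise)
    image = np.clip(image, 0.0, 1.0)

    return image, mask, top, bottom_def


def generate_dataset(spec: PhantomSpec, n: int, out_dir) -> Path:
    """Write n phantom pairs (seeds seed..seed+n-1) plus a manifest.

    Returns the manifest path.  Regeneration with the same spec and n is
    byte-identical.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        records = []
        for i in range(n):
            sub = replace(spec, seed=spec.seed + i)
            pair = generate_phantom(sub)
            img_path = out_dir / f"phantom_{i:04d}.png"
            msk_path = out_dir / f"phantom_{i:04d}_mask.png"
            write_image(img_path, pair.image)
            write_mask(msk_path, pair.mask)
            records.append({"image": img_path.name, "mask": msk_path.name,
                            "seed": sub.seed})
        manifest = out_dir / "manifest.tsv"
        write_manifest(manifest, records)
    except OSError as exc:
        raise ConfigError(f"cannot write dataset to {out_dir}: {exc}") from exc
    return manifest


def load_dataset(manifest_path) -> list[PhantomPair]:
    """Read back a generated dataset (spec metadata is not restored)."""
    from .io import read_manifest

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out = []
    for rec in read_manifest(manifest_path):
        img = read_image(base / rec["image"])
        msk = read_mask(base / rec["mask"])
        out.append(PhantomPair(image=img, mask=msk, spec=None))
    return out
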