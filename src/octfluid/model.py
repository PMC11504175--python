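"""Model/Results facade tying preprocessing, network and training together.

``FluidSegmentationModel`` is constructed from data (phantom pairs, a
manifest on disk, or raw image/mask arrays) together with the
architecture, preprocessing and optimization hyperparameters; ``fit()``
runs the training protocol and returns a ``SegmentationResults`` carrying
the trained network, the epoch history and evaluation helpers.

    >>> pairs = [generate_phantom(PhantomSpec(seed=s)) for s in range(8)]
    >>> model = FluidSegmentationModel.from_phantoms(pairs,
    ...     network=NetworkSpec(in_size=(128, 128), base_channels=8,
    ...                         n_stages=3),
    ...     train_config=TrainConfig(batch_size=4, max_steps=200))
    >>> res = model.fit(seed=17)
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ConfigError
from .io import dataclass_from_mapping
from .metrics import MetricsReport, evaluate as _evaluate
from .network import (NetworkSpec, SegmentationNetwork, build_model,
                      predict_mask)
from .phantom import PhantomPair
from .preprocess import (BScan, PreprocessParams, edge_map,
                         preprocess_pipeline)
from .training import Sample, TrainConfig, TrainHistory, normalize_inputs, train

logger = logging.getLogger("octfluid")


@dataclass(frozen=True)
class RunConfig:
    """Round-trippable bundle of every knob a run needs."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    paths: dict = field(default_factory=dict)
    version: str = "1"

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        known = {"preprocess", "network", "training", "paths", "version"}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown key(s) {unknown} in run config")
        return cls(
            preprocess=dataclass_from_mapping(
                PreprocessParams, raw.get("preprocess", {}), "preprocess"),
            network=dataclass_from_mapping(
                NetworkSpec, raw.get("network", {}), "network"),
            training=dataclass_from_mapping(
                TrainConfig, raw.get("training", {}), "training"),
            paths=dict(raw.get("paths", {})),
            version=str(raw.get("version", "1")),
        )

    def to_mapping(self) -> dict:
        def plain(obj):
            d = {}
            for k, v in asdict(obj).items():
                d[k] = list(v) if isinstance(v, tuple) else v
            return d

        return {"preprocess": plain(self.preprocess),
                "network": plain(self.network),
                "training": plain(self.training),
                "paths": dict(self.paths),
                "version": self.version}


def _resize_sample(image, edge, mask, size):
    h, w = size
    if image.shape == (h, w):
        return image, edge, mask
    img = _sk_resize(image, (h, w), order=1, preserve_range=True,
                     anti_aliasing=True)
    edg = _sk_resize(edge, (h, w), order=1, preserve_range=True,
                     anti_aliasing=True)
    msk = _sk_resize(mask.astype(float), (h, w), order=0,
                     preserve_range=True, anti_aliasing=False).astype(np.uint8)
    return np.clip(img, 0, 1), np.clip(edg, 0, 1), msk


def prepare_samples(pairs: list, params: PreprocessParams | None = None,
                    reference: BScan | None = None,
                    target_size: tuple | None = None) -> list:
    """Run the enhancement chain over image/mask pairs and co-crop masks.

    Each pair is (image, mask) arrays or a PhantomPair.  The ROI crop is
    applied to the mask as well, and everything is resized to
    ``target_size`` (the network input size) when given.
    """
    params = params or PreprocessParams()
    out = []
    for pair in pairs:
        if isinstance(pair, PhantomPair):
            image, mask = pair.image, pair.mask
        else:
            image, mask = pair
        enhanced, edges, box = preprocess_pipeline(
            BScan(np.asarray(image, dtype=float)), reference, params)
        mask = np.asarray(mask)[box.row_start:box.row_end,
                                box.col_start:box.col_end]
        img, edg, msk = enhanced.pixels, edges.response, mask
        if target_size is not None:
            img, edg, msk = _resize_sample(img, edg, msk, target_size)
        out.append(Sample(image=img, edge=edg, mask=msk))
    return out


class FluidSegmentationModel:
    """Retinal-fluid segmenter specified by data + hyperparameters."""

    def __init__(self, samples: list,
                 network: NetworkSpec | None = None,
                 train_config: TrainConfig | None = None,
                 preprocess_params: PreprocessParams | None = None):
        if not samples:
            raise ConfigError("no training samples provided")
        self.samples = samples
        self.network_spec = network or NetworkSpec()
        self.train_config = train_config or TrainConfig()
        self.preprocess_params = preprocess_params or PreprocessParams()
        h, w = self.network_spec.in_size
        for s in samples:
            if s.image.shape != (h, w):
                raise ConfigError(
                    f"sample shape {s.image.shape} does not match network "
                    f"input {self.network_spec.in_size}; use prepare_samples "
                    f"with target_size")

    # ------------------------------------------------------- constructors

    @classmethod
    def from_phantoms(cls, pairs: list, network: NetworkSpec | None = None,
                      train_config: TrainConfig | None = None,
                      preprocess_params: PreprocessParams | None = None,
                      reference: BScan | None = None):
        network = network or NetworkSpec()
        samples = prepare_samples(pairs, preprocess_params, reference,
                                  target_size=network.in_size)
        return cls(samples, network, train_config, preprocess_params)

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs):
        from .phantom import load_dataset

        return cls.from_phantoms(load_dataset(manifest_path), **kwargs)

    # --------------------------------------------------------------- fit

    def fit(self, seed: int | None = None) -> "SegmentationResults":
        """Train from scratch; `seed` overrides the config seed and also
        seeds weight initialization."""
        config = self.train_config
        if seed is not None:
            from dataclasses import replace
            config = replace(config, seed=seed)
        net = build_model(self.network_spec, seed=config.seed)
        net, history = train(net, self.samples, config)
        return SegmentationResults(self, net, history, config)


class SegmentationResults:
    """Fitted segmenter: trained weights, history and evaluation."""

    def __init__(self, model: FluidSegmentationModel,
                 network: SegmentationNetwork, history: TrainHistory,
                 config: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.config = config

    # ------------------------------------------------------- inference

    def predict_probs(self, image: np.ndarray,
                      edge: np.ndarray | None = None) -> np.ndarray:
        """Per-class probability maps for one (enhanced) image."""
        if edge is None:
            edge = edge_map(BScan(np.clip(image, 0, 1)),
                            self.model.preprocess_params.tau).response
        return self.network.predict(normalize_inputs(image), edge)

    def predict(self, image: np.ndarray, edge: np.ndarray | None = None,
                threshold: float = 0.5) -> np.ndarray:
        """Label mask for one image."""
        return predict_mask(self.predict_probs(image, edge), threshold)

    # ------------------------------------------------------- evaluation

    def evaluate(self, samples: list | None = None, threshold: float = 0.5,
                 macro: bool = False) -> MetricsReport:
        """Score against ground truth (training samples by default)."""
        return _evaluate(self.network, samples or self.model.samples,
                         threshold=threshold, macro=macro)

    def save(self, path) -> None:
        self.network.save(path)

    def summary(self) -> str:
        h = self.history
        spec = self.network.spec
        lines = [
            "Fluid segmentation network — training summary",
            "=" * 52,
            f"input size        : {spec.in_size[0]}x{spec.in_size[1]}",
            f"encoder stages    : {spec.n_stages} "
            f"(channels {spec.stage_channels})",
            f"fluid classes     : {spec.n_classes}",
            f"parameters        : {self.network.n_parameters():,}",
            f"epochs run        : {h.n_epochs()} (max {self.config.max_epochs})",
            f"final lr          : {h.lr[-1]:.2e}" if h.lr else "final lr : -",
            f"best val loss     : {min(h.val_loss):.4f}" if h.val_loss else "",
            f"final val loss    : {h.val_loss[-1]:.4f}" if h.val_loss else "",
        ]
        if h.val_dice:
            names = {0: "IRF", 1: "SRF", 2: "PED"}
            dice_str = "  ".join(
                f"{names.get(i, i)}={d:.3f}"
                for i, d in enumerate(h.val_dice[-1]))
            lines.append(f"final val Dice    : {dice_str}")
        return "\n".join(line for line in lines if line)


def load_results(checkpoint_path, samples: list | None = None,
                 preprocess_params: PreprocessParams | None = None
                 ) -> SegmentationResults:
    """Reload a fitted segmenter from a checkpoint for inference/eval."""
    net = SegmentationNetwork.load(checkpoint_path)
    if samples is None:
        h, w = net.spec.in_size
        samples = [Sample(image=np.zeros((h, w)), edge=np.zeros((h, w)),
                          mask=np.zeros((h, w), dtype=np.uint8))]
    shell = FluidSegmentationModel.__new__(FluidSegmentationModel)
    shell.samples = samples
    shell.network_spec = net.spec
    shell.train_config = TrainConfig()
    shell.preprocess_params = preprocess_params or PreprocessParams()
    return SegmentationResults(shell, net, TrainHistory(), TrainConfig())
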