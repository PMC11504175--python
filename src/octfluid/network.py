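"""Dual-input multiscale-attention encoder-decoder for fluid segmentation.

The network consumes an enhanced B-scan and its edge map.  Each encoder
stage gates the image stream with the edge stream through an
autoencoder-based attention block, refines the result with a hybrid
Inception/Residual block (parallel 1x1 / 3x3 / 5x5 convolutions plus a
stride-1 max-pool branch, fused by elementwise addition, with a projected
residual shortcut), and hands a skip tensor to the mirrored decoder.
Spatial dimensions halve between successive encoder stages and double in
the decoder; a 1x1 convolution with one kernel per fluid class and a
sigmoid produce independent per-class probability maps (background is
implied by all classes falling below threshold).

Attention block wiring: independent 3x3 convolutions of the two inputs
are multiplied elementwise and passed through ReLU; a small convolutional
autoencoder (two stride-2 encodings to ``bottleneck_ratio x channels``,
two up-samplings back) compresses and reconstructs the gated maps; a
channel softmax turns the reconstruction into attention weights that sum
to one at every pixel; separable convolutions of the two raw inputs are
weighted by those maps and concatenated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor
from ._nn import Conv2d, ConvNorm, InstanceNorm, Module, SeparableConv2d
from .errors import ConfigError, ShapeError

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters."""

    in_size: tuple = (256, 256)
    n_classes: int = 3
    base_channels: int = 32
    n_stages: int = 4
    autoencoder_bottleneck_ratio: float = 0.25
    inception_kernels: tuple = (1, 3, 5)

    def __post_init__(self):
        h, w = self.in_size
        div = 2 ** (self.n_stages - 1)
        if h % div or w % div:
            raise ConfigError(
                f"in_size {self.in_size} must be divisible by 2^(n_stages-1)={div}")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")
        if self.base_channels < 8:
            raise ConfigError("base_channels must be >= 8")
        if tuple(self.inception_kernels) != (1, 3, 5):
            raise ConfigError("inception_kernels is fixed at (1, 3, 5)")
        if not (0 < self.autoencoder_bottleneck_ratio <= 1):
            raise ConfigError("autoencoder_bottleneck_ratio must be in (0, 1]")

    @property
    def stage_channels(self) -> list:
        return [self.base_channels * 2 ** i for i in range(self.n_stages)]


def _fit_to(x: Tensor, h: int, w: int) -> Tensor:
    """Crop or zero-pad the trailing axes to exactly (h, w)."""
    xh, xw = x.shape[-2:]
    if xh > h or xw > w:
        x = x.crop2d((0, min(xh, h)), (0, min(xw, w)))
        xh, xw = x.shape[-2:]
    if xh < h or xw < w:
        x = x.pad2d(((0, h - xh), (0, w - xw)))
    return x


class AttentionBlock(Module):
    """Edge-gated autoencoder attention producing 2 x channels feature maps."""

    def __init__(self, rng, img_ch: int, edge_ch: int, channels: int,
                 bottleneck_ratio: float = 0.25):
        mid = max(channels // 2, 1)
        bott = max(int(round(channels * bottleneck_ratio)), 1)
        self.img_conv = ConvNorm(rng, img_ch, channels, 3, padding=1,
                                 relu=False)
        self.edge_conv = ConvNorm(rng, edge_ch, channels, 3, padding=1,
                                  relu=False)
        self.ae_down1 = ConvNorm(rng, channels, mid, 3, stride=2, padding=1)
        self.ae_down2 = ConvNorm(rng, mid, bott, 3, stride=2, padding=1)
        self.ae_up1 = ConvNorm(rng, bott, mid, 3, padding=1)
        self.ae_up2 = Conv2d(rng, mid, channels, 3, padding=1)
        self.sep_img = SeparableConv2d(rng, img_ch, channels)
        self.sep_edge = SeparableConv2d(rng, edge_ch, channels)
        self.norm_img = InstanceNorm(channels)
        self.norm_edge = InstanceNorm(channels)
        self.channels = channels

    def __call__(self, img: Tensor, edge: Tensor) -> Tensor:
        if img.shape[-2:] != edge.shape[-2:]:
            raise ShapeError(
                f"attention inputs disagree spatially: image {img.shape[-2:]} "
                f"vs edge map {edge.shape[-2:]}")
        h, w = img.shape[-2:]
        gated = (self.img_conv(img) * self.edge_conv(edge)).relu()
        z = self.ae_down1(gated)
        mh, mw = z.shape[-2:]
        z = self.ae_down2(z)
        z = _fit_to(self.ae_up1(z.upsample2x()), mh, mw)
        z = _fit_to(self.ae_up2(z.upsample2x()), h, w)
        attn = z.softmax(axis=1)
        si = self.norm_img(self.sep_img(img)) * attn
        se = self.norm_edge(self.sep_edge(edge)) * attn
        return Tensor.concat([si, se], axis=1)

    def attention_weights(self, img: Tensor, edge: Tensor) -> np.ndarray:
        """Channel-softmax weights only (diagnostic; sums to 1 per pixel)."""
        h, w = img.shape[-2:]
        gated = (self.img_conv(img) * self.edge_conv(edge)).relu()
        z = self.ae_down1(gated)
        mh, mw = z.shape[-2:]
        z = self.ae_down2(z)
        z = _fit_to(self.ae_up1(z.upsample2x()), mh, mw)
        z = _fit_to(self.ae_up2(z.upsample2x()), h, w)
        return z.softmax(axis=1).data


class InceptionResidualBlock(Module):
    """Multiscale fusion block; spatial dimensions are preserved.

    Parallel 1x1/3x3/5x5 convolutions and a projected stride-1 max-pool
    branch are summed, integrated by a 1x1 convolution and refined by an
    asymmetrically padded 2x2 convolution; a 1x1-projected shortcut joins
    the output so the residual path stays live even with zeroed kernels.
    """

    def __init__(self, rng, in_ch: int, out_ch: int):
        self.b1 = Conv2d(rng, in_ch, out_ch, 1)
        self.b3 = Conv2d(rng, in_ch, out_ch, 3, padding=1)
        self.b5 = Conv2d(rng, in_ch, out_ch, 5, padding=2)
        self.pool_proj = Conv2d(rng, in_ch, out_ch, 1)
        self.norm_sum = InstanceNorm(out_ch)
        self.integrate = ConvNorm(rng, out_ch, out_ch, 1)
        self.refine = ConvNorm(rng, out_ch, out_ch, 2,  # with (0,1)x(0,1) pad
                               relu=False)
        self.shortcut = Conv2d(rng, in_ch, out_ch, 1)

    def __call__(self, x: Tensor) -> Tensor:
        s = self.b1(x) + self.b3(x) + self.b5(x) \
            + self.pool_proj(x.maxpool3x3_stride1())
        y = self.integrate(self.norm_sum(s).relu())
        y = self.refine(y.pad2d(((0, 1), (0, 1))))
        return y + self.shortcut(x)


class SegmentationNetwork(Module):
    """The assembled dual-input encoder-decoder."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.seed = seed
        ch = spec.stage_channels
        ratio = spec.autoencoder_bottleneck_ratio

        self.attentions = []
        self.inceptions = []
        in_ch = 1
        for i in range(spec.n_stages):
            self.attentions.append(
                AttentionBlock(rng, in_ch, 1, ch[i], ratio))
            self.inceptions.append(
                InceptionResidualBlock(rng, 2 * ch[i], ch[i]))
            in_ch = ch[i]

        cb = ch[-1]
        self.bottleneck1 = ConvNorm(rng, cb, cb, 3, padding=1)
        self.bottleneck2 = ConvNorm(rng, cb, cb, 3, padding=1)

        self.dec_pre = []
        self.dec_post1 = []
        self.dec_post2 = []
        for j in range(spec.n_stages - 2, -1, -1):
            self.dec_pre.append(ConvNorm(rng, ch[j + 1], ch[j], 3, padding=1))
            self.dec_post1.append(ConvNorm(rng, 2 * ch[j], ch[j], 3, padding=1))
            self.dec_post2.append(ConvNorm(rng, ch[j], ch[j], 3, padding=1))

        self.head = Conv2d(rng, ch[0], spec.n_classes, 1)
        # start the sigmoid near the sparse foreground prior rather than 0.5
        self.head.bias.data[:] = -3.0

    # ------------------------------------------------------------- forward

    def _check_inputs(self, image: np.ndarray, edges: np.ndarray):
        h, w = self.spec.in_size
        if image.shape[-2:] != (h, w) or edges.shape[-2:] != (h, w):
            raise ShapeError(
                f"expected {h}x{w} inputs, got image {image.shape[-2:]} "
                f"and edges {edges.shape[-2:]}")

    def forward_tensor(self, image: Tensor, edge: Tensor,
                       return_encoder: bool = False):
        """Forward pass on (N,1,H,W) tensors; returns per-class sigmoid maps."""
        skips = []
        enc_feats = []
        x = image
        e = edge
        for i in range(self.spec.n_stages):
            if i > 0:
                x = x.maxpool2x2()
                e = e.avgpool2x2()
            a = self.attentions[i](x, e)
            f = self.inceptions[i](a)
            skips.append(f)
            enc_feats.append(f)
            x = f
        y = self.bottleneck2(self.bottleneck1(x))
        k = 0
        for j in range(self.spec.n_stages - 2, -1, -1):
            y = self.dec_pre[k](y.upsample2x())
            y = Tensor.concat([y, skips[j]], axis=1)
            y = self.dec_post1[k](y)
            y = self.dec_post2[k](y)
            k += 1
        probs = self.head(y).sigmoid()
        if return_encoder:
            return probs, enc_feats
        return probs

    def predict(self, image: np.ndarray, edges: np.ndarray) -> np.ndarray:
        """Deterministic evaluation forward: (H,W) arrays in, (C,H,W) out."""
        image = np.asarray(image, dtype=np.float32)
        edges = np.asarray(edges, dtype=np.float32)
        self._check_inputs(image, edges)
        img_t = Tensor(image[None, None])
        edge_t = Tensor(edges[None, None])
        return self.forward_tensor(img_t, edge_t).data[0]

    # --------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Single-file checkpoint: weights plus the embedded NetworkSpec."""
        state = self.state_dict()
        meta = json.dumps({"spec": asdict(self.spec), "seed": self.seed})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        spec_d = meta["spec"]
        spec_d["in_size"] = tuple(spec_d["in_size"])
        spec_d["inception_kernels"] = tuple(spec_d["inception_kernels"])
        net = cls(NetworkSpec(**spec_d), seed=meta["seed"])
        net.load_state_dict(state)
        return net


def build_model(spec: NetworkSpec, seed: int = 0) -> SegmentationNetwork:
    """Assemble a seeded network from its spec."""
    return SegmentationNetwork(spec, seed=seed)


def predict_mask(probs: np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binarize per-class probability maps into a label mask.

    Classes whose probability passes the threshold compete per pixel; the
    argmax wins, ties break to the lowest class index; pixels where no
    class passes are background (0).
    """
    if not (0 < threshold < 1):
        raise ConfigError(f"threshold must be in (0, 1), got {threshold}")
    probs = np.asarray(probs)
    passing = probs >= threshold
    masked = np.where(passing, probs, -1.0)
    winner = masked.argmax(axis=0).astype(np.uint8) + 1
    winner[~passing.any(axis=0)] = 0
    return winner
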