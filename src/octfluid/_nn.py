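"""Layer primitives and the Adam optimizer used by the segmentation network.

Parameters are named hierarchically (``"enc1.att.img_conv.weight"``) so the
training loop can apply weight decay to convolution kernels only, and so
checkpoints are plain name->array mappings.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

DTYPE = np.float32


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"checkpoint/parameter mismatch: missing={sorted(missing)} "
                f"unexpected={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(p.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Dense 2-D convolution with He-uniform init and optional ReLU fusion."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int,
                 kernel: int | tuple, stride: int = 1, padding=0):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = in_ch * kh * kw
        self.weight = Tensor(he_uniform(rng, (out_ch, in_ch, kh, kw), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class SeparableConv2d(Module):
    """Depthwise 3x3 followed by pointwise 1x1 (shape preserving)."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int):
        self.depth_weight = Tensor(he_uniform(rng, (in_ch, 3, 3), 9),
                                   requires_grad=True)
        self.point = Conv2d(rng, in_ch, out_ch, 1)

    def __call__(self, x: Tensor) -> Tensor:
        x = x.depthwise_conv2d(self.depth_weight, padding=1)
        return self.point(x)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Deterministic at inference (no running statistics); the affine
    parameters are named gain/bias so weight decay never touches them.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones((1, channels, 1, 1), dtype=DTYPE),
                           requires_grad=True)
        self.bias = Tensor(np.zeros((1, channels, 1, 1), dtype=DTYPE),
                           requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        y = xc * (var + self.eps).pow(-0.5)
        return y * self.gain + self.bias


class ConvNorm(Module):
    """Convolution -> instance norm -> optional ReLU."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel,
                 stride: int = 1, padding=0, relu: bool = True):
        self.conv = Conv2d(rng, in_ch, out_ch, kernel, stride, padding)
        self.norm = InstanceNorm(out_ch)
        self.relu = relu

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return y.relu() if self.relu else y


class Adam:
    """Adam with decoupled-from-the-graph L2: the penalty gradient
    ``l2_coeff * w`` is added to convolution kernels only (biases and
    any non-kernel parameter are exempt, the usual convention)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, l2_coeff: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2_coeff = l2_coeff
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    @staticmethod
    def _decayed(name: str) -> bool:
        return name.endswith("weight")

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.l2_coeff and self._decayed(k):
                g = g + self.l2_coeff * p.data
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
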