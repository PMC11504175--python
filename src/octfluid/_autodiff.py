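"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set a dual-input convolutional
encoder-decoder needs: elementwise arithmetic with broadcasting,
ReLU/sigmoid/log/clip, channel softmax, 2-D convolution (strided,
padded, grouped into dense and depthwise variants), pooling,
nearest-neighbour up-sampling, padding/cropping and channel
concatenation.  Gradients are accumulated by topological sweep over the
recorded tape, micrograd-style; every operator's backward rule is
checked against central finite differences in the test suite.

Arrays follow the (N, C, H, W) layout throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # keep numpy from hijacking the operators

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # ------------------------------------------------------------------ infra

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad=None) -> None:
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep enough to blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # keep scalars in the operand's dtype so float32 graphs stay float32
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------- arithmetic ops

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    # ------------------------------------------------------- unary / nonlin

    def pow(self, exponent: float):
        """Elementwise power with a constant exponent."""
        out_data = self.data ** exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient is passed through only inside the band."""
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def maximum(self, other):
        """Elementwise maximum; ties route the gradient to `self`."""
        other = self._lift(other)
        take_self = self.data >= other.data
        out_data = np.where(take_self, self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * (~take_self), other.data.shape))

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------- shape ops

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        return self._make(out_data, (self,), backward)

    def pad2d(self, pads: tuple, value: float = 0.0):
        """Pad the trailing two axes by ((top, bottom), (left, right))."""
        (pt, pb), (pl, pr) = pads
        width = [(0, 0)] * (self.data.ndim - 2) + [(pt, pb), (pl, pr)]
        out_data = np.pad(self.data, width, mode="constant", constant_values=value)
        h, w = self.data.shape[-2:]

        def backward(g):
            self._accumulate(g[..., pt:pt + h, pl:pl + w])

        return self._make(out_data, (self,), backward)

    def crop2d(self, rows: tuple, cols: tuple):
        r0, r1 = rows
        c0, c1 = cols
        out_data = self.data[..., r0:r1, c0:c1]

        def backward(g):
            full = np.zeros_like(self.data)
            full[..., r0:r1, c0:c1] = g
            self._accumulate(full)

        return self._make(out_data, (self,), backward)

    @staticmethod
    def concat(tensors: list, axis: int = 1) -> "Tensor":
        tensors = [t if isinstance(t, Tensor) else Tensor(np.asarray(t))
                   for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(a, b)
                    t._accumulate(g[tuple(idx)])

        out = Tensor(out_data)
        if any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._parents = tuple(tensors)
            out._backward = backward
        return out

    # ------------------------------------------------------- softmax

    def softmax(self, axis: int = 1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        return self._make(s, (self,), backward)

    # ------------------------------------------------------- convolutions

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding=0):
        """Cross-correlation of (N,C,H,W) with (O,C,kh,kw) weights.

        `padding` is an int or (ph, pw); output spatial size is
        floor((H + 2p - k) / stride) + 1 on each axis.
        """
        if isinstance(padding, int):
            ph = pw = padding
        else:
            ph, pw = padding
        kh, kw = weight.data.shape[-2:]
        x = self.pad2d(((ph, ph), (pw, pw))) if (ph or pw) else self
        xd = x.data
        n = xd.shape[0]
        cols, (ho, wo) = _im2col(xd, kh, kw, stride)  # (N*Ho*Wo, C*kh*kw)
        o = weight.data.shape[0]
        wmat = weight.data.reshape(o, -1)
        out_data = (cols @ wmat.T).reshape(n, ho, wo, o)
        out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
        if bias is not None:
            out_data += bias.data[None, :, None, None]

        parents = (x, weight) + ((bias,) if bias is not None else ())

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
            if weight.requires_grad:
                weight._accumulate((g2.T @ cols).reshape(weight.data.shape))
            if x.requires_grad:
                x._accumulate(_conv_input_grad(g, weight.data, xd.shape,
                                               stride, kh, kw))

        return self._make(out_data, parents, backward)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor" = None, padding=0):
        """Per-channel (depthwise) stride-1 convolution; weight is (C,kh,kw)."""
        if isinstance(padding, int):
            ph = pw = padding
        else:
            ph, pw = padding
        kh, kw = weight.data.shape[-2:]
        x = self.pad2d(((ph, ph), (pw, pw))) if (ph or pw) else self
        xd = x.data
        win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
        out_data = np.einsum("nchwij,cij->nchw", win, weight.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]

        parents = (x, weight) + ((bias,) if bias is not None else ())

        def backward(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                weight._accumulate(
                    np.einsum("nchw,nchwij->cij", g, win, optimize=True))
            if x.requires_grad:
                wf = weight.data[:, ::-1, ::-1]
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gwin = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
                x._accumulate(np.einsum("nchwij,cij->nchw", gwin, wf, optimize=True))

        return self._make(out_data, parents, backward)

    # ------------------------------------------------------- pooling / resize

    def maxpool2x2(self):
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
        r = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            grad_flat = np.zeros_like(flat)
            np.put_along_axis(grad_flat, idx[..., None], g[..., None], axis=-1)
            grad = grad_flat.reshape(n, c, h // 2, w // 2, 2, 2)
            grad = grad.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            self._accumulate(grad)

        return self._make(out_data, (self,), backward)

    def avgpool2x2(self):
        n, c, h, w = self.data.shape
        out_data = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward(g):
            self._accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

        return self._make(out_data, (self,), backward)

    def upsample2x(self):
        """Nearest-neighbour doubling of the spatial axes."""
        out_data = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)
        n, c, h, w = self.data.shape

        def backward(g):
            self._accumulate(
                g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return self._make(out_data, (self,), backward)

    def maxpool3x3_stride1(self):
        """3x3 stride-1 max pool with implicit -inf border (shape preserved)."""
        p = self.pad2d(((1, 1), (1, 1)), value=-np.inf)
        h, w = self.data.shape[-2:]
        # horizontal then vertical pairwise maxima
        m = p.crop2d((0, h + 2), (0, w)) \
            .maximum(p.crop2d((0, h + 2), (1, w + 1))) \
            .maximum(p.crop2d((0, h + 2), (2, w + 2)))
        m = m.crop2d((0, h), (0, w)) \
            .maximum(m.crop2d((1, h + 1), (0, w))) \
            .maximum(m.crop2d((2, h + 2), (0, w)))
        return m


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int = 1):
    """(N,C,H,W) -> contiguous (N*Ho*Wo, C*kh*kw) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * kh * kw), (ho, wo)


def _conv_input_grad(g, w, x_shape, stride, kh, kw):
    """Gradient of conv2d w.r.t. its (padded) input, as a full correlation
    of the zero-stuffed output gradient with the flipped kernel."""
    n, o, ho, wo = g.shape
    _, c, hp, wp = x_shape
    if stride > 1:
        gs = np.zeros((n, o, (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                      dtype=g.dtype)
        gs[:, :, ::stride, ::stride] = g
    else:
        gs = g
    # rows/cols of the padded input never reached by a window still need zeros
    tail_h = hp - (gs.shape[2] + kh - 1)
    tail_w = wp - (gs.shape[3] + kw - 1)
    gp = np.pad(gs, ((0, 0), (0, 0),
                     (kh - 1, kh - 1 + tail_h), (kw - 1, kw - 1 + tail_w)))
    wf = w[:, :, ::-1, ::-1].reshape(o, c * kh * kw)
    gcols, (hg, wg) = _im2col(gp, kh, kw, 1)        # (N*Hp*Wp, O*kh*kw)
    gcols = gcols.reshape(n * hg * wg, o, kh * kw)
    # contract over output channels and kernel positions
    dx = gcols.reshape(n * hg * wg, o * kh * kw) @ \
        wf.reshape(o, c, kh * kw).transpose(0, 2, 1).reshape(o * kh * kw, c)
    return np.ascontiguousarray(
        dx.reshape(n, hg, wg, c).transpose(0, 3, 1, 2))
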