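"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the numerical substrate for the detection blocks and the
desk-scale detector: a :class:`Tensor` wrapping an ``ndarray`` with a gradient
slot, a small set of differentiable primitives (broadcast arithmetic, matmul,
2-D convolution via im2col, pooling, patch unfolding, nearest-neighbour
upsampling, reductions, indexing, concatenation) and an SGD-with-momentum
optimizer.  Everything runs in float32 on a single thread and is deterministic
given the parameter values and inputs.

Design constraints:

* backward passes avoid per-pixel Python loops — convolution/unfold gradients
  loop only over the K*K kernel offsets;
* no operator fuses train/eval behaviour (dropout is implemented by the caller
  sampling a mask, so evaluation-mode determinism is structural, not modal).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if grad.shape[ax] != n:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------- autograd
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = _op(np.add(self.data, other.data), self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _op(-self.data, self)
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _op(np.multiply(self.data, other.data), self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _op(self.data / other.data, self, other)

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _sum_to_shape(-g * self.data / (other.data ** 2), other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _op(self.data ** p, self)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _op(np.matmul(self.data, other.data), self, other)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_sum_to_shape(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_sum_to_shape(gb, other.shape))

        out._backward = bw
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        y = np.exp(self.data)
        out = _op(y, self)
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = _op(np.log(self.data), self)
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = _op(y, self)
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (0.5 / np.maximum(y, 1e-12))
        )
        return out

    def arctan(self):
        out = _op(np.arctan(self.data), self)
        out._backward = lambda g: self.requires_grad and self._accum(
            g / (1.0 + self.data ** 2)
        )
        return out

    def minimum(self, other: "Tensor"):
        return self - (self - other).relu()

    def maximum(self, other: "Tensor"):
        return self + (other - self).relu()

    def sigmoid(self):
        y = stable_sigmoid(self.data)
        out = _op(y, self)
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1 - y))
        return out

    def silu(self):
        s = stable_sigmoid(self.data)
        out = _op(self.data * s, self)
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (s * (1 + self.data * (1 - s)))
        )
        return out

    def relu(self):
        mask = self.data > 0
        out = _op(self.data * mask, self)
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out = _op(np.clip(self.data, lo, hi), self)
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _op(self.data.sum(axis=axis, keepdims=keepdims), self)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(DTYPE))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        out_data = y if keepdims or axis is None else np.squeeze(y, axis=axis)
        if axis is None and not keepdims:
            out_data = out_data.reshape(())
        out = _op(out_data, self)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            mask = self.data == y
            # split gradient among ties to keep the op well-defined
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accum((mask / counts) * g)

        out._backward = bw
        return out

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        out = _op(self.data.reshape(*shape), self)
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape)
        )
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim - 1, -1, -1))
        out = _op(self.data.transpose(*axes), self)
        inv = np.argsort(axes)
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _op(self.data[idx], self)

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(parents)
    return out


# ------------------------------------------------------------------ functions
def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = _op(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last dimension."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gamma + beta


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits; numerically stable primitive.

    loss = mean( max(x,0) - x*t + log(1+exp(-|x|)) ),  d/dx = (sigmoid(x)-t)/n
    """
    t = np.asarray(targets, dtype=DTYPE)
    x = logits.data
    per = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = _op(np.asarray(per.mean(), dtype=DTYPE), logits)

    def bw(g):
        if logits.requires_grad:
            sig = stable_sigmoid(x)
            logits._accum(g * (sig - t) / x.size)

    out._backward = bw
    return out


def _pad_nchw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def unfold(x: Tensor, kernel: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Extract K*K patches: (N,C,H,W) -> (N, C, K*K, Ho, Wo)."""
    xp = _pad_nchw(x.data, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,K,K)
    n, c, ho, wo = win.shape[:4]
    data = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c, kernel * kernel, ho, wo)
    out = _op(np.ascontiguousarray(data), x)

    def bw(g):
        if not x.requires_grad:
            return
        g = g.reshape(n, c, kernel, kernel, ho, wo)
        gx = np.zeros_like(xp)
        for ki in range(kernel):
            for kj in range(kernel):
                gx[:, :, ki:ki + ho * stride:stride, kj:kj + wo * stride:stride] += g[
                    :, :, ki, kj
                ]
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        x._accum(gx)

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square kernel. w: (Co, Ci, K, K)."""
    co, ci, k, _ = w.shape
    cols = unfold(x, k, stride=stride, pad=pad)  # (N, Ci, K*K, Ho, Wo)
    n, _, _, ho, wo = cols.shape
    cols2 = cols.reshape(n, ci * k * k, ho * wo)
    wmat = w.reshape(co, ci * k * k)
    y = (wmat @ cols2).reshape(n, co, ho, wo)
    if b is not None:
        y = y + b.reshape(1, co, 1, 1)
    return y


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None, pad: int = 0) -> Tensor:
    stride = stride or kernel
    xp = _pad_nchw(x.data, pad)
    if pad:
        xp = xp.copy()
        xp[:, :, :pad, :] = -np.inf
        xp[:, :, -pad:, :] = -np.inf
        xp[:, :, :, :pad] = -np.inf
        xp[:, :, :, -pad:] = -np.inf
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,K,K)
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = _op(y, x)

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        hi = (np.arange(ho) * stride)[None, None, :, None] + ki
        wi = (np.arange(wo) * stride)[None, None, None, :] + kj
        ni = np.arange(n)[:, None, None, None]
        ci_ = np.arange(c)[None, :, None, None]
        np.add.at(gx, (ni, ci_, hi, wi), g)
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        x._accum(gx)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    y = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = _op(y, x)
    n, c, h, w = x.shape

    def bw(g):
        if not x.requires_grad:
            return
        g = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        x._accum(g)

    out._backward = bw
    return out


def upsample_bilinear(x: Tensor, factor: int = 2) -> Tensor:
    """Bilinear upsampling (align_corners=False convention); the gradient is
    the transpose scatter of the four corner weights."""
    n, c, h, w = x.shape
    ho, wo = h * factor, w * factor
    src_i = (np.arange(ho) + 0.5) / factor - 0.5
    src_j = (np.arange(wo) + 0.5) / factor - 0.5
    i0 = np.clip(np.floor(src_i).astype(int), 0, h - 1)
    j0 = np.clip(np.floor(src_j).astype(int), 0, w - 1)
    i1 = np.clip(i0 + 1, 0, h - 1)
    j1 = np.clip(j0 + 1, 0, w - 1)
    wi = np.clip(src_i - i0, 0, 1).astype(DTYPE)
    wj = np.clip(src_j - j0, 0, 1).astype(DTYPE)
    wi_ = wi[:, None]
    wj_ = wj[None, :]
    d = x.data
    y = (
        d[:, :, i0][:, :, :, j0] * (1 - wi_) * (1 - wj_)
        + d[:, :, i1][:, :, :, j0] * wi_ * (1 - wj_)
        + d[:, :, i0][:, :, :, j1] * (1 - wi_) * wj_
        + d[:, :, i1][:, :, :, j1] * wi_ * wj_
    )
    out = _op(y, x)

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(d)
        ni = np.arange(n)[:, None, None, None]
        ch = np.arange(c)[None, :, None, None]
        for ii, iw in ((i0, 1 - wi), (i1, wi)):
            for jj, jw in ((j0, 1 - wj), (j1, wj)):
                contrib = g * iw[None, None, :, None] * jw[None, None, None, :]
                np.add.at(gx, (ni, ch, ii[None, None, :, None],
                               jj[None, None, None, :]), contrib)
        x._accum(gx)

    out._backward = bw
    return out


# ------------------------------------------------------------------- modules
class Module:
    """Tiny module base: named parameters, recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)
    elif isinstance(v, dict):
        for item in v.values():
            yield from _collect(item)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
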