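"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supplies exactly the primitives the 3D segmentation network needs: broadcasted
arithmetic, log/exp/relu/clamp, reductions, same-padded 3D convolution
(via im2col), 2x max-pooling, 2x nearest-neighbour upsampling, channel
concatenation, and an Adam optimizer. Volumes are laid out channel-first,
(C, D, H, W), one sample at a time. Tensors default to float64 so that
analytic gradients check against central finite differences tightly;
training loops may switch to float32 (see :func:`default_dtype`) for speed.
"""

from __future__ import annotations

import contextlib

import numpy as np

_DEFAULT_DTYPE = np.dtype(np.float64)


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are created with (float64 or float32).
    float64 is the default (tight gradient checks); float32 roughly halves
    training time at phantom scale."""
    global _DEFAULT_DTYPE
    dt = np.dtype(dtype)
    if dt not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dt


def get_default_dtype() -> np.dtype:
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily switch the tensor dtype (used by training loops)."""
    prev = _DEFAULT_DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * self._coerce(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        def bw(g):
            if self.requires_grad:
                self.grad += g * exponent * np.power(self.data, exponent - 1.0)

        return Tensor._make(np.power(self.data, exponent), (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g / self.data

        return Tensor._make(np.log(self.data), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * out_data

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor._make(self.data * mask, (self,), bw)

    def clamp_min(self, lo: float):
        """max(x, lo); gradient is zero where the clamp is active."""
        mask = self.data >= lo

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor._make(np.maximum(self.data, lo), (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return Tensor._make(self.data.reshape(*shape), (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def _im2col(x: np.ndarray, ks: int) -> np.ndarray:
    """(C, D, H, W) -> windows (C, D, H, W, ks, ks, ks) with same padding."""
    pad = ks // 2
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    return np.lib.stride_tricks.sliding_window_view(xp, (ks, ks, ks), axis=(1, 2, 3))


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded, stride-1 3D convolution (cross-correlation).

    x: (C_in, D, H, W); weight: (C_out, C_in, k, k, k); bias: (C_out,).
    """
    ks = weight.data.shape[-1]
    cols = _im2col(x.data, ks)
    out_data = np.tensordot(weight.data, cols, axes=([1, 2, 3, 4], [0, 4, 5, 6]))
    if bias is not None:
        out_data = out_data + bias.data[:, None, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if weight.requires_grad:
            weight.grad += np.tensordot(g, cols, axes=([1, 2, 3], [1, 2, 3]))
        if bias is not None and bias.requires_grad:
            bias.grad += g.sum(axis=(1, 2, 3))
        if x.requires_grad:
            # dX = full correlation of g with the spatially flipped,
            # channel-swapped kernel; valid because stride 1, same padding
            w_flip = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            gcols = _im2col(g, ks)
            x.grad += np.tensordot(w_flip, gcols, axes=([1, 2, 3, 4], [0, 4, 5, 6]))

    return Tensor._make(out_data, parents, bw)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2; first-occurrence tie-break."""
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    blocks = (
        x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, d // 2, h // 2, w // 2, 8)
    )
    arg = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=-1)
        x.grad += (
            gb.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )

    return Tensor._make(out_data, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along the three spatial axes."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        if not x.requires_grad:
            return
        c, d, h, w = x.data.shape
        x.grad += g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))

    return Tensor._make(out_data, (x,), bw)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 0 (label channels), numerically shifted."""
    shift = Tensor(x.data.max(axis=0, keepdims=True))  # constant, detached
    e = (x - shift).exp()
    return e / e.sum(axis=0, keepdims=True)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
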