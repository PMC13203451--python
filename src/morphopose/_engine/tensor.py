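"""Minimal reverse-mode autodiff on NumPy arrays.

The package trains small convolutional and attention networks on CPU; this
module supplies the tape: a :class:`Tensor` wrapping an ``ndarray`` plus the
elementwise / linear-algebra primitives with hand-written VJPs.  Convolution
and pooling live in :mod:`morphopose._engine.conv`.

Gradients are accumulated (``+=``) so a value used twice receives the sum of
both contributions; ``backward`` runs a topological sort of the tape.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other, self.dtype), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _needs(*tensors):
    return any(isinstance(t, Tensor) and t.requires_grad for t in tensors)


def _make(data, parents, backward):
    out = Tensor(data, requires_grad=_needs(*parents))
    if out.requires_grad:
        out._prev = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(data, (a, b), backward)


def power(a, p: float):
    a = as_tensor(a)
    data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1))

    return _make(data, (a,), backward)


def exp(a):
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), backward)


def log(a):
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a):
    return power(a, 0.5)


def arctan(a):
    a = as_tensor(a)
    data = np.arctan(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / (1.0 + a.data ** 2))

    return _make(data, (a,), backward)


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = np.maximum(a.data, b.data)

    def backward(g):
        mask = (a.data >= b.data).astype(g.dtype)
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(data, (a, b), backward)


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = np.minimum(a.data, b.data)

    def backward(g):
        mask = (a.data <= b.data).astype(g.dtype)
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(data, (a, b), backward)


def clip(a, lo, hi):
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)

    def backward(g):
        if a.requires_grad:
            mask = ((a.data >= lo) & (a.data <= hi)).astype(g.dtype)
            a._accum(g * mask)

    return _make(data, (a,), backward)


# -- activations -----------------------------------------------------------

def sigmoid(a):
    a = as_tensor(a)
    x = a.data
    data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))

    def backward(g):
        if a.requires_grad:
            a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def tanh(a):
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - data ** 2))

    return _make(data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (a.data > 0))

    return _make(data, (a,), backward)


def silu(a):
    a = as_tensor(a)
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    data = x * s

    def backward(g):
        if a.requires_grad:
            a._accum(g * (s * (1.0 + x * (1.0 - s))))

    return _make(data, (a,), backward)


def softplus(a):
    a = as_tensor(a)
    x = a.data
    data = np.where(x > 20, x, np.log1p(np.exp(np.minimum(x, 20))))

    def backward(g):
        if a.requires_grad:
            s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(np.minimum(x, 0)) / (1.0 + np.exp(np.minimum(x, 0))))
            a._accum(g * s)

    return _make(data, (a,), backward)


def softmax(a, axis=-1):
    a = as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accum(data * (g - dot))

    return _make(data, (a,), backward)


# -- shape / indexing ------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def transpose(a, axes):
    a = as_tensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    if not axes:
        axes = tuple(reversed(range(a.ndim)))
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def take(a, idx):
    a = as_tensor(a)
    data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(data, tensors, backward)


def pad2d(a, pad):
    """Zero-pad the last two axes by ``pad`` on each side."""
    a = as_tensor(a)
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    data = np.pad(a.data, width)

    def backward(g):
        if a.requires_grad:
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            a._accum(g[sl])

    return _make(data, (a,), backward)


# -- reductions / linear algebra ------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(a, axis, keepdims=False):
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data)
    # split ties evenly so the VJP stays a valid subgradient
    mask = mask / mask.sum(axis=axis, keepdims=True)
    out_data = data if keepdims else np.squeeze(data, axis=axis)

    def backward(g):
        if a.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(g * mask)

    return _make(out_data, (a,), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)
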