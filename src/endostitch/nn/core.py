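"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The trainable parts of the stitcher (homography regression, fusion branches)
need gradients through convolutions, bilinear sampling and a linear solve.
This module provides a small define-by-run tape: a :class:`Tensor` wraps an
``ndarray`` and records a backward closure per operation.  Arrays are NCHW
throughout the network code.  float32 is the working precision for network
weights; ops preserve the dtype of their inputs so float64 graphs can be
built for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, parents=(), bwd=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._bwd = bwd

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, self.dtype)
        )
        for t in reversed(topo):
            if t._bwd is not None and t.grad is not None:
                t._bwd(t.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        a, b = self, as_tensor(other)
        out_data = a.data + b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return _node(out_data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return _node(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return _node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return _node(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return _node(a.data**p, (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

        return _node(a.data[idx], (a,), bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return _node(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return _node(a.data.transpose(axes), (a,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities -------------------------------------------
    def abs(self):
        a = self
        s = np.sign(a.data)

        def bwd(g):
            a._accum(g * s)

        return _node(np.abs(a.data), (a,), bwd)

    def relu(self):
        a = self
        m = a.data > 0

        def bwd(g):
            a._accum(g * m)

        return _node(a.data * m, (a,), bwd)

    def leaky_relu(self, slope: float = 0.1):
        a = self
        s = a.dtype.type(slope)
        neg = a.data < 0

        def bwd(g):
            gg = g.copy()
            gg[neg] *= s
            a._accum(gg)

        return _node(np.maximum(a.data, 0) + s * np.minimum(a.data, 0), (a,), bwd)

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accum(g * y * (1.0 - y))

        return _node(y, (a,), bwd)

    def tanh(self):
        a = self
        y = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - y * y))

        return _node(y, (a,), bwd)

    def clip01(self):
        """Clamp to [0,1]; gradient is zero outside the interval."""
        a = self
        m = (a.data >= 0.0) & (a.data <= 1.0)

        def bwd(g):
            a._accum(g * m)

        return _node(np.clip(a.data, 0.0, 1.0), (a,), bwd)

    def clamp_st(self, bound: float):
        """Hard clamp to [-bound, bound] with a straight-through gradient.

        The forward value is clipped (keeping downstream linear solves well
        conditioned) but the gradient passes unchanged, so an estimate pushed
        against the bound can always be pulled back by the loss — a saturating
        clamp would zero the gradient there and freeze training.
        """
        a = self

        def bwd(g):
            a._accum(g)

        return _node(np.clip(a.data, -bound, bound), (a,), bwd)

    def softmax(self, axis: int = 1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            a._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        return _node(y, (a,), bwd)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return _node(a.data @ b.data, (a, b), bwd)

    def __matmul__(self, other):
        return self.matmul(other)


def _node(data, inputs, bwd) -> Tensor:
    parents = tuple(p for p in inputs if p.requires_grad)
    if parents:
        return Tensor(data, requires_grad=True, parents=parents, bwd=bwd)
    return Tensor(data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    return _node(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)
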