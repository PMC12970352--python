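"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The whole model stack in this package (transformer encoder/decoder, MLP
projector, temporal convolution heads) is small enough that a plain NumPy
tensor with a recorded backward graph is fast and fully deterministic on a
single CPU.  Only the primitives the models actually need are implemented.

All data is kept in float64; gradients accumulate into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # --------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._node(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._node(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bwd(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._node(out_data, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data @ b.data

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._node(out_data, (a, b), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._node(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._node(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * 0.5 / out_data)

        return Tensor._node(out_data, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data ** 2))

        return Tensor._node(out_data, (a,), bwd)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))
        out_data = x * cdf

        def bwd(g):
            if a.requires_grad:
                pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
                a._accum(g * (cdf + x * pdf))

        return Tensor._node(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._node(a.data * mask, (a,), bwd)

    def softplus(self):
        """Numerically stable log(1 + exp(x))."""
        a = self
        x = a.data
        out_data = np.logaddexp(0.0, x)

        def bwd(g):
            if a.requires_grad:
                a._accum(g / (1.0 + np.exp(-x)))

        return Tensor._node(out_data, (a,), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if a.requires_grad:
                if axis is None:
                    a._accum(np.broadcast_to(g, a.data.shape).copy())
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._node(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # --------------------------------------------------------------- structure
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._node(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._node(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, key):
        a = self
        out_data = a.data[key]

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)

        return Tensor._node(out_data, (a,), bwd)

    def softmax(self, axis: int = -1):
        a = self
        x = a.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if a.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                a._accum(s * (g - dot))

        return Tensor._node(s, (a,), bwd)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        """Stable log-sum-exp with exact gradient (softmax of inputs)."""
        a = self
        x = a.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        se = e.sum(axis=axis, keepdims=True)
        out_data = (np.log(se) + m)
        soft = e / se
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bwd(g):
            if a.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(g * soft)

        return Tensor._node(out_data, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def bwd(g):
        start = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + n)
                t._accum(g[tuple(sl)])
            start += n

    return Tensor._node(out_data, tuple(tensors), bwd)
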