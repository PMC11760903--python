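"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's learnable components (the CAGS attention block and the tiny
reference detector) need gradients of scalar losses with respect to both
feature maps and convolution weights.  This module provides a small,
self-contained tape-based engine: a :class:`Tensor` wraps an ``ndarray``,
records the operations applied to it, and ``backward()`` accumulates
gradients by reverse topological traversal.

Only the primitives the package needs are implemented (elementwise
arithmetic, the transcendentals used by the box losses, reductions,
reshaping, slicing, concatenation and matrix multiplication).  Every
dispatching helper (``exp``, ``maximum`` ...) accepts either a plain
``ndarray`` (returning an ``ndarray``) or a :class:`Tensor`, so numeric code
can be written once and evaluated with or without gradient tracking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "is_tensor",
    "asdata",
    "detach",
    "exp",
    "log",
    "sqrt",
    "sin",
    "arcsin",
    "arctan",
    "sigmoid",
    "silu",
    "absolute",
    "maximum",
    "minimum",
    "clip",
    "where",
    "concatenate",
    "stack",
    "matmul",
    "tsum",
    "tmean",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the Tensor reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += _unbroadcast(g, self.data.shape)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)

        def back(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=back)

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other)

        def back(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=back)

    __rmul__ = __mul__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=back)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __truediv__(self, other):
        other = _wrap(other)

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, _parents=(self, other), _backward=back)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def back(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, _parents=(self,), _backward=back)

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def back(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=back)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=back)

    def __getitem__(self, idx):
        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=back)

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def asdata(x) -> np.ndarray:
    """Underlying ndarray of `x`, whether Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def detach(x):
    """Value of `x` with the tape cut (gradients do not flow through)."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unary(x, fn, dfn):
    if not isinstance(x, Tensor):
        return fn(np.asarray(x, dtype=np.float64))
    y = fn(x.data)

    def back(g):
        x._accum(g * dfn(x.data, y))

    return Tensor(y, _parents=(x,), _backward=back)


def exp(x):
    return _unary(x, np.exp, lambda d, y: y)


def log(x):
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, y: 0.5 / np.maximum(y, 1e-300))


def sin(x):
    return _unary(x, np.sin, lambda d, y: np.cos(d))


def arcsin(x):
    # derivative guarded near |x| = 1; exact endpoint is a degenerate input
    return _unary(x, np.arcsin, lambda d, y: 1.0 / np.sqrt(np.maximum(1.0 - d * d, 1e-12)))


def arctan(x):
    return _unary(x, np.arctan, lambda d, y: 1.0 / (1.0 + d * d))


def _sigmoid_np(d):
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ez = np.exp(d[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x):
    return _unary(x, lambda d: _sigmoid_np(np.asarray(d)), lambda d, y: y * (1.0 - y))


def silu(x):
    """Sigmoid-weighted linear unit, x * sigmoid(x)."""
    return x * sigmoid(x)


def absolute(x):
    return _unary(x, np.abs, lambda d, y: np.sign(d))


def maximum(a, b):
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.maximum(a, b)
    a, b = _wrap(a), _wrap(b)
    mask = a.data >= b.data

    def back(g):
        a._accum(g * mask)
        b._accum(g * (~mask))

    return Tensor(np.maximum(a.data, b.data), _parents=(a, b), _backward=back)


def minimum(a, b):
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.minimum(a, b)
    a, b = _wrap(a), _wrap(b)
    mask = a.data <= b.data

    def back(g):
        a._accum(g * mask)
        b._accum(g * (~mask))

    return Tensor(np.minimum(a.data, b.data), _parents=(a, b), _backward=back)


def clip(x, lo: float, hi: float):
    """Clamp to [lo, hi]; gradient is zero outside the open interval."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    inside = (x.data > lo) & (x.data < hi)

    def back(g):
        x._accum(g * inside)

    return Tensor(np.clip(x.data, lo, hi), _parents=(x,), _backward=back)


def where(cond, a, b):
    cond = np.asarray(cond, dtype=bool)
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.where(cond, a, b)
    a, b = _wrap(a), _wrap(b)

    def back(g):
        a._accum(np.where(cond, g, 0.0))
        b._accum(np.where(cond, 0.0, g))

    return Tensor(np.where(cond, a.data, b.data), _parents=(a, b), _backward=back)


def concatenate(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [_wrap(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([p.data for p in parts], axis=axis),
        _parents=tuple(parts),
        _backward=back,
    )


def stack(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.stack(parts, axis=axis)
    parts = [_wrap(p) for p in parts]

    def back(g):
        for i, p in enumerate(parts):
            p._accum(np.take(g, i, axis=axis))

    return Tensor(np.stack([p.data for p in parts], axis=axis), _parents=tuple(parts), _backward=back)


def matmul(a, b):
    if not (isinstance(a, Tensor) or isinstance(b, Tensor)):
        return np.asarray(a) @ np.asarray(b)
    a, b = _wrap(a), _wrap(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def back(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return Tensor(a.data @ b.data, _parents=(a, b), _backward=back)


def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)
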