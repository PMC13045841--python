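"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The training stack needs gradients through layer normalisation, multi-head
(self/cross) attention and the sigmoid/BCE head.  No autodiff library is a
runtime dependency of this package, so a small tape-based engine is provided
here.  Every op keeps the NumPy array semantics of its forward pass; the
functional helpers (`relu`, `softmax_last`, ...) transparently accept plain
ndarrays and return ndarrays, so the same model code runs with or without a
gradient tape.

All fused backward formulas (softmax, layer norm) are covered by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Adam",
    "as_tensor",
    "concat",
    "gather_rows",
    "layernorm_last",
    "log",
    "matmul",
    "mean",
    "relu",
    "sigmoid",
    "softmax_last",
    "softplus",
    "square",
    "sum_",
    "transpose",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` back down to `shape` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):  # only scalar division is needed
            raise TypeError("Tensor/Tensor division is not supported")
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_plain(*xs) -> bool:
    return not any(isinstance(x, Tensor) for x in xs)


# -- ops ----------------------------------------------------------------------

def matmul(a, b):
    if _is_plain(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bwd(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = bwd
    return out


def transpose(a):
    if _is_plain(a):
        return np.swapaxes(np.asarray(a), -1, -2)
    out = Tensor(np.swapaxes(a.data, -1, -2), _parents=(a,))
    out._backward = lambda g: a._accumulate(np.swapaxes(g, -1, -2))
    return out


def relu(a):
    if _is_plain(a):
        return np.maximum(np.asarray(a), 0.0)
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))
    out._backward = lambda g: a._accumulate(g * (a.data > 0.0))
    return out


def sigmoid(a):
    if _is_plain(a):
        x = np.asarray(a, dtype=np.float64)
        return 0.5 * (1.0 + np.tanh(0.5 * x))
    y = 0.5 * (1.0 + np.tanh(0.5 * a.data))
    out = Tensor(y, _parents=(a,))
    out._backward = lambda g: a._accumulate(g * y * (1.0 - y))
    return out


def softplus(a):
    """log(1 + exp(x)), numerically stable."""
    if _is_plain(a):
        x = np.asarray(a, dtype=np.float64)
        return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    y = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
    s = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # sigmoid(x) = d softplus / dx
    out = Tensor(y, _parents=(a,))
    out._backward = lambda g: a._accumulate(g * s)
    return out


def log(a):
    if _is_plain(a):
        return np.log(np.asarray(a))
    out = Tensor(np.log(a.data), _parents=(a,))
    out._backward = lambda g: a._accumulate(g / a.data)
    return out


def square(a):
    if _is_plain(a):
        x = np.asarray(a)
        return x * x
    out = Tensor(a.data * a.data, _parents=(a,))
    out._backward = lambda g: a._accumulate(2.0 * g * a.data)
    return out


def sum_(a, axis=None, keepdims=False):
    if _is_plain(a):
        return np.sum(np.asarray(a), axis=axis, keepdims=keepdims)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def bwd(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = bwd
    return out


def mean(a, axis=None, keepdims=False):
    if _is_plain(a):
        return np.mean(np.asarray(a), axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else a.data.shape[axis]
    return sum_(a, axis=axis, keepdims=keepdims) / n


def concat(parts, axis=-1):
    if _is_plain(*parts):
        return np.concatenate([np.asarray(p) for p in parts], axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]

    def bwd(g):
        offs = np.cumsum([0] + sizes)
        for p, lo, hi in zip(parts, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            p._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


def softmax_last(a):
    """Softmax along the last axis."""
    if _is_plain(a):
        x = np.asarray(a, dtype=np.float64)
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)
    e = np.exp(a.data - a.data.max(axis=-1, keepdims=True))
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, _parents=(a,))

    def bwd(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        a._accumulate(y * (g - dot))

    out._backward = bwd
    return out


def layernorm_last(a, eps: float = 1e-5):
    """Zero-mean, unit-variance normalisation along the last axis (no affine)."""
    if _is_plain(a):
        x = np.asarray(a, dtype=np.float64)
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps)
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (a.data - mu) * inv
    out = Tensor(y, _parents=(a,))

    def bwd(g):
        gm = g.mean(axis=-1, keepdims=True)
        gy = (g * y).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - y * gy))

    out._backward = bwd
    return out


def gather_rows(table, ids):
    """Row lookup `table[ids]`; backward scatter-adds into the table."""
    ids = np.asarray(ids, dtype=np.intp)
    if _is_plain(table):
        return np.asarray(table)[ids]
    out = Tensor(table.data[ids], _parents=(table,))

    def bwd(g):
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, ids, g)

    out._backward = bwd
    return out


# -- optimiser ----------------------------------------------------------------

class Adam:
    """Adam optimiser over a flat dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
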