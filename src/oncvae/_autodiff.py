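"""Compact reverse-mode automatic differentiation on numpy arrays.

The networks in this package are a handful of dense layers, so a small
tape-based engine is all that is needed.  Every operation records a
vector-Jacobian product closure; :meth:`Tensor.backward` replays them in
reverse topological order.  Gradients of every primitive are checked against
central finite differences in the test suite.

Only float64 is used, which keeps training bit-reproducible across runs on
the same platform.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import gammaln as _gammaln

__all__ = ["Tensor", "Adam"]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    # make numpy defer binary ops to Tensor's reflected methods
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for p, vjp in zip(node._parents, node._vjps):
                if not p.requires_grad:
                    continue
                contrib = vjp(g)
                p.grad = contrib if p.grad is None else p.grad + contrib

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), pow_(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __pow__(self, c):
        return pow_(self, c)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjps = tuple(vjps)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


# ------------------------------------------------------------------ primitives
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        (
            lambda g: _unbroadcast(g * b.data, a.shape),
            lambda g: _unbroadcast(g * a.data, b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, (a,), (lambda g: -g,))


def pow_(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)
    return _make(a.data**c, (a,), (lambda g: g * c * a.data ** (c - 1.0),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data @ b.data,
        (a, b),
        (lambda g: g @ b.data.T, lambda g: a.data.T @ g),
    )


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    return _make(out_data, (a,), (lambda g: g * out_data,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: g / a.data,))


def log1p(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log1p(a.data), (a,), (lambda g: g / (1.0 + a.data),))


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.sqrt(a.data)
    return _make(out_data, (a,), (lambda g: g * 0.5 / out_data,))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    return _make(s, (a,), (lambda g: g * s * (1.0 - s),))


def softplus(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    return _make(out_data, (a,), (lambda g: g * s,))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _make(a.data * mask, (a,), (lambda g: g * mask,))


def abs_(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.abs(a.data), (a,), (lambda g: g * np.sign(a.data),))


def lgamma(a) -> Tensor:
    a = as_tensor(a)
    return _make(_gammaln(a.data), (a,), (lambda g: g * _digamma(a.data),))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clip values; gradient is zero outside [lo, hi] (straight-through not used)."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)
    return _make(np.clip(a.data, lo, hi), (a,), (lambda g: g * mask,))


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.shape).copy()
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return np.broadcast_to(gg, a.shape).copy()

    return _make(out_data, (a,), (vjp,))


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    ex = np.exp(a.data - m)
    s = ex.sum(axis=axis, keepdims=True)
    out_data = m + np.log(s)
    soft = ex / s
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def vjp(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        return gg * soft

    return _make(out_data, (a,), (vjp,))


def logaddexp(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.logaddexp(a.data, b.data)
    return _make(
        out_data,
        (a, b),
        (
            lambda g: _unbroadcast(g * np.exp(a.data - out_data), a.shape),
            lambda g: _unbroadcast(g * np.exp(b.data - out_data), b.shape),
        ),
    )


def take(a, idx) -> Tensor:
    """Row gather: out[i] = a[idx[i]]; gradient scatter-adds into `a`."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        z = np.zeros_like(a.data)
        np.add.at(z, idx, g)
        return z

    return _make(a.data[idx], (a,), (vjp,))


def where(mask: np.ndarray, a, b) -> Tensor:
    """Select by a *constant* boolean mask (the mask is not differentiated)."""
    a, b = as_tensor(a), as_tensor(b)
    mask = np.asarray(mask, dtype=bool)
    return _make(
        np.where(mask, a.data, b.data),
        (a, b),
        (
            lambda g: _unbroadcast(g * mask, a.shape),
            lambda g: _unbroadcast(g * (~mask), b.shape),
        ),
    )


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), (a,), (lambda g: g.reshape(a.shape),))


# ------------------------------------------------------------------- optimizer
class Adam:
    """Adam with optional decoupled weight decay on a subset of parameters."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        decay_keys: Sequence[str] = (),
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_keys = set(decay_keys)
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**self.t)
            vhat = self._v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0 and k in self.decay_keys:
                p.data -= self.lr * self.weight_decay * p.data
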