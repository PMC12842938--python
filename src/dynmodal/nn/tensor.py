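"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's tensor library: a dynamically-built computation graph
over float64 numpy arrays with exactly the primitives the model needs
(broadcast arithmetic, batched matmul, slicing, concatenation, reductions and
a handful of activations). Every primitive optionally reports an elementary
floating-point operation count to an active :class:`FlopCounter`, which is how
the analytic cost model and the linear-complexity checks are computed — by
counting, never by wall clock.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "FlopCounter",
    "count_flops",
    "no_grad",
    "concatenate",
    "stack",
    "softmax",
    "log_softmax",
    "gelu",
    "silu",
]

_ACTIVE_COUNTER: "FlopCounter | None" = None
_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class FlopCounter:
    """Accumulates elementary-operation counts while active."""

    def __init__(self) -> None:
        self.total = 0

    def add(self, n: int) -> None:
        self.total += int(n)


@contextmanager
def count_flops():
    """Context manager yielding a :class:`FlopCounter` wired into all primitives."""
    global _ACTIVE_COUNTER
    prev = _ACTIVE_COUNTER
    counter = FlopCounter()
    _ACTIVE_COUNTER = counter
    try:
        yield counter
    finally:
        _ACTIVE_COUNTER = prev


def _count(n: int) -> None:
    if _ACTIVE_COUNTER is not None:
        _ACTIVE_COUNTER.add(n)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, children: tuple, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        needs = _GRAD_ENABLED and any(
            isinstance(c, Tensor) and c.requires_grad for c in children
        )
        out.requires_grad = needs
        if needs:
            out._backward = backward
            out._prev = tuple(c for c in children if isinstance(c, Tensor))
        else:
            out._backward = None
            out._prev = ()
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        # first contribution is kept by reference (backward fns never mutate
        # their outputs in place); later ones allocate a fresh sum
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data
        _count(data.size)

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._result(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        data = -self.data
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data - other.data
        _count(data.size)

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape))

        return Tensor._result(data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data
        _count(data.size)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._result(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        data = self.data ** p
        _count(data.size)

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._result(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = np.matmul(self.data, other.data)
        # 2*m*k*n per batched product
        batch = int(np.prod(data.shape[:-2])) if data.ndim > 2 else 1
        m = data.shape[-2] if data.ndim >= 2 else 1
        n = data.shape[-1]
        k = self.data.shape[-1]
        _count(2 * batch * m * n * k)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                if a.ndim == 1:
                    return (g * b, g * a)
                ga = np.expand_dims(g, -1) * b
                gb = (a * np.expand_dims(g, -1)).reshape(-1, b.shape[0]).sum(0)
                return (_unbroadcast(ga, a.shape), gb)
            if a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
                return (
                    _unbroadcast(ga, a.shape),
                    _unbroadcast(gb, b.shape),
                )
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._result(data, (self, other), backward)

    # -- unary nonlinearities --------------------------------------------------

    def exp(self):
        data = np.exp(self.data)
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (g * data,))

    def log(self):
        data = np.log(self.data)
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (g / self.data,))

    def tanh(self):
        data = np.tanh(self.data)
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (g * (1.0 - data ** 2),))

    def sigmoid(self):
        data = _sp.expit(self.data)
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (g * data * (1.0 - data),))

    def relu(self):
        data = np.maximum(self.data, 0.0)
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (g * (self.data > 0),))

    def erf(self):
        data = _sp.erf(self.data)
        _count(data.size)

        def backward(g):
            return (g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2),)

        return Tensor._result(data, (self,), backward)

    def softplus(self):
        data = np.logaddexp(0.0, self.data)
        _count(data.size)
        return Tensor._result(data, (self,), lambda g: (g * _sp.expit(self.data),))

    # -- reductions / shape ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        _count(self.data.size)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._result(np.asarray(data), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        src = self.data.shape
        return Tensor._result(data, (self,), lambda g: (g.reshape(src),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        data = self.data.transpose(axes)
        inv = np.argsort(axes)
        return Tensor._result(data, (self,), lambda g: (g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        data = self.data.swapaxes(a, b)
        return Tensor._result(data, (self,), lambda g: (g.swapaxes(a, b),))

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            return (buf,)

        return Tensor._result(np.asarray(data), (self,), backward)

    # -- autodiff driver -------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
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
            for child in node._prev:
                if child.requires_grad and id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for child, g in zip(node._prev, grads):
                if child.requires_grad and g is not None:
                    child._accumulate(g)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- free functions -----------------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._result(data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return Tensor._result(data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max: forward-identical, gradient-exact away from ties
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    return x * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0) * 0.5


def silu(x: Tensor) -> Tensor:
    return x * x.sigmoid()
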