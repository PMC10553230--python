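"""Minimal reverse-mode automatic differentiation over numpy arrays.

The benchmark's models are small (two fully-connected layers per network),
so a compact tape-based engine is sufficient: every op records its parents
and a closure that accumulates gradients; :meth:`Tensor.backward` walks the
tape in reverse topological order.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back down to the operand's shape (:func:`_unbroadcast`).

Module-level helpers (:func:`exp`, :func:`log`, :func:`tanh`, ...) dispatch
on input type, so the same loss-function code runs differentiably on
:class:`Tensor` inputs and as plain (fast) numpy on arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp as _np_logsumexp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # axes of size 1 that were stretched
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray op Tensor)
    __array_ufunc__ = None

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, value, parents, backward) -> "Tensor":
        out = cls(value, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.value + other.value, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._from_op(-self.value, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.value * other.value, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.value / other.value, (self, other), None)

        def backward(g):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor._from_op(self.value**exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.value ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor._from_op(self.value @ other.value, (self, other), None)

        def backward(g):
            return (g @ other.value.T, self.value.T @ g)

        out._backward = backward
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor._from_op(self.value.T, (self,), None)
        out._backward = lambda g: (g.T,)
        return out

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor._from_op(self.value.reshape(shape), (self,), None)
        out._backward = lambda g: (g.reshape(old),)
        return out

    def __getitem__(self, idx):
        out = Tensor._from_op(self.value[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self) -> "Tensor":
        val = np.exp(self.value)
        out = Tensor._from_op(val, (self,), None)
        out._backward = lambda g: (g * val,)
        return out

    def log(self) -> "Tensor":
        out = Tensor._from_op(np.log(self.value), (self,), None)
        out._backward = lambda g: (g / self.value,)
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.value)
        out = Tensor._from_op(val, (self,), None)
        out._backward = lambda g: (g * (1.0 - val**2),)
        return out

    def relu(self) -> "Tensor":
        mask = self.value > 0
        out = Tensor._from_op(np.where(mask, self.value, 0.0), (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor._from_op(self.value.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def logsumexp(self, axis, keepdims: bool = False) -> "Tensor":
        m = np.max(self.value, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        shifted = np.exp(self.value - m)
        denom = shifted.sum(axis=axis, keepdims=True)
        val = np.log(denom) + m
        if not keepdims:
            val = np.squeeze(val, axis=axis)
        soft = shifted / denom
        out = Tensor._from_op(val, (self,), None)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * soft,)

        out._backward = backward
        return out

    # ---- backward pass ---------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + pg

    def zero_grad(self) -> None:
        self.grad = None


# ---- type-dispatching functional API ------------------------------------

def _is_t(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(x, 0.0)


def square(x):
    return x**2


def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def tmean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def logsumexp(x, axis, keepdims=False):
    if isinstance(x, Tensor):
        return x.logsumexp(axis=axis, keepdims=keepdims)
    return _np_logsumexp(x, axis=axis, keepdims=keepdims)


def softmax(x, axis=-1):
    z = x - (x.logsumexp(axis, keepdims=True) if isinstance(x, Tensor)
             else _np_logsumexp(x, axis=axis, keepdims=True))
    return exp(z)


def value_of(x) -> np.ndarray:
    """Concrete numpy value of a Tensor or array-like."""
    return x.value if isinstance(x, Tensor) else np.asarray(x)


def as_float(x) -> float:
    return float(x.value) if isinstance(x, Tensor) else float(x)
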