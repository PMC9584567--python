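"""Minimal reverse-mode automatic differentiation on numpy arrays.

The drug-interaction network in :mod:`mvddi.model` is small enough (hundreds
of drugs, dense graphs) that full-batch gradient descent on dense numpy
arrays is the natural fit.  This module provides the only machinery that
requires: a :class:`Tensor` wrapping an ``ndarray`` with a backward graph,
the handful of differentiable primitives the model uses, and an Adam
optimizer.  It is deliberately tiny — no GPU, no broadcasting corner cases
beyond what numpy itself defines, no in-place mutation of graph nodes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(_as_array(other))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    @property
    def T(self) -> "Tensor":
        return Tensor._from_op(self.data.T, (self,), lambda g: (g.T,))

    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Gather rows (axis 0) by integer index; gradients accumulate."""
        idx = np.asarray(idx, dtype=np.intp)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._from_op(
            self.data * factor, (self,), lambda g: (g * factor,)
        )

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return Tensor._from_op(
            out_data, (self,), lambda g: (g * (1.0 - out_data**2),)
        )

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        return Tensor._from_op(
            np.log(self.data), (self,), lambda g: (g / self.data,)
        )

    def sqrt(self) -> "Tensor":
        """Square root; the gradient is guarded at 0 so exact zeros stay finite."""
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / np.maximum(out_data, 1e-12),)

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        return Tensor._from_op(
            np.abs(self.data), (self,), lambda g: (g * sign,)
        )

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient passes only where x > lo (ties go to zero)."""
        mask = self.data > lo
        return Tensor._from_op(
            np.maximum(self.data, lo), (self,), lambda g: (g * mask,)
        )

    # -- autodiff -------------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep at many layers/epochs
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitives (max is detached)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors (Kingma & Ba defaults)."""

    def __init__(self, params: list[Tensor], lr: float = 0.003,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1**self.t)
            v_hat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
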