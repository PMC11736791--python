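"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: every :class:`Tensor` wraps a float64 ndarray and
remembers the operation that produced it, so a single call to
:meth:`Tensor.backward` accumulates gradients through arbitrary compositions
of the primitives below (matmul, broadcasting arithmetic, reductions,
elementwise nonlinearities, slicing, concatenation).

Gradients are exact (validated against central finite differences in the
test suite); there is no graph optimisation or operator fusion — clarity and
correctness over speed. All model code in this package builds on these
primitives.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward
        self.name = name

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # --------------------------------------------------------------- helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, _prev=(self, other))

        def _backward(g):
            if a.ndim == 2 and b.ndim == 2:
                ga, gb = g @ b.T, a.T @ g
            elif a.ndim == 2 and b.ndim == 1:
                ga, gb = np.outer(g, b), a.T @ g
            elif a.ndim == 1 and b.ndim == 2:
                ga, gb = b @ g, np.outer(a, g)
            elif a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            else:  # pragma: no cover - models use <=2-D operands
                raise NotImplementedError("matmul backward for ndim > 2")
            if self.requires_grad:
                self._accumulate(ga)
            if other.requires_grad:
                other._accumulate(gb)

        out._backward = _backward
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = _backward
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = _backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = _backward
        return out

    # --------------------------------------------------------- shape surgery
    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = _backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = _backward
        return out

    # --------------------------------------------------------------- driver
    def backward(self):
        """Back-propagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: model graphs can be deep
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._prev:
                    if id(p) not in seen:
                        stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        self._accumulate(grads[id(self)])
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (max-shift treated as constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
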