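"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains recurrent networks by gradient descent, so it needs
reverse-mode differentiation through a dynamically built computation graph
(sequence length varies per batch).  This module provides exactly the op set
the models use — broadcasting add/mul/sub, matmul, sigmoid/tanh, basic-slice
indexing, reshape, stack, and axis sums — on float64 arrays.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks the
graph in reverse topological order.

Only basic (view) slices are supported by ``__getitem__``; that is all the
recurrent loop requires, and it keeps the backward pass a cheap ``+=`` into
the parent's gradient buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor.

        Seeds the output gradient with ones, which for the scalar losses used
        here is the ordinary derivative.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative post-order DFS
        path: list[tuple[Tensor, int]] = [(self, 0)]
        topo = []
        while path:
            node, idx = path.pop()
            if id(node) in seen:
                continue
            if idx < len(node._parents):
                path.append((node, idx + 1))
                child = node._parents[idx]
                if id(child) not in seen and child.requires_grad:
                    path.append((child, 0))
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _const(other) -> np.ndarray:
        return np.asarray(other, dtype=np.float64)

    def __add__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data + other.data, _parents=(self, other))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))

        else:
            c = self._const(other)
            out = Tensor(self.data + c, _parents=(self,))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -self._const(other))

    def __rsub__(self, other):
        return (-self) + self._const(other)

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data, _parents=(self, other))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))

        else:
            c = self._const(other)
            out = Tensor(self.data * c, _parents=(self,))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * c, self.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported; multiply by a constant reciprocal")
        return self * (1.0 / self._const(other))

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def square(self):
        out = Tensor(self.data * self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(2.0 * self.data * g)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[idx] += g

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Stack same-shaped tensors along a new axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw(g):
        pieces = np.moveaxis(g, axis, 0)
        for t, gt in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(gt)

    out._backward = bw
    return out
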