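"""Compact reverse-mode automatic differentiation on numpy arrays.

The flow layers in this package need exact gradients of scalar losses with
respect to a few dozen parameter tensors, over a small vocabulary of
operations (broadcasted arithmetic, batched matmul, elementwise
nonlinearities, reductions, reshapes, softmax, basic indexing).  This module
provides exactly that: a :class:`Tensor` wrapping a float64 ``ndarray`` that
records a computation graph and backpropagates through it.

Everything is float64.  Gradients for broadcasted operations are summed back
to the parent's shape.  Only the forward values are kept alive by the graph,
so evaluating a model on constant inputs and discarding the result is cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "relu", "sigmoid", "softmax", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from hijacking reflected arithmetic
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (any-shape) tensor with seed gradient 1."""
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                self._grad_if(g)
                other._grad_if(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._grad_if(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                self._grad_if(g * other.data)
                other._grad_if(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                self._grad_if(g / other.data)
                other._grad_if(-g * self.data / other.data ** 2)
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            a, b = self.data, other.data
            def bw(g):
                self._grad_if(g @ np.swapaxes(b, -1, -2))
                other._grad_if(np.swapaxes(a, -1, -2) @ g)
            out._backward = bw
        return out

    def _grad_if(self, g):
        if self.requires_grad:
            self._accumulate(g)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._grad_if(g * val)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._grad_if(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _node(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._grad_if(g * (1.0 - val ** 2))
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bw(g):
                if axis is None:
                    self._grad_if(np.broadcast_to(g, shape))
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._grad_if(np.broadcast_to(gg, shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._grad_if(g.reshape(orig))
        return out

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._grad_if(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            shape = self.data.shape
            def bw(g):
                full = np.zeros(shape)
                np.add.at(full, idx, g)
                self._grad_if(full)
            out._backward = bw
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out = _node(np.where(mask, x.data, 0.0), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._grad_if(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(val, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._grad_if(g * val * (1.0 - val))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)
    out = _node(val, (x,))
    if out.requires_grad:
        def bw(g):
            dot = (g * val).sum(axis=axis, keepdims=True)
            x._grad_if(val * (g - dot))
        out._backward = bw
    return out


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._grad_if(piece)
        out._backward = bw
    return out
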