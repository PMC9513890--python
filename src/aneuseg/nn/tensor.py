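"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` walks the recorded graph in reverse topological order and
accumulates gradients.  The op set is exactly what the segmentation networks
need: broadcasting arithmetic, reductions, a few pointwise nonlinearities,
channel concatenation, nearest-neighbour upsampling, and 3D convolution
(in :mod:`aneuseg.nn.functional`).  Everything is float32 and validated by
finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    # keep numpy from intercepting `ndarray <op> Tensor`
    __array_ufunc__ = None

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self) = 1)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        o = self._lift(other)
        out = Tensor.make(self.data + o.data, (self, o), None)
        if out.requires_grad:
            def backward(g):
                self._accum(_unbroadcast(g, self.data.shape))
                o._accum(_unbroadcast(g, o.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = self._lift(other)
        out = Tensor.make(self.data * o.data, (self, o), None)
        if out.requires_grad:
            def backward(g):
                self._accum(_unbroadcast(g * o.data, self.data.shape))
                o._accum(_unbroadcast(g * self.data, o.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        o = self._lift(other)
        return self * o ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor.make(self.data ** e, (self,), None)
        if out.requires_grad:
            def backward(g):
                self._accum(g * e * self.data ** (e - 1.0))
            out._backward = backward
        return out

    # -- reductions and reshapes ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor.make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def transpose(self, *axes):
        out = Tensor.make(self.data.transpose(*axes), (self,), None)
        if out.requires_grad:
            inv = tuple(np.argsort(axes))
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor.make(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g):
                gx = np.zeros_like(self.data)
                gx[idx] += g
                self._accum(gx)
            out._backward = backward
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor.make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    # -- pointwise nonlinearities ---------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor.make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor.make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor.make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def leaky_relu(self, slope: float = 0.01):
        pos = self.data > 0
        out = Tensor.make(np.where(pos, self.data, slope * self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.where(pos, g, slope * g))
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def softmax(self, axis: int = 1):
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor.make(val, (self,), None)
        if out.requires_grad:
            def backward(g):
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accum(val * (g - dot))
            out._backward = backward
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor.make(np.concatenate([t.data for t in tensors], axis=axis), tensors, None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
        out._backward = backward
    return out
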