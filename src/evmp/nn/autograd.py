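"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the small recurrent and attention encoders in
this package: a :class:`Tensor` wrapping an ndarray, a handful of primitive
ops with broadcasting-aware gradients, and topological-order backprop.  No
graphs are retained between calls; everything is eager and single-threaded,
which keeps training bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Optional[Callable[[Array], None]] = None):
        self.value = np.asarray(value, dtype=float)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += grad

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                current, parents = stack[-1]
                advanced = False
                for parent in parents:
                    if id(parent) not in seen and (
                        parent.requires_grad or parent._parents
                    ):
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(current)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- primitive ops -------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, _parents=(self, other))

        def backward(grad: Array) -> None:
            self._accumulate(_unbroadcast(grad, self.shape))
            other._accumulate(_unbroadcast(grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, _parents=(self,))
        out._backward = lambda grad: self._accumulate(-grad)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, _parents=(self, other))

        def backward(grad: Array) -> None:
            self._accumulate(_unbroadcast(grad * other.value, self.shape))
            other._accumulate(_unbroadcast(grad * self.value, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, _parents=(self, other))

        def backward(grad: Array) -> None:
            self._accumulate(_unbroadcast(grad / other.value, self.shape))
            other._accumulate(_unbroadcast(
                -grad * self.value / other.value ** 2, other.shape))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, _parents=(self, other))

        def backward(grad: Array) -> None:
            self._accumulate(grad @ np.swapaxes(other.value, -1, -2))
            og = np.swapaxes(self.value, -1, -2) @ grad
            other._accumulate(_unbroadcast(og, other.shape))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.value[key], _parents=(self,))

        def backward(grad: Array) -> None:
            full = np.zeros_like(self.value)
            np.add.at(full, key, grad)
            self._accumulate(full)

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        y = np.tanh(self.value)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad * (1 - y ** 2))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.value, -60, 60)))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad * y * (1 - y))
        return out

    def relu(self):
        mask = self.value > 0
        out = Tensor(self.value * mask, _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad * mask)
        return out

    def exp(self):
        y = np.exp(self.value)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad * y)
        return out

    def sqrt(self):
        y = np.sqrt(self.value)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad * 0.5 / y)
        return out

    def abs(self):
        sign = np.sign(self.value)
        out = Tensor(np.abs(self.value), _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad * sign)
        return out

    # -- reductions / shape ops ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def backward(grad: Array) -> None:
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad.reshape(self.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.value.ndim)))
        inverse = np.argsort(axes)
        out = Tensor(self.value.transpose(axes), _parents=(self,))
        out._backward = lambda grad: self._accumulate(grad.transpose(inverse))
        return out

    def softmax(self, axis: int = -1):
        # Max-shift is treated as a constant: it does not change the value or
        # the gradient of softmax.
        shifted = self - Tensor(self.value.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(sl)])

    out._backward = backward
    return out


def unbind(x: Tensor, axis: int = 1) -> list[Tensor]:
    """Split `x` into views along `axis`; gradients accumulate in place into
    a single shared buffer (cheaper than repeated `__getitem__`)."""
    outs: list[Tensor] = []
    for i in range(x.value.shape[axis]):
        child = Tensor(np.take(x.value, i, axis=axis), _parents=(x,))

        def backward(grad: Array, i=i) -> None:
            if x.grad is None:
                x.grad = np.zeros_like(x.value)
            sl = [slice(None)] * x.value.ndim
            sl[axis] = i
            x.grad[tuple(sl)] += grad

        child._backward = backward
        outs.append(child)
    return outs


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.value for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def backward(grad: Array) -> None:
        for i, t in enumerate(tensors):
            t._accumulate(np.take(grad, i, axis=axis))

    out._backward = backward
    return out
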