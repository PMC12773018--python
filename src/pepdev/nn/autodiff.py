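"""Minimal reverse-mode tensor autodiff on NumPy arrays.

Just enough machinery for the small positional heads (1-D conv,
self-attention, cross-attention): broadcast-aware elementwise ops, batched
matmul, reductions, reshaping/transposition, and a stable softmax.  Tensors
hold float64 arrays; gradients accumulate in ``.grad`` after ``backward()``.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "constant", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum out broadcast axes so ``grad`` matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing -------------------------------------------------

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
            t.grad += g
            if t._backward is not None:
                for p, pg in t._backward(g):
                    if not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops ------------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            return [
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            ]

        return Tensor._node(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            return [(self, -g)]

        return Tensor._node(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            return [
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            ]

        return Tensor._node(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def bw(g):
            return [
                (self, _unbroadcast(g / other.data, self.data.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.data.shape)),
            ]

        return Tensor._node(out_data, (self, other), bw)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            return [(self, g * p * self.data ** (p - 1))]

        return Tensor._node(out_data, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return [
                (self, _unbroadcast(ga, self.data.shape)),
                (other, _unbroadcast(gb, other.data.shape)),
            ]

        return Tensor._node(out_data, (self, other), bw)

    __matmul__ = matmul

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return [(self, g * out_data)]

        return Tensor._node(out_data, (self,), bw)

    def log(self):
        def bw(g):
            return [(self, g / self.data)]

        return Tensor._node(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            return [(self, g * (1.0 - out_data**2))]

        return Tensor._node(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            return [(self, g * mask)]

        return Tensor._node(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)  # numerically stable

        def bw(g):
            return [(self, g * out_data * (1.0 - out_data))]

        return Tensor._node(out_data, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            return [(self, g * sign)]

        return Tensor._node(np.abs(self.data), (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g, self.data.shape).copy())]

        return Tensor._node(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            denom = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return [(self, out_data * (g - dot))]

        return Tensor._node(out_data, (self,), bw)

    def transpose(self, ax1: int, ax2: int):
        out_data = np.swapaxes(self.data, ax1, ax2)

        def bw(g):
            return [(self, np.swapaxes(g, ax1, ax2))]

        return Tensor._node(out_data, (self,), bw)

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            return [(self, g.reshape(orig))]

        return Tensor._node(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return [(self, full)]

        return Tensor._node(out_data, (self,), bw)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return out

    return Tensor._node(out_data, tuple(tensors), bw)
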