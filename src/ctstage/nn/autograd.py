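"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the sequence models in this package are
implemented (broadcasting arithmetic, matmul, pointwise nonlinearities,
reductions, basic indexing, concat/stack, embedding lookup, log-sum-exp).
Everything is float64 for bit-reproducible training on CPU.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "embedding"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after a broadcast operation."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._bw = _bw

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd machinery --------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [
                p for p in node._parents if id(p) not in seen and p.requires_grad
            ]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._bw is not None:
                for parent, pg in node._bw(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic ----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            return (
                (self, _unbroadcast(g, self.data.shape)),
                (other, _unbroadcast(g, other.data.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            return (
                (self, _unbroadcast(g * other.data, self.data.shape)),
                (other, _unbroadcast(g * self.data, other.data.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                return ((self, g @ b.T), (other, a.T @ g))
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (
                (self, _unbroadcast(ga, a.shape)),
                (other, _unbroadcast(gb, b.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _bw=bw)

    # -- nonlinearities ------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            return ((self, g * (1.0 - out_data * out_data)),)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            return ((self, g * (self.data > 0)),)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = np.exp(self.data - m)
        total = shifted.sum(axis=axis, keepdims=True)
        out_data = (m + np.log(total)).squeeze(axis) if not keepdims else m + np.log(total)
        softmax = shifted / total

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, g * softmax),)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    # -- shape ops -----------------------------------------------------------
    def __getitem__(self, idx):
        out_data = self.data[idx]
        advanced = isinstance(idx, np.ndarray) or (
            isinstance(idx, tuple) and any(isinstance(i, np.ndarray) for i in idx)
        )

        def bw(g):
            full = np.zeros_like(self.data)
            if advanced:
                np.add.at(full, idx, g)
            else:
                full[idx] += g
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _bw=bw)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def bw(g):
            return ((self, g.reshape(self.data.shape)),)

        return Tensor(out_data, _parents=(self,), _bw=bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor(out_data, _parents=tuple(tensors), _bw=bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(
            (t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts)
        )

    return Tensor(out_data, _parents=tuple(tensors), _bw=bw)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)
    out_data = weight.data[ids]

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids, g)
        return ((weight, full),)

    return Tensor(out_data, _parents=(weight,), _bw=bw)
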