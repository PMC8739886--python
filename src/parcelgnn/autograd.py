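"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the parcellation networks need: broadcasted
arithmetic, matrix products, LeakyReLU / sigmoid / tanh, exp/log, axis
reductions (sum, max), concatenation, slicing, and masked softmax built from
these primitives. Everything is float64 and single-threaded numpy, so runs
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack_sum",
    "masked_softmax",
    "leaky_relu",
    "maximum",
    "segment_sum",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            grad = np.asarray(g)
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accum(np.broadcast_to(grad, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def max(self, axis: int, keepdims: bool = False):
        """Axis maximum; gradient flows to the first attaining entry."""
        out_data = self.data.max(axis=axis, keepdims=True)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            if not self.requires_grad:
                return
            grad = np.asarray(g)
            if not keepdims:
                grad = np.expand_dims(grad, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, argmax, grad, axis=axis)
            self._accum(full)

        return self._make(
            out_data if keepdims else out_data.squeeze(axis=axis), (self,), backward
        )

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).reshape(orig))

        return self._make(out_data, (self,), backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).T)

        return self._make(self.data.T, (self,), backward)

    # -- autodiff driver -----------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        g = np.asarray(g)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack_sum(tensors: Iterable[Tensor]) -> Tensor:
    """Element-wise sum of same-shaped tensors."""
    tensors = list(tensors)
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    return x.leaky_relu(slope)


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row segment ids."""
    x = Tensor._wrap(x)
    segments = np.asarray(segments, dtype=np.int64)
    out_shape = (num_segments,) + x.data.shape[1:]
    out_data = np.zeros(out_shape)
    np.add.at(out_data, segments, x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(np.asarray(g)[segments])

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a flat score vector within each segment.

    Stabilized by the (detached) per-segment maximum. Every segment must be
    non-empty for the rows it normalizes.
    """
    scores = Tensor._wrap(scores)
    segments = np.asarray(segments, dtype=np.int64)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segments, scores.data)
    e = (scores - seg_max[segments]).exp()
    denom = segment_sum(e, segments, num_segments)
    return e / denom[segments]


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum; on ties the gradient goes to ``a``."""
    a = Tensor._wrap(a)
    b = Tensor._wrap(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    out = Tensor(out_data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._prev = (a, b)
        out._backward = backward
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax restricted to ``mask`` (boolean); masked entries get weight 0.

    Numerically stabilized by subtracting the (detached) masked row maximum.
    Rows must contain at least one True entry.
    """
    neg = np.where(mask, 0.0, -1e30)  # additive mask: exp underflows to exactly 0
    shift = np.max(np.where(mask, scores.data, -np.inf), axis=axis, keepdims=True)
    e = (scores + neg - shift).exp() * mask.astype(np.float64)
    denom = e.sum(axis=axis, keepdims=True)
    return e / denom
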