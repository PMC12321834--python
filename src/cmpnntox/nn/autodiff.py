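"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core for the message-passing network: a small tape-based
autodiff with exactly the operations the model needs (dense linear algebra,
rectifier/sigmoid/tanh nonlinearities, row gather, and the segment sum/max
reductions that implement neighbourhood aggregation on molecular graphs).

All arithmetic is float64. Gradients accumulate into ``Tensor.grad`` after
calling :meth:`Tensor.backward` on a scalar result.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "concat",
    "relu",
    "sigmoid",
    "tanh",
    "gather_rows",
    "segment_sum",
    "segment_max",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient tape.

    Parameters with ``requires_grad=True`` receive accumulated gradients;
    intermediate results track their parents so :meth:`backward` can run a
    topologically ordered reverse sweep.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward
        self.grad: np.ndarray | None = None

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def sum(self):
        out = Tensor(self.data.sum(), _parents=(self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _parents=(self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g / n, self.data.shape)
        )
        return out

    # -- reverse sweep -----------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bwd(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - t * t))
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]``; the gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], _parents=(x,))

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    out._backward = bwd
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets; empty buckets are zero."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, _parents=(x,))
    out._backward = lambda g: x._accumulate(g[segment_ids])
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Element-wise max of rows per bucket; empty buckets yield zero.

    The gradient is split equally among tied maxima (a symmetric subgradient;
    with continuous-valued activations ties occur with probability zero).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    if x.data.shape[0]:
        np.maximum.at(data, segment_ids, x.data)
    empty = ~np.isfinite(data)
    data[empty] = 0.0
    out = Tensor(data, _parents=(x,))

    def bwd(g):
        if x.data.shape[0] == 0:
            return
        is_max = (x.data == data[segment_ids]) & ~empty[segment_ids]
        counts = np.zeros_like(data)
        np.add.at(counts, segment_ids, is_max.astype(np.float64))
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(counts > 0, g / np.maximum(counts, 1.0), 0.0)
        x._accumulate(is_max * share[segment_ids])

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw logits, numerically stable.

    loss_i = softplus(z_i) - y_i * z_i, averaged over i.
    """
    y = np.asarray(targets, dtype=np.float64).reshape(logits.data.shape)
    z = logits.data
    loss = np.logaddexp(0.0, z) - y * z
    out = Tensor(loss.mean(), _parents=(logits,))
    n = z.size

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (p - y) / n)

    out._backward = bwd
    return out
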