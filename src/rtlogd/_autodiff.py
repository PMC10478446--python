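"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph network needs: dense linear
algebra, elementwise nonlinearities, row gather, segment (scatter-add)
reductions over ragged graph structures, and concatenation. Gradients are
accumulated by topological-order backpropagation from a scalar loss.

The engine is deliberately small: every op is checked against central
finite differences in the test suite, and the network code reads much like
its equivalent in a mainstream tensor library.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autograd core -------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __truediv__(self, other):
        other = _wrap(other)
        out = _node(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _node(val, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - val**2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(val, (self,))
        out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))
        out._backward = lambda g: self._accumulate(g * np.where(mask, 1.0, slope))
        return out

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        val = np.where(mask, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = _node(val, (self,))
        out._backward = lambda g: self._accumulate(g * np.where(mask, 1.0, val + alpha))
        return out

    # -- reductions & shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(ge, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def gather(self, index: np.ndarray):
        """Select rows: out[k] = self[index[k]]."""
        index = np.asarray(index, dtype=np.int64)
        out = _node(self.data[index], (self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accumulate(acc)

        out._backward = bwd
        return out

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """out[s] = sum of rows whose segment id is s (scatter-add)."""
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        shape = (num_segments,) + self.data.shape[1:]
        val = np.zeros(shape, dtype=np.float64)
        np.add.at(val, segment_ids, self.data)
        out = _node(val, (self,))
        out._backward = lambda g: self._accumulate(g[segment_ids])
        return out

    def __getitem__(self, cols):
        """Column slice (static, used to split fused gate matrices)."""
        out = _node(self.data[:, cols], (self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            acc[:, cols] = g
            self._accumulate(acc)

        out._backward = bwd
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to the given (broadcast-source) shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a score column within each segment.

    The per-segment max is subtracted as a constant (the standard
    stabilization; it does not change the softmax or its gradient).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    m = np.full(num_segments, -np.inf)
    np.maximum.at(m, segment_ids, scores.data.ravel())
    shifted = scores - Tensor(m[segment_ids].reshape(scores.shape))
    z = shifted.exp()
    denom = z.segment_sum(segment_ids, num_segments)
    return z / denom.gather(segment_ids)
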