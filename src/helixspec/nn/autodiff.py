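"""Reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it;
``backward()`` accumulates gradients into every reachable tensor created with
``requires_grad=True``.  Only the operations the network uses are
implemented; all support float64 arrays and standard numpy broadcasting for
elementwise arithmetic.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, "Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        self.grad = g.copy() if self.grad is None else self.grad + g

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            o._accum(_unbroadcast(g, o.shape))

        return Tensor._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,),
                            lambda g: self._accum(-g))

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * o.data, self.shape))
            o._accum(_unbroadcast(g * self.data, o.shape))

        return Tensor._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g / o.data, self.shape))
            o._accum(_unbroadcast(-g * self.data / o.data**2, o.shape))

        return Tensor._make(self.data / o.data, (self, o), bw)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        o = as_tensor(other)
        if self.ndim != 2 or o.ndim != 2:
            raise ValueError("matmul supports 2D tensors only")

        def bw(g):
            self._accum(g @ o.data.T)
            o._accum(self.data.T @ g)

        return Tensor._make(self.data @ o.data, (self, o), bw)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, 0.0), (self,),
                            lambda g: self._accum(g * mask))

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: self._accum(g * out_data))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: self._accum(g / self.data))

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,),
                            lambda g: self._accum(g * sign))

    # -- reductions and reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: self._accum(g.reshape(old)))


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, float))


def constant(x: ArrayLike) -> Tensor:
    """A tensor that never requires gradients (inputs, geometric features)."""
    return Tensor(np.asarray(x, float), requires_grad=False)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows (axis 0) with an integer index array of any shape."""
    idx = np.asarray(idx, int)

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x._accum(gx)

    return Tensor._make(x.data[idx], (x,), bw)


def segment_sum(x: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``idx``."""
    idx = np.asarray(idx, int)
    out_data = np.zeros((n_segments,) + x.shape[1:])
    np.add.at(out_data, idx, x.data)
    return Tensor._make(out_data, (x,), lambda g: x._accum(g[idx]))


def segment_mean(x: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Mean over each bucket; empty buckets give zero rows."""
    idx = np.asarray(idx, int)
    counts = np.bincount(idx, minlength=n_segments).astype(float)
    denom = np.maximum(counts, 1.0).reshape((n_segments,) + (1,) * (x.ndim - 1))
    return segment_sum(x, idx, n_segments) / constant(denom)


def segment_max(x: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Max over each bucket; empty buckets give zero rows.

    The gradient of a tied maximum is split equally among the tied rows
    (a deterministic subgradient).
    """
    idx = np.asarray(idx, int)
    maxv = np.full((n_segments,) + x.shape[1:], -np.inf)
    np.maximum.at(maxv, idx, x.data)
    counts = np.bincount(idx, minlength=n_segments)
    empty = counts == 0
    out_data = maxv.copy()
    out_data[empty] = 0.0

    is_max = (x.data == maxv[idx]).astype(float)
    ties = np.zeros_like(maxv)
    np.add.at(ties, idx, is_max)
    ties = np.maximum(ties, 1.0)

    def bw(g):
        x._accum(is_max * g[idx] / ties[idx])

    return Tensor._make(out_data, (x,), bw)


def softmax_rows(z: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis."""
    shift = constant(z.data.max(axis=-1, keepdims=True))
    e = (z - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)
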