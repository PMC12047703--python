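"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the graph
autoencoder needs: dense linear algebra, elementwise maps, row
gather/scatter for message passing, and a numerically stable softmax
over edge groups. Everything runs in float64; gradients are accumulated
by topological traversal of the tape. The analytic gradients are
cross-checked against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor",
    "RowGrouper",
    "constant",
    "parameter",
    "concat",
    "segment_softmax",
]


class RowGrouper:
    """Precomputed row-group summation out[r] = Σ_{k: idx[k]==r} vals[k].

    Built once per index vector (per graph) as a sparse incidence matrix
    so the repeated group sums of message passing and its backward pass
    are single sparse matmuls.
    """

    def __init__(self, idx: np.ndarray, n: int):
        idx = np.asarray(idx)
        self.idx = idx
        self.n = n
        self.mat = sparse.csr_matrix(
            (np.ones(len(idx)), (idx, np.arange(len(idx)))),
            shape=(n, len(idx)),
        )

    def sum(self, vals: np.ndarray) -> np.ndarray:
        flat = vals.reshape(len(vals), -1)
        out = self.mat @ flat
        return out.reshape((self.n,) + vals.shape[1:])


class Tensor:
    """A node in the computation graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            _accum_broadcast(self, g)
            _accum_broadcast(other, g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            _accum_broadcast(self, g)
            _accum_broadcast(other, -g)

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            _accum_broadcast(self, g * other.data)
            _accum_broadcast(other, g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def square(self) -> "Tensor":
        def bwd(g):
            self._accum(g * 2.0 * self.data)

        return Tensor(self.data**2, parents=(self,), backward=bwd)

    def abs(self) -> "Tensor":
        def bwd(g):
            self._accum(g * np.sign(self.data))

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
            backward=bwd,
        )

    def mean(self) -> "Tensor":
        n = self.data.size

        def bwd(g):
            self._accum(np.broadcast_to(g / n, self.data.shape).copy())

        return Tensor(self.data.mean(), parents=(self,), backward=bwd)

    def reshape(self, *shape) -> "Tensor":
        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def gather(self, idx, grouper: Optional[RowGrouper] = None) -> "Tensor":
        """Select rows: out[k] = self[idx[k]].

        Passing the RowGrouper built for (idx, len(self)) makes the
        backward group sum a sparse matmul.
        """
        idx = np.asarray(idx)

        def bwd(g):
            if grouper is not None:
                self._accum(grouper.sum(g))
            else:
                self._accum(_segment_sum(g, idx, len(self.data)))

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    def scatter_add(
        self, idx, n_rows: int, grouper: Optional[RowGrouper] = None
    ) -> "Tensor":
        """Sum rows into groups: out[r] = Σ_{k: idx[k]==r} self[k]."""
        idx = np.asarray(idx)
        out = (
            grouper.sum(self.data)
            if grouper is not None
            else _segment_sum(self.data, idx, n_rows)
        )

        def bwd(g):
            self._accum(g[idx])

        return Tensor(out, parents=(self,), backward=bwd)


def _segment_sum(vals: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Row-group sum out[r] = Σ_{k: idx[k]==r} vals[k] via bincount."""
    if vals.ndim == 1:
        return np.bincount(idx, weights=vals, minlength=n)
    flat = vals.reshape(len(vals), -1)
    out = np.empty((n, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.bincount(idx, weights=flat[:, c], minlength=n)
    return out.reshape((n,) + vals.shape[1:])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum_broadcast(t: Tensor, g: np.ndarray) -> None:
    """Reduce gradient g over axes that were broadcast to reach t.shape."""
    if not t.requires_grad:
        return
    extra = g.ndim - t.data.ndim
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(t.data.shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    t._accum(g)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets, offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad:
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def segment_softmax(
    logits: Tensor,
    groups: np.ndarray,
    n_groups: int,
    grouper: Optional[RowGrouper] = None,
) -> Tensor:
    """Softmax of ``logits`` rows within groups (numerically stable).

    ``logits`` has shape (E, H); entry (e, h) is normalized over all e'
    with groups[e'] == groups[e], independently per column h. Empty
    groups contribute nothing. The group-wise max subtracted for
    stability is treated as a constant, the standard softmax convention.
    """
    groups = np.asarray(groups)
    gsum = (
        grouper.sum
        if grouper is not None
        else (lambda v: _segment_sum(v, groups, n_groups))
    )
    z = logits.data
    gmax = np.full((n_groups,) + z.shape[1:], -np.inf)
    np.maximum.at(gmax, groups, z)
    ez = np.exp(z - gmax[groups])
    denom = gsum(ez)
    alpha = ez / denom[groups]

    def bwd(g):
        # d/dz softmax: alpha * (g - Σ_group alpha * g)
        dot = gsum(alpha * g)
        logits._accum(alpha * (g - dot[groups]))

    return Tensor(alpha, parents=(logits,), backward=bwd)
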