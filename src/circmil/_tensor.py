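"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the bag classifier needs: broadcasted
arithmetic, matmul, pointwise nonlinearities, slicing/reshaping, embedding
lookup, per-bag (segment) softmax and weighted pooling, and a numerically
stable binary cross-entropy on logits.  Gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "stack",
    "embedding_lookup",
    "lstm_cell_c",
    "lstm_cell_h",
    "segment_softmax",
    "segment_max",
    "segment_weighted_sum",
    "softmax_cross_entropy",
    "bce_with_logits",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            if g.shape == self.data.shape:
                self.grad = np.array(g, dtype=self.data.dtype)
                return
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort: graphs from long recurrences exceed
        # the default python recursion limit
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=[p for p in parents if p.requires_grad],
                      backward=backward)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), bw)

    # -- pointwise ---------------------------------------------------------

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), bw)

    def sigmoid(self):
        s = _sigmoid(self.data)

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def relu(self):
        mask = self.data > 0
        def bw(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), bw)

    # -- reductions / shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return self._make(out_data, (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple) and all(isinstance(k, (int, slice)) for k in key))

        def bw(g):
            # accumulate in place: a fresh full-size buffer per slice would
            # make recurrent unrolling quadratic in sequence length
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:
                self.grad[key] += g
            else:
                np.add.at(self.grad, key, g)

        return self._make(out_data, (self,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tensors, bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        slabs = np.moveaxis(g, axis, 0)
        for t, slab in zip(tensors, slabs):
            if t.requires_grad:
                t._accum(slab)

    return Tensor._make(out_data, tensors, bw)


def embedding_lookup(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out_data = weight.data[idx]

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        weight._accum(full)

    return Tensor._make(out_data, (weight,), bw)


def lstm_cell_c(z: Tensor, c_prev: Tensor, hidden: int) -> Tensor:
    """New cell state from pre-activation gates ``z = [i f g o]`` (N, 4H)."""
    H = hidden
    zi, zf, zg = z.data[:, :H], z.data[:, H:2 * H], z.data[:, 2 * H:3 * H]
    i, f, g_ = _sigmoid(zi), _sigmoid(zf), np.tanh(zg)
    c = f * c_prev.data + i * g_

    def bw(gc):
        if z.requires_grad:
            dz = np.zeros_like(z.data)
            dz[:, :H] = gc * g_ * i * (1.0 - i)
            dz[:, H:2 * H] = gc * c_prev.data * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = gc * i * (1.0 - g_ * g_)
            z._accum(dz)
        if c_prev.requires_grad:
            c_prev._accum(gc * f)

    return Tensor._make(c, (z, c_prev), bw)


def lstm_cell_h(z: Tensor, c: Tensor, hidden: int) -> Tensor:
    """Hidden state ``h = o * tanh(c)`` with ``o`` taken from ``z``."""
    H = hidden
    o = _sigmoid(z.data[:, 3 * H:])
    th = np.tanh(c.data)
    h = o * th

    def bw(gh):
        if z.requires_grad:
            dz = np.zeros_like(z.data)
            dz[:, 3 * H:] = gh * th * o * (1.0 - o)
            z._accum(dz)
        if c.requires_grad:
            c._accum(gh * o * (1.0 - th * th))

    return Tensor._make(h, (z, c), bw)


def segment_softmax(logits: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a flat logit vector within each segment (bag).

    ``segment_ids`` assigns every entry to a bag; the result sums to one
    within every bag.  This is the MIL attention normalization.
    """
    x = logits.data
    m = np.full(n_segments, -np.inf, dtype=x.dtype)
    np.maximum.at(m, segment_ids, x)
    e = np.exp(x - m[segment_ids])
    denom = np.zeros(n_segments, dtype=x.dtype)
    np.add.at(denom, segment_ids, e)
    a = e / denom[segment_ids]

    def bw(g):
        dot = np.zeros(n_segments, dtype=g.dtype)
        np.add.at(dot, segment_ids, g * a)
        logits._accum(a * (g - dot[segment_ids]))

    return Tensor._make(a, (logits,), bw)


def segment_max(values: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment maximum of a flat vector (max-pooling MIL).

    The gradient is routed to the first maximizing entry of each segment.
    """
    x = values.data
    m = np.full(n_segments, -np.inf, dtype=x.dtype)
    np.maximum.at(m, segment_ids, x)
    hits = np.flatnonzero(x == m[segment_ids])
    argmax = np.full(n_segments, x.size, dtype=np.int64)
    np.minimum.at(argmax, segment_ids[hits], hits)

    def bw(g):
        dx = np.zeros_like(x)
        dx[argmax] += g
        values._accum(dx)

    return Tensor._make(m, (values,), bw)


def segment_weighted_sum(alpha: Tensor, feats: Tensor, segment_ids: np.ndarray,
                         n_segments: int) -> Tensor:
    """Per-bag weighted feature ``z_b = sum_{i in b} alpha_i * c_i``."""
    w = alpha.data[:, None] * feats.data
    out = np.zeros((n_segments, feats.data.shape[1]), dtype=feats.data.dtype)
    np.add.at(out, segment_ids, w)

    def bw(g):
        gseg = g[segment_ids]
        if alpha.requires_grad:
            alpha._accum((gseg * feats.data).sum(axis=1))
        if feats.requires_grad:
            feats._accum(alpha.data[:, None] * gseg)

    return Tensor._make(out, (alpha, feats), bw)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          sample_mask: np.ndarray | None = None) -> Tensor:
    """Mean categorical cross-entropy over (N, C) logits.

    ``sample_mask`` selects which rows contribute (used for masked-token
    prediction); the mean is over the selected rows.
    """
    x = logits.data
    t = np.asarray(targets)
    if sample_mask is None:
        sample_mask = np.ones(x.shape[0], dtype=bool)
    idx = np.flatnonzero(sample_mask)
    if idx.size == 0:
        raise ValueError("sample_mask selects no rows")
    xs = x[idx]
    m = xs.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(xs - m).sum(axis=1))
    nll = lse - xs[np.arange(idx.size), t[idx]]
    out = np.array(nll.mean(), dtype=x.dtype)

    def bw(g):
        p = np.exp(xs - m)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(idx.size), t[idx]] -= 1.0
        dx = np.zeros_like(x)
        dx[idx] = p * (g / idx.size)
        logits._accum(dx)

    return Tensor._make(out, (logits,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    x = logits.data
    y = np.asarray(targets, dtype=x.dtype)
    loss = np.logaddexp(0.0, x) - y * x
    out = np.array(loss.mean(), dtype=x.dtype)

    def bw(g):
        logits._accum(g * (_sigmoid(x) - y) / x.size)

    return Tensor._make(out, (logits,), bw)
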