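"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a small message-passing network on the CPU; this module
provides exactly the operations that network needs (affine maps, GELU,
layer normalisation, neighbor gather/scatter, embeddings, masked softmax
cross entropy) with hand-written vector-Jacobian products.  Gradients are
verified against central finite differences in the test suite.

All arrays are float64 by default; computations are deterministic.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "add",
    "sub",
    "mul",
    "matmul",
    "affine",
    "concat",
    "gelu",
    "layer_norm",
    "reduce_sum",
    "relu",
    "gather_nodes",
    "expand_neighbors",
    "embedding",
    "dropout",
    "log_softmax",
    "masked_cross_entropy",
    "Adam",
]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Tensor:
    """Node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a, b, out_data, da, db) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = a.requires_grad or b.requires_grad
    out = Tensor(out_data, requires_grad=req, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(da(g), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(db(g), b.data.shape))

    out._bwd = bwd if req else None
    return out


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def matmul(x, w) -> Tensor:
    """x: (..., m) @ w: (m, n) -> (..., n).

    Higher-rank inputs are flattened to one large GEMM rather than the
    stacked small GEMMs numpy would otherwise dispatch.
    """
    x, w = as_tensor(x), as_tensor(w)
    m, n = w.data.shape
    lead = x.data.shape[:-1]
    out_data = (x.data.reshape(-1, m) @ w.data).reshape(*lead, n)
    req = x.requires_grad or w.requires_grad
    out = Tensor(out_data, requires_grad=req, parents=(x, w))

    def bwd(g):
        g2 = g.reshape(-1, n)
        if x.requires_grad:
            x._accumulate((g2 @ w.data.T).reshape(*lead, m))
        if w.requires_grad:
            w._accumulate(x.data.reshape(-1, m).T @ g2)

    out._bwd = bwd if req else None
    return out


def affine(x, w, b=None) -> Tensor:
    y = matmul(x, w)
    return y if b is None else add(y, b)


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        g = np.moveaxis(g, axis, -1)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(np.moveaxis(g[..., lo:hi], -1, axis))

    out._bwd = bwd if req else None
    return out


def gelu(x) -> Tensor:
    """Exact (erf-based) GELU; kept for reference and gradient checks."""
    x = as_tensor(x)
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out = Tensor(x.data * phi, requires_grad=x.requires_grad, parents=(x,))

    def bwd(g):
        pdf = np.exp(-0.5 * x.data * x.data) * _INV_SQRT_2PI
        x._accumulate(g * (phi + x.data * pdf))

    out._bwd = bwd if x.requires_grad else None
    return out


def relu(x) -> Tensor:
    """Rectified linear unit; roughly 3x cheaper than erf-GELU on one CPU."""
    x = as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), requires_grad=x.requires_grad,
                 parents=(x,))

    def bwd(g):
        x._accumulate(np.where(mask, g, 0.0))

    out._bwd = bwd if x.requires_grad else None
    return out


def layer_norm(x, gain, offset, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    x, gain, offset = as_tensor(x), as_tensor(gain), as_tensor(offset)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + offset.data
    req = x.requires_grad or gain.requires_grad or offset.requires_grad
    out = Tensor(out_data, requires_grad=req, parents=(x, gain, offset))

    def bwd(g):
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        if offset.requires_grad:
            offset._accumulate(_unbroadcast(g, offset.data.shape))
        if x.requires_grad:
            dxhat = g * gain.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    out._bwd = bwd if req else None
    return out


def reduce_sum(x, axis: int, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)
    out = Tensor(out_data, requires_grad=x.requires_grad, parents=(x,))

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape))

    out._bwd = bwd if x.requires_grad else None
    return out


def gather_nodes(h, idx: np.ndarray) -> Tensor:
    """Gather per-neighbor node features.

    h: (B, N, D); idx: (B, N, K) integer node indices -> (B, N, K, D).
    """
    h = as_tensor(h)
    B, N, D = h.data.shape
    K = idx.shape[-1]
    flat = h.data.reshape(B * N, D)
    offset_idx = idx + (np.arange(B) * N)[:, None, None]
    out_data = flat[offset_idx.reshape(-1)].reshape(B, N, K, D)
    out = Tensor(out_data, requires_grad=h.requires_grad, parents=(h,))

    def bwd(g):
        gh = np.zeros((B * N, D))
        np.add.at(gh, offset_idx.reshape(-1), g.reshape(-1, D))
        h._accumulate(gh.reshape(B, N, D))

    out._bwd = bwd if h.requires_grad else None
    return out


def expand_neighbors(h, k: int) -> Tensor:
    """Broadcast node features over a neighbor axis: (B, N, D) -> (B, N, K, D)."""
    h = as_tensor(h)
    B, N, D = h.data.shape
    out_data = np.broadcast_to(h.data[:, :, None, :], (B, N, k, D)).copy()
    out = Tensor(out_data, requires_grad=h.requires_grad, parents=(h,))

    def bwd(g):
        h._accumulate(g.sum(axis=2))

    out._bwd = bwd if h.requires_grad else None
    return out


def embedding(table, idx: np.ndarray) -> Tensor:
    """table: (V, D); idx: any integer shape -> idx.shape + (D,)."""
    table = as_tensor(table)
    V, D = table.data.shape
    out_data = table.data[idx]
    out = Tensor(out_data, requires_grad=table.requires_grad, parents=(table,))

    def bwd(g):
        gt = np.zeros((V, D))
        np.add.at(gt, idx.reshape(-1), g.reshape(-1, D))
        table._accumulate(gt)

    out._bwd = bwd if table.requires_grad else None
    return out


def dropout(x, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return as_tensor(x)
    mask = (rng.random(as_tensor(x).data.shape) >= p) / (1.0 - p)
    return mul(x, Tensor(mask))


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Plain-array log softmax over the last axis (no graph)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def masked_cross_entropy(logits, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted mean categorical cross entropy.

    logits: (..., V); targets: integer (...); weights: float (...).
    Returns -sum_i w_i * log p_i(target_i) / sum_i w_i.
    """
    logits = as_tensor(logits)
    lp = log_softmax(logits.data)
    wsum = float(weights.sum())
    if wsum <= 0:
        raise ValueError("cross entropy requires positive total weight")
    picked = np.take_along_axis(lp, targets[..., None], axis=-1)[..., 0]
    out_data = -(weights * picked).sum() / wsum
    out = Tensor(out_data, requires_grad=logits.requires_grad, parents=(logits,))

    def bwd(g):
        p = np.exp(lp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
        logits._accumulate(g * weights[..., None] * (p - onehot) / wsum)

    out._bwd = bwd if logits.requires_grad else None
    return out


class Adam:
    """Adaptive-moment optimiser over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grad_clip: float | None = None) -> None:
        grads = {k: (v.grad if v.grad is not None else np.zeros_like(v.data))
                 for k, v in self.params.items()}
        if grad_clip is not None and grad_clip > 0:
            norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > grad_clip:
                scale = grad_clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
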