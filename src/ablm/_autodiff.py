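"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the operations the antibody encoder needs
(affine maps, embedding lookups, layer normalization, GELU, softmax
attention, dropout and a fused masked cross-entropy), each with a
hand-written vector-Jacobian product. Gradients are checked against
central finite differences in the test suite.

Design constraints:
  * float32 for parameters and activations (float64 accepted, useful for
    gradient checking);
  * fused primitives (layer_norm, softmax, cross_entropy) keep the graph
    small so Python overhead stays negligible next to the BLAS calls;
  * a module-level ``no_grad`` switch disables graph construction during
    inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True

@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _vjp: Callable[[np.ndarray], Iterable] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._vjp = _vjp

    # ---- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph mechanics -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # ---- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, scale(_as_tensor(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, other)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*ts: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in ts)


def _node(data, parents, vjp) -> Tensor:
    if _track(*parents):
        return Tensor(data, _parents=parents, _vjp=vjp)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---- primitives ---------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(out, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def vjp(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _node(out, (a, b), vjp)


def scale(a, s: float) -> Tensor:
    a = _as_tensor(a)
    out = a.data * s

    def vjp(g):
        return (g * s,)

    return _node(out, (a,), vjp)


def _contig(x: np.ndarray) -> np.ndarray:
    # batched GEMM on strided views falls off the fast BLAS path
    return x if x.flags["C_CONTIGUOUS"] else np.ascontiguousarray(x)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _contig(a.data) @ _contig(b.data)

    def vjp(g):
        ga = _contig(g) @ _contig(np.swapaxes(b.data, -1, -2))
        gb = _contig(np.swapaxes(a.data, -1, -2)) @ _contig(g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(out, (a, b), vjp)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    out = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def vjp(g):
        return (np.transpose(g, inv),)

    return _node(out, (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out = a.data.reshape(shape)
    orig = a.data.shape

    def vjp(g):
        return (g.reshape(orig),)

    return _node(out, (a,), vjp)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``weight[idx]`` with scatter-add backward.

    The backward accumulates via a one-hot GEMM rather than ``np.add.at``:
    for the small vocabularies involved this is an order of magnitude
    faster than the ufunc scatter loop.
    """
    idx = np.asarray(idx)
    out = weight.data[idx]

    def vjp(g):
        flat_idx = idx.reshape(-1)
        flat_g = g.reshape(len(flat_idx), -1)
        onehot = np.zeros((len(flat_idx), weight.shape[0]), dtype=flat_g.dtype)
        onehot[np.arange(len(flat_idx)), flat_idx] = 1.0
        return (onehot.T @ flat_g,)

    return _node(out, (weight,), vjp)


def take_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor (used to pull supervised positions)."""
    idx = np.asarray(idx)
    out = a.data[idx]

    def vjp(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return _node(out, (a,), vjp)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


def gelu(a) -> Tensor:
    """Gaussian error linear unit, tanh approximation (the form used in the
    reference transformer implementations)."""
    a = _as_tensor(a)
    x = a.data
    u = _GELU_C * (x + _GELU_A * x * x * x)
    t = np.tanh(u)
    out = 0.5 * x * (1.0 + t)

    def vjp(g):
        du = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
        return (g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du),)

    return _node(out, (a,), vjp)


def layer_norm(a, gamma, beta, eps: float = 1e-12) -> Tensor:
    """Normalization over the last axis with learned gain/bias."""
    a = _as_tensor(a)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def vjp(g):
        dgamma = _unbroadcast(g * xhat, gamma.shape)
        dbeta = _unbroadcast(g, beta.shape)
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2)
        return dx, dgamma, dbeta

    return _node(out, (a, gamma, beta), vjp)


def softmax(a, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``additive_mask`` is a constant (e.g. -1e9
    at padded key positions) added to the logits before normalization."""
    a = _as_tensor(a)
    if additive_mask is not None:
        y = a.data + additive_mask
    else:
        y = a.data.copy()
    y -= y.max(axis=-1, keepdims=True)
    np.exp(y, out=y)
    y /= y.sum(axis=-1, keepdims=True)

    def vjp(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        return ((g - dot) * y,)

    return _node(y, (a,), vjp)


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    a = _as_tensor(a)
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    out = a.data * keep

    def vjp(g):
        return (g * keep,)

    return _node(out, (a,), vjp)


def mean_(a) -> Tensor:
    a = _as_tensor(a)
    out = np.asarray(a.data.mean())
    n = a.data.size
    shp = a.data.shape

    def vjp(g):
        return (np.broadcast_to(g / n, shp).astype(a.data.dtype),)

    return _node(out, (a,), vjp)


def sum_(a) -> Tensor:
    a = _as_tensor(a)
    out = np.asarray(a.data.sum())
    shp = a.data.shape

    def vjp(g):
        return (np.broadcast_to(g, shp).astype(a.data.dtype),)

    return _node(out, (a,), vjp)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of rows of ``logits`` (N, V) against integer labels.

    Fused log-sum-exp formulation; backward is softmax(logits) - onehot, /N.
    """
    labels = np.asarray(labels)
    x = logits.data
    n = x.shape[0]
    if n == 0:
        raise ValueError("cross_entropy on an empty batch")
    m = x.max(axis=-1, keepdims=True)
    e = np.exp(x - m)
    z = e.sum(axis=-1, keepdims=True)
    logz = (np.log(z) + m).squeeze(-1)
    picked = x[np.arange(n), labels]
    out = np.asarray((logz - picked).mean())

    def vjp(g):
        p = e / z
        p[np.arange(n), labels] -= 1.0
        return ((g / n) * p,)

    return _node(out, (logits,), vjp)
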