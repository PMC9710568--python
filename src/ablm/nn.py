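"""Neural-network layers for the antibody encoder, built on ``ablm._autodiff``.

Layers follow the RoBERTa encoder layout: learned token + positional
embeddings with an embedding LayerNorm, post-norm transformer blocks
(attention and feed-forward sublayers each followed by residual add and
LayerNorm), GELU activations, and weight initialization N(0, 0.02).
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor

INIT_STD = 0.02


class Module:
    """Lightweight container; parameters are discovered by attribute walk."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            if isinstance(obj, Parameter):
                params.append(obj)
            elif isinstance(obj, Module):
                stack.extend(obj.__dict__[k] for k in sorted(obj.__dict__))
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
        # deterministic order: sorted attribute walk pushes/pops give a fixed
        # traversal; reverse so order matches declaration order.
        return params[::-1]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, INIT_STD, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, INIT_STD, size=(n, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-12):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with padding masked out of the keys."""

    def __init__(self, hidden: int, n_heads: int, dropout: float, rng: np.random.Generator):
        if hidden % n_heads:
            raise ValueError(f"hidden ({hidden}) not divisible by n_heads ({n_heads})")
        self.n_heads = n_heads
        self.d_head = hidden // n_heads
        self.dropout = dropout
        self.q = Linear(hidden, hidden, rng)
        self.k = Linear(hidden, hidden, rng)
        self.v = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, hidden, rng)

    def _split(self, x: Tensor, b: int, l: int) -> Tensor:
        x = ad.reshape(x, (b, l, self.n_heads, self.d_head))
        return ad.transpose(x, (0, 2, 1, 3))  # (B, nh, L, dh)

    def __call__(
        self,
        x: Tensor,
        key_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        b, l, hidden = x.shape
        # scaling applied to q (B, nh, L, dh) — cheaper than scaling the L x L scores
        q = ad.scale(self._split(self.q(x), b, l), 1.0 / np.sqrt(self.d_head))
        k = self._split(self.k(x), b, l)
        v = self._split(self.v(x), b, l)
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2)))
        # additive mask: 0 at real keys, -1e9 at padding, broadcast over heads/queries
        addmask = np.where(key_mask[:, None, None, :], 0.0, -1e9).astype(np.float32)
        attn = ad.softmax(scores, additive_mask=addmask)
        attn = ad.dropout(attn, self.dropout, rng, training)
        ctx = ad.matmul(attn, v)  # (B, nh, L, dh)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b, l, hidden))
        return self.out(ctx)


class TransformerBlock(Module):
    """Post-norm block: LN(x + Drop(Attn(x))), then LN(x + Drop(FFN(x)))."""

    def __init__(self, hidden: int, n_heads: int, inner: int, dropout: float,
                 eps: float, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(hidden, n_heads, dropout, rng)
        self.ln1 = LayerNorm(hidden, eps)
        self.fc1 = Linear(hidden, inner, rng)
        self.fc2 = Linear(inner, hidden, rng)
        self.ln2 = LayerNorm(hidden, eps)
        self.dropout = dropout

    def __call__(
        self,
        x: Tensor,
        key_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        a = self.attn(x, key_mask, training, rng)
        x = self.ln1(ad.add(x, ad.dropout(a, self.dropout, rng, training)))
        f = self.fc2(ad.gelu(self.fc1(x)))
        x = self.ln2(ad.add(x, ad.dropout(f, self.dropout, rng, training)))
        return x
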