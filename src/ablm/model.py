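"""The antibody masked language model: encoder, prediction head, and the
representations derived from them.

The encoder is a RoBERTa-style transformer over tokenized variable-region
sequences: learned token and positional embeddings (positions index token
slots, so residue ``i`` sits at position ``i + 1`` behind the start
sentinel), an embedding LayerNorm, and a stack of post-norm transformer
blocks. Three representations are exposed:

* **res-codings** — the final-block hidden state at each residue position
  (special tokens dropped), one ``hidden``-dimensional vector per residue;
* **seq-codings** — the arithmetic mean of a sequence's res-codings, a
  fixed-length whole-sequence representation;
* **likelihoods** — per-position probability distributions over the 20
  amino acids, from the prediction head's logits normalized over the
  amino-acid columns only.

The prediction head is one hidden projection with GELU and LayerNorm,
followed by an output projection tied to the token-embedding matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor
from .nn import Embedding, LayerNorm, Linear, Module, TransformerBlock
from .sequences import (
    AMINO_ACIDS,
    AntibodySequence,
    PAD_ID,
    VOCAB_SIZE,
    tokenize,
)

CHECKPOINT_FORMAT = 1


@dataclass(frozen=True)
class ModelConfig:
    """Encoder hyperparameters. Defaults are the production scale; tests use
    :func:`tiny_config`."""

    n_blocks: int = 12
    n_heads: int = 12
    hidden: int = 768
    inner: int = 3072
    max_len: int = 160
    dropout: float = 0.1
    layernorm_eps: float = 1e-12
    vocab_size: int = VOCAB_SIZE

    def __post_init__(self):
        if self.hidden % self.n_heads:
            raise ValueError(
                f"hidden ({self.hidden}) must be divisible by n_heads ({self.n_heads})"
            )
        for name in ("n_blocks", "n_heads", "hidden", "inner", "max_len", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def tiny_config(**overrides) -> ModelConfig:
    """The reduced configuration the test suite exercises end to end."""
    base = dict(n_blocks=2, n_heads=4, hidden=64, inner=256, max_len=160)
    base.update(overrides)
    return ModelConfig(**base)


class Encoder(Module):
    """Token/position embeddings plus the transformer block stack."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.tok_emb = Embedding(cfg.vocab_size, cfg.hidden, rng)
        self.pos_emb = Embedding(cfg.max_len, cfg.hidden, rng)
        self.emb_ln = LayerNorm(cfg.hidden, cfg.layernorm_eps)
        self.blocks = [
            TransformerBlock(cfg.hidden, cfg.n_heads, cfg.inner, cfg.dropout,
                             cfg.layernorm_eps, rng)
            for _ in range(cfg.n_blocks)
        ]

    def __call__(
        self,
        ids: np.ndarray,
        key_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        positions = np.broadcast_to(np.arange(ids.shape[1]), ids.shape)
        x = ad.add(self.tok_emb(ids), self.pos_emb(positions))
        x = self.emb_ln(x)
        x = ad.dropout(x, self.cfg.dropout, rng, training)
        for block in self.blocks:
            x = block(x, key_mask, training, rng)
        return x


class PredictionHead(Module):
    """RoBERTa-style LM head; output projection tied to the token embedding."""

    def __init__(self, cfg: ModelConfig, tok_emb: Embedding, rng: np.random.Generator):
        self.dense = Linear(cfg.hidden, cfg.hidden, rng)
        self.ln = LayerNorm(cfg.hidden, cfg.layernorm_eps)
        self._tied = tok_emb  # not owned: excluded from this module's parameters
        self.out_bias = Parameter(np.zeros(cfg.vocab_size))

    def parameters(self):
        return [self.dense.weight, self.dense.bias, self.ln.gamma, self.ln.beta,
                self.out_bias]

    def __call__(self, hidden: Tensor) -> Tensor:
        x = self.ln(ad.gelu(self.dense(hidden)))
        logits = ad.matmul(x, ad.transpose(self._tied.weight, (1, 0)))
        return ad.add(logits, self.out_bias)


class AbLM(Module):
    """Encoder + prediction head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.head = PredictionHead(cfg, self.encoder.tok_emb, rng)

    def parameters(self):
        return self.encoder.parameters() + self.head.parameters()

    def __call__(
        self,
        ids: np.ndarray,
        key_mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        hidden = self.encoder(ids, key_mask, training, rng)
        logits = self.head(hidden)
        return hidden, logits


def build_model(cfg: ModelConfig, rng: np.random.Generator | int) -> AbLM:
    """Construct a model with seeded N(0, 0.02) initialization."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return AbLM(cfg, rng)


# ---- batching -----------------------------------------------------------------


def batch_tokens(
    seqs: list[AntibodySequence], max_len: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Tokenize a batch, padding to the longest member (never past max_len).

    Returns (ids, key_mask, lengths); key_mask is True at non-pad slots.
    Results are padding-invariant: extra pad columns never change the
    hidden states at real positions.
    """
    toks = [tokenize(s, max_len) for s in seqs]
    width = max(t.length for t in toks) + 2
    ids = np.full((len(toks), width), PAD_ID, dtype=np.int64)
    for r, t in enumerate(toks):
        ids[r, : t.length + 2] = t.tokens[: t.length + 2]
    key_mask = ids != PAD_ID
    return ids, key_mask, [t.length for t in toks]


# ---- representations ----------------------------------------------------------


def res_codings_batch(model: AbLM, seqs: list[AntibodySequence]) -> list[np.ndarray]:
    """Final-block hidden states at residue positions, one (L_i, hidden)
    matrix per sequence (start/end/pad rows dropped)."""
    ids, key_mask, lengths = batch_tokens(seqs, model.cfg.max_len)
    with ad.no_grad():
        hidden = model.encoder(ids, key_mask)
    h = hidden.data
    return [h[i, 1 : 1 + n].copy() for i, n in enumerate(lengths)]


def res_codings(model: AbLM, seq: AntibodySequence) -> np.ndarray:
    return res_codings_batch(model, [seq])[0]


def seq_coding(rc: np.ndarray) -> np.ndarray:
    """Whole-sequence representation: the mean of the res-codings rows."""
    rc = np.asarray(rc)
    if rc.ndim != 2 or rc.shape[0] == 0:
        raise ValueError("res-codings must be a non-empty (L, hidden) matrix")
    return rc.mean(axis=0)


def likelihoods_batch(model: AbLM, seqs: list[AntibodySequence]) -> list[np.ndarray]:
    """Per-position amino-acid probabilities, one (L_i, 20) matrix per
    sequence. Logits of mask/pad/start/end are excluded from the softmax so
    each row is a distribution over the 20 amino acids."""
    ids, key_mask, lengths = batch_tokens(seqs, model.cfg.max_len)
    with ad.no_grad():
        _, logits = model(ids, key_mask)
    z = logits.data[:, :, : len(AMINO_ACIDS)]
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return [p[i, 1 : 1 + n].copy() for i, n in enumerate(lengths)]


def likelihoods(model: AbLM, seq: AntibodySequence) -> np.ndarray:
    return likelihoods_batch(model, [seq])[0]


# ---- persistence & export -----------------------------------------------------


def save_checkpoint(model: AbLM, path) -> None:
    """Single-file checkpoint: versioned header with the config embedded."""
    header = json.dumps({"format": CHECKPOINT_FORMAT, "config": asdict(model.cfg)})
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, header=np.array(header), **arrays)


def load_checkpoint(path) -> AbLM:
    with np.load(str(path), allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unsupported checkpoint format: {header.get('format')}")
        cfg = ModelConfig(**header["config"])
        model = build_model(cfg, rng=np.random.default_rng(0))
        params = model.parameters()
        for i, p in enumerate(params):
            arr = z[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.data = arr.astype(np.float32)
    return model


def codings_to_csv(ids: list[str], codings: list[np.ndarray], path) -> None:
    """Export seq-codings (one row per sequence) as CSV."""
    df = pd.DataFrame(np.vstack(codings))
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)


def codings_to_hdf5(ids: list[str], codings: list[np.ndarray], path) -> None:
    """Export res-codings (one dataset per sequence) as HDF5."""
    with h5py.File(path, "w") as f:
        for sid, rc in zip(ids, codings):
            f.create_dataset(sid, data=np.asarray(rc))
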