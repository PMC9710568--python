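"""Masked-LM pre-training loop.

Optimization follows the recipe the encoder's architecture comes from:
Adam with decoupled weight decay (betas (0.9, 0.98), eps 1e-6), a linear
learning-rate warm-up from zero over the first 5% of optimizer steps to a
peak of 2e-4, then cosine decay to zero. Cross-entropy is computed only at
the corruption-selected positions, against the original residues recorded
in each plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter
from .corruption import MASK, CorruptionConfig, apply_plan, draw_plan
from .model import AbLM, batch_tokens, likelihoods_batch
from .sequences import AA_TO_ID, AMINO_ACIDS, AntibodySequence


@dataclass(frozen=True)
class TrainConfig:
    peak_lr: float = 2e-4
    warmup_fraction: float = 0.05
    weight_decay: float = 0.01
    epochs: int = 20
    batch_size: int = 8192
    seed: int = 0
    adam_betas: tuple[float, float] = (0.9, 0.98)
    adam_eps: float = 1e-6
    grad_clip: float | None = None

    def __post_init__(self):
        if not (0.0 < self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.peak_lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("peak_lr, batch_size and epochs must be positive")


def lr_schedule(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear warm-up 0 -> peak over ``warmup_fraction`` of the steps, then
    cosine decay peak -> 0 over the remainder."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if step < 0 or step > total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    warmup = cfg.warmup_fraction * total_steps
    if step <= warmup:
        return cfg.peak_lr * step / warmup
    t = (step - warmup) / (total_steps - warmup)
    return float(cfg.peak_lr * 0.5 * (1.0 + np.cos(np.pi * t)))


class AdamW:
    """Adam with decoupled weight decay. Decay is not applied to 1-D
    parameters (biases, LayerNorm gains), following common transformer
    practice."""

    def __init__(self, params: list[Parameter], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        b1, b2 = self.cfg.adam_betas
        eps = self.cfg.adam_eps
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            g = g.astype(np.float32)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + eps)
            if p.data.ndim > 1 and self.cfg.weight_decay:
                update = update + self.cfg.weight_decay * p.data
            p.data = (p.data - lr * update).astype(np.float32, copy=False)


def _clip_gradients(params: list[Parameter], max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train(
    model: AbLM,
    dataset: list[AntibodySequence],
    cfg: TrainConfig,
    corruption_cfg: CorruptionConfig | None = None,
) -> list[dict]:
    """Train in place; returns the loss trace (one row per optimizer step).

    An epoch is one shuffled pass over the dataset with fresh corruption
    draws for every sequence encounter (dynamic masking).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    corruption_cfg = corruption_cfg or CorruptionConfig()
    rng = np.random.default_rng(cfg.seed)
    corrupt_rng = np.random.default_rng(rng.integers(2**31))
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    params = model.parameters()
    opt = AdamW(params, cfg)
    n = len(dataset)
    batches_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * batches_per_epoch
    trace: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for b in range(batches_per_epoch):
            batch = [dataset[i] for i in order[b * cfg.batch_size : (b + 1) * cfg.batch_size]]
            corrupted = []
            targets: list[tuple[int, int, int]] = []  # (row, residue_idx, label_id)
            for row, seq in enumerate(batch):
                plan = draw_plan(seq, corruption_cfg, corrupt_rng)
                cseq, labels = apply_plan(seq, plan)
                corrupted.append(cseq)
                for i, aa in labels.items():
                    targets.append((row, i, AA_TO_ID[aa]))
            ids, key_mask, _ = batch_tokens(corrupted, model.cfg.max_len)
            width = ids.shape[1]
            hidden = model.encoder(ids, key_mask, training=True, rng=dropout_rng)
            flat = ad.reshape(hidden, (ids.shape[0] * width, model.cfg.hidden))
            # residue i sits at token slot i + 1 (behind the start sentinel);
            # the head runs only on the supervised rows
            rows = np.array([r * width + i + 1 for r, i, _ in targets])
            labels_arr = np.array([t for _, _, t in targets])
            logits = model.head(ad.take_rows(flat, rows))
            loss = ad.cross_entropy(logits, labels_arr)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss_val}"
                )
            model.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                _clip_gradients(params, cfg.grad_clip)
            step += 1
            lr = lr_schedule(step, total_steps, cfg)
            opt.step(lr)
            trace.append(
                {"epoch": epoch, "step": step, "lr": lr, "loss": loss_val}
            )
    return trace


# ---- evaluation helpers -------------------------------------------------------


def positional_consensus(train_seqs: list[AntibodySequence]) -> list[str]:
    """Most frequent residue at each absolute position of the training set —
    the context-free baseline a language model has to beat."""
    max_len = max(len(s) for s in train_seqs)
    counts = np.zeros((max_len, len(AMINO_ACIDS)), dtype=np.int64)
    for s in train_seqs:
        for i, c in enumerate(s.residues):
            counts[i, AA_TO_ID[c]] += 1
    return [AMINO_ACIDS[j] for j in counts.argmax(axis=1)]


def masked_accuracy(
    model: AbLM,
    seqs: list[AntibodySequence],
    corruption_cfg: CorruptionConfig,
    seed: int,
    consensus: list[str] | None = None,
) -> tuple[float, float]:
    """Mask residues per the corruption scheme, predict them by likelihood
    argmax, and score the fraction recovered. Returns (model accuracy,
    consensus-baseline accuracy on the same masked positions); the baseline
    is nan when no consensus is given."""
    rng = np.random.default_rng(seed)
    masked_seqs = []
    masked_positions: list[list[tuple[int, str]]] = []
    for seq in seqs:
        plan = draw_plan(seq, corruption_cfg, rng)
        cseq, labels = apply_plan(seq, plan)
        pos = [(i, labels[i]) for i in plan.selected if plan.action[i] == MASK]
        masked_seqs.append(cseq)
        masked_positions.append(pos)
    probs = likelihoods_batch(model, masked_seqs)
    hits = tries = base_hits = 0
    for p, pos in zip(probs, masked_positions):
        for i, truth in pos:
            tries += 1
            if AMINO_ACIDS[int(p[i].argmax())] == truth:
                hits += 1
            if consensus is not None and i < len(consensus) and consensus[i] == truth:
                base_hits += 1
    if tries == 0:
        return float("nan"), float("nan")
    base = base_hits / tries if consensus is not None else float("nan")
    return hits / tries, base
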