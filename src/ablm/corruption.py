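"""Masked-LM corruption scheme for pre-training.

For each training sequence a fraction of residues, drawn uniformly between
``select_min`` and ``select_max`` (defaults 1%–25%), is selected for
supervision. Each selected position is independently masked with
probability 0.80, swapped to a different random amino acid with 0.10, or
left unchanged with 0.10. Loss is later computed only at the selected
positions, against the original residues recorded in the plan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import AMINO_ACIDS, WILDCARD, AntibodySequence, SequenceError

MASK = "mask"
SWAP = "swap"
KEEP = "keep"


@dataclass(frozen=True)
class CorruptionConfig:
    select_min: float = 0.01
    select_max: float = 0.25
    p_mask: float = 0.80
    p_swap: float = 0.10
    p_keep: float = 0.10

    def __post_init__(self):
        if not (0.0 < self.select_min <= self.select_max <= 1.0):
            raise ValueError("need 0 < select_min <= select_max <= 1")
        if abs(self.p_mask + self.p_swap + self.p_keep - 1.0) > 1e-9:
            raise ValueError("action probabilities must sum to 1")


@dataclass(frozen=True)
class CorruptionPlan:
    selected: tuple[int, ...]
    action: dict[int, str]
    swap_residue: dict[int, str]
    labels: dict[int, str]


def draw_plan(
    seq: AntibodySequence, cfg: CorruptionConfig, rng: np.random.Generator
) -> CorruptionPlan:
    """Draw a fresh corruption plan for one complete training sequence.

    The number selected is ``max(1, round(fraction * len))`` (round half up)
    so every sequence contributes at least one supervised position; swap
    replacements are drawn uniformly from the 19 amino acids different from
    the original.
    """
    if WILDCARD in seq.residues:
        raise SequenceError(
            f"{seq.id}: corruption applies to complete training sequences only"
        )
    n = len(seq.residues)
    frac = rng.uniform(cfg.select_min, cfg.select_max)
    count = max(1, int(np.floor(frac * n + 0.5)))
    selected = np.sort(rng.choice(n, size=count, replace=False))
    u = rng.random(count)
    action: dict[int, str] = {}
    swap_residue: dict[int, str] = {}
    labels: dict[int, str] = {}
    for i, ui in zip(selected.tolist(), u):
        labels[i] = seq.residues[i]
        if ui < cfg.p_mask:
            action[i] = MASK
        elif ui < cfg.p_mask + cfg.p_swap:
            action[i] = SWAP
            alternatives = AMINO_ACIDS.replace(seq.residues[i], "")
            swap_residue[i] = alternatives[rng.integers(len(alternatives))]
        else:
            action[i] = KEEP
    return CorruptionPlan(
        selected=tuple(selected.tolist()),
        action=action,
        swap_residue=swap_residue,
        labels=labels,
    )


def apply_plan(
    seq: AntibodySequence, plan: CorruptionPlan
) -> tuple[AntibodySequence, dict[int, str]]:
    """Apply a plan: mask -> ``*``, swap -> replacement, keep -> unchanged.

    Returns the corrupted sequence and the labels at selected positions
    (the supervision targets for the loss).
    """
    n = len(seq.residues)
    if any(i < 0 or i >= n for i in plan.selected):
        raise SequenceError(f"{seq.id}: corruption plan index out of bounds")
    body = list(seq.residues)
    for i in plan.selected:
        if plan.labels[i] != seq.residues[i]:
            raise SequenceError(f"{seq.id}: plan labels disagree with the sequence")
        a = plan.action[i]
        if a == MASK:
            body[i] = WILDCARD
        elif a == SWAP:
            body[i] = plan.swap_residue[i]
        elif a != KEEP:
            raise SequenceError(f"unknown corruption action {a!r}")
    return seq.with_residues("".join(body)), dict(plan.labels)
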