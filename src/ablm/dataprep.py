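"""Redundancy reduction and split construction for training corpora.

The pipeline mirrors standard repertoire curation: drop rarely observed
sequences (seen fewer than three times), group by identical CDR3, keep the
longest representative per group, cluster the representatives at 70%
whole-sequence identity, and split the survivors into training and
evaluation sets.

Identity clustering is a deterministic greedy centroid pass (sequences
processed in descending length, ties by id; a sequence joins the first
centroid it matches at or above the threshold, else founds a new one).
Pairwise identity is matches / global-alignment length, so gap columns
count against identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .sequences import AntibodySequence, Numberer, WILDCARD, imgt_ordinal

logger = logging.getLogger(__name__)

CDR3_RANGE = (105, 117)


@dataclass(frozen=True)
class Cluster:
    representative: AntibodySequence
    members: tuple[str, ...]
    level: str  # "cdr3" or "identity"
    key: str = ""


def filter_min_count(
    records: list[tuple[AntibodySequence, int]], min_count: int = 3
) -> list[AntibodySequence]:
    """Keep sequences observed ``min_count`` or more times (inclusive)."""
    for _, c in records:
        if c < 1:
            raise ValueError("observed counts must be >= 1")
    return [s for s, c in records if c >= min_count]


def extract_cdr3(seq: AntibodySequence, numberer: Numberer | None = None) -> str:
    """CDR3 residues: IMGT positions 105-117 inclusive."""
    numbering = seq.numbering or (numberer.number(seq) if numberer else None)
    if numbering is None:
        raise ValueError(f"{seq.id}: CDR3 extraction needs a numbering")
    return "".join(
        seq.residues[i]
        for pos, i in numbering
        if CDR3_RANGE[0] <= imgt_ordinal(pos)[0] <= CDR3_RANGE[1]
    )


def _pick_representative(members: list[AntibodySequence]) -> AntibodySequence:
    # longest member; ties broken by lexicographic id
    return min(members, key=lambda s: (-len(s.residues), s.id))


def cluster_cdr3(
    seqs: list[AntibodySequence], numberer: Numberer | None = None
) -> tuple[list[Cluster], list[str]]:
    """One cluster per distinct CDR3 string (exact equality).

    Sequences whose CDR3 cannot be extracted, is empty, or contains ``*``
    go to the returned reject list.
    """
    chains = {s.chain for s in seqs}
    if len(chains) > 1:
        raise ValueError("cluster_cdr3 requires a single-chain input")
    groups: dict[str, list[AntibodySequence]] = {}
    rejects: list[str] = []
    for seq in seqs:
        try:
            cdr3 = extract_cdr3(seq, numberer)
        except (ValueError, KeyError) as e:
            logger.warning("CDR3 extraction failed for %s: %s", seq.id, e)
            rejects.append(seq.id)
            continue
        if not cdr3 or WILDCARD in cdr3:
            rejects.append(seq.id)
            continue
        groups.setdefault(cdr3, []).append(seq)
    clusters = [
        Cluster(
            representative=_pick_representative(members),
            members=tuple(sorted(s.id for s in members)),
            level="cdr3",
            key=cdr3,
        )
        for cdr3, members in groups.items()
    ]
    clusters.sort(key=lambda c: c.representative.id)
    return clusters, rejects


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -2.0
_aligner.extend_gap_score = -0.5


def pairwise_identity(a: str, b: str) -> float:
    """matches / alignment length (gap columns included) under global
    alignment."""
    aln = _aligner.align(a, b)[0]
    c = aln.counts()
    length = c.gaps + c.identities + c.mismatches
    return c.identities / length if length else 0.0


def cluster_identity(
    reps: list[AntibodySequence], threshold: float = 0.70
) -> list[Cluster]:
    """Greedy centroid clustering at a whole-sequence identity threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(reps, key=lambda s: (-len(s.residues), s.id))
    centroids: list[AntibodySequence] = []
    members: list[list[str]] = []
    for seq in ordered:
        for ci, cen in enumerate(centroids):
            if pairwise_identity(seq.residues, cen.residues) >= threshold:
                members[ci].append(seq.id)
                break
        else:
            centroids.append(seq)
            members.append([seq.id])
    return [
        Cluster(
            representative=cen,
            members=tuple(sorted(mem)),
            level="identity",
            key=cen.id,
        )
        for cen, mem in zip(centroids, members)
    ]


def split(
    seqs: list[AntibodySequence], n_eval: int, seed: int
) -> tuple[list[AntibodySequence], list[AntibodySequence]]:
    """Seeded uniform train/eval split without replacement."""
    if n_eval < 0 or n_eval >= len(seqs):
        raise ValueError(f"n_eval must be in [0, {len(seqs) - 1}]")
    rng = np.random.default_rng(seed)
    eval_idx = set(rng.choice(len(seqs), size=n_eval, replace=False).tolist())
    train = [s for i, s in enumerate(seqs) if i not in eval_idx]
    evals = [s for i, s in enumerate(seqs) if i in eval_idx]
    return train, evals


def build_test_set(
    eval_seqs: list[AntibodySequence],
    alleles: dict[str, str],
    per_allele: int = 100,
    seed: int = 0,
    include_small: bool = False,
) -> list[AntibodySequence]:
    """Sample ``per_allele`` complete sequences per germline allele.

    Sequences containing ``*`` are excluded. Alleles with fewer than
    ``per_allele`` complete members are skipped (logged) unless
    ``include_small``, in which case all their members are taken.
    """
    rng = np.random.default_rng(seed)
    by_allele: dict[str, list[AntibodySequence]] = {}
    for seq in eval_seqs:
        if WILDCARD in seq.residues:
            continue
        allele = alleles.get(seq.id)
        if allele is not None:
            by_allele.setdefault(allele, []).append(seq)
    out: list[AntibodySequence] = []
    for allele in sorted(by_allele):
        pool = sorted(by_allele[allele], key=lambda s: s.id)
        if len(pool) < per_allele:
            if include_small:
                out.extend(pool)
            else:
                logger.info(
                    "allele %s has %d complete sequences (< %d); skipped",
                    allele, len(pool), per_allele,
                )
            continue
        idx = rng.choice(len(pool), size=per_allele, replace=False)
        out.extend(pool[i] for i in sorted(idx.tolist()))
    return out


def clusters_to_tsv(clusters: list[Cluster], path) -> None:
    rows = [
        {
            "cluster_id": c.key or c.representative.id,
            "member_id": m,
            "is_representative": m == c.representative.id,
        }
        for c in clusters
        for m in c.members
    ]
    pd.DataFrame(rows, columns=["cluster_id", "member_id", "is_representative"]).to_csv(
        path, sep="\t", index=False
    )
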