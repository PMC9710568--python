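"""Restoration of missing antibody residues.

Three restorers are provided:

* :func:`restore_masked` — fill every ``*`` with the amino acid of highest
  model likelihood at that position (one forward pass per sequence).
* :func:`restore_nterm` — when the number of missing N-terminal residues is
  unknown, search candidate lengths around the numbering-derived estimate
  (eight shorter to two longer, covering indels and the variable CDR1
  length), restore each candidate, and keep the one whose restored *first
  residue* carries the highest likelihood. The search can be run a second
  round, re-centered on the first round's answer, keeping the higher-scoring
  outcome.
* :func:`restore_germline` — the germline baseline: assign the best-matching
  germline allele by fractional identity at shared IMGT positions and copy
  its residues into the unknown positions. By construction this predicts
  the unmutated residue, so it is wrong wherever the query carries a
  somatic mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import AbLM, likelihoods_batch
from .sequences import (
    AA_TO_ID,
    AMINO_ACIDS,
    WILDCARD,
    AntibodySequence,
    Numberer,
    SequenceError,
    imgt_ordinal,
)

logger = logging.getLogger(__name__)

Restorer = Callable[[AntibodySequence], "RestorationResult"]


@dataclass(frozen=True)
class RestorationResult:
    restored: AntibodySequence
    n_prepended: int
    first_residue_likelihood: float
    per_position: dict[int, tuple[str, float]]
    rounds_used: int = 1
    warning: str | None = None
    allele: str | None = None
    identity: float | None = None
    failed_positions: tuple[int, ...] = ()


# ---- germline database --------------------------------------------------------


@dataclass(frozen=True)
class GermlineRecord:
    name: str
    chain: str
    residues: str
    positions: tuple[str, ...]  # IMGT scheme position per residue

    @property
    def position_map(self) -> dict[str, str]:
        return dict(zip(self.positions, self.residues))


class GermlineDB:
    """Allele name -> germline variable-region sequence with IMGT positions.

    Built from FASTA: IMGT-gapped records (``.`` at unoccupied scheme
    positions, so string index i is scheme position i+1) or ungapped ones
    (positions assigned 1..L). Chain is read from a ``chain=...`` tag in the
    header, falling back to the IGH/IGK/IGL name prefix.
    """

    def __init__(self, records: dict[str, GermlineRecord]):
        if not records:
            raise ValueError("empty germline database")
        self.records = dict(sorted(records.items()))

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> GermlineRecord:
        return self.records[name]

    def alleles(self, chain: str | None = None) -> list[str]:
        return [n for n, r in self.records.items() if chain is None or r.chain == chain]

    def subset(self, names: Iterable[str]) -> "GermlineDB":
        return GermlineDB({n: self.records[n] for n in names})

    @classmethod
    def from_fasta(cls, path) -> "GermlineDB":
        records: dict[str, GermlineRecord] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            raw = str(rec.seq).upper()
            if "chain=light" in rec.description:
                chain = "light"
            elif "chain=heavy" in rec.description:
                chain = "heavy"
            else:
                chain = "heavy" if rec.id.upper().startswith("IGH") else "light"
            if "." in raw:
                positions = tuple(str(i + 1) for i, c in enumerate(raw) if c != ".")
                residues = raw.replace(".", "")
            else:
                positions = tuple(str(i + 1) for i in range(len(raw)))
                residues = raw
            if rec.id in records:
                raise ValueError(f"duplicate allele name {rec.id}")
            bad = set(residues) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"{rec.id}: invalid germline symbols {sorted(bad)}")
            records[rec.id] = GermlineRecord(rec.id, chain, residues, positions)
        return cls(records)


def germline_identity(
    query: dict[str, str], germline: GermlineRecord
) -> float:
    """Fractional identity over scheme positions present in both the query
    numbering (non-``*`` residues only) and the germline."""
    gmap = germline.position_map
    aligned = matches = 0
    for pos, res in query.items():
        g = gmap.get(pos)
        if g is None:
            continue
        aligned += 1
        if g == res:
            matches += 1
    return matches / aligned if aligned else 0.0


def assign_germline(
    seq: AntibodySequence, db: GermlineDB, numberer: Numberer | None = None
) -> tuple[str, float]:
    """Best allele by identity at shared IMGT positions; ties broken by
    lexicographic allele name."""
    numbering = seq.numbering or (numberer.number(seq) if numberer else None)
    if numbering is None:
        raise SequenceError(f"{seq.id}: germline assignment needs a numbering")
    query = {
        pos: seq.residues[i]
        for pos, i in numbering
        if seq.residues[i] != WILDCARD
    }
    best_name, best_ident = None, -1.0
    for name in db.alleles(seq.chain) or db.alleles():
        ident = germline_identity(query, db[name])
        if ident > best_ident:
            best_name, best_ident = name, ident
    if best_name is None:
        raise SequenceError("no alleles available for assignment")
    return best_name, best_ident


# ---- masked-LM restorers ------------------------------------------------------


def restore_masked(model: AbLM, seq: AntibodySequence) -> RestorationResult:
    """Replace each ``*`` by the argmax of the model's likelihood row.

    Likelihoods are computed once on the full input; known residues are
    never altered. Ties in the argmax resolve to the alphabetically first
    amino acid (numpy argmax over the fixed column order).
    """
    return _restore_masked_batch(model, [seq])[0]


def _restore_masked_batch(
    model: AbLM, seqs: list[AntibodySequence]
) -> list[RestorationResult]:
    probs = likelihoods_batch(model, seqs)
    out = []
    for seq, p in zip(seqs, probs):
        body = list(seq.residues)
        per_position: dict[int, tuple[str, float]] = {}
        warning = None
        if WILDCARD not in seq.residues:
            warning = "input contains no '*'; nothing to restore"
        else:
            for i, c in enumerate(body):
                if c == WILDCARD:
                    j = int(p[i].argmax())
                    body[i] = AMINO_ACIDS[j]
                    per_position[i] = (AMINO_ACIDS[j], float(p[i, j]))
        restored = replace(seq, residues="".join(body))
        first = float(p[0, AA_TO_ID[body[0]]])
        out.append(
            RestorationResult(
                restored=restored,
                n_prepended=0,
                first_residue_likelihood=first,
                per_position=per_position,
                warning=warning,
            )
        )
    return out


def _nterm_candidates(
    seq: AntibodySequence, m: int, search_lo: int, search_hi: int, allow_trim: bool
) -> list[int]:
    lo = m - search_lo
    ks = list(range(lo if allow_trim else max(0, lo), m + search_hi + 1))
    if allow_trim:
        ks = [k for k in ks if k >= -(len(seq.residues) - 1)]
    return ks


def _nterm_search(
    model: AbLM,
    seq: AntibodySequence,
    m: int,
    search_lo: int,
    search_hi: int,
    allow_trim: bool,
) -> RestorationResult:
    capacity = model.cfg.max_len - 2
    variants: list[tuple[int, AntibodySequence]] = []
    for k in _nterm_candidates(seq, m, search_lo, search_hi, allow_trim):
        if k >= 0:
            residues = WILDCARD * k + seq.residues
        else:
            residues = seq.residues[-k:]  # trim |k| observed leading residues
        if len(residues) > capacity:
            logger.warning("%s: candidate k=%d exceeds model capacity; skipped", seq.id, k)
            continue
        variants.append((k, seq.with_residues(residues)))
    if not variants:
        raise SequenceError(f"{seq.id}: no feasible N-terminus candidates")
    # restore all candidates in one batched forward pass
    results = _restore_masked_batch(model, [v for _, v in variants])
    best_k, best = None, None
    for (k, _), res in zip(variants, results):
        if best is None or res.first_residue_likelihood > best.first_residue_likelihood:
            best_k, best = k, res
    return replace(best, n_prepended=best_k)


def restore_nterm(
    model: AbLM,
    seq: AntibodySequence,
    numberer: Numberer,
    rounds: int = 1,
    search_lo: int = 8,
    search_hi: int = 2,
    allow_trim: bool = False,
) -> RestorationResult:
    """Determine the unknown N-terminus length and restore it.

    Candidate lengths run from ``search_lo`` residues shorter to
    ``search_hi`` longer than the numbering-derived standard missing count
    (clipped at zero unless ``allow_trim``, in which case negative
    candidates remove observed leading residues). The candidate whose
    restored first residue has the highest likelihood wins. With
    ``rounds=2`` the search is repeated with the window re-centered on the
    round-1 answer (the round-1 additions stripped back to ``*``), and the
    higher-scoring outcome is kept.
    """
    if rounds not in (1, 2):
        raise ValueError("rounds must be 1 or 2")
    if WILDCARD in seq.residues:
        raise SequenceError(f"{seq.id}: restore_nterm expects no internal '*'")
    m = numberer.standard_missing(seq)
    best = _nterm_search(model, seq, m, search_lo, search_hi, allow_trim)
    if rounds == 2:
        m2 = best.n_prepended + numberer.standard_missing(best.restored)
        second = _nterm_search(model, seq, m2, search_lo, search_hi, allow_trim)
        if second.first_residue_likelihood > best.first_residue_likelihood:
            best = second
        best = replace(best, rounds_used=2)
    return best


def masked_lm_restorer(model: AbLM) -> Restorer:
    return lambda seq: restore_masked(model, seq)


# ---- germline baseline --------------------------------------------------------


def restore_germline(
    seq: AntibodySequence,
    db: GermlineDB,
    numberer: Numberer | None = None,
    complete_nterm: bool = True,
) -> RestorationResult:
    """Fill ``*`` positions (and, when ``complete_nterm``, the missing
    N-terminal positions) from the best-matching germline allele.

    Positions the chosen germline does not cover are left as ``*`` and
    reported in ``failed_positions``. Reported per-position probabilities
    are 1.0: the germline lookup is deterministic.
    """
    numbering = seq.numbering or (numberer.number(seq) if numberer else None)
    if numbering is None:
        raise SequenceError(f"{seq.id}: germline restoration needs a numbering")
    name, ident = assign_germline(seq, db, numberer)
    gmap = db[name].position_map
    pos_of = {i: pos for pos, i in numbering}
    body = list(seq.residues)
    per_position: dict[int, tuple[str, float]] = {}
    failed: list[int] = []
    for i, c in enumerate(body):
        if c != WILDCARD:
            continue
        g = gmap.get(pos_of.get(i, "?"))
        if g is None:
            failed.append(i)
            logger.warning("%s: allele %s does not cover position %s", seq.id, name, pos_of.get(i))
        else:
            body[i] = g
            per_position[i] = (g, 1.0)
    prefix = ""
    if complete_nterm and numbering:
        first_pos = imgt_ordinal(numbering[0][0])
        missing = [
            (imgt_ordinal(p), r)
            for p, r in zip(db[name].positions, db[name].residues)
            if imgt_ordinal(p) < first_pos
        ]
        missing.sort()
        prefix = "".join(r for _, r in missing)
        shift = len(prefix)
        per_position = {i + shift: v for i, v in per_position.items()}
        failed = [i + shift for i in failed]
        for j, r in enumerate(prefix):
            per_position[j] = (r, 1.0)
    restored = replace(seq, residues=prefix + "".join(body), numbering=None)
    return RestorationResult(
        restored=restored,
        n_prepended=len(prefix),
        first_residue_likelihood=1.0,
        per_position=per_position,
        allele=name,
        identity=ident,
        failed_positions=tuple(failed),
    )


def germline_restorer(db: GermlineDB, numberer: Numberer | None = None) -> Restorer:
    return lambda seq: restore_germline(seq, db, numberer, complete_nterm=False)


# ---- benchmarks ---------------------------------------------------------------


def benchmark_nterm(
    restorer: Restorer,
    test_set: Sequence[AntibodySequence],
    max_missing: int = 30,
    margin: int = 10,
) -> pd.DataFrame:
    """Mask prefixes of length 1..max_missing, restore, score per length.

    Test sequences must be complete (no ``*``); each row of the returned
    frame is (missing_length, accuracy, n_sequences) where accuracy is the
    fraction of masked residues restored correctly.
    """
    eligible = []
    for seq in test_set:
        if WILDCARD in seq.residues:
            raise SequenceError(f"{seq.id}: benchmark inputs must be complete")
        if len(seq.residues) < max_missing + margin:
            logger.info("%s: shorter than max_missing + margin; skipped", seq.id)
            continue
        eligible.append(seq)
    rows = []
    for L in range(1, max_missing + 1):
        correct = total = 0
        for seq in eligible:
            masked = replace(seq, residues=WILDCARD * L + seq.residues[L:])
            res = restorer(masked)
            got = res.restored.residues
            correct += sum(got[i] == seq.residues[i] for i in range(L))
            total += L
        rows.append(
            {
                "missing_length": L,
                "accuracy": correct / total if total else float("nan"),
                "n_sequences": len(eligible),
            }
        )
    return pd.DataFrame(rows)


def benchmark_random_sites(
    restorer: Restorer,
    test_set: Sequence[AntibodySequence],
    n_masked: int,
    seed: int = 0,
) -> float:
    """Mask ``n_masked`` random residues per sequence and score the overall
    fraction restored correctly. Site selection is seeded; sequences shorter
    than ``n_masked`` are skipped."""
    rng = np.random.default_rng(seed)
    correct = total = 0
    for seq in test_set:
        n = len(seq.residues)
        if n_masked >= n:
            logger.info("%s: fewer residues than n_masked; skipped", seq.id)
            continue
        sites = rng.choice(n, size=n_masked, replace=False)
        body = list(seq.residues)
        for i in sites:
            body[i] = WILDCARD
        res = restorer(replace(seq, residues="".join(body)))
        got = res.restored.residues
        correct += sum(got[i] == seq.residues[i] for i in sites)
        total += n_masked
    if total == 0:
        return float("nan")
    return correct / total
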