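"""Synthetic antibody repertoires with known ground truth.

Sequences are drawn from a bundled toy germline set (hand-constructed,
plausible variable-region alleles in IMGT-gapped FASTA — not copies of any
germline database), then modified to emulate the artefacts of real
repertoire sequencing:

* independent per-residue point substitutions at ``mutation_rate``
  (somatic-hypermutation stand-in; position-independent, no indels);
* an N-terminal truncation drawn from ``truncation_distribution``. The
  default distribution puts 20% of its mass at zero, a decaying profile
  over lengths 1–14, and ~43% on lengths >= 15, emulating the reported
  prevalence of N-terminal loss in public repertoire data (~80% of
  sequences missing more than one residue, ~43% missing the first 15);
* with probability ``ambiguous_rate`` per sequence, one internal residue
  replaced by ``*`` (ambiguous-base stand-in, ~1% of sequences).

Every generated sequence carries full ground truth (source allele, mutated
positions, complete sequence, truncation length, CDR3 span, numbering), so
all benchmarks are scorable without external data, and
:class:`TruthNumberer` stands in for an external numbering tool.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .restoration import GermlineDB
from .sequences import (
    AMINO_ACIDS,
    WILDCARD,
    AntibodySequence,
    imgt_ordinal,
)

CDR3_RANGE = (105, 117)  # IMGT positions, inclusive


def toy_germlines() -> GermlineDB:
    """The bundled toy germline set: 6 heavy + 6 light synthetic alleles."""
    path = importlib.resources.files("ablm").joinpath("data/toy_germlines.fasta")
    with importlib.resources.as_file(path) as p:
        return GermlineDB.from_fasta(p)


def default_truncation_distribution() -> dict[int, float]:
    dist = {0: 0.20}
    w = 0.9 ** np.arange(14)
    w = 0.37 * w / w.sum()
    for i, l in enumerate(range(1, 15)):
        dist[l] = float(w[i])
    w2 = 0.85 ** np.arange(16)
    w2 = 0.43 * w2 / w2.sum()
    for i, l in enumerate(range(15, 31)):
        dist[l] = float(w2[i])
    return dist


@dataclass(frozen=True)
class GeneratorConfig:
    n_sequences: int
    chain: str = "heavy"
    germlines: GermlineDB | None = None  # default: toy set, chain-filtered
    mutation_rate: float = 0.03
    truncation_distribution: dict[int, float] | None = None
    ambiguous_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.ambiguous_rate <= 1.0):
            raise ValueError("rates must be in [0, 1]")
        if self.truncation_distribution is not None:
            total = sum(self.truncation_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("truncation_distribution must sum to 1")
            if any(l < 0 or p < 0 for l, p in self.truncation_distribution.items()):
                raise ValueError("truncation lengths and masses must be nonnegative")


def complete_truncation_distribution() -> dict[int, float]:
    """All mass at zero: every sequence complete (training-corpus setting)."""
    return {0: 1.0}


@dataclass(frozen=True)
class GroundTruthRecord:
    id: str
    allele: str
    chain: str
    full_residues: str
    positions: tuple[str, ...]  # IMGT position per full-sequence residue
    mutated_positions: tuple[int, ...]  # indices into full_residues
    truncation: int
    cdr3_span: tuple[int, int]  # half-open indices into full_residues
    emitted_len: int
    ambiguous_index: int | None  # index into the emitted sequence, or None


@dataclass(frozen=True)
class GroundTruth:
    records: dict[str, GroundTruthRecord]

    def __getitem__(self, sid: str) -> GroundTruthRecord:
        return self.records[sid]

    def cdr3_of(self, sid: str) -> str:
        """The true CDR3 of a sequence (from the full, untruncated form)."""
        r = self.records[sid]
        a, b = r.cdr3_span
        return r.full_residues[a:b]

    def to_csv(self, path) -> None:
        rows = [
            {
                "id": r.id,
                "allele": r.allele,
                "truncation": r.truncation,
                "mutated_positions": ";".join(map(str, r.mutated_positions)),
                "cdr3_start": r.cdr3_span[0],
                "cdr3_end": r.cdr3_span[1],
            }
            for r in self.records.values()
        ]
        pd.DataFrame(
            rows,
            columns=["id", "allele", "truncation", "mutated_positions", "cdr3_start", "cdr3_end"],
        ).to_csv(path, index=False)


def generate(cfg: GeneratorConfig) -> tuple[list[AntibodySequence], GroundTruth]:
    """Generate a repertoire; byte-identical output for a given seed."""
    db = cfg.germlines or toy_germlines()
    alleles = db.alleles(cfg.chain)
    if not alleles:
        raise ValueError(f"germline set has no {cfg.chain}-chain alleles")
    dist = cfg.truncation_distribution or default_truncation_distribution()
    lengths = np.array(sorted(dist))
    masses = np.array([dist[l] for l in lengths])
    rng = np.random.default_rng(cfg.seed)
    seqs: list[AntibodySequence] = []
    records: dict[str, GroundTruthRecord] = {}
    width = len(str(cfg.n_sequences))
    for n in range(cfg.n_sequences):
        sid = f"syn-{cfg.chain[0]}{n:0{width}d}"
        allele = alleles[rng.integers(len(alleles))]
        g = db[allele]
        body = list(g.residues)
        hits = np.flatnonzero(rng.random(len(body)) < cfg.mutation_rate)
        for i in hits:
            alternatives = AMINO_ACIDS.replace(body[i], "")
            body[i] = alternatives[rng.integers(len(alternatives))]
        full = "".join(body)
        cdr3_idx = [
            i
            for i, p in enumerate(g.positions)
            if CDR3_RANGE[0] <= imgt_ordinal(p)[0] <= CDR3_RANGE[1]
        ]
        cdr3_span = (cdr3_idx[0], cdr3_idx[-1] + 1) if cdr3_idx else (0, 0)
        # truncation capped so at least the CDR3 and framework 4 survive
        t = int(lengths[rng.choice(len(lengths), p=masses)])
        t = min(t, max(0, len(full) - 40))
        emitted = list(full[t:])
        amb: int | None = None
        if len(emitted) > 2 and rng.random() < cfg.ambiguous_rate:
            amb = int(rng.integers(1, len(emitted) - 1))
            emitted[amb] = WILDCARD
        numbering = tuple(
            (g.positions[t + j], j) for j in range(len(emitted))
        )
        seqs.append(
            AntibodySequence(
                id=sid, chain=cfg.chain, residues="".join(emitted), numbering=numbering
            )
        )
        records[sid] = GroundTruthRecord(
            id=sid,
            allele=allele,
            chain=cfg.chain,
            full_residues=full,
            positions=g.positions,
            mutated_positions=tuple(int(i) for i in hits),
            truncation=t,
            cdr3_span=cdr3_span,
            emitted_len=len(emitted),
            ambiguous_index=amb,
        )
    return seqs, GroundTruth(records)


class TruthNumberer:
    """Ground-truth IMGT numberer for generated repertoires.

    Stands in for an external numbering tool in tests. Sequences are
    identified by id and assumed suffix-aligned to their recorded full
    form (true for generated sequences, prefix-masked variants and
    restoration outputs). ``perturb`` injects a systematic error of δ
    positions into ``standard_missing`` for robustness experiments.
    """

    scheme = "IMGT"

    def __init__(self, truth: GroundTruth, perturb: int = 0):
        self.truth = truth
        self.perturb = perturb

    def _missing(self, seq: AntibodySequence) -> int:
        rec = self.truth.records.get(seq.id)
        if rec is None:
            raise KeyError(f"unknown sequence id: {seq.id}")
        return max(0, len(rec.full_residues) - len(seq.residues))

    def number(self, seq: AntibodySequence) -> tuple[tuple[str, int], ...]:
        rec = self.truth.records.get(seq.id)
        if rec is None:
            raise KeyError(f"unknown sequence id: {seq.id}")
        m = self._missing(seq)
        return tuple(
            (rec.positions[m + j], j) for j in range(len(seq.residues))
        )

    def standard_missing(self, seq: AntibodySequence) -> int:
        return max(0, self._missing(seq) + self.perturb)


def truth_numberer(truth: GroundTruth, perturb: int = 0) -> TruthNumberer:
    return TruthNumberer(truth, perturb)
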