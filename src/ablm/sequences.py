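"""Core antibody sequence types, tokenization and I/O.

Sequences are variable-region amino-acid strings over the 20 standard
one-letter codes plus ``*`` for an unknown residue. Tokenization maps a
sequence to a fixed-length id vector with ``<start>``/``<end>`` sentinels
and right padding; ``*`` becomes the mask token, so a sequence with
unknowns is already a valid masked-LM query.

Residue indices are 0-based half-open throughout. IMGT scheme positions
are strings ("1" .. "128", insertion codes allowed) and 1-based, as in the
numbering scheme itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Protocol

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "*"
ALPHABET = set(AMINO_ACIDS) | {WILDCARD}

#: token ids: the 20 amino acids in alphabetical order, then specials
AA_TO_ID = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MASK_ID = 20
PAD_ID = 21
START_ID = 22
END_ID = 23
VOCAB_SIZE = 24
ID_TO_AA = {i: aa for aa, i in AA_TO_ID.items()}

HEAVY = "heavy"
LIGHT = "light"


class SequenceError(ValueError):
    """Invalid residue content or structure."""


class LengthError(SequenceError):
    """Sequence does not fit the model's maximum token length."""


@dataclass(frozen=True)
class AntibodySequence:
    """A variable-region amino-acid sequence with optional IMGT numbering.

    ``numbering`` is a list of ``(scheme_position, residue_index)`` pairs
    with strictly increasing residue indices; it covers the residues for
    which an IMGT position is known.
    """

    id: str
    chain: str
    residues: str
    numbering: tuple[tuple[str, int], ...] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_wildcard(self) -> bool:
        return WILDCARD in self.residues

    def with_residues(self, residues: str) -> "AntibodySequence":
        return replace(self, residues=residues, numbering=None)


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[int, ...]
    length: int  # residue count (excludes start/end/pad)


def validate(seq: AntibodySequence) -> AntibodySequence:
    """Check alphabet and chain; normalize lowercase residues to uppercase."""
    if seq.chain not in (HEAVY, LIGHT):
        raise SequenceError(f"unknown chain type: {seq.chain!r}")
    residues = seq.residues.upper()
    if not residues:
        raise SequenceError(f"{seq.id}: empty sequence")
    bad = set(residues) - ALPHABET
    if bad:
        raise SequenceError(f"{seq.id}: invalid symbols {sorted(bad)}")
    if seq.numbering is not None:
        idx = [i for _, i in seq.numbering]
        if any(j <= i for i, j in zip(idx, idx[1:])):
            raise SequenceError(f"{seq.id}: numbering indices not strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(residues)):
            raise SequenceError(f"{seq.id}: numbering index out of range")
    if residues == seq.residues:
        return seq
    return replace(seq, residues=residues)


def tokenize(seq: AntibodySequence, max_len: int) -> TokenSequence:
    """Encode as [start] + residues (``*`` -> mask) + [end], padded to max_len.

    The effective maximum residue length is ``max_len - 2`` because the
    start/end sentinels occupy two slots.
    """
    n = len(seq.residues)
    if n + 2 > max_len:
        raise LengthError(
            f"{seq.id}: {n} residues exceed the {max_len - 2}-residue capacity "
            f"of a max_len={max_len} model"
        )
    body = [MASK_ID if c == WILDCARD else AA_TO_ID[c] for c in seq.residues]
    toks = [START_ID] + body + [END_ID]
    toks += [PAD_ID] * (max_len - len(toks))
    return TokenSequence(tokens=tuple(toks), length=n)


def detokenize(tok: TokenSequence, id: str = "seq", chain: str = HEAVY) -> AntibodySequence:
    """Inverse of :func:`tokenize`; mask tokens render as ``*``."""
    toks = list(tok.tokens)
    if not toks or toks[0] != START_ID:
        raise SequenceError("token sequence does not begin with the start token")
    body: list[str] = []
    i = 1
    while i < len(toks) and toks[i] not in (END_ID, PAD_ID):
        t = toks[i]
        if t == MASK_ID:
            body.append(WILDCARD)
        elif t in ID_TO_AA:
            body.append(ID_TO_AA[t])
        else:
            raise SequenceError(f"unexpected token id {t} inside the sequence body")
        i += 1
    if i >= len(toks) or toks[i] != END_ID:
        raise SequenceError("token sequence has no end token")
    if any(t != PAD_ID for t in toks[i + 1:]):
        raise SequenceError("non-pad tokens after the end token")
    return AntibodySequence(id=id, chain=chain, residues="".join(body))


class Numberer(Protocol):
    """IMGT numbering provider.

    Implementations assign IMGT scheme positions to residues and report how
    many N-terminal positions a sequence is missing relative to position 1
    of a complete variable region. Production users plug in an external
    numbering tool; the synthetic-data module provides a ground-truth
    implementation for testing.
    """

    scheme: str

    def number(self, seq: AntibodySequence) -> tuple[tuple[str, int], ...]:
        ...

    def standard_missing(self, seq: AntibodySequence) -> int:
        ...


# ---- I/O ----------------------------------------------------------------------


def read_fasta(path, chain: str = HEAVY) -> list[AntibodySequence]:
    """Read amino-acid FASTA; ``*`` is permitted in sequence lines."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(validate(AntibodySequence(id=rec.id, chain=chain, residues=str(rec.seq))))
    return out


def write_fasta(seqs: Iterable[AntibodySequence], path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_numbering_csv(path) -> dict[str, tuple[tuple[str, int], ...]]:
    """Read precomputed numberings: columns id, scheme_position, residue_index."""
    df = pd.read_csv(path, dtype={"id": str, "scheme_position": str, "residue_index": int})
    out: dict[str, tuple[tuple[str, int], ...]] = {}
    for sid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("residue_index")
        out[str(sid)] = tuple(zip(grp["scheme_position"], grp["residue_index"]))
    return out


def write_numbering_csv(numberings: dict[str, tuple[tuple[str, int], ...]], path) -> None:
    rows = [
        {"id": sid, "scheme_position": pos, "residue_index": idx}
        for sid, pairs in numberings.items()
        for pos, idx in pairs
    ]
    pd.DataFrame(rows, columns=["id", "scheme_position", "residue_index"]).to_csv(path, index=False)


def imgt_ordinal(position: str) -> tuple[int, str]:
    """Sortable key for an IMGT scheme position like '111' or '111A'."""
    digits = "".join(c for c in position if c.isdigit())
    letters = position[len(digits):]
    return int(digits), letters
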