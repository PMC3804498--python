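"""Fixed-length, gapless antibody framework alignments and position masks.

Antibody framework regions are length-conserved within a chain type, so a
framework "alignment" is simply a stack of equal-length residue strings with
no gap characters. This module reads, validates and writes such alignments
(FASTA), removes exact duplicate sequences, and applies user-supplied
position masks that drop the structurally variable CDR stretches from a
full-length numbered chain.

Masks are configuration, not knowledge shipped by the package: the exact set
of excluded CDR positions is a curation choice, so callers must provide it
(an illustrative, non-authoritative example lives in ``examples/``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import encode

CHAIN_TYPES = ("heavy", "kappa", "lambda")


def _validate_residues(seq: str, record_id: str) -> None:
    try:
        encode(seq)
    except ValueError as exc:
        raise ValueError(f"record {record_id!r}: {exc}") from None


@dataclass(frozen=True)
class QuerySequence:
    """A single fixed-length framework sequence to be scored or optimized."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        _validate_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FrameworkMSA:
    """A validated gapless, fixed-length framework alignment.

    Invariants enforced on construction: at least two sequences, all of one
    length, every character one of the 20 canonical residues.
    """

    sequences: tuple[str, ...]
    ids: tuple[str, ...]
    chain_type: str
    species: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "ids", tuple(self.ids))
        if self.chain_type not in CHAIN_TYPES:
            raise ValueError(
                f"chain_type must be one of {CHAIN_TYPES}, got {self.chain_type!r}"
            )
        if len(self.sequences) != len(self.ids):
            raise ValueError("sequences and ids must have equal length")
        if len(self.sequences) < 2:
            raise ValueError(
                f"alignment needs at least 2 sequences, got {len(self.sequences)}"
            )
        n = len(self.sequences[0])
        for rid, seq in zip(self.ids, self.sequences):
            if len(seq) != n:
                raise ValueError(
                    f"length mismatch: record {rid!r} has {len(seq)} residues, "
                    f"expected {n}"
                )
            _validate_residues(seq, rid)

    @property
    def n_positions(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def to_array(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_sequences, n_positions)."""
        return np.vstack([encode(s) for s in self.sequences])


def read_msa(path: str | Path, chain_type: str, species: str) -> FrameworkMSA:
    """Read a framework alignment from FASTA.

    Lowercase residues are uppercased; duplicate ids and duplicate sequences
    are retained as read (see :func:`deduplicate`). Ragged lengths or
    non-canonical characters (including gaps) raise ``ValueError`` naming
    the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return FrameworkMSA(sequences=seqs, ids=ids, chain_type=chain_type, species=species)


def write_msa(msa: FrameworkMSA, path: str | Path) -> None:
    """Write an alignment as FASTA, sequence lines wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s), id=rid, description="")
        for rid, s in zip(msa.ids, msa.sequences)
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def deduplicate(msa: FrameworkMSA) -> FrameworkMSA:
    """Drop exact duplicate *sequences* (ids are ignored for identity).

    The first occurrence is kept and original order is otherwise preserved,
    matching the redundancy filter applied to public antibody repertoires
    before frequency estimation. Idempotent.
    """
    seen: set[str] = set()
    keep_idx = []
    for i, s in enumerate(msa.sequences):
        if s not in seen:
            seen.add(s)
            keep_idx.append(i)
    return replace(
        msa,
        sequences=tuple(msa.sequences[i] for i in keep_idx),
        ids=tuple(msa.ids[i] for i in keep_idx),
    )


def read_queries(path: str | Path) -> list[QuerySequence]:
    """Read query sequences from FASTA (uppercased, validated)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [QuerySequence(id=r.id, residues=str(r.seq).upper()) for r in records]


@dataclass(frozen=True)
class PositionMask:
    """Which positions of a fully numbered chain enter the analysis.

    ``labels`` are position labels for the full chain (e.g. Kabat-style
    strings "H1".."H112"); ``keep`` flags the positions retained — the
    framework plus the structurally conserved CDR stubs.
    """

    labels: tuple[str, ...]
    keep: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "keep", tuple(bool(k) for k in self.keep))
        if len(self.labels) != len(self.keep):
            raise ValueError("labels and keep must have equal length")

    @property
    def n_kept(self) -> int:
        return sum(self.keep)

    def kept_labels(self) -> tuple[str, ...]:
        return tuple(l for l, k in zip(self.labels, self.keep) if k)


def apply_mask(full_sequence: str, mask: PositionMask) -> QuerySequence:
    """Select the kept positions of a full-length chain, order preserved."""
    if len(full_sequence) != len(mask.labels):
        raise ValueError(
            f"sequence has {len(full_sequence)} residues but mask labels "
            f"{len(mask.labels)} positions"
        )
    sub = "".join(c for c, k in zip(full_sequence, mask.keep) if k)
    return QuerySequence(id="masked", residues=sub)


def read_mask(path: str | Path) -> PositionMask:
    """Read a mask as a two-column table: position label, keep flag (0/1).

    Lines starting with ``#`` are comments.
    """
    labels: list[str] = []
    keep: list[bool] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: expected '<label> <0|1>', got {line!r}")
        labels.append(parts[0])
        keep.append(parts[1] == "1")
    if not labels:
        raise ValueError(f"{path}: empty mask")
    return PositionMask(labels=tuple(labels), keep=tuple(keep))


def write_mask(mask: PositionMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, k in zip(mask.labels, mask.keep):
            fh.write(f"{label}\t{int(k)}\n")
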