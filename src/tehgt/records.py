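"""Sequence containers used throughout the pipeline.

A :class:`SequenceRecord` is a named nucleotide or peptide sequence with
provenance (species tag and source type); an :class:`Alignment` is an
ordered stack of equal-length records.  Coordinates everywhere in this
package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

NT_ALPHABET = set("ACGTN-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")


class Source(str, Enum):
    """Provenance of a sequence record."""

    GENOMIC = "genomic"
    EST = "est"
    SIMULATED = "simulated"
    CONSENSUS = "consensus"


@dataclass
class SequenceRecord:
    id: str
    residues: str
    description: str = ""
    species: str = "unknown"
    source: Source = Source.GENOMIC
    moltype: str = "nt"  # "nt" or "aa"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        self.residues = self.residues.upper()
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} not in "
                f"{self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> "SequenceRecord":
        """Residues with alignment gaps removed (never edits letters)."""
        return replace(self, residues=self.residues.replace("-", ""))

    def reverse_complement(self) -> "SequenceRecord":
        if self.moltype != "nt":
            raise ValueError("reverse complement of a peptide is undefined")
        return replace(self, residues=revcomp(self.residues))


_COMP = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id!r}")
        seen.add(rec.id)


@dataclass
class Alignment:
    """Equal-length stack of records; rows keep their identity and order."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        n = len(self.records[0].residues)
        if n < 1:
            raise ValueError("alignment length must be >= 1")
        for rec in self.records:
            if len(rec.residues) != n:
                raise ValueError(
                    f"row {rec.id!r} has length {len(rec.residues)}, expected {n}"
                )
        check_unique_ids(self.records)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def row(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def to_matrix(self) -> np.ndarray:
        """Rows x columns array of single characters."""
        return np.array([list(rec.residues) for rec in self.records])

    def select_columns(self, keep: Sequence[int] | np.ndarray) -> "Alignment":
        keep = list(keep)
        recs = [
            replace(rec, residues="".join(rec.residues[i] for i in keep))
            for rec in self.records
        ]
        return Alignment(recs)

    def select_rows(self, ids: Sequence[str]) -> "Alignment":
        wanted = set(ids)
        return Alignment([rec for rec in self.records if rec.id in wanted])
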