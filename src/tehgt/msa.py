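"""Multiple alignment and the two alignment-level filters.

Alignment is delegated to MAFFT (the field-standard progressive
aligner); the filters are applied in a fixed order — gap-heavy columns
first, then short rows, with row completeness measured against the
post-column-filter width.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from .io import read_fasta, write_fasta
from .records import Alignment, SequenceRecord


def progressive_align(records: list[SequenceRecord]) -> Alignment:
    """Align records with MAFFT (default progressive settings).

    A single record is returned unchanged as a one-row alignment.
    Row order and record metadata are preserved.
    """
    if not records:
        raise ValueError("nothing to align")
    if len(records) == 1:
        return Alignment([records[0]])
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(records, inp)
        proc = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = Path(tmp) / "out.fasta"
        out.write_text(proc.stdout)
        aligned = {rec.id: rec.residues for rec in read_fasta(out)}
    rows = [replace(rec, residues=aligned[rec.id]) for rec in records]
    return Alignment(rows)


def filter_gap_columns(alignment: Alignment, max_gap_fraction: float = 0.15) -> Alignment:
    """Delete columns whose gap fraction is >= ``max_gap_fraction``."""
    mat = alignment.to_matrix()
    gap_frac = (mat == "-").mean(axis=0)
    keep = np.nonzero(gap_frac < max_gap_fraction)[0]
    if keep.size == 0:
        raise ValueError("empty alignment after gap-column filtering")
    return alignment.select_columns(keep)


def drop_short_rows(alignment: Alignment, min_fraction: float = 0.75) -> Alignment:
    """Remove rows whose residue count is below ``min_fraction`` of the
    alignment width (inclusive at the threshold)."""
    n_cols = alignment.n_cols
    kept = [
        rec
        for rec in alignment
        if len(rec.residues) - rec.residues.count("-") >= min_fraction * n_cols
    ]
    if len(kept) < 2:
        raise ValueError("fewer than 2 rows remain after length filtering")
    return Alignment(kept)
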