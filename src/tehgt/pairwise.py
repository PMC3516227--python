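"""Pairwise alignment helpers shared by harvesting, dedup and identity
computations.

All identity figures in this package are percent identity over aligned
columns, excluding columns where either row has a gap; ambiguous bases
(N/X) count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_AMBIGUOUS = set("NX")


def _aligner(mode: str, match: float, mismatch: float, open_gap: float,
             extend: float, free_ends: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend
    if free_ends and mode == "global":
        aligner.end_gap_score = 0
    return aligner


@dataclass
class PairwiseResult:
    gapped_a: str
    gapped_b: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.gapped_a)

    def comparable_sites(self, count_end_gaps: bool = False) -> int:
        """Columns where both rows carry a residue."""
        return sum(
            1
            for x, y in zip(self.gapped_a, self.gapped_b)
            if x != "-" and y != "-"
        )

    def identity(self) -> float:
        """Percent identity over gap-excluded columns (N/X mismatch)."""
        matches = 0
        compared = 0
        for x, y in zip(self.gapped_a, self.gapped_b):
            if x == "-" or y == "-":
                continue
            compared += 1
            if x == y and x not in _AMBIGUOUS:
                matches += 1
        if compared == 0:
            return 0.0
        return 100.0 * matches / compared


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    open_gap: float = -4.0,
    extend: float = -1.0,
    free_ends: bool = True,
) -> PairwiseResult:
    """Needleman-Wunsch with affine gaps; end gaps free by default."""
    aligner = _aligner("global", match, mismatch, open_gap, extend, free_ends)
    aln = aligner.align(a, b)[0]
    return PairwiseResult(str(aln[0]), str(aln[1]), aln.score)


def local_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    open_gap: float = -5.0,
    extend: float = -2.0,
) -> PairwiseResult:
    """Smith-Waterman; used as the reference local aligner."""
    aligner = _aligner("local", match, mismatch, open_gap, extend, False)
    aln = aligner.align(a, b)[0]
    return PairwiseResult(str(aln[0]), str(aln[1]), aln.score)


def percent_identity(a: str, b: str, free_ends: bool = True) -> float:
    """Identity of two unaligned sequences after global alignment.

    With ``free_ends=False`` terminal gaps are penalized, which keeps
    unrelated sequences from scoring high identity over a tiny
    coincidental core (use this when whole sequences are compared, as
    in dedup clustering).
    """
    return global_align(a, b, free_ends=free_ends).identity()
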