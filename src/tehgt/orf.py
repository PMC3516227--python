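"""ORF location, disruption classification, and peptide deduction.

Most aged TE copies carry frameshift or nonsense mutations.  To use
them in protein-level phylogenetics anyway, a copy is aligned to the
family consensus ORF and every consensus-frame codon that contains a
frame-breaking indel, or that translates to a stop, is excised before
translation.  Translation uses the standard genetic code only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from Bio.Seq import Seq

from .pairwise import global_align
from .records import SequenceRecord, Source, revcomp

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class Disruption:
    position: int  # codon index on the consensus ORF
    kind: str  # "frameshift" or "nonsense"


@dataclass
class OrfAnnotation:
    interval: tuple[int, int]  # 0-based half-open; (0, 0) when absent
    frame: int  # 0/1/2; frame on the strand the ORF was found on
    strand: str  # "+" or "-"
    intact: bool
    disruptions: list[Disruption] = field(default_factory=list)

    def __post_init__(self) -> None:
        a, b = self.interval
        if self.intact:
            if (b - a) % 3 != 0:
                raise ValueError("intact ORF length must be a multiple of 3")
            if self.disruptions:
                raise ValueError("intact ORF cannot carry disruptions")


def _longest_orf_one_strand(seq: str, min_codons: int) -> tuple[int, int] | None:
    best: tuple[int, int] | None = None
    n = len(seq)
    for frame in range(3):
        i = frame
        start = None
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                span = (start, i + 3)
                if (span[1] - span[0]) // 3 >= min_codons:
                    if best is None or span[1] - span[0] > best[1] - best[0]:
                        best = span
                start = None
            i += 3
    return best


def locate_orf(record: SequenceRecord, min_length_codons: int = 50) -> OrfAnnotation:
    """Longest ATG-to-stop reading frame on either strand.

    ``intact`` is true iff an ORF of at least ``min_length_codons``
    codons (start and stop included) exists; otherwise the annotation
    carries an empty interval.
    """
    seq = record.residues.replace("-", "")
    fwd = _longest_orf_one_strand(seq, min_length_codons)
    rev = _longest_orf_one_strand(revcomp(seq), min_length_codons)
    if fwd is None and rev is None:
        return OrfAnnotation((0, 0), 0, "+", intact=False)
    use_rev = rev is not None and (fwd is None or
                                   rev[1] - rev[0] > fwd[1] - fwd[0])
    if use_rev:
        a, b = rev  # coordinates on the reverse strand
        n = len(seq)
        return OrfAnnotation((n - b, n - a), a % 3, "-", intact=True)
    a, b = fwd
    return OrfAnnotation((a, b), a % 3, "+", intact=True)


def translate(seq: str) -> str:
    """Standard-code translation of an in-frame nucleotide string,
    excluding a terminal stop."""
    aa = str(Seq(seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


ConsensusLike = Union[str, SequenceRecord]


def _consensus_orf(reference: ConsensusLike) -> str:
    """Extract the ORF substring of a consensus (profile, record or str)."""
    if hasattr(reference, "consensus"):
        seq = reference.consensus  # ConsensusProfile duck-type
    elif isinstance(reference, SequenceRecord):
        seq = reference.residues
    else:
        seq = str(reference)
    seq = seq.upper().replace("-", "")
    ann = locate_orf(
        SequenceRecord(id="_ref", residues=seq, source=Source.CONSENSUS),
        min_length_codons=30,
    )
    if not ann.intact:
        raise ValueError("reference consensus contains no intact ORF")
    a, b = ann.interval
    return seq[a:b] if ann.strand == "+" else revcomp(seq)[a:b]


def _aligned_to_orf(copy: SequenceRecord, orf: str, min_coverage: float):
    copy_seq = copy.residues.replace("-", "")
    fwd = global_align(copy_seq, orf)
    rev = global_align(revcomp(copy_seq), orf)
    res = fwd if fwd.score >= rev.score else rev
    if res.comparable_sites() < min_coverage * len(orf):
        raise ValueError(
            f"insufficient homology: copy {copy.id!r} covers "
            f"{res.comparable_sites()} of {len(orf)} consensus ORF sites"
        )
    return res


def _frame_excise(res, orf: str) -> tuple[list[str], list[Disruption]]:
    """Per consensus codon: the copy's triplet, or "---" when the codon
    is excised (frameshift, stop) or absent (clean deletion).

    Indel runs are classified whole: a run whose length is divisible
    by 3 preserves the reading frame (clean codon indel, inserted
    residues dropped), any other run is a frameshift and every codon
    it touches is excised.  Codons straddled by one clean run are
    merged and re-read as consensus-frame triplets.  The consensus
    ORF's own terminal stop is not a disruption.
    """
    n_codons = len(orf) // 3
    # column bookkeeping: consensus position per column, indel runs
    ref_pos_of: list[int] = []
    ref_pos = -1
    for ref_char in res.gapped_b:
        if ref_char != "-":
            ref_pos += 1
        ref_pos_of.append(max(ref_pos, 0))
    runs: list[tuple[str, int, int]] = []  # (kind, start col, end col)
    kind_of: list[str | None] = []
    for a_char, b_char in zip(res.gapped_a, res.gapped_b):
        kind_of.append("del" if a_char == "-" else
                       "ins" if b_char == "-" else None)
    col = 0
    while col < len(kind_of):
        if kind_of[col] is None:
            col += 1
            continue
        start = col
        while col < len(kind_of) and kind_of[col] == kind_of[start]:
            col += 1
        runs.append((kind_of[start], start, col))

    # blocks: consecutive codons connected by a straddling run;
    # a block is "bad" when it contains a frame-breaking run
    parent = list(range(n_codons))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bad_run_positions: list[int] = []
    for kind, start, end in runs:
        codons = sorted({ref_pos_of[c] // 3 for c in range(start, end)})
        for a, b in zip(codons, codons[1:]):
            parent[find(b)] = find(a)
        if (end - start) % 3 != 0:
            bad_run_positions.append(codons[0])

    # columns of each codon (insertions attach via ref_pos_of)
    codon_cols: list[list[int]] = [[] for _ in range(n_codons)]
    for c, rp in enumerate(ref_pos_of):
        codon_cols[rp // 3].append(c)

    blocks: dict[int, list[int]] = {}
    for ci in range(n_codons):
        blocks.setdefault(find(ci), []).append(ci)

    out = ["---"] * n_codons
    disruptions: list[Disruption] = []
    for root in sorted(blocks):
        codons = sorted(blocks[root])
        codon_set = set(codons)
        bad = sorted(p for p in bad_run_positions if p in codon_set)
        if bad:
            for pos in bad:
                disruptions.append(Disruption(pos, "frameshift"))
            continue  # whole block excised
        chars = []
        for ci in codons:
            chars.extend(
                res.gapped_a[c]
                for c in codon_cols[ci]
                if res.gapped_b[c] != "-" and res.gapped_a[c] != "-"
            )
        triplets = [
            "".join(chars[i:i + 3]) for i in range(0, len(chars) - 2, 3)
        ]
        for k, ci in enumerate(codons):
            if k >= len(triplets):
                break  # clean deletion: trailing codons of the block absent
            trip = triplets[k]
            if trip in _STOPS:
                if ci == n_codons - 1 and orf[3 * ci:3 * ci + 3] in _STOPS:
                    continue  # the ORF's own terminator
                disruptions.append(Disruption(ci, "nonsense"))
                continue
            out[ci] = trip
    disruptions.sort(key=lambda d: d.position)
    return out, disruptions


def deduce_peptide_with_report(
    copy: SequenceRecord,
    reference: ConsensusLike,
    min_coverage: float = 0.5,
) -> tuple[SequenceRecord, list[Disruption]]:
    """Peptide deduction anchored on the consensus reading frame.

    The copy is globally aligned (free end gaps) to the consensus ORF;
    consensus-frame codons carrying a frame-breaking indel or a
    premature stop are excised, the rest translated.  In-frame
    inserted residues are dropped, so the peptide never exceeds the
    consensus ORF in codons.
    """
    orf = _consensus_orf(reference)
    res = _aligned_to_orf(copy, orf, min_coverage)
    codons, disruptions = _frame_excise(res, orf)
    peptide = "".join(
        str(Seq(c).translate()) for c in codons if c != "---"
    )
    pep = SequenceRecord(
        id=f"{copy.id}_pep",
        residues=peptide or "X",
        description=f"{copy.description} deduced_peptide",
        species=copy.species,
        source=copy.source,
        moltype="aa",
    )
    return pep, disruptions


def consensus_frame_codons(
    copy: SequenceRecord,
    reference: ConsensusLike,
    min_coverage: float = 0.5,
) -> str:
    """The copy's codons laid out on the consensus ORF frame.

    Returns a string of length 3 x (consensus ORF codons) where each
    consensus-frame codon holds the copy's aligned triplet, or ``---``
    when the codon is absent, frameshifted, or a stop.  Two such
    strings are directly comparable codon-by-codon (e.g. for Ka/Ks).
    """
    orf = _consensus_orf(reference)
    res = _aligned_to_orf(copy, orf, min_coverage)
    codons, _ = _frame_excise(res, orf)
    return "".join(codons)


def deduce_peptide(copy: SequenceRecord, reference: ConsensusLike,
                   min_coverage: float = 0.5) -> SequenceRecord:
    pep, _ = deduce_peptide_with_report(copy, reference, min_coverage)
    return pep


def disruption_report(
    copies: list[SequenceRecord], reference: ConsensusLike
) -> list[tuple[str, int, int, bool]]:
    """Rows of (copy id, n frameshifts, n stops, intact flag)."""
    rows = []
    for copy in copies:
        try:
            _, dis = deduce_peptide_with_report(copy, reference)
        except ValueError:
            rows.append((copy.id, -1, -1, False))
            continue
        nfs = sum(1 for d in dis if d.kind == "frameshift")
        nst = sum(1 for d in dis if d.kind == "nonsense")
        rows.append((copy.id, nfs, nst, not dis))
    return rows
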