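"""TE copy harvesting: similarity search, fragment assembly, consensus
building, retrieval filters, dedup, copy counting, and in-silico PCR.

The search is a BLASTN-like seed-and-extend: exact shared words
nominate subject windows, a Smith-Waterman-Gotoh kernel produces the
gapped local alignment, and hits are thresholded on percent identity
(over aligned columns, gaps excluded, N = mismatch) and aligned length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pairwise import global_align, local_align, percent_identity
from .records import SequenceRecord, Source, revcomp
from .swalign import smith_waterman

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CHARS = "ACGTN-"


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(_CHARS[i] for i in arr)


# ---------------------------------------------------------------------
# similarity search


@dataclass
class SearchHit:
    query_id: str
    subject_id: str
    query_interval: tuple[int, int]  # on the query, 0-based half-open
    subject_interval: tuple[int, int]  # forward-strand subject coordinates
    strand: str  # "+" or "-"
    identity: float  # percent over aligned, gap-excluded columns
    aligned_length: int  # alignment columns
    gapped_query: str
    gapped_subject: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be within [0, 100]")


def _alignment_stats(qa: np.ndarray, sa: np.ndarray) -> tuple[float, int]:
    cols = len(qa)
    both = (qa != 5) & (sa != 5)
    matches = int(((qa == sa) & both & (qa != 4)).sum())
    compared = int(both.sum())
    identity = 100.0 * matches / compared if compared else 0.0
    return identity, cols


def _seed_windows(q: np.ndarray, s: np.ndarray, word: int) -> list[tuple[int, int]]:
    """Subject windows around diagonals sharing an exact word with the query."""
    if len(q) < word or len(s) < word:
        return []
    index: dict[bytes, bool] = {}
    qb = q.tobytes()
    for i in range(len(q) - word + 1):
        index[qb[i:i + word]] = True
    sb = s.tobytes()
    hit_pos = [j for j in range(len(s) - word + 1) if sb[j:j + word] in index]
    if not hit_pos:
        return []
    # one window per run of nearby seeds; the margin only needs to span
    # seedless stretches between conserved words, not the whole query
    margin = min(len(q) + 50, 250)
    windows: list[tuple[int, int]] = []
    start = hit_pos[0]
    prev = hit_pos[0]
    for j in hit_pos[1:]:
        if j - prev > margin:
            windows.append((max(0, start - margin), min(len(s), prev + word + margin)))
            start = j
        prev = j
    windows.append((max(0, start - margin), min(len(s), prev + word + margin)))
    return windows


def similarity_search(
    query: SequenceRecord,
    subjects: list[SequenceRecord],
    min_identity: float = 90.0,
    min_aligned_length: int = 100,
    word_size: int = 11,
    max_hits_per_subject: int = 16,
) -> list[SearchHit]:
    """Seed-and-extend local search on both strands.

    Reverse-strand hits carry forward-strand subject coordinates and
    strand "-"; the hit list is sorted by descending identity, then
    aligned length.  Repeated hits on one subject are found by masking
    already-matched subject stretches and re-aligning.
    """
    q = _encode(query.residues)
    hits: list[SearchHit] = []
    for subject in subjects:
        for strand in "+-":
            sseq = subject.residues if strand == "+" else revcomp(subject.residues)
            s = _encode(sseq)
            slen = len(s)
            for w0, w1 in _seed_windows(q, s, word_size):
                window = s[w0:w1].copy()
                for _ in range(max_hits_per_subject):
                    score, qiv, siv, qa, sa = smith_waterman(q, window)
                    if score <= 0:
                        break
                    identity, cols = _alignment_stats(qa, sa)
                    if cols < min_aligned_length or identity < min_identity:
                        break
                    s0, s1 = w0 + siv[0], w0 + siv[1]
                    if strand == "-":
                        fwd_iv = (slen - s1, slen - s0)
                    else:
                        fwd_iv = (s0, s1)
                    hits.append(
                        SearchHit(
                            query_id=query.id,
                            subject_id=subject.id,
                            query_interval=qiv,
                            subject_interval=fwd_iv,
                            strand=strand,
                            identity=identity,
                            aligned_length=cols,
                            gapped_query=_decode(qa),
                            gapped_subject=_decode(sa),
                        )
                    )
                    window[siv[0]:siv[1]] = 4  # mask as N and re-scan
    hits.sort(key=lambda h: (-h.identity, -h.aligned_length, h.subject_id))
    return hits


# ---------------------------------------------------------------------
# fragment assembly (greedy overlap merging)


def _best_overlap(a: str, b: str) -> tuple[float, int, "str | None"]:
    """Best end-spanning local alignment of a and b.

    Returns (identity, overlap columns, merged sequence or None).  The
    alignment must reach an end of each sequence so that the pair can
    be merged into one contig; the overlap takes a's residues (the
    first-listed record wins ties between two sequences).
    """
    res = local_align(a, b)
    if res.n_columns == 0:
        return 0.0, 0, None
    # locate the aligned blocks on each input
    a_core = res.gapped_a.replace("-", "")
    b_core = res.gapped_b.replace("-", "")
    a0 = a.find(a_core)
    b0 = b.find(b_core)
    if a0 < 0 or b0 < 0:
        return 0.0, 0, None
    a1 = a0 + len(a_core)
    b1 = b0 + len(b_core)
    identity = res.identity()
    cols = res.comparable_sites()
    # b hangs off a's right end
    if a1 == len(a) and b0 == 0 and (a0 > 0 or b1 < len(b)):
        merged = a + b[b1:]
        return identity, cols, merged
    # b hangs off a's left end
    if b1 == len(b) and a0 == 0 and (b0 > 0 or a1 < len(a)):
        merged = b[:b0] + a
        return identity, cols, merged
    # containment
    if a0 == 0 and a1 == len(a):
        return identity, cols, b
    if b0 == 0 and b1 == len(b):
        return identity, cols, a
    return identity, cols, None


def merge_overlapping_fragments(
    records: list[SequenceRecord],
    min_identity: float = 99.0,
    min_overlap: int = 40,
) -> list[SequenceRecord]:
    """Greedy single-linkage assembly of overlapping fragments.

    While any pair overlaps by at least ``min_overlap`` aligned bases
    at ``min_identity`` percent or better, the pair is merged into one
    contig.  Output count never exceeds input count.
    """
    pool = [(rec.id, rec.residues, rec) for rec in records]
    merged_flag = True
    while merged_flag and len(pool) > 1:
        merged_flag = False
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                ident, cols, merged = _best_overlap(pool[i][1], pool[j][1])
                if merged is not None and cols >= min_overlap and ident >= min_identity:
                    base = pool[i][2]
                    contig = SequenceRecord(
                        id=f"{pool[i][0]}+{pool[j][0]}",
                        residues=merged,
                        description=f"contig of {pool[i][0]},{pool[j][0]}",
                        species=base.species,
                        source=base.source,
                    )
                    pool = (
                        pool[:i] + pool[i + 1:j] + pool[j + 1:]
                        + [(contig.id, contig.residues, contig)]
                    )
                    merged_flag = True
                    break
            if merged_flag:
                break
    return [entry[2] for entry in pool]


# ---------------------------------------------------------------------
# majority-rule consensus


@dataclass
class ConsensusProfile:
    counts: np.ndarray  # (query length, 5) over A,C,G,T,-
    consensus: str
    n_support: int
    kept_columns: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def build_consensus(hits: list[SearchHit], top_n: int = 300) -> ConsensusProfile:
    """Simple-majority consensus over hits stacked on query coordinates.

    Per column, the most frequent residue wins; ties break by the fixed
    order A < C < G < T, with the gap losing every tie.  Columns where
    the gap is the strict majority are deleted from the consensus
    string.  Subject positions a hit does not cover count as gaps, so
    the consensus spans the well-supported core of the query frame.
    """
    if not hits:
        raise ValueError("no hits to build a consensus from")
    if len(hits) < top_n:
        logger.warning("only %d hits available (top_n=%d); using all",
                       len(hits), top_n)
    use = sorted(hits, key=lambda h: (-h.identity, -h.aligned_length))[:top_n]
    qlen = max(h.query_interval[1] for h in use)
    counts = np.zeros((qlen, 5), dtype=np.int64)
    for hit in use:
        qpos = hit.query_interval[0]
        counts[:hit.query_interval[0], 4] += 1
        for qc, sc in zip(hit.gapped_query, hit.gapped_subject):
            if qc == "-":
                continue  # insertion relative to the query frame
            if sc in _CODE:
                counts[qpos, _CODE[sc]] += 1
            else:  # subject gap or N
                counts[qpos, 4] += 1
            qpos += 1
        counts[qpos:, 4] += 1
    consensus_chars = []
    kept = []
    for col in range(qlen):
        base_counts = counts[col, :4]
        gap_count = counts[col, 4]
        if gap_count > base_counts.sum():
            continue  # strict gap majority: column deleted
        consensus_chars.append("ACGT"[int(np.argmax(base_counts))])
        kept.append(col)
    return ConsensusProfile(
        counts=counts,
        consensus="".join(consensus_chars),
        n_support=len(use),
        kept_columns=kept,
    )


def consensus_record(profile: ConsensusProfile, rec_id: str = "consensus") -> SequenceRecord:
    return SequenceRecord(
        id=rec_id,
        residues=profile.consensus,
        description=f"majority-rule consensus of {profile.n_support} hits",
        species="consensus",
        source=Source.CONSENSUS,
    )


# ---------------------------------------------------------------------
# retrieval filters


def filter_by_orf_overlap(
    hits: list[SearchHit],
    orf_interval: tuple[int, int],
    min_fraction: float = 0.75,
) -> list[SearchHit]:
    """Keep hits whose query-coordinate span covers at least
    ``min_fraction`` of the ORF length (inclusive threshold)."""
    a, b = orf_interval
    orf_len = b - a
    if orf_len <= 0:
        raise ValueError("empty ORF interval")
    kept = []
    for hit in hits:
        q0, q1 = hit.query_interval
        overlap = max(0, min(q1, b) - max(q0, a))
        if overlap >= min_fraction * orf_len:
            kept.append(hit)
    return kept


def dedupe_representatives(
    records: list[SequenceRecord],
    nt_threshold: float = 95.0,
    aa_threshold: float = 80.0,
) -> list[SequenceRecord]:
    """One representative per cluster of highly similar sequences.

    Single-linkage clustering at the molecule-type threshold (pairwise
    identity, gap-excluded), run within each species independently;
    the representative is the longest member, ties by lexicographic id.
    """
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    out = []
    for species in sorted(by_species):
        group = by_species[species]
        threshold = aa_threshold if group[0].moltype == "aa" else nt_threshold
        parent = list(range(len(group)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if find(i) == find(j):
                    continue
                if percent_identity(group[i].residues, group[j].residues,
                                    free_ends=False) >= threshold:
                    parent[find(j)] = find(i)
        clusters: dict[int, list[SequenceRecord]] = {}
        for i, rec in enumerate(group):
            clusters.setdefault(find(i), []).append(rec)
        for members in clusters.values():
            members.sort(key=lambda r: (-len(r.residues), r.id))
            out.append(members[0])
    out.sort(key=lambda r: r.id)
    return out


# ---------------------------------------------------------------------
# copy counting


def count_copies_and_fraction(
    hits: list[SearchHit],
    min_identity: float = 90.0,
    assembly_size: int = 1,
) -> tuple[int, int, float]:
    """(copy count, occupied bp, genome fraction) from filtered hits.

    Occupied bp is the union of subject intervals per subject; the
    fraction is reported unrounded.
    """
    if assembly_size <= 0:
        raise ValueError("assembly size must be > 0")
    passing = [h for h in hits if h.identity >= min_identity]
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for hit in passing:
        by_subject.setdefault(hit.subject_id, []).append(hit.subject_interval)
    occupied = 0
    for intervals in by_subject.values():
        intervals.sort()
        cur_a, cur_b = intervals[0]
        for a, b in intervals[1:]:
            if a > cur_b:
                occupied += cur_b - cur_a
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        occupied += cur_b - cur_a
    return len(passing), occupied, occupied / assembly_size


# ---------------------------------------------------------------------
# in-silico PCR


@dataclass
class Amplicon:
    template_id: str
    forward_interval: tuple[int, int]
    reverse_interval: tuple[int, int]
    product_length: int
    mismatches: int
    orientation: str = "+"


def _primer_sites(template: str, primer: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(start, mismatches) of primer annealing sites; the 3'-terminal
    3 nt must match exactly and N counts as a mismatch."""
    t = _encode(template)
    p = _encode(primer)
    n, k = len(t), len(p)
    if n < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, k)
    mismatch = (windows != p) | (windows == 4) | (p == 4)
    total = mismatch.sum(axis=1)
    tail_ok = ~mismatch[:, -3:].any(axis=1)
    keep = np.nonzero((total <= max_mismatches) & tail_ok)[0]
    return [(int(i), int(total[i])) for i in keep]


def in_silico_pcr(
    templates: list[SequenceRecord],
    forward: str,
    reverse: str,
    max_mismatches: int = 2,
    max_product: int = 2000,
) -> list[Amplicon]:
    """Predicted PCR products on each template, both orientations.

    The forward primer must match the plus strand and the reverse
    primer's reverse complement must occur downstream, each with at
    most ``max_mismatches`` and an exact 3'-terminal 3 nt.
    """
    forward = forward.upper()
    reverse = reverse.upper()
    if len(forward) < 15 or len(reverse) < 15:
        raise ValueError("primers must be at least 15 nt")
    amplicons = []
    for rec in templates:
        for orientation, fwd_p, rev_p in (
            ("+", forward, reverse),
            ("-", reverse, forward),
        ):
            f_sites = _primer_sites(rec.residues, fwd_p, max_mismatches)
            r_sites = _primer_sites(rec.residues, revcomp(rev_p), max_mismatches)
            for f0, fmm in f_sites:
                for r0, rmm in r_sites:
                    r1 = r0 + len(rev_p)
                    product = r1 - f0
                    if r0 >= f0 + len(fwd_p) and 0 < product <= max_product:
                        amplicons.append(
                            Amplicon(
                                template_id=rec.id,
                                forward_interval=(f0, f0 + len(fwd_p)),
                                reverse_interval=(r0, r1),
                                product_length=product,
                                mismatches=fmm + rmm,
                                orientation=orientation,
                            )
                        )
    return amplicons
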