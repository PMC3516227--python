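"""Similarity search (with a Smith-Waterman oracle), fragment
assembly, consensus building, filters, dedup, copy counting and
in-silico PCR."""

import numpy as np
import pytest
from Bio import Align

from tehgt.harvest import (build_consensus, count_copies_and_fraction,
                           dedupe_representatives, filter_by_orf_overlap,
                           in_silico_pcr, merge_overlapping_fragments,
                           similarity_search)
from tehgt.records import SequenceRecord, revcomp
from tehgt.simulate import SimConfig, evolve_family
from tehgt.tree import PhyloTree


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, p_sub):
    out = []
    for c in seq:
        if rng.random() < p_sub:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


# -- similarity search -------------------------------------------------


def test_exact_containment_hit():
    rng = np.random.default_rng(0)
    query = SequenceRecord(id="q", residues=_rand_seq(rng, 200))
    subject = SequenceRecord(
        id="s", residues=_rand_seq(rng, 100) + query.residues + _rand_seq(rng, 80))
    hits = similarity_search(query, [subject], min_identity=90,
                             min_aligned_length=150)
    assert len(hits) == 1
    hit = hits[0]
    assert hit.identity == 100.0
    assert hit.strand == "+"
    assert hit.subject_interval == (100, 300)
    assert hit.aligned_length == 200


def test_reverse_complement_hit_on_forward_coordinates():
    rng = np.random.default_rng(1)
    query = SequenceRecord(id="q", residues=_rand_seq(rng, 150))
    subject = SequenceRecord(id="s", residues=revcomp(query.residues))
    hits = similarity_search(query, [subject], min_identity=90,
                             min_aligned_length=100)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].identity == 100.0
    assert hits[0].subject_interval == (0, 150)


def test_unrelated_sequences_give_no_hits_confirmed_by_oracle():
    rng = np.random.default_rng(2)
    query = SequenceRecord(id="q", residues=_rand_seq(rng, 1610))
    subject = SequenceRecord(id="s", residues=_rand_seq(rng, 1000))
    hits = similarity_search(query, [subject], min_identity=90,
                             min_aligned_length=100)
    assert hits == []
    # Smith-Waterman oracle: the best local alignment of the same pair
    # is far below the thresholds
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score, aligner.mismatch_score = 1, -2
    aligner.open_gap_score, aligner.extend_gap_score = -5, -2
    best = aligner.align(query.residues, subject.residues)[0]
    assert best.score < 100  # cannot reach 100 aligned columns at 90%


def test_search_agrees_with_smith_waterman_oracle():
    """Best-hit score/identity/coordinates vs Biopython's SW on 50
    mutated pairs (co-optimal tracebacks may differ, scores may not)."""
    rng = np.random.default_rng(3)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score, aligner.mismatch_score = 1, -2
    aligner.open_gap_score, aligner.extend_gap_score = -5, -2
    for trial in range(50):
        n = int(rng.integers(120, 500))
        base = _rand_seq(rng, n)
        query = SequenceRecord(id="q", residues=base)
        mutated = _mutate(rng, base, p_sub=0.05)
        subject = SequenceRecord(
            id="s", residues=_rand_seq(rng, 30) + mutated + _rand_seq(rng, 30))
        hits = similarity_search(query, [subject], min_identity=80,
                                 min_aligned_length=50)
        assert hits, f"trial {trial}: no hit on a 95%-identical pair"
        hit = hits[0]
        oracle = aligner.align(query.residues, subject.residues)[0]
        ours = (hit.identity / 100.0) * hit.aligned_length  # approx matches
        score_ours = sum(
            (1 if a == b else -2)
            for a, b in zip(hit.gapped_query, hit.gapped_subject)
            if a != "-" and b != "-"
        )
        # recompute the full affine score of our traceback
        score_ours = _affine_score(hit.gapped_query, hit.gapped_subject)
        assert score_ours == pytest.approx(oracle.score)
        q0, q1 = oracle.aligned[0][0][0], oracle.aligned[0][-1][1]
        assert abs(hit.query_interval[0] - q0) <= 3
        assert abs(hit.query_interval[1] - q1) <= 3


def _affine_score(ga, gb, match=1, mismatch=-2, open_=-5, ext=-2):
    score = 0
    in_gap = False
    for a, b in zip(ga, gb):
        if a == "-" or b == "-":
            score += ext if in_gap else open_
            in_gap = True
        else:
            score += match if a == b else mismatch
            in_gap = False
    return score


# -- fragment assembly -------------------------------------------------


def test_exact_overlap_merges_to_one_contig():
    rng = np.random.default_rng(4)
    contig = _rand_seq(rng, 150)
    a = SequenceRecord(id="a", residues=contig[:100])
    b = SequenceRecord(id="b", residues=contig[50:])
    merged = merge_overlapping_fragments([a, b])
    assert len(merged) == 1
    assert merged[0].residues == contig


def test_short_overlap_below_40bp_not_merged():
    rng = np.random.default_rng(5)
    contig = _rand_seq(rng, 170)
    a = SequenceRecord(id="a", residues=contig[:100])
    b = SequenceRecord(id="b", residues=contig[70:])  # 30 bp overlap
    merged = merge_overlapping_fragments([a, b])
    assert len(merged) == 2


def test_tiling_fragments_reconstruct_master(master):
    seq = master.residues
    frags = [
        SequenceRecord(id="f1", residues=seq[0:700]),
        SequenceRecord(id="f2", residues=seq[600:1200]),
        SequenceRecord(id="f3", residues=seq[1100:]),
    ]
    merged = merge_overlapping_fragments(frags)
    assert len(merged) == 1
    assert merged[0].residues == seq


# -- consensus ---------------------------------------------------------


def _hits_for(query_rec, subjects):
    return similarity_search(query_rec, subjects, min_identity=60,
                             min_aligned_length=100)


def test_consensus_of_identical_hits_is_that_sequence(master):
    subjects = [
        SequenceRecord(id=f"s{i}", residues=master.residues)
        for i in range(5)
    ]
    hits = _hits_for(master, subjects)
    profile = build_consensus(hits, top_n=5)
    assert profile.consensus == master.residues
    assert profile.n_support == 5


def test_majority_column_tie_break():
    # 3 A's beat 1 C and 1 G at a single column
    base = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    variants = [base, base, base,
                "C" + base[1:], "G" + base[1:]]
    query = SequenceRecord(id="q", residues=base)
    subjects = [SequenceRecord(id=f"s{i}", residues=v)
                for i, v in enumerate(variants)]
    hits = similarity_search(query, subjects, min_identity=60,
                             min_aligned_length=30, word_size=8)
    profile = build_consensus(hits, top_n=5)
    assert profile.consensus[0] == "A"


def test_consensus_permutation_invariant(master):
    rng = np.random.default_rng(6)
    tree = PhyloTree.from_newick("(A:0.02,B:0.02);")
    cfg = SimConfig(host_tree=tree, master=master, burst_size=10,
                    birth_rate=0.0, seed=17)
    records, _ = evolve_family(cfg)
    hits = _hits_for(master, records)
    profile = build_consensus(hits, top_n=len(hits))
    shuffled = list(hits)
    rng.shuffle(shuffled)
    profile2 = build_consensus(shuffled, top_n=len(hits))
    assert profile.consensus == profile2.consensus


def test_simulated_consensus_recovers_master(master):
    tree = PhyloTree.from_newick("(A:0.02,B:0.02);")
    # prolif_time=0 makes each copy an independent 2% draw from the master
    cfg = SimConfig(host_tree=tree, master=master, burst_size=40,
                    birth_rate=0.0, prolif_time=0.0, seed=19)
    records, _ = evolve_family(cfg)
    hits = similarity_search(master, records, min_identity=90)
    profile = build_consensus(hits, top_n=80)
    matches = sum(a == b for a, b in zip(profile.consensus, master.residues))
    assert matches / len(master.residues) >= 0.995


# -- filters -----------------------------------------------------------


def _fake_hit(q0, q1, identity=95.0):
    from tehgt.harvest import SearchHit

    return SearchHit(
        query_id="q", subject_id="s", query_interval=(q0, q1),
        subject_interval=(q0, q1), strand="+", identity=identity,
        aligned_length=q1 - q0, gapped_query="A" * (q1 - q0),
        gapped_subject="A" * (q1 - q0),
    )


def test_orf_overlap_filter_thresholds():
    orf = (100, 500)  # 400 nt
    full = _fake_hit(100, 500)
    half = _fake_hit(100, 300)  # 50%
    exact = _fake_hit(200, 500)  # exactly 75%
    kept = filter_by_orf_overlap([full, half, exact], orf, 0.75)
    assert full in kept and exact in kept and half not in kept


def test_dedupe_within_species_only():
    rng = np.random.default_rng(7)
    base = _rand_seq(rng, 300)
    variant = _mutate(rng, base, 0.04)  # ~96% identical
    same_sp = [
        SequenceRecord(id="x1", residues=base, species="sp1"),
        SequenceRecord(id="x2", residues=variant, species="sp1"),
    ]
    assert len(dedupe_representatives(same_sp)) == 1
    cross_sp = [
        SequenceRecord(id="x1", residues=base, species="sp1"),
        SequenceRecord(id="x2", residues=variant, species="sp2"),
    ]
    assert len(dedupe_representatives(cross_sp)) == 2
    distinct = [
        SequenceRecord(id=f"d{i}", residues=_rand_seq(rng, 300), species="sp1")
        for i in range(4)
    ]
    assert len(dedupe_representatives(distinct)) == 4


def test_copy_count_and_interval_union():
    h1 = _fake_hit(0, 100)
    h2 = _fake_hit(50, 150)
    count, occupied, fraction = count_copies_and_fraction(
        [h1, h2], min_identity=90, assembly_size=1000)
    assert count == 2
    assert occupied == 150
    assert fraction == pytest.approx(0.15)
    assert count_copies_and_fraction([], 90, 1000) == (0, 0, 0.0)


def test_genome_fraction_is_unrounded():
    big = _fake_hit(0, 6_400_000)
    _, occupied, fraction = count_copies_and_fraction(
        [big], min_identity=90, assembly_size=831_700_000)
    assert occupied == 6_400_000
    assert fraction == pytest.approx(6.4e6 / 831.7e6)


# -- in-silico PCR -----------------------------------------------------

FWD = "CCAAGGATGTCAGGGACAAG"
REV = "CCCAGTTGTCTTCTGAATCATTC"


def _template_with_sites(rng, fwd=FWD, rev=REV, spacer=400):
    return (_rand_seq(rng, 50) + fwd + _rand_seq(rng, spacer)
            + revcomp(rev) + _rand_seq(rng, 50))


def test_pcr_detects_embedded_primer_sites():
    rng = np.random.default_rng(8)
    template = SequenceRecord(id="t", residues=_template_with_sites(rng))
    amps = in_silico_pcr([template], FWD, REV)
    assert len(amps) == 1
    amp = amps[0]
    assert amp.mismatches == 0
    assert amp.product_length == len(FWD) + 400 + len(REV)


def test_pcr_requires_both_sites():
    rng = np.random.default_rng(9)
    template = SequenceRecord(
        id="t", residues=_rand_seq(rng, 50) + FWD + _rand_seq(rng, 400))
    assert in_silico_pcr([template], FWD, REV) == []


def test_pcr_mismatch_threshold_and_exact_3prime():
    rng = np.random.default_rng(10)
    # three internal mismatches in the forward site: over the limit
    bad_fwd = "GGTAGT" + FWD[6:]
    template = SequenceRecord(
        id="t",
        residues=_rand_seq(rng, 50) + bad_fwd + _rand_seq(rng, 300)
        + revcomp(REV) + _rand_seq(rng, 50),
    )
    assert in_silico_pcr([template], FWD, REV, max_mismatches=2) == []
    # a single 3'-terminal mismatch also blocks annealing
    tail_fwd = FWD[:-1] + ("A" if FWD[-1] != "A" else "C")
    template2 = SequenceRecord(
        id="t2",
        residues=_rand_seq(rng, 50) + tail_fwd + _rand_seq(rng, 300)
        + revcomp(REV) + _rand_seq(rng, 50),
    )
    assert in_silico_pcr([template2], FWD, REV, max_mismatches=2) == []
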