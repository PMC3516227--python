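"""Study-condition validation scenarios.

Each function sets up one of the package's standard simulated
experiments — the conditions mirror the real study: a recently
proliferated cross-species family at 95-99% identity, an old divergent
within-species family, burst amplification after horizontal transfer —
runs the pipeline machinery on it, and returns the measured
quantities.  The acceptance script and the test suite both call these,
so the numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .datasets import (pcr_presence_pattern, teleost_leaves,
                       vertebrate_host_tree)
from .harvest import build_consensus, consensus_record, similarity_search
from .hgt import call_transfers, dollo_loss_count, identity_to_consensus, nei_gojobori
from .likelihood import GTRParams, constrain_monophyly, topology_test_rell
from .msa import progressive_align
from .phylo import build_nj, p_distance
from .simulate import (SimConfig, TransferEvent, emit_background_family,
                       evolve_family, make_master, master_orf_interval,
                       simulate_alignment)
from .tree import PhyloTree

HOST_NEWICK = ("((lampN:0.06,lampS:0.06):0.04,"
               "((tel1:0.05,tel2:0.05):0.03,outg:0.08):0.02);")

# a copy gene tree with teleost clades nested inside the lamprey
# cluster — the mosaic signature of repeated horizontal transfer
MOSAIC_GENE_NEWICK = (
    "((out1:0.3,out2:0.3):0.1,(((L1:0.02,(T1a:0.01,T1b:0.01):0.02):0.02,"
    "(L2:0.02,L3:0.02):0.02):0.02,((L4:0.02,(T2a:0.01,T2b:0.01):0.02):0.02,"
    "L5:0.03):0.02):0.15);"
)


def dollo_losses() -> dict:
    """Independent losses a vertical-origin scenario would require for
    the built-in vertebrate PCR survey (all, and outside the teleosts)."""
    tree = vertebrate_host_tree()
    count, branches = dollo_loss_count(tree, pcr_presence_pattern())
    teleosts = teleost_leaves()
    outside = [b for b in branches if not (b & teleosts)]
    return {"losses_outside_teleosts": len(outside), "losses_total": count,
            "n_species": tree.n_leaves}


def consensus_recovery(seed: int, n_copies: int = 300,
                       divergence: float = 0.02) -> dict:
    """Percent of master positions recovered by the majority-rule
    consensus of independently diverged copies."""
    master = make_master(seed)
    half = max(n_copies // 2, 1)
    tree = PhyloTree.from_newick(f"(A:{divergence},B:{divergence});")
    cfg = SimConfig(host_tree=tree, master=master, burst_size=half,
                    birth_rate=0.0, prolif_time=0.0, seed=seed + 1)
    records, _ = evolve_family(cfg)
    hits = similarity_search(master, records, min_identity=90)
    profile = build_consensus(hits, top_n=n_copies)
    matches = sum(a == b for a, b in zip(profile.consensus, master.residues))
    return {"accuracy_percent": 100.0 * matches / len(master.residues),
            "n_copies": len(records)}


def neutral_omega(seed: int, n_pairs: int = 100, branch: float = 0.08) -> dict:
    """Median Nei-Gojobori omega over neutrally evolved ORF pairs."""
    master = make_master(seed)
    a, b = master_orf_interval(master)
    orf = master.residues[a:b]
    pair_tree = PhyloTree.from_newick(f"(p:{branch},q:{branch});")
    omegas = []
    for k in range(n_pairs):
        aln = simulate_alignment(pair_tree, root_seq=orf, kappa=2.0,
                                 seed=seed + 1000 + k)
        res = nei_gojobori(aln.row("p").residues, aln.row("q").residues)
        if res.omega is not None:
            omegas.append(res.omega)
    return {"median_omega": float(np.median(omegas)), "n_pairs": len(omegas)}


def group_separation(seed: int, n_recent: int = 50, n_old: int = 25,
                     recent_divergence: float = 0.02,
                     old_age: float = 0.30) -> dict:
    """Identity-to-consensus distribution of a recent cross-species
    family plus an old within-species family."""
    master = make_master(seed)
    tree = PhyloTree.from_newick(
        f"(A:{recent_divergence},B:{recent_divergence});")
    cfg = SimConfig(host_tree=tree, master=master,
                    burst_size=max(n_recent // 2, 1), birth_rate=0.0,
                    prolif_time=0.0, seed=seed + 2)
    recent, _ = evolve_family(cfg)
    old = emit_background_family(cfg, age=old_age, n_copies=n_old)
    hits = similarity_search(master, recent, min_identity=90)
    cons = consensus_record(build_consensus(hits, top_n=300))
    idents = dict(identity_to_consensus(recent + old, cons))
    recent_ids = [idents[r.id] for r in recent if r.id in idents]
    old_ids = [idents[r.id] for r in old if r.id in idents]
    return {
        "recent_min_identity": float(min(recent_ids)),
        "recent_max_identity": float(max(recent_ids)),
        "old_max_identity": float(max(old_ids)),
        "old_min_identity": float(min(old_ids)),
        "n_recent": len(recent_ids),
        "n_old": len(old_ids),
    }


def _one_transfer_replicate(master, seed: int, with_transfer: bool,
                            burst: int) -> list:
    host = PhyloTree.from_newick(HOST_NEWICK)
    transfers = ([TransferEvent("lampN", "tel1", 0.9)]
                 if with_transfer else [])
    cfg = SimConfig(host_tree=host, master=master, transfers=transfers,
                    burst_size=burst, seed=seed)
    records, _ = evolve_family(cfg)
    aln = progressive_align(records)
    gene_tree = build_nj(p_distance(aln))
    species = {rec.id: rec.species for rec in records}
    calls, _ = call_transfers(gene_tree, species)
    return calls


def transfer_detection(seed: int, n_replicates: int = 20,
                       n_null: int = 20, burst: int = 30) -> dict:
    """Detection rate of a recent lampN -> tel1 transfer, and the
    total spurious calls on transfer-free (concordant) replicates."""
    master = make_master(seed)
    detected = 0
    for rep in range(n_replicates):
        calls = _one_transfer_replicate(master, seed + 10 + rep, True, burst)
        if any(c.recipient == "tel1" and "lampN" in c.donor for c in calls):
            detected += 1
    spurious = 0
    for rep in range(n_null):
        spurious += len(_one_transfer_replicate(master, seed + 500 + rep,
                                                False, burst))
    return {
        "detection_rate_percent": 100.0 * detected / n_replicates,
        "n_replicates": n_replicates,
        "spurious_calls_total": spurious,
        "n_null_replicates": n_null,
    }


def topology_rejection(seed: int, n_replicates: int = 20,
                       n_sites: int = 1020) -> dict:
    """How often the lamprey-monophyly constraint is rejected by
    KH/RELL on data simulated under the mosaic gene tree."""
    gene = PhyloTree.from_newick(MOSAIC_GENE_NEWICK)
    lamprey = {"L1", "L2", "L3", "L4", "L5"}
    params = GTRParams.k80(2.0, alpha=np.inf, n_categories=1)
    rejected = 0
    deltas = []
    for rep in range(n_replicates):
        aln = simulate_alignment(gene, length=n_sites, kappa=2.0,
                                 seed=seed + 9000 + rep)
        nj = build_nj(p_distance(aln))
        constrained = constrain_monophyly(nj, lamprey, aln, params)
        tests = topology_test_rell(aln, [nj, constrained], params,
                                   replicates=1000, seed=seed + rep)
        free, con = tests
        deltas.append(con.delta)
        if con.delta < 0 and con.p_value < 0.05:
            rejected += 1
    return {
        "rejection_rate_percent": 100.0 * rejected / n_replicates,
        "mean_delta_lnl": float(np.mean(deltas)),
        "n_replicates": n_replicates,
        "n_sites": n_sites,
    }
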