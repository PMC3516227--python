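"""End-to-end pipeline: from copy sequences (real or simulated) to
consensus, trees, identity distributions, Ka/Ks, loss counts and
transfer calls, with every threshold recorded in a machine-readable
run log."""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .harvest import (build_consensus, consensus_record, dedupe_representatives,
                      filter_by_orf_overlap, similarity_search)
from .hgt import (PresenceAbsence, call_transfers, classify_groups,
                  dollo_loss_count, histogram_identities, identity_to_consensus,
                  nei_gojobori)
from .io import read_fasta, write_fasta, write_tsv
from .likelihood import (GTRParams, constrain_monophyly, optimize_branch_lengths,
                         topology_test_rell)
from .msa import drop_short_rows, filter_gap_columns, progressive_align
from .orf import consensus_frame_codons, locate_orf
from .phylo import bootstrap_support, build_nj, p_distance
from .records import Alignment, SequenceRecord
from .tree import PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialized into the run log."""

    input_fasta: Optional[str] = None  # copy sequences with species= tags
    query_fasta: Optional[str] = None  # search query (defaults to first input)
    host_tree: Optional[str] = None  # Newick species tree
    presence_tsv: Optional[str] = None  # species<TAB>present|absent|unknown
    out_dir: str = "tehgt_out"
    seed: int = 0
    # harvest thresholds
    search_min_identity: float = 60.0
    search_min_length: int = 100
    consensus_top_n: int = 300
    orf_overlap_fraction: float = 0.75
    dedup_nt_identity: float = 95.0
    dedup_aa_identity: float = 80.0
    # alignment filters
    max_gap_fraction: float = 0.15
    min_row_fraction: float = 0.75
    # grouping
    group1_floor: float = 92.5
    divergent_ceiling: float = 90.0
    identity_min_sites: int = 150
    histogram_bin_width: float = 0.5
    # phylogenetics
    bootstrap_replicates: int = 100
    gamma_categories: int = 4
    kappa: float = 2.0
    rell_replicates: int = 1000
    constraint_species: list[str] = field(default_factory=list)
    min_call_support: int = 0
    kaks_max_pairs: int = 50

    def validate(self) -> None:
        for name, lo, hi in [
            ("search_min_identity", 0, 100), ("orf_overlap_fraction", 0, 1),
            ("dedup_nt_identity", 0, 100), ("dedup_aa_identity", 0, 100),
            ("max_gap_fraction", 0, 1), ("min_row_fraction", 0, 1),
            ("group1_floor", 0, 100), ("divergent_ceiling", 0, 100),
        ]:
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.bootstrap_replicates < 0:
            raise ValueError("bootstrap replicate count must be >= 0")
        if self.input_fasta is None:
            raise ValueError("input_fasta is required")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write a report directory.

    Outputs: consensus FASTA, filtered alignment, Newick trees,
    identity histogram TSV, Ka/Ks TSV, loss report, transfer calls and
    a JSON run log recording config, seed and version.  Deterministic
    given the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("load")
        copies = read_fasta(config.input_fasta)
        if config.query_fasta:
            query = read_fasta(config.query_fasta)[0]
        else:
            query = copies[0]
        log["stages"][name] = {"n_records": len(copies), "query": query.id}

        name = stage("harvest")
        hits = similarity_search(
            query, copies,
            min_identity=config.search_min_identity,
            min_aligned_length=config.search_min_length,
        )
        profile = build_consensus(hits, top_n=config.consensus_top_n)
        cons = consensus_record(profile)
        write_fasta([cons], out / "consensus.fasta")
        ann = locate_orf(cons)
        if ann.intact:
            hits = filter_by_orf_overlap(hits, ann.interval,
                                         config.orf_overlap_fraction)
        log["stages"][name] = {
            "n_hits": len(hits),
            "consensus_length": len(cons.residues),
            "orf": list(ann.interval),
        }

        name = stage("identity")
        idents = identity_to_consensus(copies, cons,
                                       min_sites=config.identity_min_sites)
        species_map = {rec.id: rec.species for rec in copies}
        hist = histogram_identities(idents, species_map,
                                    config.histogram_bin_width)
        hist.to_csv(out / "identity_histogram.tsv", sep="\t")
        groups = classify_groups(idents, config.group1_floor,
                                 config.divergent_ceiling)
        write_tsv(
            [(g.record_id, f"{g.identity:.2f}", g.group.value) for g in groups],
            ["record", "identity", "group"],
            out / "groups.tsv",
        )
        group1_ids = {g.record_id for g in groups if g.group.value == "group1"}
        log["stages"][name] = {
            "n_scored": len(idents),
            "n_group1": len(group1_ids),
        }

        name = stage("dedup_align")
        group1 = [rec for rec in copies if rec.id in group1_ids] or copies
        reps = dedupe_representatives(group1, config.dedup_nt_identity,
                                      config.dedup_aa_identity)
        if len(reps) < 4:
            reps = group1  # too few representatives to build a tree from
        aln = progressive_align(reps)
        aln = filter_gap_columns(aln, config.max_gap_fraction)
        aln = drop_short_rows(aln, config.min_row_fraction)
        write_fasta(list(aln), out / "filtered_alignment.fasta")
        log["stages"][name] = {"n_rows": aln.n_rows, "n_cols": aln.n_cols}

        name = stage("tree")
        nj_tree = build_nj(p_distance(aln))
        if config.bootstrap_replicates > 0:
            nj_tree = bootstrap_support(
                aln, config.bootstrap_replicates, seed=config.seed,
                base_tree=nj_tree,
            )
        (out / "nj_tree.nwk").write_text(nj_tree.to_newick() + "\n")
        log["stages"][name] = {"n_leaves": nj_tree.n_leaves}

        name = stage("toptest")
        params = GTRParams.k80(config.kappa, alpha=1.0,
                               n_categories=config.gamma_categories)
        row_species = {rec.id: rec.species for rec in aln}
        constrained_leaves = {
            rec_id for rec_id, sp in row_species.items()
            if sp in config.constraint_species
        }
        if 2 <= len(constrained_leaves) <= aln.n_rows - 2:
            constrained = constrain_monophyly(nj_tree, constrained_leaves,
                                              aln, params)
            tests = topology_test_rell(
                aln, [nj_tree, constrained], params,
                replicates=config.rell_replicates, seed=config.seed,
            )
            write_tsv(
                [(("unconstrained", "constrained")[i], f"{t.loglik:.3f}",
                  f"{t.delta:.3f}", f"{t.p_value:.4f}")
                 for i, t in enumerate(tests)],
                ["topology", "lnL", "delta_lnL", "p_value"],
                out / "topology_tests.tsv",
            )
            log["stages"][name] = {
                "delta_lnL": tests[1].delta,
                "p_value": tests[1].p_value,
            }
        else:
            log["stages"][name] = {"skipped": "no usable constraint"}

        name = stage("kaks")
        rng = np.random.default_rng(config.seed)
        codon_strings = {}
        for rec in reps:
            try:
                codon_strings[rec.id] = consensus_frame_codons(rec, cons)
            except ValueError:
                continue
        pairs = list(itertools.combinations(sorted(codon_strings), 2))
        if len(pairs) > config.kaks_max_pairs:
            picked = rng.choice(len(pairs), config.kaks_max_pairs, replace=False)
            pairs = [pairs[i] for i in sorted(picked)]
        rows = []
        omegas = []
        for a, b in pairs:
            try:
                res = nei_gojobori(codon_strings[a], codon_strings[b])
            except ValueError:
                continue
            rows.append((a, b, f"{res.S:.1f}", f"{res.N:.1f}", res.Sd, res.Nd,
                         "NA" if res.dS is None else f"{res.dS:.4f}",
                         "NA" if res.dN is None else f"{res.dN:.4f}",
                         "NA" if res.omega is None else f"{res.omega:.3f}"))
            if res.omega is not None:
                omegas.append(res.omega)
        write_tsv(rows, ["seq_a", "seq_b", "S", "N", "Sd", "Nd", "dS", "dN",
                         "omega"], out / "kaks.tsv")
        log["stages"][name] = {
            "n_pairs": len(rows),
            "median_omega": float(np.median(omegas)) if omegas else None,
        }

        name = stage("losses")
        if config.host_tree and config.presence_tsv:
            host = PhyloTree.from_newick(Path(config.host_tree).read_text())
            states = {}
            for line in Path(config.presence_tsv).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                sp, state = line.split("\t")[:2]
                states[sp] = state
            count, lost = dollo_loss_count(host, PresenceAbsence(states))
            write_tsv(
                [(";".join(sorted(clade)),) for clade in lost],
                ["lost_clade"], out / "losses.tsv",
            )
            log["stages"][name] = {"n_losses": count}
        else:
            log["stages"][name] = {"skipped": "no host tree / presence data"}

        name = stage("transfers")
        # nesting detection needs the within-species copy clusters that
        # dedup removes, so the call tree uses every group-1 copy
        if len(reps) < len(group1):
            full_aln = drop_short_rows(
                filter_gap_columns(progressive_align(group1),
                                   config.max_gap_fraction),
                config.min_row_fraction,
            )
            call_tree = build_nj(p_distance(full_aln))
            call_species = {rec.id: rec.species for rec in full_aln}
        else:
            call_tree, call_species = nj_tree, row_species
        calls, mosaic = call_transfers(call_tree, call_species,
                                       min_support=config.min_call_support)
        write_tsv(
            [(c.recipient, ";".join(sorted(c.donor)), c.nesting_depth,
              c.support if c.support is not None else "NA") for c in calls],
            ["recipient", "donor_clade", "nesting_depth", "support"],
            out / "transfer_calls.tsv",
        )
        log["stages"][name] = {"n_calls": len(calls), "mosaic": mosaic}
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise StageError(name, exc) from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str)
                                      + "\n")
    return out
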