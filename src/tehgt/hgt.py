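"""Horizontal-transfer evidence synthesis.

Four independent lines of evidence are computed here: (1) the
distribution of copy identities to the family consensus, which
separates a recently proliferated family from older background copies;
(2) Nei-Gojobori Ka/Ks, which tests whether copies evolve neutrally
(omega near one, as expected for dead transposon copies); (3) Dollo
parsimony loss counting, which quantifies how many independent losses
a purely vertical scenario would require; and (4) nesting-based
transfer calls on the copy gene tree, which name recipient and donor
lineages.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .pairwise import global_align
from .records import SequenceRecord
from .tree import Node, PhyloTree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# identity to consensus, histogram, grouping


def identity_to_consensus(
    records: list[SequenceRecord],
    consensus: "str | SequenceRecord",
    min_sites: int = 150,
) -> list[tuple[str, float]]:
    """Percent identity of each record to the consensus (gap-excluded
    aligned columns).  Records aligning over fewer than ``min_sites``
    comparable positions are dropped with a logged reason."""
    cons = consensus.residues if isinstance(consensus, SequenceRecord) else consensus
    out = []
    for rec in records:
        res = global_align(rec.residues.replace("-", ""), cons)
        if res.comparable_sites() < min_sites:
            logger.info(
                "dropping %s: only %d aligned sites (< %d)",
                rec.id, res.comparable_sites(), min_sites,
            )
            continue
        out.append((rec.id, res.identity()))
    return out


def histogram_identities(
    identities: list[tuple[str, float]],
    species: Mapping[str, str],
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Right-closed identity histogram, counts partitioned by species.

    Rows are labelled by the bin's upper edge: identity x falls in
    (upper - width, upper]."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if not identities:
        return pd.DataFrame()
    rows = []
    for rec_id, ident in identities:
        upper = math.ceil(ident / bin_width - 1e-9) * bin_width
        rows.append((round(upper, 6), species.get(rec_id, "unknown")))
    df = pd.DataFrame(rows, columns=["bin_upper", "species"])
    table = df.groupby(["bin_upper", "species"]).size().unstack(fill_value=0)
    return table.sort_index()


class Group(str, Enum):
    GROUP1 = "group1"
    GROUP2 = "group2"
    UNASSIGNED = "unassigned"


@dataclass
class GroupLabel:
    record_id: str
    identity: float
    group: Group


def classify_groups(
    identities: list[tuple[str, float]],
    group1_floor: float = 92.5,
    divergent_ceiling: float = 90.0,
) -> list[GroupLabel]:
    """Assign each sequence to the recent high-identity family
    (identity >= floor), the divergent background (< ceiling), or the
    empty zone in between."""
    if group1_floor < divergent_ceiling:
        raise ValueError("group-1 floor must be >= divergent ceiling")
    labels = []
    for rec_id, ident in identities:
        if ident >= group1_floor:
            group = Group.GROUP1
        elif ident < divergent_ceiling:
            group = Group.GROUP2
        else:
            group = Group.UNASSIGNED
        labels.append(GroupLabel(rec_id, ident, group))
    return labels


# ---------------------------------------------------------------------
# Nei-Gojobori Ka/Ks

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# standard-code lookup tables, built once
_AA_TABLE: dict[str, str] = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in _BASES for b in _BASES for c in _BASES
}


def _aa(codon: str) -> str:
    return _AA_TABLE[codon]


def _syn_fraction_uncached(codon: str) -> float:
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == aa0:
                s += 1.0 / 3.0
    return s


# synonymous site count of each codon: per position, the fraction of
# the three possible changes that preserve the amino acid (changes to
# stop codons count as nonsynonymous)
_SYN_SITES: dict[str, float] = {c: _syn_fraction_uncached(c) for c in _AA_TABLE}


def _syn_fraction(codon: str) -> float:
    return _SYN_SITES[codon]


@lru_cache(maxsize=4096)
def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons,
    averaged over all minimal mutational pathways; pathways passing
    through a stop codon are excluded when any stop-free pathway
    exists."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = a
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if nxt in _STOPS:
                through_stop = True
            if _aa(nxt) == _aa(current) and nxt not in _STOPS \
                    and current not in _STOPS:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((through_stop, syn, nonsyn))
    clean = [p for p in paths if not p[0]]
    use = clean if clean else paths
    syn = sum(p[1] for p in use) / len(use)
    nonsyn = sum(p[2] for p in use) / len(use)
    return syn, nonsyn


@dataclass
class KaKsResult:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    dS: Optional[float]  # None when saturated
    dN: Optional[float]
    omega: Optional[float]  # None when dS is 0 or unavailable
    codons_compared: int = 0
    codons_skipped: int = 0


def _jc_correct(p: float) -> Optional[float]:
    if p >= 0.75:
        return None  # saturated
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(seq_a: str, seq_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) unweighted-pathway Ka/Ks for one pair.

    Sequences must be equal-length in-frame codon strings; codons with
    gaps, Ns, or stops in either sequence are skipped pairwise (logged
    count).  Distances carry the Jukes-Cantor multiple-hit correction;
    omega is reported missing when dS = 0 or a class is saturated.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    compared = skipped = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if (set(ca + cb) - set(_BASES)) or ca in _STOPS or cb in _STOPS:
            skipped += 1
            continue
        compared += 1
        sa, sb = _syn_fraction(ca), _syn_fraction(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        syn, nonsyn = _pathway_counts(ca, cb)
        Sd += syn
        Nd += nonsyn
    if skipped:
        logger.info("nei_gojobori: skipped %d codons (ambiguity/stop)", skipped)
    if compared == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return KaKsResult(S, N, Sd, Nd, pS, pN, dS, dN, omega,
                      codons_compared=compared, codons_skipped=skipped)


# ---------------------------------------------------------------------
# Dollo parsimony loss counting


@dataclass
class PresenceAbsence:
    """Species -> {present, absent, unknown}; unknown taxa are excluded
    from loss counting rather than imputed."""

    states: dict[str, str]

    def __post_init__(self) -> None:
        for sp, state in self.states.items():
            if state not in ("present", "absent", "unknown"):
                raise ValueError(f"bad state {state!r} for {sp!r}")

    def present(self) -> set[str]:
        return {s for s, v in self.states.items() if v == "present"}

    def absent(self) -> set[str]:
        return {s for s, v in self.states.items() if v == "absent"}

    def unknown(self) -> set[str]:
        return {s for s, v in self.states.items() if v == "unknown"}


def dollo_loss_count(
    tree: PhyloTree,
    pattern: PresenceAbsence,
    origin: "str | Node | None" = None,
) -> tuple[int, list[frozenset[str]]]:
    """Minimum independent losses under a single gain at ``origin``.

    With one gain and unlimited losses, the minimum equals the number
    of maximal subtrees below the origin whose (known-state) leaves are
    all absent.  Returns the count and the lost clades' leaf sets.
    Raises if a present taxon falls outside the origin's subtree.
    """
    for sp in pattern.states:
        if sp not in tree.leaf_names():
            raise ValueError(f"species {sp!r} not on the tree")
    work = tree
    unknown = pattern.unknown()
    if unknown:
        work = tree.prune_leaves(unknown)
    if origin is None or origin == "root":
        origin_node = work.root
    elif isinstance(origin, Node):
        origin_node = origin if not unknown else _find_node(work, origin.label)
    else:
        origin_node = _find_node(work, origin)
    present = pattern.present()
    outside = present - origin_node.leaf_names()
    if outside:
        raise ValueError(
            f"present taxa {sorted(outside)} outside the origin subtree: "
            "origin violates the single-gain assumption"
        )
    absent = pattern.absent()

    losses: list[frozenset[str]] = []

    def collect(node: Node) -> None:
        if node.is_leaf:
            if node.label in absent:
                losses.append(frozenset([node.label]))
            return
        for child in node.children:
            if _all_absent(child, absent):
                losses.append(child.leaf_names())
            else:
                collect(child)

    collect(origin_node)
    return len(losses), losses


def _all_absent(node: Node, absent: set[str]) -> bool:
    return all(leaf in absent for leaf in node.leaf_names())


def _find_node(tree: PhyloTree, label: str) -> Node:
    for node in tree.root.preorder():
        if node.label == label:
            return node
    raise KeyError(f"no node labelled {label!r}")


def fitch_changes(tree: PhyloTree, states: Mapping[str, str]) -> int:
    """Minimum state changes of a multistate character (Fitch count);
    multifurcations are folded pairwise in child order."""
    changes = 0

    def walk(node: Node) -> set[str]:
        nonlocal changes
        if node.is_leaf:
            return {states[node.label]}
        acc: set[str] | None = None
        for child in node.children:
            cs = walk(child)
            if acc is None:
                acc = cs
            elif acc & cs:
                acc = acc & cs
            else:
                acc = acc | cs
                changes += 1
        return acc or set()

    walk(tree.root)
    return changes


# ---------------------------------------------------------------------
# nesting-based transfer calls


@dataclass
class TransferCall:
    recipient: str
    donor: frozenset[str]
    nesting_depth: int
    support: Optional[int]
    clade_leaves: frozenset[str]
    identity_to_donor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.recipient in self.donor:
            raise ValueError("recipient cannot be in its own donor clade")


def call_transfers(
    gene_tree: PhyloTree,
    species: Mapping[str, str],
    min_support: int = 0,
    max_relative_divergence: float = 2.0,
) -> tuple[list[TransferCall], bool]:
    """Name transfer recipients by nesting on the copy gene tree.

    A maximal single-species clade C (species S) is called a transfer
    recipient when it sits strictly inside a cluster of copies from a
    different donor species set D: C's sister lineages belong to D and
    at least one further ancestor adds only D species (nesting depth
    >= 1).  A copy that arrived horizontally and amplified in place
    shows exactly this signature, whereas on a gene tree concordant
    with the species history every species clade's successive
    ancestors add *different* species, so no calls are emitted.

    A recent transfer additionally leaves the recipient's copies about
    as close to the donor's copies as those are to each other; a
    nesting whose recipient-donor distance exceeds
    ``max_relative_divergence`` times the donor cluster's own mean
    pairwise distance (the signature of an old intragenomic
    duplication, not a transfer) is discarded.  Also returns a
    mosaicism verdict: true when the species character needs more than
    (number of species - 1) changes under Fitch parsimony.
    """
    for leaf in gene_tree.leaf_names():
        if leaf not in species:
            raise ValueError(f"leaf {leaf!r} has no species tag")
    all_species = set(species[leaf] for leaf in gene_tree.leaf_names())
    if len(all_species) < 2:
        return [], False

    def species_of(node: Node) -> set[str]:
        return {species[leaf] for leaf in node.leaf_names()}

    # midpoint rooting makes the parent/ancestor walk insensitive to
    # where the (arbitrary) NJ trifurcation happened to sit
    gene_tree = gene_tree.midpoint_root()
    dist_labels, dist_mat = gene_tree.path_distances()
    dist_index = {lab: i for i, lab in enumerate(dist_labels)}

    def mean_distance(group_a, group_b) -> float:
        pairs = [
            dist_mat[dist_index[a], dist_index[b]]
            for a in group_a for b in group_b if a != b
        ]
        return float(np.mean(pairs)) if pairs else 0.0

    calls: dict[tuple[str, frozenset[str]], TransferCall] = {}
    for node in gene_tree.root.postorder():
        if node is gene_tree.root or node.parent is None:
            continue
        sp_set = species_of(node)
        if len(sp_set) != 1:
            continue
        (s,) = sp_set
        parent = node.parent
        if species_of(parent) == {s}:
            continue  # not the maximal pure-S clade
        donor = frozenset(species_of(parent) - {s})
        if donor == frozenset(all_species - {s}) and len(all_species) > 2:
            continue  # nested inside "everything": no directional signal
        # nesting depth: climb while ancestors add only donor (or more
        # S) copies; each ancestor that adds donor copies deepens the
        # nesting.  A clade merely *sister* to a cluster scores 0.
        depth = 0
        anc = parent.parent
        seen = parent.leaf_names()
        while anc is not None:
            added = {species[leaf] for leaf in anc.leaf_names() - seen}
            if added and added <= donor | {s}:
                if added & donor:
                    depth += 1
                seen = anc.leaf_names()
                anc = anc.parent
            else:
                break
        if depth < 1:
            continue  # sister to a cluster, not nested inside one
        support = node.support if not node.is_leaf else parent.support
        if support is not None and support < min_support:
            continue
        # old-duplication guard: the recipient must sit at donor-level
        # divergence, not at the species-split distance
        donor_neighbors = {
            leaf for leaf in parent.leaf_names() - node.leaf_names()
            if species[leaf] in donor
        }
        within_set = donor_neighbors if len(donor_neighbors) >= 2 else {
            leaf for leaf in gene_tree.leaf_names() if species[leaf] in donor
        }
        d_cross = mean_distance(node.leaf_names(), donor_neighbors)
        d_within = mean_distance(within_set, within_set)
        if d_within > 0 and d_cross > max_relative_divergence * d_within:
            continue
        key = (s, donor)
        call = TransferCall(
            recipient=s,
            donor=donor,
            nesting_depth=depth,
            support=support,
            clade_leaves=node.leaf_names(),
            identity_to_donor=max(0.0, 100.0 * (1.0 - d_cross)),
        )
        prev = calls.get(key)
        if prev is None or call.nesting_depth > prev.nesting_depth:
            calls[key] = call
    leaf_states = {leaf: species[leaf] for leaf in gene_tree.leaf_names()}
    mosaic = fitch_changes(gene_tree, leaf_states) > len(all_species) - 1
    return sorted(calls.values(), key=lambda c: (c.recipient, sorted(c.donor))), mosaic
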