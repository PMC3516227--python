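"""Synthetic transposable-element families with known history.

The generator models the scenario this package is built to detect: a TE
family descending vertically along a host species tree, amplifying by
intragenomic copy births, decaying neutrally (K80 substitutions plus
short indels that disrupt reading frames), and optionally jumping
between contemporaneous host lineages by horizontal transfer, after
which a single transferred copy burst-amplifies in the recipient.

Branch lengths on the host tree are in expected substitutions per site,
so copy divergence is directly comparable to the identity thresholds
used by the harvesting stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import SequenceRecord, Source
from .tree import Node, PhyloTree

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------
# master element


def make_master(
    seed: int = 0,
    orf_codons: int = 340,
    total_length: int = 1610,
    utr5: int = 300,
) -> SequenceRecord:
    """A random master element: UTR + intact ORF + UTR.

    Defaults give a 1,610-nt element whose ORF spans 1,020 nt (ATG, 338
    sense codons, one stop), mirroring the size class of Tc1
    transposase elements.
    """
    rng = np.random.default_rng(seed)
    orf_len = 3 * orf_codons
    utr3 = total_length - utr5 - orf_len
    if utr3 < 0:
        raise ValueError("total_length too short for the requested ORF")

    def random_stretch(n: int) -> str:
        return "".join(rng.choice(list(_BASES), size=n))

    codons = []
    while len(codons) < orf_codons - 2:
        c = random_stretch(3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    seq = random_stretch(utr5) + orf + random_stretch(utr3)
    return SequenceRecord(
        id="master",
        residues=seq,
        description=f"orf={utr5}-{utr5 + orf_len}",
        species="ancestral",
        source=Source.SIMULATED,
    )


def master_orf_interval(master: SequenceRecord) -> tuple[int, int]:
    """ORF interval recorded by :func:`make_master` (0-based half-open)."""
    for token in master.description.split():
        if token.startswith("orf="):
            a, b = token[4:].split("-")
            return int(a), int(b)
    raise ValueError("master record carries no orf= token")


# ---------------------------------------------------------------------
# configuration and ground truth


@dataclass
class TransferEvent:
    """A horizontal jump: one donor copy seeds the recipient lineage."""

    donor: str  # label of the node subtending the donor branch
    recipient: str
    time: float  # fraction along the recipient branch, in [0, 1]
    copy_id: Optional[str] = None  # filled in with the realized donor copy

    def __post_init__(self) -> None:
        if not 0.0 <= self.time <= 1.0:
            raise ValueError("transfer time must be a fraction in [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for one simulated family.

    A single master copy descends from the root; on every terminal
    branch the family burst-amplifies to ``burst_size`` copies at
    fraction ``prolif_time`` along the branch (recent intragenomic
    proliferation, coinciding across species), and each horizontal
    transfer likewise seeds a ``burst_size`` amplification in the
    recipient.  Background copy births are rare (burst-dominated
    proliferation), so without transfers each species' copies form a
    recent within-genome cluster.
    """

    host_tree: PhyloTree
    master: SequenceRecord
    birth_rate: float = 0.2  # stray copy births per copy per unit branch length
    rate_multiplier: float = 1.0  # scales all branch lengths
    kappa: float = 2.0  # K80 transition/transversion rate ratio
    indel_rate: float = 0.005  # indel events per site per unit branch length
    indel_geom_p: float = 0.5  # geometric decay over lengths 1-3
    transfers: list[TransferEvent] = field(default_factory=list)
    burst_size: int = 30  # copies after a proliferation or transfer burst
    prolif_time: Optional[float] = 0.8  # fraction along terminal branches
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.birth_rate, self.rate_multiplier, self.indel_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.burst_size < 1:
            raise ValueError("burst size must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class CopyEvent:
    parent: Optional[str]
    kind: str  # founder | birth | descent | transfer
    branch: str
    time: float  # absolute depth on the host tree


@dataclass
class SimTruth:
    genealogy: dict[str, CopyEvent] = field(default_factory=dict)
    transfers: list[TransferEvent] = field(default_factory=list)
    intact: dict[str, bool] = field(default_factory=dict)
    presence: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------
# K80 machinery


def k80_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """Transition probabilities after t expected substitutions/site.

    Base order A, C, G, T; transitions are A<->G and C<->T.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    same = 0.25 + 0.25 * e1 + 0.5 * e2
    ts = 0.25 + 0.25 * e1 - 0.5 * e2
    tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), tv)
    np.fill_diagonal(P, same)
    P[0, 2] = P[2, 0] = ts  # A<->G
    P[1, 3] = P[3, 1] = ts  # C<->T
    return P


def k80_expected_p_distance(t: float, kappa: float) -> float:
    """Expected proportion of differing sites at divergence t."""
    P = k80_transition_matrix(t, kappa)
    return 1.0 - float(np.diag(P).mean())


_ENCODE = {b: i for i, b in enumerate(_BASES)}


def encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE.get(b, 0) for b in seq], dtype=np.int8)


def decode(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def _substitute(seq: np.ndarray, t: float, kappa: float,
                rng: np.random.Generator) -> np.ndarray:
    if t <= 0 or len(seq) == 0:
        return seq.copy()
    cum = np.cumsum(k80_transition_matrix(t, kappa), axis=1)
    r = rng.random(len(seq))
    return (r[:, None] > cum[seq]).sum(axis=1).astype(np.int8)


def _apply_indels(seq: np.ndarray, t: float, cfg: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    n_events = rng.poisson(cfg.indel_rate * t * len(seq))
    for _ in range(n_events):
        if len(seq) < 10:
            break
        length = min(int(rng.geometric(cfg.indel_geom_p)), 3)
        if rng.random() < 0.5:  # deletion
            start = rng.integers(0, len(seq) - length + 1)
            seq = np.delete(seq, np.s_[start:start + length])
        else:  # insertion of random bases
            start = rng.integers(0, len(seq) + 1)
            ins = rng.integers(0, 4, size=length).astype(np.int8)
            seq = np.insert(seq, start, ins)
    return seq


def _evolve_seq(seq: np.ndarray, t: float, cfg: SimConfig,
                rng: np.random.Generator) -> np.ndarray:
    return _apply_indels(_substitute(seq, t, cfg.kappa, rng), t, cfg, rng)


# ---------------------------------------------------------------------
# family evolution


class _Copy:
    __slots__ = ("id", "seq")

    def __init__(self, copy_id: str, seq: np.ndarray):
        self.id = copy_id
        self.seq = seq


def _branch_label(node: Node, fallback: dict[int, str]) -> str:
    return node.label if node.label else fallback[id(node)]


def evolve_family(config: SimConfig) -> tuple[list[SequenceRecord], SimTruth]:
    """Simulate one TE family on the host tree.

    Returns one :class:`SequenceRecord` per surviving copy at the leaves
    (species tag = leaf label) plus the full ground truth: the copy
    genealogy, realized transfers, per-copy intact-ORF flags and the
    per-species presence map.  Deterministic given ``config.seed``.
    """
    tree = config.host_tree
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    counter = itertools.count()

    # stable labels for unnamed internal nodes
    fallback: dict[int, str] = {}
    for i, node in enumerate(tree.root.preorder()):
        fallback[id(node)] = f"node{i}"
    labels = {_branch_label(n, fallback): n for n in tree.root.preorder()}
    depths_by_node = tree.node_depths()
    depths = {_branch_label(n, fallback): depths_by_node[n]
              for n in tree.root.preorder()}

    def branch_interval(label: str) -> tuple[float, float]:
        node = labels[label]
        if node.parent is None:
            raise ValueError(f"{label!r} is the root, not a branch")
        end = depths[label]
        return end - (node.length or 0.0), end

    # validate transfers against node depths (contemporaneity)
    taps: dict[str, list[tuple[float, TransferEvent]]] = {}
    for ev in config.transfers:
        if ev.donor not in labels or ev.recipient not in labels:
            raise ValueError(f"unknown branch in transfer {ev.donor}->{ev.recipient}")
        d0, d1 = branch_interval(ev.donor)
        r0, r1 = branch_interval(ev.recipient)
        t_abs = r0 + ev.time * (r1 - r0)
        if not (d0 - 1e-9 <= t_abs <= d1 + 1e-9):
            raise ValueError(
                f"transfer at depth {t_abs:.4g} outside donor branch "
                f"{ev.donor!r} interval [{d0:.4g}, {d1:.4g}]: branches are "
                "not contemporaneous"
            )
        taps.setdefault(ev.donor, []).append((t_abs - d0, ev))

    def new_copy(seq: np.ndarray, parent: Optional[str], kind: str,
                 branch: str, time: float) -> _Copy:
        cid = f"cp{next(counter)}"
        truth.genealogy[cid] = CopyEvent(parent, kind, branch, time)
        return _Copy(cid, seq)

    captured: dict[int, np.ndarray] = {}  # id(event) -> donor sequence

    def evolve_branch(copies: list[_Copy], branch: str, length: float,
                      depth0: float, terminal: bool) -> list[_Copy]:
        """Evolve copies along one branch, handling births, the
        terminal proliferation burst, and donor taps."""
        length = length * config.rate_multiplier
        events: list[tuple[float, str, object]] = []
        for cp in copies:
            for bt in rng.uniform(0, length,
                                  size=rng.poisson(config.birth_rate * length)):
                events.append((bt, "birth", cp))
        if terminal and config.prolif_time is not None:
            events.append((config.prolif_time * length, "prolif", None))
        for tau, ev in taps.get(branch, []):
            events.append((tau * config.rate_multiplier, "tap", ev))
        events.sort(key=lambda e: e[0])
        copies = list(copies)
        t_prev = 0.0
        for t_ev, kind, payload in events:
            dt = t_ev - t_prev
            for cp in copies:
                cp.seq = _evolve_seq(cp.seq, dt, config, rng)
            t_prev = t_ev
            if kind == "birth":
                parent: _Copy = payload  # type: ignore[assignment]
                if parent in copies:
                    copies.append(new_copy(parent.seq.copy(), parent.id,
                                           "birth", branch, depth0 + t_ev))
            elif kind == "prolif":
                while len(copies) < config.burst_size:
                    src = copies[rng.integers(0, len(copies))]
                    copies.append(new_copy(src.seq.copy(), src.id,
                                           "prolif", branch, depth0 + t_ev))
            else:
                ev: TransferEvent = payload  # type: ignore[assignment]
                donor_cp = copies[rng.integers(0, len(copies))]
                captured[id(ev)] = donor_cp.seq.copy()
                ev.copy_id = donor_cp.id
        dt = length - t_prev
        for cp in copies:
            cp.seq = _evolve_seq(cp.seq, dt, config, rng)
        return copies

    emitted: dict[str, list[_Copy]] = {}

    def descend(node: Node, copies: list[_Copy]) -> None:
        label = _branch_label(node, fallback)
        if node.is_leaf:
            emitted.setdefault(label, []).extend(copies)
            return
        for child in node.children:
            clabel = _branch_label(child, fallback)
            inherited = [
                new_copy(cp.seq.copy(), cp.id, "descent", clabel, depths[label])
                for cp in copies
            ]
            evolved = evolve_branch(inherited, clabel, child.length or 0.0,
                                    depths[label], terminal=child.is_leaf)
            descend(child, evolved)

    founder = new_copy(encode(config.master.residues), None, "founder",
                       _branch_label(tree.root, fallback), 0.0)
    descend(tree.root, [founder])

    # inject transfers: burst-amplify the captured copy, then evolve it
    # down the remainder of the recipient branch and subtree
    for ev in config.transfers:
        seq = captured[id(ev)]
        node = labels[ev.recipient]
        r0, r1 = branch_interval(ev.recipient)
        t_abs = r0 + ev.time * (r1 - r0)
        burst = [
            new_copy(seq.copy(), ev.copy_id, "transfer", ev.recipient, t_abs)
            for _ in range(config.burst_size)
        ]
        remaining = (r1 - t_abs) * config.rate_multiplier
        for cp in burst:
            cp.seq = _evolve_seq(cp.seq, remaining, config, rng)
        # copy births in the short post-transfer stretch are neglected
        if node.is_leaf:
            emitted.setdefault(ev.recipient, []).extend(burst)
        else:
            descend(node, burst)
        truth.transfers.append(ev)

    records: list[SequenceRecord] = []
    from .orf import locate_orf  # local import to avoid a cycle

    orf_a, orf_b = master_orf_interval(config.master)
    min_codons = max(1, int(0.9 * (orf_b - orf_a) // 3))
    for leaf in sorted(emitted):
        for k, cp in enumerate(emitted[leaf]):
            rec = SequenceRecord(
                id=f"{leaf}_{cp.id}",
                residues=decode(cp.seq),
                description=f"species={leaf} copy={cp.id}",
                species=leaf,
                source=Source.SIMULATED,
            )
            ann = locate_orf(rec, min_length_codons=min_codons)
            truth.intact[rec.id] = ann.intact
            records.append(rec)
    for leaf in tree.leaf_names():
        truth.presence[leaf] = leaf in emitted and bool(emitted[leaf])
    return records, truth


# ---------------------------------------------------------------------
# background (old, within-species) family


def emit_background_family(
    config: SimConfig, age: float, species: str = "background_sp",
    n_copies: Optional[int] = None,
) -> list[SequenceRecord]:
    """An old, divergent family confined to one species.

    Each copy diverges from the master by ``age`` expected
    substitutions/site on its own lineage (star genealogy), emulating a
    family whose proliferation predates the recent one.
    """
    if age <= 0:
        raise ValueError("age must be > 0")
    rng = np.random.default_rng(config.seed + 1)
    n = n_copies or config.burst_size
    master = encode(config.master.residues)
    records = []
    for k in range(n):
        seq = _evolve_seq(master.copy(), age, config, rng)
        records.append(
            SequenceRecord(
                id=f"{species}_old{k}",
                residues=decode(seq),
                description=f"species={species} age={age}",
                species=species,
                source=Source.SIMULATED,
            )
        )
    return records


# ---------------------------------------------------------------------
# gapless sequence evolution on an arbitrary tree


def simulate_alignment(
    tree: PhyloTree, length: int = 1000, kappa: float = 2.0, seed: int = 0,
    root_seq: Optional[str] = None,
):
    """Evolve a gapless K80 alignment down any tree (e.g. a gene tree
    with a known mosaic topology), one row per leaf."""
    from .records import Alignment

    rng = np.random.default_rng(seed)
    if root_seq is None:
        root = rng.integers(0, 4, size=length).astype(np.int8)
    else:
        root = encode(root_seq)
    seqs: dict[str, np.ndarray] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            evolved = _substitute(seq, child.length or 0.0, kappa, rng)
            if child.is_leaf:
                seqs[child.label] = evolved
            else:
                walk(child, evolved)

    walk(tree.root, root)
    return Alignment([
        SequenceRecord(id=name, residues=decode(seqs[name]),
                       species=name, source=Source.SIMULATED)
        for name in sorted(seqs)
    ])


# ---------------------------------------------------------------------
# EST-like fragmentation


def fragmentize(
    records: list[SequenceRecord], mean_length: float, seed: int = 0
) -> list[SequenceRecord]:
    """Cut each record into one EST-like fragment: uniform start,
    geometric length with the given mean (capped at the record length)."""
    if mean_length < 50:
        raise ValueError("mean fragment length must be >= 50")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        n = len(rec.residues)
        length = min(int(rng.geometric(1.0 / mean_length)), n)
        length = max(length, 1)
        start = int(rng.integers(0, n - length + 1))
        out.append(
            SequenceRecord(
                id=f"{rec.id}_frag",
                residues=rec.residues[start:start + length],
                description=f"{rec.description} fragment_of={rec.id} "
                            f"interval={start}-{start + length}",
                species=rec.species,
                source=Source.EST,
            )
        )
    return out
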