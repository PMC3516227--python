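"""Distance phylogenetics: p-distances, Poisson correction,
neighbor joining, and nonparametric bootstrap supports."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .records import Alignment
from .tree import Node, PhyloTree


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite distances")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(list(labels), self.matrix[np.ix_(idx, idx)])


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Proportion of differing sites per pair, pairwise-deletion:
    columns with a gap in either row are excluded for that pair."""
    if alignment.n_rows < 2:
        raise ValueError("need at least 2 rows")
    mat = alignment.to_matrix()
    n = alignment.n_rows
    labels = [rec.id for rec in alignment]
    out = np.zeros((n, n))
    gaps = mat == "-"
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            diff = int((mat[i, ok] != mat[j, ok]).sum())
            out[i, j] = out[j, i] = diff / compared
    return DistanceMatrix(labels, out)


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p) for a difference
    proportion p; saturates (errors) at p >= 1."""
    if not 0.0 <= p:
        raise ValueError("p must be >= 0")
    if p >= 1.0:
        raise ValueError("saturated: p >= 1")
    return -math.log(1.0 - p)


def poisson_correct(matrix: DistanceMatrix) -> DistanceMatrix:
    corrected = np.zeros_like(matrix.matrix)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            corrected[i, j] = corrected[j, i] = poisson_distance(matrix.matrix[i, j])
    return DistanceMatrix(list(matrix.labels), corrected)


# ---------------------------------------------------------------------
# neighbor joining


def build_nj(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break on the smallest (i, j) index pair;
    negative branch lengths are clamped to zero with the deficit moved
    to the sister branch.  The returned tree carries a trifurcating
    root (an unrooted tree) for >= 3 taxa.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = matrix.matrix.astype(float).copy()
    nodes: list[Node] = [Node(label) for label in matrix.labels]
    if n == 2:
        root = Node()
        half = d[0, 1] / 2.0
        for node in nodes:
            node.length = half
            root.add_child(node)
        return PhyloTree(root)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-12:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]
    # final trifurcation
    i, j, k = active
    root = Node()
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.add_child(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------
# bootstrap

TreeMethod = Union[str, Callable[[Alignment], PhyloTree]]


def _tree_builder(method: TreeMethod) -> Callable[[Alignment], PhyloTree]:
    if callable(method):
        return method
    if method == "nj-p":
        return lambda aln: build_nj(p_distance(aln))
    if method == "nj-poisson":
        return lambda aln: build_nj(poisson_correct(p_distance(aln)))
    raise ValueError(f"unknown tree method {method!r}")


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    tree_method: TreeMethod = "nj-p",
    base_tree: PhyloTree | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap; internal-branch support is the
    percentage of replicate trees containing the bipartition."""
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    build = _tree_builder(tree_method)
    tree = (base_tree or build(alignment)).copy()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {split: 0 for split in tree.bipartitions()}
    n_cols = alignment.n_cols
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = alignment.select_columns(cols)
        try:
            rep_tree = build(rep)
        except ValueError:
            continue  # e.g. a pair with no comparable resampled sites
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1
    all_names = tree.leaf_names()
    for node in tree.root.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(all_names - side) < 2:
            continue
        key = min(side, all_names - side, key=lambda s: (len(s), sorted(s)))
        node.support = round(100.0 * counts.get(key, 0) / replicates)
    return tree
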