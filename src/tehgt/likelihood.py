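"""GTR+Gamma likelihood machinery: Felsenstein pruning with discrete
Gamma rate categories, branch-length optimization, constrained-topology
construction, and the Kishino-Hasegawa topology test with RELL
resampling of per-site log-likelihoods.

Tree search is deliberately out of scope: likelihoods are evaluated on
given topologies (neighbor-joining or constrained variants), which is
what the vertical-vs-horizontal topology comparisons require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .phylo import DistanceMatrix, build_nj, p_distance
from .records import Alignment
from .tree import Node, PhyloTree

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class GTRParams:
    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0  # Gamma shape; np.inf disables rate variation
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if not self.alpha > 0:
            raise ValueError("Gamma shape must be > 0")
        if self.n_categories < 1:
            raise ValueError("need >= 1 rate category")

    @classmethod
    def k80(cls, kappa: float = 2.0, alpha: float = np.inf,
            n_categories: int = 1) -> "GTRParams":
        rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls(rates=rates, freqs=np.full(4, 0.25), alpha=alpha,
                   n_categories=n_categories)


def rate_matrix(params: GTRParams) -> np.ndarray:
    """GTR rate matrix normalized to one expected substitution per
    unit branch length."""
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(params.rates, _PAIRS):
        Q[i, j] = rate * params.freqs[j]
        Q[j, i] = rate * params.freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(params.freqs * np.diag(Q)).sum()
    return Q / scale


def gamma_category_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Equal-weight discrete Gamma rates (mean of each quantile bin)."""
    if n_categories == 1 or not np.isfinite(alpha):
        return np.ones(n_categories)
    probs = np.arange(1, n_categories) / n_categories
    # Gamma(shape=alpha, rate=alpha) has mean 1
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    upper = gammainc(alpha + 1.0, edges[1:])
    lower = gammainc(alpha + 1.0, edges[:-1])
    return (upper - lower) * n_categories


class _Eigen:
    def __init__(self, params: GTRParams):
        Q = rate_matrix(params)
        pi = params.freqs
        sq = np.sqrt(pi)
        S = (Q * sq[None, :] / sq[:, None] + (Q * sq[None, :] / sq[:, None]).T) / 2
        w, U = np.linalg.eigh(S)
        self.w = w
        self.left = U.T * sq[None, :]
        self.right = U / sq[:, None]

    def transition(self, t: float) -> np.ndarray:
        P = self.right @ (np.exp(self.w * t)[:, None] * self.left)
        return np.clip(P, 0.0, None)


def _encode_alignment(alignment: Alignment) -> tuple[np.ndarray, list[str]]:
    rows = []
    for rec in alignment:
        rows.append([_BASE_INDEX.get(c, 4) for c in rec.residues])
    return np.array(rows, dtype=np.int8), [rec.id for rec in alignment]


def _compress(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and site -> pattern index."""
    patterns, inverse, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts, inverse


def _site_likelihoods(
    patterns: np.ndarray,
    row_index: dict[str, int],
    tree: PhyloTree,
    params: GTRParams,
    eigen: _Eigen,
) -> np.ndarray:
    """Per-pattern likelihood, averaged over Gamma categories."""
    n_pat = patterns.shape[1]
    cat_rates = gamma_category_rates(params.alpha, params.n_categories)
    total = np.zeros(n_pat)
    leaf_partials: dict[int, np.ndarray] = {}
    for cat_rate in cat_rates:
        partial: dict[int, np.ndarray] = {}
        for node in tree.root.postorder():
            if node.is_leaf:
                key = id(node)
                if key not in leaf_partials:
                    states = patterns[row_index[node.label]]
                    lp = np.zeros((n_pat, 4))
                    known = states < 4
                    lp[known, states[known]] = 1.0
                    lp[~known, :] = 1.0  # gap/N: missing data
                    leaf_partials[key] = lp
                below = leaf_partials[key]
            else:
                below = np.ones((n_pat, 4))
                for child in node.children:
                    below = below * partial[id(child)]
            if node is tree.root:
                partial[id(node)] = below
            else:
                P = eigen.transition(cat_rate * (node.length or 0.0))
                partial[id(node)] = below @ P.T
        root_like = partial[id(tree.root)] @ params.freqs
        total += root_like
    return total / len(cat_rates)


def gtr_gamma_loglik(
    alignment: Alignment,
    tree: PhyloTree,
    params: GTRParams,
    per_site: bool = False,
) -> "float | np.ndarray":
    """Log-likelihood of the alignment on the tree under GTR+Gamma.

    Gaps and Ns are treated as missing data.  With ``per_site=True``
    the vector of per-site log-likelihoods is returned instead of the
    sum (for RELL resampling).
    """
    mat, labels = _encode_alignment(alignment)
    row_index = {label: i for i, label in enumerate(labels)}
    for leaf in tree.leaf_names():
        if leaf not in row_index:
            raise ValueError(f"tree leaf {leaf!r} has no alignment row")
    patterns, counts, inverse = _compress(mat)
    eigen = _Eigen(params)
    like = _site_likelihoods(patterns, row_index, tree, params, eigen)
    if np.any(like <= 0):
        like = np.clip(like, 1e-300, None)
    log_like = np.log(like)
    if per_site:
        return log_like[inverse]
    return float((log_like * counts).sum())


# ---------------------------------------------------------------------
# branch-length optimization


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    params: GTRParams,
    sweeps: int = 2,
    max_length: float = 10.0,
    nodes: "list[Node] | None" = None,
) -> tuple[PhyloTree, float]:
    """Brent optimization of branch lengths, one branch at a time.

    Returns the optimized copy of the tree and its log-likelihood.
    When ``nodes`` is given (nodes of the *returned copy*), only those
    branches are optimized.
    """
    tree = tree.copy()
    targets = nodes if nodes is not None else [
        n for n in tree.root.postorder() if n is not tree.root
    ]

    def loglik() -> float:
        return gtr_gamma_loglik(alignment, tree, params)

    best = loglik()
    for _ in range(sweeps):
        improved = False
        for node in targets:
            if node is tree.root:
                continue
            current = node.length or 0.0

            def objective(x: float, node=node) -> float:
                node.length = x
                return -gtr_gamma_loglik(alignment, tree, params)

            res = minimize_scalar(
                objective, bounds=(1e-9, max_length), method="bounded",
                options={"xatol": 1e-5},
            )
            if -res.fun > best + 1e-9:
                node.length = float(res.x)
                best = -res.fun
                improved = True
            else:
                node.length = current
        if not improved:
            break
    return tree, best


def estimate_gtr_params(
    alignment: Alignment,
    tree: PhyloTree,
    n_categories: int = 4,
    estimate_alpha: bool = True,
    maxiter: int = 200,
) -> GTRParams:
    """Nelder-Mead estimate of GTR exchangeabilities (GT fixed at 1)
    and the Gamma shape on a fixed evaluation tree, starting from
    empirical base frequencies and equal rates."""
    mat, _ = _encode_alignment(alignment)
    counts = np.bincount(mat[mat < 4].ravel(), minlength=4).astype(float)
    freqs = counts / counts.sum()

    def unpack(x: np.ndarray) -> GTRParams:
        rates = np.concatenate([np.exp(x[:5]), [1.0]])
        alpha = float(np.exp(x[5])) if estimate_alpha else np.inf
        return GTRParams(rates=rates, freqs=freqs, alpha=alpha,
                         n_categories=n_categories)

    def objective(x: np.ndarray) -> float:
        try:
            return -gtr_gamma_loglik(alignment, tree, unpack(x))
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = np.zeros(6)
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3})
    return unpack(res.x)


# ---------------------------------------------------------------------
# constrained topologies


def constrain_monophyly(
    tree: PhyloTree,
    subset: "set[str] | frozenset[str]",
    alignment: Alignment,
    params: GTRParams,
    matrix: "DistanceMatrix | None" = None,
) -> PhyloTree:
    """Best tree (by likelihood) in which ``subset`` is monophyletic.

    The subset's leaves are pruned, their induced subtree rebuilt by
    neighbor joining on the induced distance submatrix, and the
    subtree tried on every backbone branch; each placement's junction
    branches are Brent-optimized and the best placement then receives
    a full branch-length optimization.  If the subset is already
    monophyletic the input tree is returned unchanged.
    """
    subset = frozenset(subset)
    leaves = tree.leaf_names()
    if not 2 <= len(subset) <= len(leaves) - 2:
        raise ValueError("constraint must cover 2..n-2 leaves")
    if tree.is_monophyletic(subset):
        return tree
    if matrix is None:
        matrix = p_distance(alignment.select_rows(list(leaves)))

    backbone = tree.prune_leaves(subset)
    if len(subset) == 2:
        a, b = sorted(subset)
        sub_root = Node()
        d = matrix.matrix[matrix.labels.index(a), matrix.labels.index(b)]
        for name in (a, b):
            sub_root.add_child(Node(name, length=max(d / 2.0, 1e-6)))
    else:
        sub_tree = build_nj(matrix.submatrix(sorted(subset)))
        # root the (trifurcating) NJ subtree on its first child branch
        r = sub_tree.root
        first = r.children[0]
        sub_root = Node()
        sub_root.add_child(first)
        rest = Node()
        first.length = (first.length or 0.0) / 2.0 or 1e-6
        rest.length = first.length
        for child in r.children[1:]:
            rest.add_child(child)
        sub_root.add_child(rest)

    candidates = []
    for branch_node in [n for n in backbone.root.postorder()
                        if n is not backbone.root]:
        cand = backbone.copy()
        # find the matching node in the copy by postorder position
        originals = [n for n in backbone.root.postorder()]
        copies = [n for n in cand.root.postorder()]
        target = copies[originals.index(branch_node)]
        parent = target.parent
        junction = Node()
        half = (target.length or 0.0) / 2.0
        junction.length = max(half, 1e-6)
        parent.children[parent.children.index(target)] = junction
        junction.parent = parent
        target.length = max(half, 1e-6)
        junction.add_child(target)

        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for ch in node.children:
                new.add_child(clone(ch))
            return new

        attached = clone(sub_root)
        attached.length = 0.05
        junction.add_child(attached)
        cand_tree = PhyloTree(cand.root)
        cand_tree, lnl = optimize_branch_lengths(
            cand_tree, alignment, params, sweeps=1,
            nodes=[junction, target, attached],
        )
        candidates.append((lnl, cand_tree))
    candidates.sort(key=lambda c: -c[0])
    best_tree, _ = optimize_branch_lengths(candidates[0][1], alignment,
                                           params, sweeps=1)
    return best_tree


# ---------------------------------------------------------------------
# KH/RELL topology test


@dataclass
class TopologyTestResult:
    tree: PhyloTree
    loglik: float
    delta: float
    p_value: float
    best: bool


def topology_test_rell(
    alignment: Alignment,
    trees: list[PhyloTree],
    params: GTRParams,
    replicates: int = 1000,
    seed: int = 0,
    optimize: bool = True,
) -> list[TopologyTestResult]:
    """Kishino-Hasegawa test with RELL resampling.

    Per-site log-likelihoods are computed for every topology (branch
    lengths optimized unless ``optimize=False``); the best tree has
    delta = 0 and p = 1, and every other tree gets a one-sided p-value
    from the centered RELL distribution of its log-likelihood deficit.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    leaf_sets = {t.leaf_names() for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees must share an identical leaf set")
    site_lnls = []
    fitted = []
    for tree in trees:
        if optimize:
            tree, _ = optimize_branch_lengths(tree, alignment, params, sweeps=2)
        fitted.append(tree)
        site_lnls.append(gtr_gamma_loglik(alignment, tree, params, per_site=True))
    site_lnls = np.array(site_lnls)  # (trees, sites)
    totals = site_lnls.sum(axis=1)
    best_idx = int(np.argmax(totals))
    rng = np.random.default_rng(seed)
    n_sites = site_lnls.shape[1]
    idx = rng.integers(0, n_sites, size=(replicates, n_sites))
    results = []
    for i, tree in enumerate(fitted):
        delta = totals[i] - totals[best_idx]
        if i == best_idx or delta == 0.0:
            results.append(TopologyTestResult(tree, float(totals[i]), 0.0, 1.0,
                                              best=(i == best_idx)))
            continue
        diff_site = site_lnls[i] - site_lnls[best_idx]
        boot = diff_site[idx].sum(axis=1)
        centered = boot - boot.mean()
        p = float((centered <= delta).mean())
        results.append(TopologyTestResult(tree, float(totals[i]), float(delta),
                                          p, best=False))
    return results
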