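"""Independent brute-force oracles used by the test suite: exhaustive
unrooted-topology enumeration with least-squares branch fitting, and
full internal-state enumeration for tree likelihoods."""

import itertools
import math

import numpy as np

from tehgt.likelihood import _Eigen, gamma_category_rates
from tehgt.tree import Node, PhyloTree

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies on the labels (as PhyloTrees
    with a trifurcating root); 3 taxa -> 1, 4 -> 3, 5 -> 15, 6 -> 105."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def clone(node):
        new = Node(node.label, node.length)
        for child in node.children:
            new.add_child(clone(child))
        return new

    def edges(root):
        return [n for n in root.postorder() if n is not root]

    base = Node()
    for lab in labels[:3]:
        base.add_child(Node(lab, 1.0))
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for tree in trees:
            for k in range(len(edges(tree))):
                new_tree = clone(tree)
                target = edges(new_tree)[k]
                parent = target.parent
                joint = Node(length=1.0)
                parent.children[parent.children.index(target)] = joint
                joint.parent = parent
                joint.add_child(target)
                joint.add_child(Node(lab, 1.0))
                nxt.append(new_tree)
        trees = nxt
    return [PhyloTree(t) for t in trees]


def least_squares_fit(tree, labels, matrix):
    """Fit branch lengths to pairwise distances by least squares;
    returns (residual sum of squares, fitted path-length matrix)."""
    branch_nodes = [n for n in tree.root.postorder() if n is not tree.root]
    index = {id(n): k for k, n in enumerate(branch_nodes)}
    leaves = {n.label: n for n in tree.root.leaves()}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(branch_nodes)))
    y = np.zeros(len(pairs))

    def path_edges(a, b):
        anc_a = []
        node = leaves[a]
        while node is not None:
            anc_a.append(node)
            node = node.parent
        seen = {id(n) for n in anc_a}
        chain_b = []
        node = leaves[b]
        while id(node) not in seen:
            chain_b.append(node)
            node = node.parent
        lca = node
        chain_a = []
        for n in anc_a:
            if n is lca:
                break
            chain_a.append(n)
        return chain_a + chain_b

    for row, (i, j) in enumerate(pairs):
        for edge in path_edges(labels[i], labels[j]):
            A[row, index[id(edge)]] = 1.0
        y[row] = matrix[i, j]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((A @ lengths - y) ** 2).sum())
    return rss, A @ lengths


def best_tree_by_least_squares(labels, matrix):
    """The topology whose least-squares fit to the distances is best."""
    best = None
    for tree in enumerate_unrooted_topologies(labels):
        rss, _ = least_squares_fit(tree, labels, matrix)
        if best is None or rss < best[0]:
            best = (rss, tree)
    return best[1], best[0]


def brute_force_loglik(alignment, tree, params):
    """Likelihood by explicit summation over internal-node states."""
    cats = gamma_category_rates(params.alpha, params.n_categories)
    eigen = _Eigen(params)
    rows = {rec.id: rec.residues for rec in alignment}
    nodes = list(tree.root.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    n_sites = len(next(iter(rows.values())))
    total = 0.0
    for site in range(n_sites):
        site_like = 0.0
        for rate in cats:
            P = {id(n): eigen.transition(rate * (n.length or 0.0))
                 for n in nodes}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = {id(n): a for n, a in zip(internals, assign)}
                prob = params.freqs[amap[id(tree.root)]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    parent_state = amap[id(n.parent)]
                    if n.is_leaf:
                        c = rows[n.label][site]
                        if c in _BASE_INDEX:
                            prob *= P[id(n)][parent_state, _BASE_INDEX[c]]
                    else:
                        prob *= P[id(n)][parent_state, amap[id(n)]]
                acc += prob
            site_like += acc
        total += math.log(site_like / len(cats))
    return total


def brute_force_dollo(tree, absent):
    """Minimum loss count by enumerating every subset of branches as
    loss placements (trees small enough to enumerate)."""
    nodes = [n for n in tree.root.postorder() if n is not tree.root]
    leaves = tree.root.leaves()
    best = None
    for r in range(len(nodes) + 1):
        if best is not None and r >= best:
            break
        for combo in itertools.combinations(range(len(nodes)), r):
            lost_roots = [nodes[k] for k in combo]

            def is_lost(leaf):
                node = leaf
                while node is not None:
                    if any(node is lr for lr in lost_roots):
                        return True
                    node = node.parent
                return False

            pattern_ok = all(
                (leaf.label in absent) == is_lost(leaf) for leaf in leaves
            )
            if pattern_ok:
                best = r
                break
    return best
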