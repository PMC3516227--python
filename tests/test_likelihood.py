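"""GTR+Gamma likelihood, branch optimization, constrained topologies
and the KH/RELL topology test."""

import numpy as np
import pytest

from oracles import brute_force_loglik
from tehgt.likelihood import (GTRParams, constrain_monophyly,
                              gamma_category_rates, gtr_gamma_loglik,
                              optimize_branch_lengths, rate_matrix,
                              topology_test_rell)
from tehgt.phylo import build_nj, p_distance
from tehgt.records import Alignment, SequenceRecord
from tehgt.simulate import simulate_alignment
from tehgt.tree import PhyloTree


def _aln(rows):
    return Alignment([SequenceRecord(id=n, residues=s) for n, s in rows])


def _random_params(rng, ncat=2):
    freqs = rng.dirichlet(np.full(4, 10.0))
    return GTRParams(rates=rng.uniform(0.5, 2.0, 6), freqs=freqs,
                     alpha=float(rng.uniform(0.3, 2.0)), n_categories=ncat)


def test_rate_matrix_normalized_and_reversible():
    params = GTRParams(rates=np.array([1, 2, 1, 1, 2, 1.0]))
    Q = rate_matrix(params)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    assert -(params.freqs * np.diag(Q)).sum() == pytest.approx(1.0)
    flux = params.freqs[:, None] * Q
    assert np.allclose(flux, flux.T)


def test_gamma_rates_have_unit_mean():
    for alpha in (0.2, 0.7, 1.5, 10.0):
        rates = gamma_category_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-6)
        assert all(a < b for a, b in zip(rates, rates[1:]))
    assert gamma_category_rates(np.inf, 4).tolist() == [1, 1, 1, 1]


def test_zero_branch_two_identical_sequences_closed_form():
    aln = _aln([("X", "ACGT"), ("Y", "ACGT")])
    tree = PhyloTree.from_newick("(X:0,Y:0);")
    lnl = gtr_gamma_loglik(aln, tree, GTRParams())
    assert lnl == pytest.approx(4 * np.log(0.25))


def test_pruning_matches_state_enumeration_oracle():
    rng = np.random.default_rng(1)
    for trial in range(4):
        n_taxa = 4 if trial % 2 == 0 else 5
        labels = [f"t{k}" for k in range(n_taxa)]
        if n_taxa == 4:
            tree = PhyloTree.from_newick(
                "((t0:0.1,t1:0.25):0.12,(t2:0.3,t3:0.05):0.07);")
        else:
            tree = PhyloTree.from_newick(
                "((t0:0.1,t1:0.25):0.12,((t2:0.3,t3:0.05):0.1,t4:0.2):0.07);")
        rows = [(lab, "".join(rng.choice(list("ACGT"), 30)))
                for lab in labels]
        aln = _aln(rows)
        params = _random_params(rng)
        fast = gtr_gamma_loglik(aln, tree, params)
        slow = brute_force_loglik(aln, tree, params)
        assert fast == pytest.approx(slow, rel=1e-10)


def test_likelihood_invariant_under_rerooting():
    rng = np.random.default_rng(2)
    gene = PhyloTree.from_newick(
        "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08,E:0.3);")
    aln = simulate_alignment(gene, length=200, seed=3)
    params = _random_params(rng, ncat=3)
    base = gtr_gamma_loglik(aln, gene, params)
    rerooted = gene.midpoint_root()
    assert gtr_gamma_loglik(aln, rerooted, params) == pytest.approx(base,
                                                                    rel=1e-9)


def test_gaps_treated_as_missing_data():
    aln = _aln([("X", "ACG-"), ("Y", "ACGT")])
    tree = PhyloTree.from_newick("(X:0.1,Y:0.1);")
    full = gtr_gamma_loglik(_aln([("X", "ACG"), ("Y", "ACG")]), tree,
                            GTRParams())
    with_gap = gtr_gamma_loglik(aln, tree, GTRParams())
    # the gapped column contributes only Y's marginal probability
    assert with_gap == pytest.approx(full + np.log(0.25))


def test_single_category_equals_infinite_alpha():
    gene = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);")
    aln = simulate_alignment(gene, length=150, seed=4)
    one_cat = GTRParams(alpha=1.0, n_categories=1)
    inf_alpha = GTRParams(alpha=np.inf, n_categories=4)
    assert gtr_gamma_loglik(aln, gene, one_cat) == pytest.approx(
        gtr_gamma_loglik(aln, gene, inf_alpha), rel=1e-12)


def test_branch_optimization_improves_likelihood():
    gene = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);")
    aln = simulate_alignment(gene, length=300, seed=5)
    params = GTRParams.k80()
    bad = gene.copy()
    for node in bad.root.postorder():
        if node is not bad.root:
            node.length = 0.5
    before = gtr_gamma_loglik(aln, bad, params)
    optimized, after = optimize_branch_lengths(bad, aln, params, sweeps=2)
    assert after > before
    assert after == pytest.approx(gtr_gamma_loglik(aln, optimized, params))


def test_constrain_monophyly_returns_input_when_already_monophyletic():
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    aln = simulate_alignment(tree, length=100, seed=6)
    out = constrain_monophyly(tree, {"A", "B"}, aln, GTRParams.k80())
    assert out is tree


def test_constrain_monophyly_rejects_trivial_subsets():
    tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    aln = simulate_alignment(tree, length=100, seed=7)
    with pytest.raises(ValueError):
        constrain_monophyly(tree, {"A", "B", "C"}, aln, GTRParams.k80())
    with pytest.raises(ValueError):
        constrain_monophyly(tree, {"A"}, aln, GTRParams.k80())


def test_constrained_tree_scores_lower_on_discordant_data():
    gene = PhyloTree.from_newick(
        "((A:0.05,C:0.05):0.2,(B:0.05,D:0.05):0.2,E:0.3);")
    aln = simulate_alignment(gene, length=500, seed=8)
    params = GTRParams.k80(alpha=np.inf, n_categories=1)
    nj = build_nj(p_distance(aln))
    constrained = constrain_monophyly(nj, {"A", "B"}, aln, params)
    assert constrained.is_monophyletic({"A", "B"})
    nj_opt, lnl_free = optimize_branch_lengths(nj, aln, params)
    _, lnl_con = optimize_branch_lengths(constrained, aln, params)
    assert lnl_con < lnl_free


def test_topology_test_self_comparison_and_determinism():
    gene = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);")
    aln = simulate_alignment(gene, length=200, seed=9)
    params = GTRParams.k80()
    results = topology_test_rell(aln, [gene, gene.copy()], params,
                                 replicates=100, seed=0, optimize=False)
    for res in results:
        assert res.delta == 0.0
        assert res.p_value == 1.0
    again = topology_test_rell(aln, [gene, gene.copy()], params,
                               replicates=100, seed=0, optimize=False)
    assert [r.p_value for r in again] == [r.p_value for r in results]


def test_topology_test_rejects_wrong_tree_on_clear_data():
    true_tree = PhyloTree.from_newick(
        "((A:0.05,B:0.05):0.3,(C:0.05,D:0.05):0.3);")
    wrong = PhyloTree.from_newick(
        "((A:0.05,C:0.05):0.3,(B:0.05,D:0.05):0.3);")
    aln = simulate_alignment(true_tree, length=800, seed=10)
    params = GTRParams.k80(alpha=np.inf, n_categories=1)
    results = topology_test_rell(aln, [true_tree, wrong], params,
                                 replicates=500, seed=1)
    assert results[0].best
    assert results[1].delta < 0
    assert results[1].p_value < 0.05
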