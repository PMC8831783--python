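"""Pruning likelihood, gradients, ML fitting and model comparison."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import codonmf as cm
from codonmf.inference import (
    CodonAlignment,
    FitConfig,
    InferenceResult,
    PruningEngine,
    _ParamMap,
    compare,
    fit,
    log_likelihood,
)


@pytest.fixture(scope="module")
def toy_model(gtr_params_module):
    sigma, rho = gtr_params_module
    return cm.build_mg(sigma, rho, 0.3, scaling="mutation")


@pytest.fixture(scope="module")
def gtr_params_module():
    return np.array([0.3, 0.2, 0.2, 0.3]), np.array([1.0, 2.0, 0.8, 1.2, 2.5, 1.0])


def brute_force_log_likelihood(model, tree, aln):
    """Independent oracle: sum over all internal-state assignments."""
    P = {n: expm(model.Q * tree.length[n]) for n in range(tree.n_nodes) if n != tree.root}
    internals = [n for n in range(tree.n_nodes) if tree.children[n] and n != tree.root]
    row = {label: k for k, label in enumerate(aln.labels)}
    total = 0.0
    for site in range(aln.n_sites):
        s = 0.0
        for states in itertools.product(range(61), repeat=len(internals)):
            assign = dict(zip(internals, states))
            for r in range(61):
                assign[tree.root] = r
                term = model.pi[r]
                for n in range(tree.n_nodes):
                    if n == tree.root:
                        continue
                    parent_state = assign[tree.parent[n]]
                    if tree.children[n]:
                        term *= P[n][parent_state, assign[n]]
                    else:
                        obs = aln.codons[row[tree.labels[n]], site]
                        if obs >= 0:
                            term *= P[n][parent_state, obs]
                s += term
        total += np.log(s)
    return total


def test_pruning_matches_enumeration_oracle(toy_model):
    tree = cm.PhyloTree.from_newick("((a:0.1,b:0.25):0.15,c:0.4);")
    aln = CodonAlignment.from_dict({"a": "AAACCTGGA", "b": "AAGCCTGGA", "c": "ATACGTGGC"})
    assert log_likelihood(toy_model, tree, aln) == pytest.approx(
        brute_force_log_likelihood(toy_model, tree, aln), abs=1e-8
    )


def test_zero_branch_two_taxa_log_pi(toy_model):
    tree = cm.PhyloTree.from_newick("(a:0.0,b:0.0);")
    codon = "ATG"
    i = cm.codon_space().codon_index[codon]
    aln = CodonAlignment.from_dict({"a": codon, "b": codon})
    assert log_likelihood(toy_model, tree, aln) == pytest.approx(np.log(toy_model.pi[i]), abs=1e-12)


def test_missing_data_contributes_flat_partial(toy_model):
    tree = cm.PhyloTree.from_newick("(a:0.2,b:0.3);")
    aln_one = CodonAlignment.from_dict({"a": "ATG", "b": "---"})
    # marginalizing taxon b leaves the stationary probability of a's codon
    i = cm.codon_space().codon_index["ATG"]
    assert log_likelihood(toy_model, tree, aln_one) == pytest.approx(
        np.log(toy_model.pi[i]), abs=1e-10
    )


def test_likelihood_invariant_under_relabeling(toy_model):
    tree1 = cm.PhyloTree.from_newick("((a:0.1,b:0.25):0.15,c:0.4);")
    tree2 = cm.PhyloTree.from_newick("((x:0.1,y:0.25):0.15,z:0.4);")
    seqs = {"a": "AAACCT", "b": "AAGCCT", "c": "ATACGT"}
    aln1 = CodonAlignment.from_dict(seqs)
    aln2 = CodonAlignment.from_dict({"x": seqs["a"], "y": seqs["b"], "z": seqs["c"]})
    assert log_likelihood(toy_model, tree1, aln1) == pytest.approx(
        log_likelihood(toy_model, tree2, aln2), abs=1e-12
    )


@pytest.mark.parametrize("kind,fix_bl", [("MG", True), ("MG", False), ("MF", True)])
def test_gradient_matches_numerical_differentiation(kind, fix_bl):
    tree = cm.PhyloTree.balanced(4, 0.2)
    mut = cm.build_lambda_matrix(2.0)
    land = cm.sample_landscape(cm.ProfileSpec(n_sites=30, seed=2, nr=1.0))
    aln = CodonAlignment.from_dict(cm.simulate(tree, mut, land, seed=5).alignment)
    cfg = FitConfig(fix_branch_lengths=fix_bl)
    pmap = _ParamMap(kind, tree, aln, cfg)
    engine = PruningEngine(tree, aln)
    rng = np.random.default_rng(1)
    theta = pmap.theta0 + rng.normal(0, 0.1, pmap.n_free)

    def f(th):
        Q, pi = pmap.build(th)
        return engine.log_likelihood(Q, pi, pmap.unpack(th)["lengths"])

    Q, pi = pmap.build(theta)
    dQ, dpi = pmap.derivatives(theta)
    lengths = pmap.unpack(theta)["lengths"]
    ll, gp, gl = engine.log_likelihood_and_gradient(
        Q, pi, lengths, dQ, dpi, branch_gradient=pmap.n_branch > 0
    )
    grad = (
        np.concatenate([gp, gl[pmap.branch_nodes] * lengths[pmap.branch_nodes]])
        if pmap.n_branch
        else gp
    )
    assert ll == pytest.approx(f(theta), abs=1e-9)
    for k in rng.choice(pmap.n_free, size=min(12, pmap.n_free), replace=False):
        h = 1e-5
        tp = theta.copy()
        tp[k] += h
        fp = f(tp)
        tp[k] -= 2 * h
        fm = f(tp)
        assert grad[k] == pytest.approx((fp - fm) / (2 * h), rel=2e-4, abs=1e-5)


def test_mg_self_consistency_recovery():
    """Long MG-simulated data: the MG fit recovers its own parameters."""
    tree = cm.PhyloTree.balanced(8, 0.08)
    sigma = np.array([1 / 3, 1 / 6, 1 / 6, 1 / 3])
    omega = 0.25
    truth = cm.build_mg(sigma, np.ones(6), omega, scaling="mutation")
    rng_errs = []
    for rep in range(3):
        aln = CodonAlignment.from_dict(cm.simulate_alignment(truth, tree, 800, seed=60 + rep))
        res = fit("MG", tree, aln, FitConfig(fix_branch_lengths=True, n_restarts=1))
        rng_errs.append((res.omega - omega) / omega)
        assert res.converged
        assert res.lambda_hat == pytest.approx(2.0, rel=0.15)
    assert abs(np.mean(rng_errs)) < 0.08


def test_mf_nests_mg_in_likelihood():
    tree = cm.PhyloTree.balanced(4, 0.1)
    mut = cm.build_lambda_matrix(2.0)
    land = cm.sample_landscape(cm.ProfileSpec(n_sites=120, seed=8, nr=1.0))
    aln = CodonAlignment.from_dict(cm.simulate(tree, mut, land, seed=9).alignment)
    cfg = FitConfig(fix_branch_lengths=True, n_restarts=1)
    res_mg = fit("MG", tree, aln, cfg)
    res_mf = fit("MF", tree, aln, cfg)
    assert res_mf.log_likelihood >= res_mg.log_likelihood - 1e-6
    report = compare(res_mg, res_mf)
    assert report["df"] == 93
    assert report["lrt_stat"] >= -1e-6
    assert 0.0 <= report["p_value"] <= 1.0


def test_compare_identical_likelihoods_trivial_case():
    """MF constrained to MG: LRT is 0 and dAIC = -2 x extra parameters."""
    base = dict(
        sigma=np.full(4, 0.25),
        rho=np.ones(6),
        branch_lengths=np.zeros(3),
        lambda_hat=1.0,
        pfix={"all": 0.3, "WS": 0.3, "SW": 0.3},
        n_sites=100,
        n_taxa=3,
        converged=True,
        n_iterations=10,
        message="",
        fix_branch_lengths=True,
    )
    mg = InferenceResult(kind="MG", log_likelihood=-1000.0, omega=0.3, beta=None,
                         epsilon=None, n_free_parameters=9, **base)
    mf = InferenceResult(kind="MF", log_likelihood=-1000.0, omega=None,
                         beta=np.ones((20, 20)), epsilon=np.full(20, 0.05),
                         n_free_parameters=102, **base)
    report = compare(mg, mf)
    assert report["lrt_stat"] == 0.0
    assert report["delta_aic"] == -2.0 * 93
    assert report["df"] == 93


def test_compare_rejects_mismatched_data():
    kwargs = dict(
        sigma=np.full(4, 0.25), rho=np.ones(6), branch_lengths=np.zeros(3),
        lambda_hat=1.0, pfix={"all": 0.3, "WS": 0.3, "SW": 0.3}, n_taxa=3,
        converged=True, n_iterations=1, message="", fix_branch_lengths=True,
    )
    mg = InferenceResult(kind="MG", log_likelihood=-10.0, omega=0.3, beta=None,
                         epsilon=None, n_free_parameters=9, n_sites=100, **kwargs)
    mf = InferenceResult(kind="MF", log_likelihood=-9.0, omega=None,
                         beta=np.ones((20, 20)), epsilon=np.full(20, 0.05),
                         n_free_parameters=102, n_sites=200, **kwargs)
    with pytest.raises(ValueError):
        compare(mg, mf)


def test_saturated_branches_still_recover_mutation_bias():
    """At high divergence the MF mutation-bias estimate degrades gracefully."""
    tree = cm.PhyloTree.balanced(4, 1.0)
    mut = cm.build_lambda_matrix(2.0)
    land = cm.sample_landscape(cm.ProfileSpec(n_sites=150, seed=12, nr=1.0))
    aln = CodonAlignment.from_dict(cm.simulate(tree, mut, land, seed=13).alignment)
    res = fit("MF", tree, aln, FitConfig(fix_branch_lengths=True, n_restarts=1))
    assert 1.3 < res.lambda_hat < 3.0


def test_result_json_round_trip(tmp_path):
    tree = cm.PhyloTree.balanced(4, 0.1)
    mut = cm.build_lambda_matrix(2.0)
    land = cm.sample_landscape(cm.ProfileSpec(n_sites=60, seed=20, nr=1.0))
    aln = CodonAlignment.from_dict(cm.simulate(tree, mut, land, seed=21).alignment)
    res = fit("MG", tree, aln, FitConfig(fix_branch_lengths=True, n_restarts=1))
    path = tmp_path / "mg.json"
    res.to_json(path)
    back = InferenceResult.from_json(path)
    assert back.log_likelihood == pytest.approx(res.log_likelihood)
    assert np.allclose(back.sigma, res.sigma)
    assert back.kind == "MG"


def test_alignment_fasta_round_trip(tmp_path):
    aln = CodonAlignment.from_dict({"a": "ATGAAA", "b": "ATGAAG"})
    path = tmp_path / "aln.fasta"
    aln.to_fasta(path)
    back = CodonAlignment.from_fasta(path)
    assert back.labels == aln.labels
    assert np.array_equal(back.codons, aln.codons)
    # stops and ambiguity are masked, not errors
    masked = CodonAlignment.from_dict({"a": "TAAATG", "b": "NNNATG"})
    assert masked.codons[0, 0] == -1
    assert masked.codons[1, 0] == -1
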