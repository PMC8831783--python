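"""MG and MF inference-side codon models."""

import numpy as np
import pytest

import codonmf as cm
from codonmf.codon_models import (
    OmegaTensor,
    build_mf,
    build_mg,
    mf_mean_pfix,
    predicted_position_frequencies,
)
from codonmf.mutation import stationary_distribution


def test_mg_neutral_equals_mutation_matrix(gtr_params):
    sigma, rho = gtr_params
    model = build_mg(sigma, rho, 1.0, scaling="mutation")
    # with omega = 1 every neighbor rate is the bare mutation rate
    space = cm.codon_space()
    nt = space.codon_nt
    for codon in ("AAA", "TGG"):
        i = space.codon_index[codon]
        for nb in space.neighbors(codon):
            a, b = "ACGT".index(nb.source_nt), "ACGT".index(nb.target_nt)
            assert model.Q[i, nb.index] == pytest.approx(model.mut.rates[a, b], rel=1e-12)


def test_mg_omega_zero_silences_nonsynonymous(gtr_params):
    sigma, rho = gtr_params
    model = build_mg(sigma, rho, 0.0, scaling="mutation")
    space = cm.codon_space()
    nonsyn = space.nb_sense & ~space.nb_syn
    rows = np.repeat(np.arange(61), 9).reshape(61, 9)
    assert np.all(model.Q[rows[nonsyn], space.nb_target[nonsyn]] == 0.0)
    syn = space.nb_syn
    assert np.all(model.Q[rows[syn], space.nb_target[syn]] > 0.0)


@pytest.mark.parametrize("kind", ["MG", "MF"])
def test_equilibrium_matches_null_space_oracle(kind, gtr_params, generic_tensor):
    sigma, rho = gtr_params
    model = (
        build_mg(sigma, rho, 0.4)
        if kind == "MG"
        else build_mf(sigma, rho, generic_tensor)
    )
    assert np.allclose(model.pi, stationary_distribution(model.Q), atol=1e-10)
    assert model.pi.sum() == pytest.approx(1.0, abs=1e-12)


def test_mg_equilibrium_is_product_form(gtr_params):
    sigma, rho = gtr_params
    model = build_mg(sigma, rho, 0.4)
    space = cm.codon_space()
    prod = np.prod(sigma[space.codon_nt], axis=1)
    assert np.allclose(model.pi, prod / prod.sum(), atol=1e-14)


def test_mf_equilibrium_gains_epsilon_factor(gtr_params, generic_tensor):
    sigma, rho = gtr_params
    model = build_mf(sigma, rho, generic_tensor)
    space = cm.codon_space()
    prod = np.prod(sigma[space.codon_nt], axis=1) * generic_tensor.epsilon[space.aa_of]
    assert np.allclose(model.pi, prod / prod.sum(), atol=1e-14)


def test_mf_reduces_to_mg(gtr_params):
    """Uniform epsilon and constant beta collapse the tensor model onto MG."""
    sigma, rho = gtr_params
    omega = 0.27
    mg = build_mg(sigma, rho, omega)
    mf = build_mf(sigma, rho, OmegaTensor.from_scalar(omega))
    assert np.allclose(mf.Q, mg.Q, atol=1e-13)
    assert np.allclose(mf.pi, mg.pi, atol=1e-14)
    assert mf_mean_pfix(mf) == pytest.approx(omega, rel=1e-12)


def test_mf_detailed_balance(gtr_params, generic_tensor):
    sigma, rho = gtr_params
    model = build_mf(sigma, rho, generic_tensor)
    flux = model.pi[:, None] * model.Q
    assert np.allclose(flux, flux.T, atol=1e-16)


def test_omega_tensor_validation_and_counts():
    with pytest.raises(ValueError):
        OmegaTensor(beta=np.ones((20, 20)), epsilon=np.zeros(20))
    bad = np.ones((20, 20))
    bad[0, 1] = 2.0
    with pytest.raises(ValueError):
        OmegaTensor(beta=bad, epsilon=np.full(20, 0.05))
    tens = OmegaTensor.from_scalar(0.5)
    assert OmegaTensor.N_SELECTION_PARAMETERS == 95
    assert OmegaTensor.N_FREE_SELECTION_PARAMETERS == 94
    assert int(np.isfinite(tens.omega).sum()) == 150


def test_position_frequencies_mg_match_marginalization_oracle(gtr_params, tmp_path):
    sigma, rho = gtr_params
    model = build_mg(sigma, rho, 0.4)
    table = predicted_position_frequencies(model)
    from codonmf.codon_models import write_position_frequencies

    write_position_frequencies(table, tmp_path / "pos.tsv")
    body = (tmp_path / "pos.tsv").read_text().splitlines()
    assert body[0] == "position\tA\tC\tG\tT" and len(body) == 4
    assert np.allclose(table.sum(axis=1), 1.0, atol=1e-12)
    # independent oracle: enumerate codons and marginalize the product measure
    space = cm.codon_space()
    prod = np.prod(sigma[space.codon_nt], axis=1)
    prod /= prod.sum()
    expected = np.zeros((3, 4))
    for i in range(61):
        for k in range(3):
            expected[k, space.codon_nt[i, k]] += prod[i]
    assert np.allclose(table, expected, atol=1e-14)
    # all three rows approximate sigma; removing the three stop codons
    # (T-led, A/G-rich) perturbs the marginals by a few percent at most
    assert np.abs(table - sigma[None, :]).max() < 0.06


def test_position_frequencies_mf_third_position_tracks_mutation_bias(lam2_mut, sparse_landscape):
    """With selection on amino acids, position 3 stays closest to the
    mutational AT/GC ratio while positions 1-2 are pulled away."""
    from scipy.special import logsumexp
    from codonmf.mean_field import _log_norm_constants, omega_true_matrix

    om = omega_true_matrix(lam2_mut, sparse_landscape)
    logc = _log_norm_constants(lam2_mut, sparse_landscape)
    logS = logsumexp(logc[:, None] + sparse_landscape.F, axis=0)
    eps = np.exp(logS - logsumexp(logS))
    mask = cm.codon_space().reachable_pair_mask()
    beta = np.where(mask, np.nan_to_num(om) / eps[None, :], 0.0)
    model = build_mf(lam2_mut.sigma, np.ones(6), OmegaTensor(beta=beta, epsilon=eps))
    table = predicted_position_frequencies(model)
    target = cm.at_gc_ratio(lam2_mut.sigma)
    devs = [abs(cm.at_gc_ratio(table[k]) - target) for k in range(3)]
    # position 2 is dominated by which amino acids are preferred and can fall
    # anywhere; the robust pattern is third versus first position
    assert devs[2] < devs[0]


def test_mf_mean_pfix_matches_direct_enumeration(gtr_params, generic_tensor, space):
    sigma, rho = gtr_params
    model = build_mf(sigma, rho, generic_tensor)
    for restriction in ("all", "WS", "SW"):
        num = den = 0.0
        for i, codon in enumerate(space.codons):
            for nb in space.neighbors(codon):
                if nb.is_synonymous:
                    continue
                weak, strong = set("AT"), set("CG")
                if restriction == "WS" and not (
                    nb.source_nt in weak and nb.target_nt in strong
                ):
                    continue
                if restriction == "SW" and not (
                    nb.source_nt in strong and nb.target_nt in weak
                ):
                    continue
                a, b = "ACGT".index(nb.source_nt), "ACGT".index(nb.target_nt)
                mu = model.mut.rates[a, b]
                w = (
                    generic_tensor.epsilon[space.aa_of[nb.index]]
                    * generic_tensor.beta[space.aa_of[i], space.aa_of[nb.index]]
                )
                num += model.pi[i] * mu * w
                den += model.pi[i] * mu
        assert mf_mean_pfix(model, restriction) == pytest.approx(num / den, rel=1e-12)


def test_flat_tensor_pfix_is_one(gtr_params):
    sigma, rho = gtr_params
    assert mf_mean_pfix(build_mf(sigma, rho, OmegaTensor.from_scalar(1.0))) == pytest.approx(1.0)


def test_simulate_alignment_shapes_and_determinism(gtr_params, small_tree):
    sigma, rho = gtr_params
    model = build_mg(sigma, rho, 0.3)
    a = cm.simulate_alignment(model, small_tree, 50, seed=1)
    b = cm.simulate_alignment(model, small_tree, 50, seed=1)
    assert sorted(a) == sorted(small_tree.leaf_labels)
    for k in a:
        assert a[k].shape == (50,)
        assert np.array_equal(a[k], b[k])
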