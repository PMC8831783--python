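import numpy as np
import pytest

import codonmf as cm


@pytest.fixture(scope="session")
def space():
    return cm.codon_space()


@pytest.fixture(scope="session")
def lam2_mut():
    """AT-biased mutation matrix with lambda = 2."""
    return cm.build_lambda_matrix(2.0)


@pytest.fixture(scope="session")
def sparse_landscape():
    """Small sparse landscape at intermediate selection stringency."""
    return cm.sample_landscape(cm.ProfileSpec(n_sites=40, concentration=0.1, nr=1.0, seed=7))


@pytest.fixture(scope="session")
def flat_landscape():
    """Selectively neutral landscape (all amino acids equivalent)."""
    return cm.FitnessLandscape(psi=np.full((25, 20), 1.0 / 20), nr=1.0)


@pytest.fixture(scope="session")
def small_tree():
    return cm.PhyloTree.balanced(4, 0.15)


@pytest.fixture(scope="session")
def generic_tensor(space):
    """A random reversible omega tensor with non-uniform epsilon."""
    rng = np.random.default_rng(42)
    mask = space.reachable_pair_mask()
    vals = rng.lognormal(np.log(6.0), 0.5, size=(20, 20))
    vals = 0.5 * (vals + vals.T)
    beta = np.where(mask, vals, 0.0)
    eps = rng.dirichlet(np.full(20, 3.0))
    return cm.OmegaTensor(beta=beta, epsilon=eps)


@pytest.fixture(scope="session")
def gtr_params():
    sigma = np.array([0.3, 0.2, 0.2, 0.3])
    rho = np.array([1.0, 2.0, 0.8, 1.2, 2.5, 1.0])
    return sigma, rho
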