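"""Inference-side codon substitution models.

Two nested, site-homogeneous, reversible 61-state models built on a GTR
nucleotide mutation matrix ``R[a, b] = rho[a, b] sigma[b]``:

* the Muse-Gaut (MG) model, where every nonsynonymous rate is multiplied by
  one scalar ``omega``; equilibrium codon frequencies are the products of
  nucleotide frequencies (renormalized over the 61 sense codons);
* the mean-field (MF) model, where each ordered amino-acid pair carries its
  own factor ``omega[x, y] = epsilon[y] * beta[x, y]`` with symmetric
  exchangeabilities ``beta`` (75 active unordered pairs, 150 directed
  nonzero entries) and 20 stationary effects ``epsilon``; equilibrium codon
  frequencies gain a factor ``epsilon[A(i)]``.

Setting ``epsilon`` uniform and ``beta`` constant on the reachable pairs
collapses MF onto MG entry by entry, which makes the two models directly
comparable by likelihood-ratio test and AIC.  Both satisfy detailed balance,
so the equilibrium frequencies are available in closed form and the
generators can be exponentiated through a symmetric eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .genetic_code import N_AMINO_ACIDS, N_SENSE, codon_space
from .mutation import MutationMatrix, build_gtr_matrix
from .trees import PhyloTree

SCALINGS = ("mutation", "substitution")


@dataclass(frozen=True)
class OmegaTensor:
    """Reversible parameterization of the amino-acid rate tensor.

    ``beta`` is a symmetric 20x20 array of exchangeabilities (only the 75
    single-step-reachable unordered pairs are active; other entries are
    ignored) and ``epsilon`` a 20-vector of stationary effects on the
    simplex (the simplex constraint fixes the scale gauge between epsilon
    and the codon frequency products).  The derived rate factor is
    ``omega[x, y] = epsilon[y] * beta[x, y]``.
    """

    beta: np.ndarray
    epsilon: np.ndarray

    #: selection parameters before normalization constraints: 75 beta + 20 epsilon
    N_SELECTION_PARAMETERS = 95
    #: free selection parameters: 75 beta + (20 - 1) epsilon on the simplex
    N_FREE_SELECTION_PARAMETERS = 94

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        if beta.shape != (N_AMINO_ACIDS, N_AMINO_ACIDS):
            raise ValueError("beta must be 20x20")
        if not np.allclose(beta, beta.T, equal_nan=True):
            raise ValueError("beta must be symmetric")
        if eps.shape != (N_AMINO_ACIDS,) or np.any(eps <= 0):
            raise ValueError("epsilon must be a positive 20-vector")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "epsilon", eps / eps.sum())

    @property
    def omega(self) -> np.ndarray:
        """Directed rate factors, NaN at unreachable pairs."""
        out = self.epsilon[None, :] * self.beta
        out = np.where(codon_space().reachable_pair_mask(), out, np.nan)
        return out

    @classmethod
    def from_scalar(cls, omega: float) -> "OmegaTensor":
        """The MG-equivalent tensor: uniform epsilon, constant beta.

        With ``epsilon = 1/20`` and ``beta = 20 * omega`` every directed
        entry equals ``omega``.
        """
        mask = codon_space().reachable_pair_mask()
        beta = np.where(mask, N_AMINO_ACIDS * float(omega), 0.0)
        return cls(beta=beta, epsilon=np.full(N_AMINO_ACIDS, 1.0 / N_AMINO_ACIDS))


@dataclass(frozen=True)
class CodonModel:
    """A 61-state reversible codon substitution model.

    ``Q`` is the generator on the fixed sense-codon order, ``pi`` its
    equilibrium distribution, ``mut`` the underlying unit-flow nucleotide
    matrix, ``omega`` either the MG scalar or an :class:`OmegaTensor`.
    ``scaling`` records the time units: ``"mutation"`` leaves the generator
    on the mutation clock of ``mut`` (branch lengths are expected neutral
    mutations per nucleotide site, matching the simulator), while
    ``"substitution"`` rescales to one expected substitution per codon site.
    """

    mut: MutationMatrix
    omega: Union[float, OmegaTensor]
    Q: np.ndarray
    pi: np.ndarray
    scaling: str

    @property
    def kind(self) -> str:
        return "MG" if np.isscalar(self.omega) or isinstance(self.omega, float) else "MF"


def _omega_factor_table(omega: Union[float, OmegaTensor]) -> np.ndarray:
    """Per-variant-slot rate factor (61, 9): 1 synonymous, omega nonsyn, 0 stop."""
    space = codon_space()
    if isinstance(omega, OmegaTensor):
        tgt = np.where(space.nb_sense, space.nb_target, 0)
        full = omega.epsilon[None, :] * omega.beta
        fac = full[np.repeat(space.aa_of, 9).reshape(N_SENSE, 9), space.aa_of[tgt]]
    else:
        fac = np.full((N_SENSE, 9), float(omega))
    fac = np.where(space.nb_syn, 1.0, fac)
    return np.where(space.nb_sense, fac, 0.0)


def _equilibrium(mut: MutationMatrix, omega: Union[float, OmegaTensor]) -> np.ndarray:
    space = codon_space()
    logpi = np.log(mut.sigma)[space.codon_nt].sum(axis=1)
    if isinstance(omega, OmegaTensor):
        logpi = logpi + np.log(omega.epsilon)[space.aa_of]
    logpi -= logpi.max()
    pi = np.exp(logpi)
    return pi / pi.sum()


def _build(
    mut: MutationMatrix, omega: Union[float, OmegaTensor], scaling: str
) -> CodonModel:
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    space = codon_space()
    mu9 = np.where(space.nb_sense, mut.rates[space.nb_src, space.nb_dst], 0.0)
    rate9 = mu9 * _omega_factor_table(omega)
    Q = np.zeros((N_SENSE, N_SENSE))
    rows = np.repeat(np.arange(N_SENSE), 9).reshape(N_SENSE, 9)
    sel = space.nb_sense
    Q[rows[sel], space.nb_target[sel]] = rate9[sel]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = _equilibrium(mut, omega)
    if scaling == "substitution":
        total = float(-np.sum(pi * np.diag(Q)))
        if total <= 0:
            raise ValueError("degenerate model: zero expected substitution rate")
        Q = Q / total
    return CodonModel(mut=mut, omega=omega, Q=Q, pi=pi, scaling=scaling)


def build_mg(
    sigma: np.ndarray,
    rho: np.ndarray,
    omega: float,
    scaling: str = "substitution",
) -> CodonModel:
    """Muse-Gaut codon model with scalar omega."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    return _build(build_gtr_matrix(sigma, rho), float(omega), scaling)


def build_mf(
    sigma: np.ndarray,
    rho: np.ndarray,
    tensor: OmegaTensor,
    scaling: str = "substitution",
) -> CodonModel:
    """Mean-field codon model with an omega tensor."""
    return _build(build_gtr_matrix(sigma, rho), tensor, scaling)


def predicted_position_frequencies(model: CodonModel) -> np.ndarray:
    """Marginal nucleotide frequencies at the three codon positions.

    Rows (positions 1-3) each sum to one.  Under MG all three rows equal the
    stop-codon-renormalized sigma; under MF with non-uniform epsilon the
    third position tracks the mutational AT/GC bias more closely than the
    first two, reproducing the position-specific composition of real coding
    sequences without any position-specific mutation parameters.
    """
    space = codon_space()
    out = np.zeros((3, 4))
    for k in range(3):
        np.add.at(out[k], space.codon_nt[:, k], model.pi)
    return out


def write_position_frequencies(table: np.ndarray, path) -> None:
    """Write a 3x4 position-frequency table as TSV (A C G T header)."""
    from pathlib import Path

    lines = ["position\tA\tC\tG\tT"]
    for k, row in enumerate(np.asarray(table), start=1):
        lines.append(f"{k}\t" + "\t".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def mf_mean_pfix(model: CodonModel, restriction: str = "all") -> float:
    """Equilibrium mean-scaled fixation probability of the model.

    The ratio of the equilibrium-weighted total nonsynonymous substitution
    rate to the equilibrium-weighted total nonsynonymous mutation rate,
    optionally restricted to weak-to-strong ("WS") or strong-to-weak ("SW")
    nucleotide changes.  Independent of the generator scaling.  For an
    MG-reduced tensor (or an MG model) this returns omega exactly.
    """
    space = codon_space()
    nonsyn = space.nb_sense & ~space.nb_syn
    if restriction == "WS":
        mask = nonsyn & (space.nb_ws == 1)
    elif restriction == "SW":
        mask = nonsyn & (space.nb_ws == -1)
    elif restriction == "all":
        mask = nonsyn
    else:
        raise ValueError("restriction must be 'all', 'WS' or 'SW'")
    mu9 = np.where(space.nb_sense, model.mut.rates[space.nb_src, space.nb_dst], 0.0)
    rate9 = mu9 * _omega_factor_table(model.omega)
    num = float(model.pi @ (rate9 * mask).sum(axis=1))
    den = float(model.pi @ (mu9 * mask).sum(axis=1))
    if den <= 0:
        raise ValueError(f"no eligible mutations under restriction {restriction!r}")
    return num / den


def simulate_alignment(
    model: CodonModel, tree: PhyloTree, n_sites: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Sample a leaf alignment from a codon model along a tree.

    Phenomenological sampling through per-branch transition matrices (matrix
    exponentials), independent across sites; used for self-consistency
    recovery experiments.  Returns label -> codon index array.
    """
    from scipy.linalg import expm

    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    cdf_root = np.cumsum(model.pi)
    states[tree.root] = np.searchsorted(cdf_root, rng.random(n_sites), side="right")
    states[tree.root] = np.minimum(states[tree.root], N_SENSE - 1)
    out: dict[str, np.ndarray] = {}
    for node in reversed(range(tree.n_nodes)):  # preorder (root last in postorder)
        if node == tree.root:
            continue
        P = expm(model.Q * tree.length[node])
        cdf = np.cumsum(P, axis=1)
        parent_states = states[tree.parent[node]]
        u = rng.random(n_sites)
        child = (u[:, None] > cdf[parent_states]).sum(axis=1)
        states[node] = np.minimum(child, N_SENSE - 1)
        if not tree.children[node]:
            out[tree.labels[node]] = states[node]
    return out
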