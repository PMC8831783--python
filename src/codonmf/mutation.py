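"""Nucleotide-level mutation matrices.

Two constructions are provided on the fixed nucleotide order (A, C, G, T):

* the AT-biased mutation matrix used by the simulator, in which every
  mutation toward a weak nucleotide (A or T) is multiplied by the bias
  ``lam`` relative to mutations toward strong nucleotides (C or G); and
* the general time-reversible (GTR) matrix used on the inference side,
  ``R[a, b] = rho[a, b] * sigma[b]`` with symmetric exchangeabilities.

Both are normalized so that the expected mutation flow at stationarity,
``-sum_a sigma[a] R[a, a]``, equals one: branch lengths are then expected
mutations per nucleotide site.  The AT-biased matrix is the special GTR case
with all exchangeabilities equal and stationary frequencies
``(lam, 1, 1, lam) / (2 + 2 lam)``, whose weak/strong frequency ratio is
exactly ``lam``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NUCLEOTIDES = "ACGT"
#: unordered nucleotide pairs in fixed order (AC, AG, AT, CG, CT, GT)
NUC_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_WEAK = np.array([True, False, False, True])


@dataclass(frozen=True)
class MutationMatrix:
    """A normalized reversible 4x4 nucleotide rate matrix.

    Attributes
    ----------
    rates : (4, 4) ndarray
        Generator over (A, C, G, T); rows sum to zero, off-diagonals >= 0.
    sigma : (4,) ndarray
        Stationary frequencies.
    rho : (4, 4) ndarray
        Symmetric exchangeabilities with ``rates[a, b] = rho[a, b] * sigma[b]``
        off the diagonal (zero diagonal by convention).
    mu : float
        Overall scale after normalization to unit expected flow.
    lam : float or None
        AT bias when constructed in lambda form, else None.
    """

    rates: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    mu: float
    lam: float | None = None

    def expected_flow(self) -> float:
        """Expected mutations per site per unit time at stationarity."""
        return float(-np.sum(self.sigma * np.diag(self.rates)))

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of the generator (numerical check of sigma)."""
        return stationary_distribution(self.rates)

    def to_tsv(self, path: str | Path) -> None:
        header = "\t".join(NUCLEOTIDES)
        rows = "\n".join(
            f"{n}\t" + "\t".join(f"{v:.12g}" for v in row)
            for n, row in zip(NUCLEOTIDES, self.rates)
        )
        Path(path).write_text(f"\t{header}\n{rows}\n")


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix via its left null space."""
    n = rates.shape[0]
    # solve pi Q = 0 with sum(pi) = 1
    a = np.vstack([rates.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return pi


def _normalize(rates: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, float]:
    flow = float(-np.sum(sigma * np.diag(rates)))
    if flow <= 0:
        raise ValueError("degenerate mutation matrix with zero expected flow")
    return rates / flow, 1.0 / flow


def build_lambda_matrix(lam: float, mu: float = 1.0) -> MutationMatrix:
    """AT-biased mutation matrix with weak/strong bias ``lam``.

    Off-diagonal rates are ``mu * lam`` toward weak nucleotides (A, T) and
    ``mu`` toward strong nucleotides (C, G); the matrix is then rescaled so
    the expected flow at stationarity is one, which fixes the effective
    ``mu`` (the argument only sets the pre-normalization scale).  The
    stationary distribution is ``(lam, 1, 1, lam) / (2 + 2 lam)``.
    """
    if lam <= 0 or mu <= 0:
        raise ValueError("lam and mu must be positive")
    rates = np.where(np.tile(_WEAK, (4, 1)), mu * lam, mu).astype(float)
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    sigma = np.where(_WEAK, lam, 1.0) / (2.0 + 2.0 * lam)
    rates, scale = _normalize(rates, sigma)
    rho = np.full((4, 4), mu * (2.0 + 2.0 * lam) * scale)
    np.fill_diagonal(rho, 0.0)
    return MutationMatrix(rates=rates, sigma=sigma, rho=rho, mu=mu * scale, lam=lam)


def build_gtr_matrix(sigma: np.ndarray, rho: np.ndarray) -> MutationMatrix:
    """GTR mutation matrix ``R[a, b] = rho[a, b] sigma[b]``, unit flow.

    Parameters
    ----------
    sigma : length-4 array on the simplex, order (A, C, G, T).
    rho : either six exchangeabilities in pair order (AC, AG, AT, CG, CT, GT)
        or a symmetric (4, 4) array; all positive.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (4,) or np.any(sigma < 0) or abs(sigma.sum() - 1.0) > 1e-8:
        raise ValueError("sigma must be a length-4 probability vector")
    rho = np.asarray(rho, dtype=float)
    if rho.shape == (6,):
        mat = np.zeros((4, 4))
        for (a, b), r in zip(NUC_PAIRS, rho):
            mat[a, b] = mat[b, a] = r
        rho = mat
    elif rho.shape == (4, 4):
        if not np.allclose(rho, rho.T):
            raise ValueError("rho must be symmetric")
        rho = rho.copy()
        np.fill_diagonal(rho, 0.0)
    else:
        raise ValueError("rho must have shape (6,) or (4, 4)")
    if np.any(rho[~np.eye(4, dtype=bool)] < 0):
        raise ValueError("exchangeabilities must be non-negative")
    rates = rho * sigma[None, :]
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    rates, scale = _normalize(rates, sigma)
    return MutationMatrix(rates=rates, sigma=sigma, rho=rho * scale, mu=scale, lam=None)


def at_gc_ratio(sigma: np.ndarray) -> float:
    """Weak/strong frequency ratio (sigma_A + sigma_T) / (sigma_C + sigma_G)."""
    sigma = np.asarray(sigma, dtype=float)
    strong = sigma[1] + sigma[2]
    if strong <= 0:
        raise ZeroDivisionError("no strong nucleotides: AT/GC ratio undefined")
    return float((sigma[0] + sigma[3]) / strong)
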