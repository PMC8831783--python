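"""Analytic projection of the site-specific process onto a gene-level
mean-field codon process.

At mutation-selection equilibrium, the site-averaged substitution rate from
codon ``i`` to ``j`` weights each site by the probability that a sequence
currently in state ``i`` is at that site, ``P(z | i) = pi[i|z] / sum_z
pi[i|z]``.  Synonymous mean rates reduce to the bare mutation rates; the
nonsynonymous ones factor into the mutation rate times a mean-scaled
fixation probability that depends only on the source and target amino acids
``(x, y)``:

``omega_true[x, y] = sum_z w[z|x] * pfix(F[z,y] - F[z,x])``,

a weighted average of per-site scaled fixation factors with weights
``w[z|x] propto C(z) * exp(F[z, x])``, where ``C(z)`` is the normalizing
constant of the site's stationary distribution.  (The nucleotide-frequency
product over codon positions is site-independent and cancels from the
weights, which is why the average is per amino-acid pair, not per codon
pair.)  This 20x20 array is the "true" omega tensor that the mean-field
inference model estimates; amino-acid pairs not connected by any single
nonsynonymous nucleotide change are flagged undefined (NaN), never zero.

The weighted-sum and closed-form routes are both implemented and agree to
numerical precision; the closed form is evaluated through log-space weights
(softmax), which is stable for strongly scaled landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp, softmax

from ._numerics import scaled_pfix
from .genetic_code import AMINO_ACIDS, N_SENSE, codon_space
from .mutation import MutationMatrix
from .synthetic_fitness import FitnessLandscape


@dataclass
class MeanFieldProjection:
    """Site-averaged gene-level process.

    ``mean_rates`` is the 61x61 mean generator; ``site_weights[z, i]`` the
    weights P(z | i); ``omega`` the 20x20 true omega tensor with NaN at
    unreachable pairs.
    """

    mean_rates: np.ndarray
    site_weights: np.ndarray
    omega: np.ndarray

    def write_omega_tsv(self, path: str | Path) -> None:
        write_omega_tsv(self.omega, path)


def write_omega_tsv(omega: np.ndarray, path: str | Path) -> None:
    """20x20 omega table as TSV (rows = source, columns = target, NaN as NA)."""
    header = "\t".join(AMINO_ACIDS)
    lines = [f"\t{header}"]
    for a, row in zip(AMINO_ACIDS, omega):
        cells = "\t".join("NA" if not np.isfinite(v) else f"{v:.10g}" for v in row)
        lines.append(f"{a}\t{cells}")
    Path(path).write_text("\n".join(lines) + "\n")


def _log_norm_constants(mut: MutationMatrix, land: FitnessLandscape) -> np.ndarray:
    """log C(z) = -log sum_j prod_k sigma[j_k] exp(F[z, A(j)])."""
    space = codon_space()
    log_sigma_prod = np.log(mut.sigma)[space.codon_nt].sum(axis=1)  # (61,)
    return -logsumexp(log_sigma_prod[None, :] + land.F[:, space.aa_of], axis=1)


def omega_true_matrix(mut: MutationMatrix, land: FitnessLandscape) -> np.ndarray:
    """The full 20x20 true omega tensor (NaN at unreachable pairs)."""
    space = codon_space()
    logc = _log_norm_constants(mut, land)  # (Z,)
    # log-weights per source amino acid: (Z, 20)
    logw = logc[:, None] + land.F
    w = softmax(logw, axis=0)  # normalized over sites, per source amino acid
    # value[z, x, y] = pfix(F[z, y] - F[z, x]); average over z with w[:, x]
    s = land.F[:, None, :] - land.F[:, :, None]  # (Z, x, y)
    omega = np.einsum("zx,zxy->xy", w, scaled_pfix(s))
    omega[~space.reachable_pair_mask()] = np.nan
    return omega


def omega_true(x: str, y: str, mut: MutationMatrix, land: FitnessLandscape) -> float:
    """Site-averaged scaled fixation probability for one amino-acid pair.

    Raises for pairs not reachable by a single nonsynonymous nucleotide
    change under the standard code.
    """
    space = codon_space()
    ix, iy = space.aa_index[x], space.aa_index[y]
    if not space.reachable_pair_mask()[ix, iy]:
        raise ValueError(f"amino-acid pair {x}->{y} is not single-step reachable")
    logc = _log_norm_constants(mut, land)
    w = softmax(logc + land.F[:, ix])
    return float(np.sum(w * scaled_pfix(land.F[:, iy] - land.F[:, ix])))


def project(
    mut: MutationMatrix, land: FitnessLandscape, method: str = "closed_form"
) -> MeanFieldProjection:
    """Project the site-specific process onto the mean-field generator.

    ``method='closed_form'`` evaluates the per-amino-acid-pair closed form;
    ``method='explicit'`` performs the direct weighted sum of per-site rate
    matrices under P(z | i).  The two agree to numerical precision and the
    explicit route serves as the independent check of the algebra.
    """
    from .simulator import SiteTables

    space = codon_space()
    tables = SiteTables(mut, land)
    pi = tables.stationary  # (Z, 61)
    weights = pi / pi.sum(axis=0, keepdims=True)  # P(z | i), (Z, 61)

    mean_rates = np.zeros((N_SENSE, N_SENSE))
    rows = np.repeat(np.arange(N_SENSE), 9).reshape(N_SENSE, 9)
    sel = space.nb_sense
    if method == "explicit":
        mean9 = np.einsum("zi,zim->im", weights, tables.rate)  # (61, 9)
        mean_rates[rows[sel], space.nb_target[sel]] = mean9[sel]
        omega = omega_true_matrix(mut, land)
    elif method == "closed_form":
        omega = omega_true_matrix(mut, land)
        fac = np.where(
            space.nb_syn,
            1.0,
            np.where(
                sel,
                omega[
                    np.repeat(space.aa_of, 9).reshape(N_SENSE, 9),
                    space.aa_of[np.where(sel, space.nb_target, 0)],
                ],
                0.0,
            ),
        )
        mean9 = tables.mu9 * fac
        mean_rates[rows[sel], space.nb_target[sel]] = mean9[sel]
    else:
        raise ValueError("method must be 'closed_form' or 'explicit'")
    np.fill_diagonal(mean_rates, -np.nansum(mean_rates, axis=1))
    return MeanFieldProjection(mean_rates=mean_rates, site_weights=weights, omega=omega)
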