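"""Site-specific fitness landscapes.

The simulator's selective regime is a matrix of scaled log-fitnesses
``F[z, a] = Nr * ln(psi[z, a])``, one row per coding site, one column per
amino acid, where ``psi`` are Wrightian fitness profiles on the 20-simplex
and ``Nr`` is a relative effective population size multiplying all
log-fitness differences (the stringency of selection).

Deep-mutational-scanning preference tables have exactly this shape, and the
default generator emulates their qualitative structure: sparse symmetric
Dirichlet draws in which a handful of amino acids per site carry most of the
fitness mass while the rest are strongly deleterious.  A resampling path
accepts an external preference table (sites x 20, one-letter amino-acid
columns) and draws site profiles from it with replacement.

Only log-fitness *differences* matter: adding a constant to any row of ``F``
leaves every substitution rate and stationary distribution unchanged.
Profiles are floored at a small positive value before taking logs, since a
Wrightian fitness of exactly zero has no finite logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import AMINO_ACIDS, N_AMINO_ACIDS

DEFAULT_FLOOR = 1e-8
DEFAULT_CONCENTRATION = 0.1


@dataclass(frozen=True)
class ProfileSpec:
    """Specification of a synthetic landscape draw.

    Parameters
    ----------
    n_sites : number of coding sites Z.
    concentration : symmetric Dirichlet concentration of the profile sampler;
        small values give sparse profiles (few favored amino acids per site).
    nr : relative effective population size scaling log-fitnesses.
    seed : RNG seed.
    floor : lower bound applied to Wrightian fitnesses before the log.
    """

    n_sites: int
    concentration: float = DEFAULT_CONCENTRATION
    nr: float = 1.0
    seed: int = 0
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.nr < 0:
            raise ValueError("nr must be non-negative")


@dataclass(frozen=True)
class FitnessLandscape:
    """Z x 20 fitness landscape.

    ``psi`` holds the Wrightian profiles (each row positive, summing to one
    up to flooring); ``F`` the scaled log-fitnesses ``nr * ln(psi)``.
    """

    psi: np.ndarray
    nr: float

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        if psi.ndim != 2 or psi.shape[1] != N_AMINO_ACIDS:
            raise ValueError("psi must have shape (Z, 20)")
        if np.any(psi <= 0) or not np.all(np.isfinite(psi)):
            raise ValueError("Wrightian fitnesses must be positive and finite")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "_F", self.nr * np.log(psi))

    @property
    def F(self) -> np.ndarray:
        """Scaled log-fitnesses, shape (Z, 20)."""
        return self._F

    @property
    def n_sites(self) -> int:
        return self.psi.shape[0]

    def flat(self) -> bool:
        """True when every site is selectively neutral (all F equal per row)."""
        return bool(np.allclose(self.F, self.F[:, :1]))


def _floor_and_renormalize(psi: np.ndarray, floor: float) -> np.ndarray:
    psi = np.maximum(psi, floor)
    return psi / psi.sum(axis=1, keepdims=True)


def sample_landscape(spec: ProfileSpec) -> FitnessLandscape:
    """Draw Z independent sparse profiles and scale them by Nr.

    With ``nr == 0`` the landscape is exactly flat (neutral); with a large
    concentration the profiles approach uniformity, which is the other
    neutral limit.
    """
    rng = np.random.default_rng(spec.seed)
    psi = rng.dirichlet(np.full(N_AMINO_ACIDS, spec.concentration), size=spec.n_sites)
    return FitnessLandscape(psi=_floor_and_renormalize(psi, spec.floor), nr=spec.nr)


def resample_landscape(
    profiles: np.ndarray | pd.DataFrame,
    n_sites: int,
    nr: float = 1.0,
    seed: int = 0,
    floor: float = DEFAULT_FLOOR,
) -> FitnessLandscape:
    """Sample site profiles with replacement from an external table.

    ``profiles`` is a (n_profiles, 20) array or DataFrame of amino-acid
    preferences (rows renormalized to the simplex after flooring).
    """
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles[list(AMINO_ACIDS)].to_numpy(dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != N_AMINO_ACIDS:
        raise ValueError("profile table must have 20 amino-acid columns")
    if np.any(~np.isfinite(profiles)) or np.any(profiles < 0):
        raise ValueError("profile table entries must be finite and non-negative")
    profiles = _floor_and_renormalize(profiles, floor)
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, profiles.shape[0], size=n_sites)
    return FitnessLandscape(psi=profiles[rows], nr=nr)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read a preference table (TSV, one-letter amino-acid header).

    Rows are renormalized to the simplex; normalization conventions of the
    source table therefore do not matter beyond relative preferences.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [a for a in AMINO_ACIDS if a not in df.columns]
    if missing:
        raise ValueError(f"profile table lacks amino-acid columns {missing}")
    df = df[list(AMINO_ACIDS)].astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("profile table entries must be non-negative")
    total = df.sum(axis=1).to_numpy()
    if np.any(total <= 0):
        raise ValueError("profile rows must have positive mass")
    return df.div(df.sum(axis=1), axis=0)


def write_profiles(landscape_or_psi: FitnessLandscape | np.ndarray, path: str | Path) -> None:
    """Write profiles as TSV with the alphabetical one-letter header."""
    psi = (
        landscape_or_psi.psi
        if isinstance(landscape_or_psi, FitnessLandscape)
        else np.asarray(landscape_or_psi, dtype=float)
    )
    pd.DataFrame(psi, columns=list(AMINO_ACIDS)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
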