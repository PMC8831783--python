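"""Forward Gillespie simulation under the site-specific mutation-selection
process, with full substitution recording.

Each coding site ``z`` evolves on the 61 sense codons with generator

``Q[i, j | z] = R[M(i, j)]``                          for synonymous neighbors,
``Q[i, j | z] = R[M(i, j)] * s / (1 - exp(-s))``      for nonsynonymous ones,

where ``R`` is the nucleotide mutation matrix, ``s = F[z, A(j)] - F[z, A(i)]``
the scaled log-fitness difference, and non-neighbor rates are zero.  The
process is reversible with site stationary distribution

``pi[i | z]  propto  sigma[i1] sigma[i2] sigma[i3] * exp(F[z, A(i)])``.

The root sequence is drawn from these per-site stationary distributions and
every branch is simulated with Gillespie's algorithm: exponential waiting
times from the summed exit rate of the current sequence, one substitution
drawn per event, only the mutated site's rates refreshed.  Sites are
independent, so per-site rate rows are precomputed once per landscape.

Besides the leaf alignment, the recorded trajectory supports the
mean-scaled fixation probability of nonsynonymous mutations,
``<2NePfix>``: the time integral, over all branches, of the ratio of total
nonsynonymous substitution rate to total nonsynonymous mutation rate away
from the current sequence, normalized by total tree length.  Restrictions to
weak-to-strong (AT -> GC) or strong-to-weak nucleotide changes use the same
ratio with both sums restricted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._numerics import scaled_pfix
from .genetic_code import N_AMINO_ACIDS, N_SENSE, codon_space
from .mutation import MutationMatrix
from .synthetic_fitness import FitnessLandscape
from .trees import PhyloTree

RESTRICTIONS = ("all", "WS", "SW")

EVENT_DTYPE = np.dtype(
    [("site", np.int64), ("time", np.float64), ("source", np.int64), ("target", np.int64)]
)


class SiteTables:
    """Precomputed per-site Gillespie rate tables.

    ``rate[z, i, m]`` is the substitution rate of variant slot ``m`` (of the
    nine single-nucleotide changes) away from codon ``i`` at site ``z``;
    slots landing on stop codons carry rate zero.
    """

    def __init__(self, mut: MutationMatrix, land: FitnessLandscape) -> None:
        space = codon_space()
        self.space = space
        self.n_sites = land.n_sites
        mu9 = mut.rates[space.nb_src, space.nb_dst]
        self.mu9 = np.where(space.nb_sense, mu9, 0.0)  # (61, 9)
        tgt = np.where(space.nb_sense, space.nb_target, 0)
        aa_i = space.aa_of
        aa_j = aa_i[tgt]  # (61, 9)
        s = land.F[:, aa_j] - land.F[:, aa_i][:, :, None]  # (Z, 61, 9)
        fac = scaled_pfix(s)
        fac = np.where(space.nb_syn[None], 1.0, fac)
        fac = np.where(space.nb_sense[None], fac, 0.0)
        self.rate = self.mu9[None] * fac  # (Z, 61, 9)
        self.exit = self.rate.sum(axis=-1)  # (Z, 61)

        nonsyn = space.nb_sense & ~space.nb_syn
        self.class_masks = {
            "all": nonsyn,
            "WS": nonsyn & (space.nb_ws == 1),
            "SW": nonsyn & (space.nb_ws == -1),
        }
        # per-site, per-state aggregates for the pfix integrand
        self.agg_q = {k: (self.rate * m).sum(-1) for k, m in self.class_masks.items()}
        self.agg_mu = {k: (self.mu9 * m).sum(-1) for k, m in self.class_masks.items()}

        # per-pair scatter index: directed amino-acid pair of each nonsyn slot
        self.pair_index = aa_i[:, None] * N_AMINO_ACIDS + aa_j  # (61, 9)
        self.nonsyn = nonsyn

        # stationary distributions
        log_sigma_prod = np.log(mut.sigma)[space.codon_nt].sum(axis=1)  # (61,)
        logpi = log_sigma_prod[None, :] + land.F[:, aa_i]  # (Z, 61)
        logpi -= logpi.max(axis=1, keepdims=True)
        pi = np.exp(logpi)
        self.stationary = pi / pi.sum(axis=1, keepdims=True)


def site_rate_matrix(z: int, mut: MutationMatrix, land: FitnessLandscape) -> np.ndarray:
    """Dense 61x61 generator of site ``z`` (rows sum to zero)."""
    tables = SiteTables(mut, land)
    return _dense_from_tables(tables, z)


def _dense_from_tables(tables: SiteTables, z: int) -> np.ndarray:
    space = tables.space
    Q = np.zeros((N_SENSE, N_SENSE))
    sel = space.nb_sense
    rows = np.repeat(np.arange(N_SENSE), 9).reshape(N_SENSE, 9)
    Q[rows[sel], space.nb_target[sel]] = tables.rate[z][sel]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def site_stationary_distribution(
    z: int, mut: MutationMatrix, land: FitnessLandscape
) -> np.ndarray:
    """Stationary distribution over the 61 sense codons at site ``z``."""
    space = codon_space()
    log_sigma_prod = np.log(mut.sigma)[space.codon_nt].sum(axis=1)
    logpi = log_sigma_prod + land.F[z, space.aa_of]
    logpi -= logpi.max()
    pi = np.exp(logpi)
    return pi / pi.sum()


@dataclass
class Trajectory:
    """Recorded substitution history of one simulation.

    ``events[n]`` holds the ordered events on the branch above node ``n``
    (times measured from the start of the branch); ``root_seq`` the codon
    index sequence drawn at the root; ``leaf_seqs`` the sequences reached at
    the leaves, keyed by label.
    """

    tree: PhyloTree
    root_seq: np.ndarray
    events: dict[int, np.ndarray]
    leaf_seqs: dict[str, np.ndarray]

    @property
    def n_events(self) -> int:
        return sum(len(e) for e in self.events.values())

    def to_tsv(self, path: str | Path) -> None:
        space = codon_space()
        lines = ["branch\tsite\ttime\tsource\ttarget\tsynonymous\tws_class"]
        from .genetic_code import ws_class

        for node in sorted(self.events):
            for ev in self.events[node]:
                i, j = int(ev["source"]), int(ev["target"])
                diff = np.nonzero(space.codon_nt[i] != space.codon_nt[j])[0][0]
                wsc = ws_class(space.codon_nt[i][diff], space.codon_nt[j][diff])
                syn = int(space.aa_of[i] == space.aa_of[j])
                lines.append(
                    f"{node}\t{int(ev['site'])}\t{ev['time']:.8g}\t"
                    f"{space.codons[i]}\t{space.codons[j]}\t{syn}\t{wsc}"
                )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SimulationResult:
    trajectory: Trajectory
    alignment: dict[str, np.ndarray]  # label -> codon index sequence


def _branch_rng(seed: int, node: int) -> np.random.Generator:
    # independent, reproducible substream per branch
    return np.random.default_rng([int(seed), int(node)])


def _evolve_branch(
    seq: np.ndarray,
    tables: SiteTables,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gillespie simulation of one branch; mutates ``seq`` in place."""
    space = tables.space
    z_index = np.arange(len(seq))
    exit_rates = tables.exit[z_index, seq].copy()
    t = 0.0
    events = []
    while True:
        total = exit_rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > length:
            break
        cum = np.cumsum(exit_rates)
        z = int(np.searchsorted(cum, rng.uniform(0.0, cum[-1]), side="right"))
        z = min(z, len(seq) - 1)
        rates = tables.rate[z, seq[z]]
        cum9 = np.cumsum(rates)
        m = int(np.searchsorted(cum9, rng.uniform(0.0, cum9[-1]), side="right"))
        m = min(m, 8)
        j = int(space.nb_target[seq[z], m])
        events.append((z, t, int(seq[z]), j))
        seq[z] = j
        exit_rates[z] = tables.exit[z, j]
    return np.array(events, dtype=EVENT_DTYPE)


def simulate(
    tree: PhyloTree,
    mut: MutationMatrix,
    land: FitnessLandscape,
    seed: int = 0,
) -> SimulationResult:
    """Simulate codon sequences along ``tree`` and record every substitution.

    The root is drawn from the per-site stationary distributions, so the
    process starts (and stays) at mutation-selection equilibrium.  A fixed
    seed yields a bit-identical trajectory; branches use independent
    substreams derived from the node index.
    """
    tables = SiteTables(mut, land)
    Z = land.n_sites
    rng_root = _branch_rng(seed, tree.root)
    u = rng_root.random(Z)
    cdf = np.cumsum(tables.stationary, axis=1)
    root_seq = (u[:, None] > cdf).sum(axis=1).astype(np.intp)
    root_seq = np.minimum(root_seq, N_SENSE - 1)

    events: dict[int, np.ndarray] = {}
    leaf_seqs: dict[str, np.ndarray] = {}

    def descend(node: int, seq: np.ndarray) -> None:
        for child in tree.children[node]:
            child_seq = seq.copy()
            events[child] = _evolve_branch(
                child_seq, tables, tree.length[child], _branch_rng(seed, child)
            )
            if tree.children[child]:
                descend(child, child_seq)
            else:
                leaf_seqs[tree.labels[child]] = child_seq

    descend(tree.root, root_seq)
    traj = Trajectory(tree=tree, root_seq=root_seq, events=events, leaf_seqs=leaf_seqs)
    return SimulationResult(trajectory=traj, alignment=leaf_seqs)


@dataclass
class TrajectorySummary:
    """Time-integrated selection statistics of one trajectory.

    ``pfix[c]`` is the mean-scaled fixation probability for restriction class
    ``c`` in {"all", "WS", "SW"}; ``pair_q`` / ``pair_mu`` are 20x20 time
    integrals of the nonsynonymous substitution and mutation rates per
    directed amino-acid pair, whose ratio estimates the pairwise mean-scaled
    fixation probability; ``pair_counts`` are realized substitution counts.
    """

    pfix: dict[str, float]
    pair_q: np.ndarray
    pair_mu: np.ndarray
    pair_counts: np.ndarray
    total_time: float

    def pairwise_pfix(self, min_count: int = 0) -> np.ndarray:
        """Empirical 20x20 pairwise estimates (NaN where undefined)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            est = self.pair_q / self.pair_mu
        est[self.pair_mu <= 0] = np.nan
        if min_count > 0:
            est[self.pair_counts < min_count] = np.nan
        return est


def summarize_trajectory(
    traj: Trajectory, mut: MutationMatrix, land: FitnessLandscape
) -> TrajectorySummary:
    """Replay a trajectory and integrate the fixation-probability ratios."""
    tables = SiteTables(mut, land)
    tree = traj.tree
    Z = land.n_sites
    z_index = np.arange(Z)
    npair = N_AMINO_ACIDS * N_AMINO_ACIDS

    integ_ratio = {k: 0.0 for k in RESTRICTIONS}
    pair_q = np.zeros(npair)
    pair_mu = np.zeros(npair)
    pair_counts = np.zeros(npair)

    def walk(node: int, seq: np.ndarray) -> None:
        nonlocal pair_q, pair_mu
        for child in tree.children[node]:
            child_seq = seq.copy()
            length = tree.length[child]
            # class aggregates for the piecewise-constant ratio integrand
            q = {k: float(tables.agg_q[k][z_index, child_seq].sum()) for k in RESTRICTIONS}
            mu = {k: float(tables.agg_mu[k][child_seq].sum()) for k in RESTRICTIONS}
            # pairwise rate aggregates (time integrals of rates)
            sel = tables.nonsyn[child_seq]  # (Z, 9)
            pidx = tables.pair_index[child_seq]
            r9 = tables.rate[z_index, child_seq]
            cur_pq = np.bincount(pidx[sel], weights=r9[sel], minlength=npair)
            cur_pmu = np.bincount(
                pidx[sel], weights=tables.mu9[child_seq][sel], minlength=npair
            )
            t_prev = 0.0
            for ev in traj.events.get(child, ()):
                dt = float(ev["time"]) - t_prev
                t_prev = float(ev["time"])
                for k in RESTRICTIONS:
                    if mu[k] > 0:
                        integ_ratio[k] += dt * q[k] / mu[k]
                pair_q += dt * cur_pq
                pair_mu += dt * cur_pmu
                z, i, j = int(ev["site"]), int(ev["source"]), int(ev["target"])
                space = tables.space
                if space.aa_of[i] != space.aa_of[j]:
                    pair_counts[space.aa_of[i] * N_AMINO_ACIDS + space.aa_of[j]] += 1
                # refresh the mutated site's contribution to all aggregates
                for k in RESTRICTIONS:
                    q[k] += float(tables.agg_q[k][z, j] - tables.agg_q[k][z, i])
                    mu[k] += float(tables.agg_mu[k][j] - tables.agg_mu[k][i])
                old_sel = tables.nonsyn[i]
                new_sel = tables.nonsyn[j]
                np.subtract.at(cur_pq, tables.pair_index[i][old_sel], tables.rate[z, i][old_sel])
                np.subtract.at(cur_pmu, tables.pair_index[i][old_sel], tables.mu9[i][old_sel])
                np.add.at(cur_pq, tables.pair_index[j][new_sel], tables.rate[z, j][new_sel])
                np.add.at(cur_pmu, tables.pair_index[j][new_sel], tables.mu9[j][new_sel])
                child_seq[z] = j
            dt = length - t_prev
            for k in RESTRICTIONS:
                if mu[k] > 0:
                    integ_ratio[k] += dt * q[k] / mu[k]
            pair_q += dt * cur_pq
            pair_mu += dt * cur_pmu
            if tree.children[child]:
                walk(child, child_seq)

    walk(tree.root, traj.root_seq.copy())
    total = tree.total_length
    pfix = {k: float(integ_ratio[k] / total) for k in RESTRICTIONS}
    return TrajectorySummary(
        pfix=pfix,
        pair_q=pair_q.reshape(N_AMINO_ACIDS, N_AMINO_ACIDS),
        pair_mu=pair_mu.reshape(N_AMINO_ACIDS, N_AMINO_ACIDS),
        pair_counts=pair_counts.reshape(N_AMINO_ACIDS, N_AMINO_ACIDS),
        total_time=total,
    )


def mean_scaled_pfix(
    traj: Trajectory,
    mut: MutationMatrix,
    land: FitnessLandscape,
    restriction: str = "all",
) -> float:
    """Trajectory-recorded ``<2NePfix>`` with optional WS/SW restriction."""
    if restriction not in RESTRICTIONS:
        raise ValueError(f"restriction must be one of {RESTRICTIONS}")
    summary = summarize_trajectory(traj, mut, land)
    value = summary.pfix[restriction]
    if not np.isfinite(value):
        raise ValueError(f"no eligible mutations for restriction {restriction!r}")
    return value
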