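"""Maximum-likelihood fitting of the MG and MF codon models on a fixed
topology, plus nested model comparison.

The likelihood is the standard pruning recursion over the 61 sense codons
with root frequencies equal to the model's equilibrium distribution.  Both
models are reversible, so each generator is exponentiated through one
symmetric eigendecomposition per likelihood evaluation
(``Q = V diag(lam) V^-1`` with ``V = diag(pi)^-1/2 U``), shared by all
branches.

Gradients are computed semi-analytically: the directional derivative of a
matrix exponential in the eigenbasis is exact (first divided differences of
``exp`` on the spectrum), and one outer (root-to-tip) pruning pass yields
the sensitivity of the log-likelihood to every branch transition matrix at
the cost of a second likelihood evaluation.  Only the derivative of the
generator construction with respect to the free parameters -- a cheap,
smooth algebraic map -- is taken by central finite differences.  The whole
gradient therefore costs a small constant multiple of one likelihood, which
is what makes the 100+-parameter MF model practical to fit; the gradient is
validated against full numerical differentiation in the test suite.

Parameters are optimized unconstrained (L-BFGS-B with box bounds): simplex
quantities (sigma, epsilon) through logit transforms with a fixed reference
category, strictly positive quantities (rho, omega, beta, branch lengths)
through logs.  Branch lengths may be fixed to their input values -- in which
case the generator keeps the simulator's mutation-clock time units -- or
re-estimated jointly under the conventional one-expected-substitution
scaling.

Conditional likelihoods are propagated unscaled in double precision, which
is ample for trees of up to a few dozen taxa; very large trees would need
per-node rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.special import softmax
from scipy.stats import chi2

from .codon_models import CodonModel, OmegaTensor, _build, mf_mean_pfix
from .genetic_code import AMINO_ACIDS, N_AMINO_ACIDS, N_SENSE, codon_space
from .mutation import at_gc_ratio, build_gtr_matrix
from .trees import PhyloTree

# --------------------------------------------------------------------------- #
# alignment container


class CodonAlignment:
    """An in-frame codon alignment as a (taxa x sites) codon-index matrix.

    Codons containing non-ACGT characters, gaps, or stops are masked (-1)
    and contribute a flat partial likelihood.
    """

    def __init__(self, labels: list[str], codons: np.ndarray) -> None:
        codons = np.asarray(codons, dtype=np.intp)
        if codons.ndim != 2 or codons.shape[0] != len(labels):
            raise ValueError("codons must be (n_taxa, n_sites)")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        if codons.size and (codons.max() >= N_SENSE or codons.min() < -1):
            raise ValueError("codon indices out of range")
        self.labels = list(labels)
        self.codons = codons

    # ------------------------------------------------------------------ #

    @classmethod
    def from_dict(cls, seqs: dict[str, Union[np.ndarray, str]]) -> "CodonAlignment":
        space = codon_space()
        labels, rows = [], []
        for label, seq in seqs.items():
            labels.append(label)
            if isinstance(seq, str):
                seq = seq.upper().replace("U", "T")
                if len(seq) % 3:
                    raise ValueError(f"sequence {label!r} length not divisible by 3")
                idx = [
                    space.codon_index.get(seq[k : k + 3], -1)
                    for k in range(0, len(seq), 3)
                ]
                rows.append(np.array(idx, dtype=np.intp))
            else:
                rows.append(np.asarray(seq, dtype=np.intp))
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        return cls(labels, np.vstack(rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls.from_dict(seqs)

    def to_fasta(self, path: str | Path) -> None:
        space = codon_space()
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.codons):
                seq = "".join(space.codons[i] if i >= 0 else "---" for i in row)
                fh.write(f">{label}\n{seq}\n")

    # ------------------------------------------------------------------ #

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def nucleotide_frequencies(self, position: Optional[int] = None) -> np.ndarray:
        """Observed nucleotide frequencies, optionally at one codon position
        (1-based)."""
        space = codon_space()
        valid = self.codons >= 0
        nts = space.codon_nt[np.where(valid, self.codons, 0)]  # (taxa, sites, 3)
        if position is None:
            counts = np.bincount(nts[valid].ravel(), minlength=4)
        else:
            if position not in (1, 2, 3):
                raise ValueError("position must be 1, 2 or 3")
            counts = np.bincount(nts[..., position - 1][valid], minlength=4)
        return counts / counts.sum()

    def at_gc_ratio(self, position: Optional[int] = None) -> float:
        return at_gc_ratio(self.nucleotide_frequencies(position))

    def amino_acid_frequencies(self) -> np.ndarray:
        space = codon_space()
        valid = self.codons >= 0
        counts = np.bincount(
            space.aa_of[self.codons[valid]], minlength=N_AMINO_ACIDS
        ).astype(float)
        return counts / counts.sum()


# --------------------------------------------------------------------------- #
# pruning engine


def _rev_eig(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a pi-reversible generator.

    Returns (lam, V, Vinv) with Q = V diag(lam) Vinv, obtained from the
    symmetric similarity transform diag(pi)^1/2 Q diag(pi)^-1/2.
    """
    d = np.sqrt(pi)
    S = Q * (d[:, None] / d[None, :])
    S = 0.5 * (S + S.T)
    lam, U = eigh(S)
    V = U / d[:, None]
    Vinv = U.T * d[None, :]
    return lam, V, Vinv


def _exp_divided_differences(lam: np.ndarray, t: float) -> np.ndarray:
    """First divided differences of x -> exp(x t) on the spectrum."""
    e = np.exp(lam * t)
    diff = lam[:, None] - lam[None, :]
    near = np.abs(diff) < 1e-12 * max(1.0, float(np.abs(lam).max()))
    num = e[:, None] - e[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        E = num / np.where(near, 1.0, diff)
    return np.where(near, t * 0.5 * (e[:, None] + e[None, :]), E)


class PruningEngine:
    """Felsenstein pruning (and its adjoint) on compressed site patterns."""

    def __init__(self, tree: PhyloTree, aln: CodonAlignment) -> None:
        missing = set(tree.leaf_labels) - set(aln.labels)
        if missing:
            raise ValueError(f"alignment lacks taxa {sorted(missing)}")
        self.tree = tree
        row_of = {label: k for k, label in enumerate(aln.labels)}
        leaf_rows = np.array(
            [row_of[tree.labels[i]] for i in tree.leaves], dtype=np.intp
        )
        data = aln.codons[leaf_rows]  # rows ordered as tree.leaves
        patterns, counts = np.unique(data, axis=1, return_counts=True)
        self.patterns = patterns  # (n_tree_leaves, n_patterns)
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        self.n_sites = aln.n_sites
        # per-leaf base conditionals
        self._leaf_L: dict[int, np.ndarray] = {}
        for k, node in enumerate(tree.leaves):
            L = np.zeros((N_SENSE, self.n_patterns))
            obs = patterns[k]
            ok = obs >= 0
            L[obs[ok], np.nonzero(ok)[0]] = 1.0
            L[:, ~ok] = 1.0
            self._leaf_L[int(node)] = L

    # ------------------------------------------------------------------ #

    def _forward(self, lam, V, Vinv, lengths):
        tree = self.tree
        P: dict[int, np.ndarray] = {}
        A: dict[int, np.ndarray] = {}
        L: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            if not tree.children[node]:
                L[node] = self._leaf_L[node]
            else:
                prod = None
                for c in tree.children[node]:
                    Pc = V @ (np.exp(lam * lengths[c])[:, None] * Vinv)
                    P[c] = Pc
                    Ac = Pc @ L[c]
                    A[c] = Ac
                    prod = Ac if prod is None else prod * Ac
                L[node] = prod
        return P, A, L

    def log_likelihood(self, Q: np.ndarray, pi: np.ndarray, lengths: np.ndarray) -> float:
        lam, V, Vinv = _rev_eig(Q, pi)
        _, _, L = self._forward(lam, V, Vinv, lengths)
        u = pi @ L[self.tree.root]
        if np.any(u <= 0) or not np.all(np.isfinite(u)):
            return -np.inf
        return float(self.weights @ np.log(u))

    def log_likelihood_and_gradient(
        self,
        Q: np.ndarray,
        pi: np.ndarray,
        lengths: np.ndarray,
        dQ: np.ndarray,
        dpi: np.ndarray,
        branch_gradient: bool = False,
    ):
        """Log-likelihood with gradients.

        ``dQ`` (K, 61, 61) and ``dpi`` (K, 61) are derivatives of generator
        and root frequencies with respect to K free parameters.  Returns
        ``(ll, grad_params (K,), grad_lengths (n_nodes,) or None)``.
        """
        tree = self.tree
        lam, V, Vinv = _rev_eig(Q, pi)
        P, A, L = self._forward(lam, V, Vinv, lengths)
        u = pi @ L[tree.root]
        if np.any(u <= 0) or not np.all(np.isfinite(u)):
            k = dQ.shape[0]
            return -np.inf, np.zeros(k), (np.zeros(tree.n_nodes) if branch_gradient else None)
        ll = float(self.weights @ np.log(u))
        wu = self.weights / u

        upper: dict[int, np.ndarray] = {tree.root: pi[:, None] * wu[None, :]}
        M = np.zeros((N_SENSE, N_SENSE))
        grad_lengths = np.zeros(tree.n_nodes) if branch_gradient else None
        for node in reversed(tree.postorder):
            kids = tree.children[node]
            if not kids:
                continue
            up = upper[node]
            for c in kids:
                others = None
                for s in kids:
                    if s == c:
                        continue
                    others = A[s] if others is None else others * A[s]
                mid = up if others is None else up * others
                W = mid @ L[c].T  # (61, 61) sensitivity to P_c
                H = V.T @ W @ Vinv.T
                M += H * _exp_divided_differences(lam, lengths[c])
                if branch_gradient:
                    e = np.exp(lam * lengths[c])
                    grad_lengths[c] = float(np.sum(np.diag(H) * lam * e))
                if tree.children[c]:
                    upper[c] = P[c].T @ mid

        # batched C_k = Vinv dQ_k V, then <M, C_k>; root-frequency term
        C = np.matmul(np.matmul(Vinv[None, :, :], dQ), V[None, :, :])
        grad = np.einsum("ij,kij->k", M, C)
        grad += dpi @ (L[tree.root] @ wu)
        return ll, grad, grad_lengths


def log_likelihood(model: CodonModel, tree: PhyloTree, aln: CodonAlignment) -> float:
    """Pruning log-likelihood of a codon model on a fixed tree."""
    engine = PruningEngine(tree, aln)
    return engine.log_likelihood(model.Q, model.pi, tree.length)


# --------------------------------------------------------------------------- #
# parameterization


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit`.

    ``fix_branch_lengths`` keeps the input branch lengths (mutation-clock
    units, matching the simulator); otherwise lengths are re-estimated
    jointly under unit-substitution scaling.  ``n_restarts`` optimizations
    are run from the data-driven initial point (first) and seeded random
    perturbations of it; the best optimum is kept.
    """

    fix_branch_lengths: bool = False
    n_restarts: int = 3
    maxiter: int = 500
    seed: int = 0
    init_omega: float = 0.3
    ftol: float = 1e-9
    gtol: float = 1e-5
    fd_step: float = 1e-6


class _ParamMap:
    """Packing/unpacking of free parameters for one model kind."""

    def __init__(self, kind: str, tree: PhyloTree, aln: CodonAlignment, cfg: FitConfig):
        if kind not in ("MG", "MF"):
            raise ValueError("model kind must be 'MG' or 'MF'")
        self.kind = kind
        self.cfg = cfg
        self.tree = tree
        self.scaling = "mutation" if cfg.fix_branch_lengths else "substitution"
        mask = codon_space().reachable_pair_mask()
        iu = np.triu_indices(N_AMINO_ACIDS, k=1)
        keep = mask[iu]
        self.beta_rows = iu[0][keep]
        self.beta_cols = iu[1][keep]
        self.n_beta = len(self.beta_rows)  # 75

        self.n_sigma = 3
        self.n_rho = 5  # GT exchangeability fixed to 1
        if kind == "MG":
            self.n_sel = 1
        else:
            self.n_sel = (N_AMINO_ACIDS - 1) + self.n_beta  # 19 + 75
        self.n_params = self.n_sigma + self.n_rho + self.n_sel
        self.branch_nodes = tree.branch_nodes()
        self.n_branch = 0 if cfg.fix_branch_lengths else len(self.branch_nodes)
        self.n_free = self.n_params + self.n_branch

        # data-driven initial point
        sig = np.clip(aln.nucleotide_frequencies(), 0.02, None)
        sig = sig / sig.sum()
        theta = [np.log(sig[:3] / sig[3]), np.zeros(self.n_rho)]
        if kind == "MG":
            theta.append(np.array([np.log(cfg.init_omega)]))
        else:
            eps = np.clip(aln.amino_acid_frequencies(), 1e-3, None)
            eps = eps / eps.sum()
            theta.append(np.log(eps[:-1] / eps[-1]))
            theta.append(np.full(self.n_beta, np.log(cfg.init_omega * N_AMINO_ACIDS)))
        if self.n_branch:
            theta.append(np.log(np.maximum(tree.length[self.branch_nodes], 1e-4)))
        self.theta0 = np.concatenate(theta)

        lo = np.full(self.n_free, -15.0)
        hi = np.full(self.n_free, 15.0)
        if self.n_branch:
            lo[self.n_params :] = np.log(1e-6)
            hi[self.n_params :] = np.log(50.0)
        self.bounds = list(zip(lo, hi))

    # ------------------------------------------------------------------ #

    def unpack(self, theta: np.ndarray) -> dict:
        k = 0
        logits = np.append(theta[k : k + 3], 0.0)
        sigma = softmax(logits)
        k += 3
        rho = np.append(np.exp(theta[k : k + 5]), 1.0)
        k += 5
        if self.kind == "MG":
            omega: Union[float, OmegaTensor] = float(np.exp(theta[k]))
            k += 1
        else:
            eps = softmax(np.append(theta[k : k + N_AMINO_ACIDS - 1], 0.0))
            k += N_AMINO_ACIDS - 1
            beta = np.zeros((N_AMINO_ACIDS, N_AMINO_ACIDS))
            vals = np.exp(theta[k : k + self.n_beta])
            beta[self.beta_rows, self.beta_cols] = vals
            beta[self.beta_cols, self.beta_rows] = vals
            omega = OmegaTensor(beta=beta, epsilon=eps)
            k += self.n_beta
        lengths = self.tree.length.copy()
        if self.n_branch:
            lengths[self.branch_nodes] = np.exp(theta[k : k + self.n_branch])
        return {"sigma": sigma, "rho": rho, "omega": omega, "lengths": lengths}

    def build(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.unpack(theta)
        model = _build(build_gtr_matrix(p["sigma"], p["rho"]), p["omega"], self.scaling)
        return model.Q, model.pi

    def model(self, theta: np.ndarray) -> CodonModel:
        p = self.unpack(theta)
        return _build(build_gtr_matrix(p["sigma"], p["rho"]), p["omega"], self.scaling)

    def derivatives(self, theta: np.ndarray):
        """Central finite differences of (Q, pi) in the free parameters."""
        K = self.n_params
        dQ = np.empty((K, N_SENSE, N_SENSE))
        dpi = np.empty((K, N_SENSE))
        for k in range(K):
            h = self.cfg.fd_step * (1.0 + abs(theta[k]))
            tp = theta.copy()
            tp[k] += h
            Qp, pip = self.build(tp)
            tp[k] -= 2 * h
            Qm, pim = self.build(tp)
            dQ[k] = (Qp - Qm) / (2 * h)
            dpi[k] = (pip - pim) / (2 * h)
        return dQ, dpi


# --------------------------------------------------------------------------- #
# results and fitting


@dataclass
class InferenceResult:
    """Fitted parameters, likelihood and derived statistics of one model."""

    kind: str
    log_likelihood: float
    sigma: np.ndarray
    rho: np.ndarray  # six exchangeabilities (AC, AG, AT, CG, CT, GT), GT = 1
    omega: Optional[float]
    beta: Optional[np.ndarray]
    epsilon: Optional[np.ndarray]
    branch_lengths: np.ndarray
    lambda_hat: float
    pfix: dict[str, float]
    n_free_parameters: int
    n_sites: int
    n_taxa: int
    converged: bool
    n_iterations: int
    message: str
    fix_branch_lengths: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_parameters - 2.0 * self.log_likelihood

    def to_json(self, path: Optional[str | Path] = None) -> str:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        payload = {k: clean(v) for k, v in self.__dict__.items()}
        payload["aic"] = self.aic
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "InferenceResult":
        payload = json.loads(Path(path).read_text())
        payload.pop("aic", None)
        for key in ("sigma", "rho", "branch_lengths", "beta", "epsilon"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _pack_result(
    pmap: _ParamMap, theta: np.ndarray, ll: float, res, aln: CodonAlignment
) -> InferenceResult:
    p = pmap.unpack(theta)
    model = pmap.model(theta)
    rho6 = np.array([p["rho"][i] for i in range(6)])
    if pmap.kind == "MG":
        omega, beta, eps = float(p["omega"]), None, None
    else:
        omega, beta, eps = None, p["omega"].beta, p["omega"].epsilon
    pfix = {r: mf_mean_pfix(model, r) for r in ("all", "WS", "SW")}
    return InferenceResult(
        kind=pmap.kind,
        log_likelihood=float(ll),
        sigma=p["sigma"],
        rho=rho6,
        omega=omega,
        beta=beta,
        epsilon=eps,
        branch_lengths=p["lengths"],
        lambda_hat=at_gc_ratio(p["sigma"]),
        pfix=pfix,
        n_free_parameters=pmap.n_free,
        n_sites=aln.n_sites,
        n_taxa=aln.n_taxa,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        message=str(res.message),
        fix_branch_lengths=pmap.cfg.fix_branch_lengths,
    )


def fit(
    model_kind: str,
    tree: PhyloTree,
    aln: CodonAlignment,
    config: Optional[FitConfig] = None,
) -> InferenceResult:
    """Maximum-likelihood fit of the MG or MF codon model.

    Derived quantities (the mutational-bias estimate ``lambda_hat`` from the
    fitted nucleotide frequencies, and the equilibrium mean-scaled fixation
    probabilities overall and restricted to WS / SW changes) are computed
    from the fitted model.  Non-convergence is reported in the result, never
    silently ignored.
    """
    cfg = config or FitConfig()
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    pmap = _ParamMap(model_kind, tree, aln, cfg)
    engine = PruningEngine(tree, aln)

    def objective(theta: np.ndarray):
        Q, pi = pmap.build(theta)
        dQ, dpi = pmap.derivatives(theta)
        lengths = pmap.unpack(theta)["lengths"]
        ll, gparam, glen = engine.log_likelihood_and_gradient(
            Q, pi, lengths, dQ, dpi, branch_gradient=bool(pmap.n_branch)
        )
        if not np.isfinite(ll):
            return 1e12, np.zeros(pmap.n_free)
        grad = np.empty(pmap.n_free)
        grad[: pmap.n_params] = gparam
        if pmap.n_branch:
            # chain rule through the log-length transform
            grad[pmap.n_params :] = (
                glen[pmap.branch_nodes] * lengths[pmap.branch_nodes]
            )
        return -ll, -grad

    rng = np.random.default_rng(cfg.seed)
    best = None
    for restart in range(max(1, cfg.n_restarts)):
        theta0 = pmap.theta0.copy()
        if restart > 0:
            theta0 += rng.normal(0.0, 0.3, size=theta0.shape)
            theta0 = np.clip(theta0, -14.0, 14.0)
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=pmap.bounds,
            options={"maxiter": cfg.maxiter, "ftol": cfg.ftol, "gtol": cfg.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    return _pack_result(pmap, best.x, -best.fun, best, aln)


def compare(res_mg: InferenceResult, res_mf: InferenceResult) -> dict:
    """Nested comparison of fitted MG and MF results on the same data.

    Returns the AIC difference (MG minus MF; positive favors MF), the
    likelihood-ratio statistic ``2 (l_MF - l_MG)``, the degrees of freedom
    (difference in free parameter counts; 93 when branch treatment matches)
    and the chi-squared tail probability.
    """
    if res_mg.kind != "MG" or res_mf.kind != "MF":
        raise ValueError("compare expects an MG result and an MF result")
    if (res_mg.n_sites, res_mg.n_taxa) != (res_mf.n_sites, res_mf.n_taxa):
        raise ValueError("results come from different data")
    if res_mg.fix_branch_lengths != res_mf.fix_branch_lengths:
        raise ValueError("results use different branch-length treatments")
    df = res_mf.n_free_parameters - res_mg.n_free_parameters
    lrt = 2.0 * (res_mf.log_likelihood - res_mg.log_likelihood)
    return {
        "delta_aic": res_mg.aic - res_mf.aic,
        "lrt_stat": lrt,
        "df": df,
        "p_value": float(chi2.sf(max(lrt, 0.0), df)),
    }
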