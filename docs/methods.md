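# Methods

## The model

`codonmf` implements an origination–fixation view of protein-coding
sequence evolution.  Between substitutions the population is monomorphic;
the substitution rate from codon `i` to a single-nucleotide neighbor `j`
is the mutation rate times a scaled fixation probability,

    Q[i, j | z] = R[a→b] · s / (1 − e^(−s)),     s = F[z, A(j)] − F[z, A(i)],

where `R` is a 4×4 nucleotide mutation matrix, `A(i)` the encoded amino
acid, and `F[z, a] = Nr · ln ψ[z, a]` the scaled log-fitness of amino acid
`a` at coding site `z` (`ψ` are Wrightian fitness profiles on the
20-simplex, `Nr` a relative effective population size that sets the
stringency of selection).  Synonymous changes are neutral (`s = 0`, factor
1); changes through stop codons have rate zero; codons differing at more
than one position have rate zero.  Each site is reversible with stationary
distribution

    π[i | z] ∝ σ[i₁] σ[i₂] σ[i₃] · e^(F[z, A(i)]),

where `σ` are the stationary nucleotide frequencies of `R`.

Two mutation matrices are provided.  The simulator uses an AT-biased matrix
in which every rate toward a weak nucleotide (A or T) carries a factor `λ`;
its stationary distribution is `(λ, 1, 1, λ)/(2+2λ)`, so the weak/strong
frequency ratio is exactly `λ` — this is the "mutational bias" that
inference tries to recover.  The inference side uses a general
time-reversible (GTR) matrix `R[a,b] = ρ[a,b] σ[b]`.  Both are normalized
to unit expected mutation flow at stationarity, so time is measured in
expected neutral mutations per nucleotide site.

## Mean-field projection and the omega tensor

Averaging the site-specific processes at equilibrium, with site weights
`P(z|i) = π[i|z] / Σ_z π[i|z]`, yields a site-homogeneous gene-level
process whose synonymous rates are the bare mutation rates and whose
nonsynonymous rates factor as mutation rate × a mean-scaled fixation
probability that depends only on the amino-acid pair:

    ω_true[x, y] = Σ_z w[z|x] · pfix(F[z,y] − F[z,x]),
    w[z|x] ∝ C(z) · e^(F[z,x]),

with `C(z)` the normalizing constant of site `z`'s stationary distribution.
The nucleotide-product factor cancels from the weights, which is why the
average is per amino-acid pair rather than per codon pair.  `ω_true`
factors exactly as `ε_y β_{x,y}` with symmetric `β` (taking
`ε_x ∝ Σ_z C(z) e^{F[z,x]}`), which motivates the reversible
parameterization of the inference model.  Of the 190 unordered amino-acid
pairs, 75 are connected by a single nonsynonymous nucleotide change under
the standard code; the remaining entries are undefined and are reported as
NA, never zero.

Two inference models share the GTR mutation part:

* **MG** (Muse–Gaut): one scalar `ω` multiplying all nonsynonymous rates;
  equilibrium codon frequencies are products of nucleotide frequencies
  renormalized over the 61 sense codons.
* **MF** (mean-field): `ω[x,y] = ε_y β_{x,y}` with 75 active symmetric
  exchangeabilities and 20 stationary effects on the simplex (95 selection
  parameters, 94 free after the simplex constraint); equilibrium
  frequencies gain a factor `ε_{A(i)}`.  With uniform `ε` and constant `β`
  the model collapses onto MG, so the two are nested with 93 degrees of
  freedom between them.

From a fitted model, the mutational-bias estimate is
`λ̂ = (σ̂_A+σ̂_T)/(σ̂_C+σ̂_G)`, and the equilibrium mean-scaled fixation
probability is the π-weighted ratio of total nonsynonymous substitution
rate to total nonsynonymous mutation rate, optionally restricted to
weak→strong (AT→GC) or strong→weak nucleotide changes (changes within a
class, A↔T and G↔C, belong to neither).

## Simulation and trajectory statistics

The simulator draws the root from the per-site stationary distributions and
runs Gillespie's algorithm along each branch: exponential waiting times
from the summed exit rate, one event drawn per step, only the mutated
site's rates refreshed (sites are independent).  Per-branch RNG substreams
derived from the node index make trajectories bit-reproducible and
independent of traversal order.

The recorded trajectory supports the mean-scaled fixation probability of
nonsynonymous mutations: the time integral over all branches of the
piecewise-constant ratio of total nonsynonymous substitution rate to total
nonsynonymous mutation rate away from the current sequence, divided by the
total tree length so the result is a mean on the scale of a probability.
Pairwise (per amino-acid pair) estimates instead use the ratio of the two
time *integrals*, which is consistent for `ω_true[x,y]` at equilibrium and
much less noisy than integrating a per-pair ratio whose denominator can be
tiny.

## Likelihood and optimization

The likelihood on a fixed topology is the pruning recursion over 61 codon
states on compressed site patterns, with root frequencies equal to the
model's equilibrium distribution.  Both models are reversible, so the
generator is symmetrized by `diag(π)^{1/2}` and exponentiated through one
symmetric eigendecomposition per evaluation, shared across branches.
Conditional likelihoods are propagated unscaled in double precision, which
is safe for trees up to a few dozen taxa; hundreds of taxa would require
per-node rescaling (a known limitation).

Gradients are semi-analytic.  The directional derivative of each branch
transition matrix is exact in the eigenbasis (first divided differences of
the exponential on the spectrum), and a single outer root-to-tip pass
collects the sensitivity of the log-likelihood to every branch matrix, so
the full gradient costs a small constant multiple of one likelihood
evaluation regardless of the parameter count.  Only the derivative of the
generator construction itself — a cheap, smooth algebraic map from the free
parameters to `(Q, π)` — is taken by central finite differences (step
`1e-6·(1+|θ|)`).  The combined gradient matches full numerical
differentiation to ~1e-5 relative error (tested), and it is what makes the
102-parameter MF model practical to fit: an MF fit on 10 taxa × 500 sites
takes seconds rather than hours.

Free parameters are transformed to unconstrained space: simplex vectors
(`σ`, `ε`) through logits with a fixed reference category, positive scalars
(`ρ` with the GT entry fixed to 1, `ω`, `β`, branch lengths) through logs;
L-BFGS-B with box bounds (±15 on the transformed scale) and a data-driven
initial point (observed nucleotide and amino-acid frequencies, `ω` = 0.3).
The library default runs 3 restarts (the first from the data-driven point,
the rest from seeded perturbations); the studies below use a single start,
which the restart option confirmed to be stable.  Convergence is declared
when the relative likelihood improvement falls below 1e-9 or the projected
gradient below 1e-5; non-convergence is reported in the result object.

Branch-length treatment and time units: with branch lengths fixed to input
values the generator keeps the simulator's mutation clock (so `ω̂` and the
derived fixation probabilities are directly comparable to trajectory
truth); with branch lengths re-estimated (the default) the generator is
rescaled to one expected substitution per codon site, the conventional
codon-model scaling.

Model comparison reports `ΔAIC = AIC_MG − AIC_MF` and the likelihood-ratio
statistic `2(ℓ_MF − ℓ_MG)` against a χ² with degrees of freedom equal to
the difference in free parameter counts (93 when the branch treatment
matches), computed from the implementation's own parameter bookkeeping.

## Synthetic fitness landscapes

Site profiles are symmetric Dirichlet draws with concentration 0.1 on the
20-simplex, floored at 1e-8 and renormalized, then scaled by `Nr`.  This
emulates the structure of deep-mutational-scanning preference tables — a
few amino acids carrying most of the fitness mass per site — and matches
their typical per-site entropy (a Dirichlet(0.1) draw on 20 categories has
mean entropy ≈1.35 nats, effective amino-acid number ≈4).  What it does not
reproduce: the smooth lower tail of experimentally inferred preferences
(regularized estimates rarely go below ~1e-4, while floored Dirichlet draws
reach 1e-8, i.e. harder fitness cliffs), correlations between sites, and
any biochemical structure in which amino acids co-occur.  Passing tests on
these landscapes therefore demonstrate correctness of the machinery and the
qualitative mutation–selection phenomenology, not quantitative transfer to
any particular protein.  An external preference table (sites × 20, TSV,
alphabetical one-letter header) can be resampled with replacement instead;
rows are renormalized to the simplex on input, so the source normalization
convention does not matter.

`Nr = 0` gives an exactly flat (neutral) landscape; the package exposes
`Nr` freely and the studies use levels {0.5, 1, 2} with 1.0 as the
intermediate stringency.

## Study conditions and what the numbers mean

The replicate studies (and `scripts/acceptance.py`) use a 10-taxon balanced
tree with all branch lengths 0.05 expected neutral mutations per nucleotide
site — a miniature of a shallow primate-scale phylogeny — with 500 codon
sites, 10 replicates, fresh landscapes per replicate, and branch lengths
fixed to truth during fitting.  At this reduced scale the recovered
mutational bias `λ̂_MF` is accurate to a few percent while `λ̂_MG` lands
between the alignment's observed AT/GC ratio and the truth, and the
precision of the selection-strength estimates (1 − mean relative error of
`ω̂_MG`, and of the MF-derived mean fixation probability, against
trajectory truth) is around 92–94%.  Two effects bound it: sampling noise
(a few hundred nonsynonymous events per replicate) and a small systematic
attenuation of site-homogeneous estimates on site-specific data, which
grows quickly with divergence — at branch lengths ≥0.1 multiple
substitutions at constrained sites depress `ω̂` by 10–20%, which is why the
studies stay in the shallow regime.

## Numerical choices

* `s/(1−e^(−s))` is evaluated as `s / (−expm1(−s))` with the series
  `1 + s/2 + s²/12` for `|s| < 1e-6`; the tensor average is computed with
  log-space weights (softmax), stable for strongly scaled landscapes.
* Wrightian fitnesses are floored at 1e-8 before taking logs (a zero
  fitness has no finite log-fitness; the floor is configurable).
* Degenerate eigenvalue pairs in the divided-difference matrix use the
  limit `t·e^{λt}` when the spectral gap is below 1e-12 of the spectral
  radius.
* Stationary-distribution cross-checks solve the left null space by least
  squares with an explicit normalization row.
* Stops are excluded as states and as mutation targets everywhere
  (rate zero), and equilibrium distributions are renormalized over the 61
  sense codons.

## Known limitations

No indels, no site-to-site mutation-rate variation, no epistasis, no
time-varying landscapes, no GC-biased gene conversion; the genetic code is
the standard nuclear code only.  The pruning engine does not rescale
partial likelihoods (dozens of taxa at most), and topology is never
inferred.  Alignment codons containing ambiguity characters or stops are
treated as missing data.
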