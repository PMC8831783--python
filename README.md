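# codonmf

Mutation–selection codon simulation and mean-field ω-tensor codon models.

In protein-coding sequences, the nucleotide composition observed in an
alignment is a compromise between the mutation process and selection at the
protein level: under an AT-biased mutation process, selection pushes back
toward GC, so the realized AT/GC ratio understates the true mutational bias
λ = (σ_A+σ_T)/(σ_C+σ_G).  Classical phylogenetic codon models with a single
dN/dS scalar ω (the Muse–Gaut form, `MG`) conflate the two and estimate a
bias somewhere between the observed composition and the truth.

`codonmf` is a toolkit for studying and fixing this, aimed at molecular
evolution researchers.  It provides:

* a **Gillespie simulator** of codon sequences along a phylogeny under a
  site-specific mutation–selection process: rates
  `Q[i,j|z] = R[M(i,j)] · s/(1−e^{−s})` with `s = F[z,A(j)] − F[z,A(i)]`
  and site-wise amino-acid fitness profiles `F = Nr·ln ψ`, with full
  substitution recording and the trajectory statistic 〈2NePfix〉 (the mean
  scaled fixation probability of nonsynonymous mutations, optionally
  restricted to AT→GC or GC→AT changes);
* the **analytic mean-field projection** of that process: the site-averaged
  generator and the true 20×20 tensor
  ω_true[x,y] = 〈2NePfix(x→y)〉 per amino-acid pair;
* two nested **maximum-likelihood codon models** on a fixed topology — MG
  with scalar ω, and the mean-field model `MF` in which ω is a tensor
  ω[x,y] = ε_y·β[x,y] with 75 symmetric exchangeabilities and 20 stationary
  effects — plus AIC/likelihood-ratio comparison (93 degrees of freedom
  between them).  The MF fit recovers the mutational bias λ accurately
  where MG cannot, while both recover the overall strength of selection;
* a **synthetic fitness-landscape generator** (sparse Dirichlet profiles
  emulating deep-mutational-scanning preference tables, stringency scaled
  by a relative population size Nr), so everything is testable without
  external data.

## Worked example

Simulate 300 codon sites on a 6-taxon tree under mutational bias λ = 2 and
intermediate selection (Nr = 1), then fit both models and compare them:

```bash
codonmf simulate --tree tree.nwk --n-sites 300 --lam 2 --nr 1 --seed 7 \
                 --out-prefix demo
codonmf fit --alignment demo.fasta --tree tree.nwk --model MG \
            --fix-branch-lengths --out mg.json
codonmf fit --alignment demo.fasta --tree tree.nwk --model MF \
            --fix-branch-lengths --out mf.json
codonmf compare mg.json mf.json
```

Output from this exact run:

```
simulated 300 sites on 6 taxa: 172 substitutions, <2NePfix> = 0.1874
MG: logL = -2075.106, lambda_hat = 1.7810, <2NePfix> = 0.2269
MF: logL = -2019.857, lambda_hat = 1.8778, <2NePfix> = 0.2305
{
  "delta_aic": -75.50179747418497,
  "lrt_stat": 110.49820252581458,
  "df": 93,
  "p_value": 0.10409356215860913
}
```

Reading the numbers: the simulation recorded a true mean scaled fixation
probability of 0.187 (strong purifying selection: a random nonsynonymous
mutation fixes at ~19% of the neutral rate).  Both fitted models estimate
the strength of selection in the right range (0.23 at this very small data
size), but the tensor model's mutational-bias estimate (1.88) is closer to
the true λ = 2 than the scalar model's (1.78), which sits between the
alignment composition and the truth — the central point of the approach.
At only 300 sites the 93 extra tensor parameters are not yet worth their
AIC cost (ΔAIC < 0, LRT p ≈ 0.10); on longer alignments the MF model is
decisively favored and its λ̂ is accurate to a few percent (see the test
suite's replicate studies).

The same machinery is available as a library (`codonmf.simulate`,
`codonmf.fit`, `codonmf.project`, `codonmf.omega_true_matrix`, ...); see
`docs/methods.md` for the model, its assumptions, parameter conventions and
numerical choices.

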