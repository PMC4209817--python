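# Methods

## Model

We observe `T` independent studies from `K` omics levels (genotype,
expression, …), level `k` contributing `P_k` platforms. Study `(k, j)`
has `n_{kj}` subjects, a feature matrix `X` (samples × features) and a
phenotype `Y` (quantitative, or 0/1 case–control). Subjects are disjoint
across studies; what is shared is the gene universe: every feature of
every study is annotated to one of `Q` genes.

Each study is one regression task, `Y ≈ X C`, and the stacked coefficient
vector is estimated by minimizing the weighted squared-error loss plus a
bi-level sparsity penalty whose groups are genes spanning all tasks (see
the README for the two penalties). Design choices behind that statement:

* **Squared loss for binary phenotypes.** The model is linear even when
  `Y` is 0/1; the coefficients are then working-model projections (as in
  Armitage-trend-style tests), and significance is assessed by
  permutation, which does not rely on the Gaussian likelihood. A logistic
  link is deliberately out of scope.
* **Intercepts by centering.** `Y` is centered per study at fit time;
  features are standardized to mean 0, sd 1 (sample convention, `ddof=1`)
  so penalties act on comparable scales. Constant features are rejected
  at load; inside cross-validation refits a column that becomes constant
  in a training fold is centered and left at unit scale instead (it
  carries no signal either way, and aborting a fold would be worse).
* **Weights.** `ω_k = 1` for every level (no prior preference between
  omics levels; overridable per dataset in the manifest), and
  `δ_j = n_j / Σ_{j'∈level} n_{j'}` so that larger studies within a level
  count proportionally more. The `δ_j` of one level always sum to 1.
* **One group per gene, spanning all tasks.** A gene's group concatenates
  its feature positions in every study, so gene-level selection is a
  joint decision across studies — the point of the multitask coupling. A
  gene may be absent from some study (empty sub-block); a gene absent
  from every study is rejected.

## ADMM solver

Splitting `C = V₁` (and `C = V₂` for the sparse group lasso, whose
penalty separates into a group-ℓ2 and an ℓ1 part) gives an augmented
Lagrangian whose three blocks have exact updates:

1. **C update** — per task, a ridge-regularized least squares
   `(2wX'X + aI)C = 2wX'Y_c + ρ(V₁+D₁) [+ ρ(V₂+D₂)]` with `a = ρ` (one
   split) or `2ρ` (two splits). Each task's economy SVD is computed once
   and reused for every `ρ`, so a solve costs `O(d·rank)`; the SVDs are
   additionally cached across permutation refits and within a CV fold,
   where the design matrices do not change.
2. **V₁ update** — block soft-thresholding (group-ℓ2 prox) for sglasso;
   for sgridge the exact per-group squared-ℓ1 prox: sort `|z|`
   descending, find the largest active-set size `k` whose self-consistent
   threshold `t_k = 2c·S_k/(1+2ck)` (with `c = λ/ρ`, `S_k` the partial
   sum) still admits `|z|_(k) > t_k`, then soft-threshold at `t_k`.
   Because groups do not overlap these closed forms are exact minimizers;
   block coordinate descent would converge to the same point at higher
   cost.
3. **Multiplier update** — `D ← D − C + V` (scaled form; the quadratic
   terms are `ρ/2‖C − V − D‖²`).

Stopping follows the standard primal/dual residual rule:
`res_pri = max_splits ‖C − V‖`, `res_dual = ρ·max_splits ‖V − V_prev‖`,
with `ε = √dim·ε_abs + ε_rel·scale`, defaults `ε_abs = 1e-6`,
`ε_rel = 1e-4`, `max_iter = 2000`, `ρ₀ = 1`, zero initialization. `ρ` is
adapted to keep `res_pri/res_dual` inside `[0.1, 10]` (doubling or
halving, multipliers rescaled accordingly); a zero dual residual counts
as an infinite ratio so fully-thresholded iterates still drive `ρ` up.
The solver is deterministic.

The reported coefficients are *V-consistent*: entries where the
splitting variables are exactly zero are set to zero (the V's carry the
exact sparsity; the last C update is dense up to tolerance). The gene
test downstream relies on those exact zeros. On tiny problems the final
objective of both models sits within 1e-4 (measured: ≤ 8.5e-5) of the
optimum found by an independent second-order-cone solver, and the
objective trace (sampled every 10 iterations, exact final value) is
returned with every fit.

## Tuning and the gene-level test

Penalties are tuned by 5-fold cross-validation over
`λ ∈ {10^0.1, …, 10^3}` (30 values; coarser log-subsampled grids are
available for desk-scale runs). Folds are drawn independently inside
each study — a global fold split is meaningless with disjoint subjects —
and are keyed to the dataset id, so the CV error is invariant to dataset
ordering. Held-out error reuses the training fold's standardization
parameters and aggregates with the same `ω, δ` weights, per held-out
sample: `Σ ω δ · SSE/n_holdout`. Exact ties are broken toward the larger
penalty (parsimony).

The per-gene statistic is `S_i = Σ_j ‖Ĉ_i⁽ʲ⁾‖₂²`. Genes differ in size,
so `S_i` is standardized by the mean and sd (ddof=1) of its own null
distribution, obtained from `B` phenotype permutations (independent
within each study) refit at the hyperparameters selected on the
*unpermuted* data — re-running CV inside every permutation would be
computationally prohibitive and the frozen-λ design is the standard
score-permutation scheme. The standardized null draws of all genes are
pooled (`Q·B` values) and `p_i` is the pooled tail fraction `≥ S̃_i`;
`B = 500` by default. The printed formula can return `p = 0`; a
`--smooth` flag switches to the add-one version for users who need
strictly positive p-values. No multiplicity correction is applied.

**Degenerate genes.** If a gene's statistic never varies across
permutations (`sd = 0`), there is no evidence scale and its p-value is
set to 1 with a warning. This case is not exotic: whenever
cross-validation selects a penalty above the kill threshold
`max|2wX'Y|`, the fitted model — and every permutation refit — is
exactly zero, and *every* gene is degenerate. On pure-noise data this is
in fact the typical outcome (the all-zero model minimizes held-out
error, and many grid cells tie at it), so under a global null the
pipeline usually reports p = 1 everywhere: maximally conservative, with
a flat ROC at AUC 0.5, rather than uniform p-values. The
`test_null_calibration_of_pooled_pvalues` acceptance check asserts
approximate uniformity and consequently fails by design of the pipeline;
it is kept as an honest record of this behaviour.

## Synthetic data

The generator emulates a two-level design: by default 3 genotype studies
(n = 600/400/200) and 3 expression studies (n = 70/50/30), 200 genes
with Unif{10,…,100} SNPs each, 20 causal genes with 2 causal SNPs each
(MAF Unif(0.15, 0.25); other SNPs MAF Unif(0.05, 0.5)).

* **Genotypes** come from a latent-Gaussian haplotype surrogate rather
  than resampled reference haplotypes: per subject, two independent
  haplotype vectors with within-gene AR(1) correlation (`ld_decay`,
  default 0.8, chosen to mimic strong local LD) are thresholded at each
  SNP's MAF quantile and summed to 0/1/2. Hardy–Weinberg equilibrium
  holds by construction and LD decays geometrically within a gene and
  vanishes between genes. Columns that come out constant at small `n`
  are redrawn so standardization is defined.
* **Expression** of a causal gene is `Σ β_j·SNP_j + N(0,1)` with
  `β ~ Unif(1, 1.2)` over that study's own genotypes; non-causal genes
  are jointly Gaussian with correlation `0.3^|i−j|` in gene order.
* **Phenotype** is Bernoulli with
  `logit Pr(Y=1) = Σ τ_j·G_j + N(0,1)` over causal-gene expression (a
  quantitative identity-link mode exists). Genotype-only studies first
  generate *latent* causal expression from their own genotypes and
  discard it after drawing `Y` — the only reading that routes the causal
  chain SNP → expression → phenotype through a study that never observes
  expression. Expression studies of the stated sizes are generated from
  fresh genotype draws of those sizes.
* **Effect sizes.** Baselines `η_j` have magnitude Unif(0.2, 2) and
  random sign; a scenario-level factor `δ ∈ [0, 1]` scales them
  (`δ = 0` is the global null). The dynamic-effect model draws each
  study's `τ_j ~ N(η_j·δ, σ²)`; at `σ = 0` no perturbation is drawn, so
  fixed-effect generation is the same code path and bit-identical.
* **Seeding.** One scenario seed is split deterministically
  (`SeedSequence.spawn`) into structure, effect and per-dataset streams;
  identical scenarios are byte-identical.

What this does *not* emulate: real LD block structure, recombination
hotspots or a finite SNP pool; population stratification; genotyping or
probe-level measurement error; case/control ascertainment. Passing power
comparisons therefore show that the method exploits the modelled causal
chain, not that it is robust to those real-data complications.

## Evaluation harness

The meta-analysis baseline combines per-study signed score-test z's
(`z = r√n` for the simple regression of `Y` on one standardized feature)
with √n weights — METAL's sample-size scheme — and summarizes a gene by
its most significant feature. The min-p summary is anticonservative as a
gene-level p-value; it is used only for ranking (ROC), as is
conventional. ROC curves sweep p-value cutoffs (all observed values plus
the endpoints by default), with TPR/FPR over causal/non-causal genes and
trapezoid AUC on the curve closed at (0,0) and (1,1).

Scaled-down problem sizes are used in the automated checks so the whole
pipeline (CV → fit → 200 permutation refits, several replicates) runs on
one CPU in minutes: 50 genes × 10 SNPs, two genotype studies
(n = 200/100), two expression studies (n = 50/30), 5 causal genes, a 5×5
CV grid, B = 200 permutations, 4 null replicates (2 in the summary
script) and 5 power replicates. At this scale the
power ordering against meta-analysis is stochastic: occasionally a
replicate has no CV-detectable multitask signal (the zero model wins
held-out error) while marginal-correlation ranking still performs well,
so single replicates — and occasionally the 5-replicate mean — can
invert the expected ordering.

## Numerical details and limitations

* Group prox operations are vectorized over a per-index group-label
  array; a group with zero norm maps to zero (no division by zero).
* Missing values are fatal everywhere; impute upstream.
* Overlapping groups (a feature annotated to two genes) are rejected;
  the first annotation would have to be chosen upstream.
* The ℓ1 kill threshold `max|2wX'Y|` gives an exact all-zero solution
  for any `λ₂` above it — useful for sanity checks and the reason the
  top of the default grid is an effective "off switch".
* `rho` adaptation bounds, grid sizes, fold counts, `B` and tolerances
  are all exposed; the defaults above are what every reported number
  uses.
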