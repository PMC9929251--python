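# Methods

## Pooling model

Cells are grouped into strata — one (donor, stimulus) sample crossed with
one cluster label — and each stratum of *n* cells is partitioned uniformly
at random into ⌊n/k⌋ pseudocells of exactly *k* cells (k ∈ {5, 10, 15, 20}
by default; any positive integer is accepted).  The *n* mod *k* leftover
cells are unassigned for that iteration rather than forming a short pool or
being appended to an existing one, so a 63-cell stratum yields exactly 12,
6, 4 and 3 pseudocells at sizes 5/10/15/20.  Iterations reshuffle
independently; there is no rotation scheme guaranteeing every cell is used
at least once.  Pseudocell counts are the per-gene sums over members, and
expression is counts per 100,000 (CP100K = counts / row total × 10⁵).
Pseudocell ids follow `<donor>_<stimulus>_<cluster>_k<k>_it<i>_p<j>` for
traceability across outputs.

All randomness in the package flows from a single user seed.  `run_scpool`
spawns one child stream per (pool size, iteration) from that seed, so adding
a pool size or iteration never perturbs the draws of another.

## Variance partitioning

Per expressed gene the model is a crossed random-intercepts decomposition

    y = μ + u_Stimulus + u_Status + u_Batch + u_Donor + u_Stimulus:Status + ε,

fitted to `log₂(CP100K + 1)` by default.  The log transform is a package
choice (exposed via `transform="raw"`): variance-partitioning methodology
for expression data conventionally operates on log scale, and the
multiplicative effects of the synthetic generator are linear there.  A gene
is *expressed* in a cell type when its mean CP100K over that cell type's
pseudocells is ≥ 1 (inclusive).

Estimation is REML with non-negativity constraints: L-BFGS-B on the
restricted log-likelihood with analytic gradient, started from the
method-of-moments solution, followed by active-set Newton polishing to a
gradient tolerance of 1e-10.  The method-of-moments estimator solves the
linear (trace) system equating each effect's between-level sum of squares,
plus the total sum of squares, to its expectation, by non-negative least
squares; on balanced designs this is the classical expected-mean-squares
ANOVA estimator and coincides with REML whenever all estimates are interior
(verified to ~1e-13 in the tests).  It is also the fallback when REML does
not converge (`backend` flag).  Negative components are clamped to zero
before fractions are formed; a constant response returns residual
fraction 1 with `converged=False`.  Genes are fitted independently, so
results are invariant to execution order.

Fixed-effect inference (used by the proportion ANOVA) is a 1-df Wald F with
Satterthwaite denominator df: ν = 2g²/Var(g) with g = c′(X′V⁻¹X)⁻¹c, the
variance obtained by the delta method with the inverse observed REML
information (numeric Jacobian of the analytic gradient).  On a reference
dataset the engine reproduces lmerTest (lme4) F, df, p and variance
components to ≈6 significant digits (frozen oracle test).

### Design limits that are properties, not bugs

* Stimulus and Status have two levels each, so their variance estimates are
  intrinsically noisy; this mirrors the experimental design and is
  documented rather than corrected.
* With 8 donors nested in Status (6/2) and Batch (4 × 2 donors), the
  donor-level factors are finite-level aliases of Donor: under a
  donor-only generative model the full five-effect fit re-apportions part
  of the donor variance to Status/Batch (lme4 behaves identically).
  Parameter-recovery validation therefore fits the balanced
  Donor + Stimulus subset (`effects=("Donor", "Stimulus")`), while the full
  model is validated under the null, where all non-residual mean fractions
  stay below 0.01 at 160 pseudocells.
* Averaging per-gene *fractions* over a block of genes sharing one
  generative fraction is biased downward (Jensen: the realized donor
  variance of an 8-donor panel has CV ≈ 0.53, giving ≈ −0.03 at f = 0.5
  even for an ideal estimator).  Recovery is therefore summarized by the
  pooled fraction — mean σ²_Donor over the block divided by mean total σ² —
  which is unbiased; both summaries are available
  (`pooled_fraction`, `summarize_components`).
* For the proportion ANOVA, the 3-df Batch component absorbs donor-pair
  variance in roughly a fifth of donor-only simulations (again reproduced
  by lme4), so donor-variance dominance holds for the clear majority of
  datasets and on average, not near-universally.

## Concordance (AUCC)

For two ranked top-K lists, C[i] = |top_i(a) ∩ top_i(b)| for i = 1..K and
AUCC = ΣC[i] / (K²/2) under the default `paper` normalization.  Identical
lists then score (K+1)/K (1.01 at K = 100), slightly above 1; the `exact`
normalization divides by K(K+1)/2 instead so that identical lists score
exactly 1.  Both are shipped because the published description both states
a 0–1 range and divides by K²/2; the package does not silently resolve the
inconsistency.  Unequal-length lists are truncated to the shorter with a
logged warning; ranking ties are broken by raw variance then gene id.

## Proportion ANOVA

Per cell type, per-sample fractions are modeled with fixed Stimulus, Status
and Stimulus × Status (sum-to-zero coding, so each 1-df test is the
Type-III main effect), random Donor and Batch intercepts, REML, and
Satterthwaite df as above.  The default response is the raw proportion; a
logit option with shrinkage offset p* = (pn + 0.5)/(n + 1) is available for
boundedness.  Raw p-values are reported; Benjamini–Hochberg adjustment is
optional and off by default.  Donor/batch variance fractions are the
components over the total (donor + batch + residual).

## Synthetic data generator

The generator emulates the study design the pipeline assumes: 8 donors
(6 cases / 2 controls), stimulus crossed within donor (16 samples), 4
batches of 2 donors assigned round-robin so statuses are spread over
batches, ~2,900 cells per sample (Poisson), up to 17 cell types with
geometrically decaying baseline proportions (~15% down to ~1%), 2,000 genes
with log-normal abundance spread, and negative-binomial counts
(gamma–Poisson, default dispersion 0.1) around per-cell means
`library_size · p_gene · 2^(effects + cell noise)`.

Expression effects are zero-mean normal intercepts per donor / batch /
stimulus / status / interaction drawn once per gene, with variances
`fraction × sigma2_base` (log2² scale) set per gene block.  **Fractions are
defined at the pseudocell level** for pools of `pool_size_ref` cells
(default 10): the per-cell residual variance is scaled up by inverting the
lognormal pooled-mean relation var(log mean of k) = log1p((e^v − 1)/k), and
the predicted count-sampling noise (1/m + α/k on the log scale, m the
expected pooled count) is deducted first.  The ground truth records every
drawn effect, the variance parameters, and the predicted realized fractions;
for small simulations the per-cell noise matrix is kept so every generative
mean can be reconstructed exactly.  Measured end-to-end: a generative donor
fraction of 0.5 pooled at k = 10 recovers 0.505.

Default gene blocks (when none are given): 70% invariant genes, 15% with
donor 0.4 / batch 0.1, 10% with stimulus 0.4 / donor 0.1, 2.5% status 0.3,
2.5% interaction 0.3 — echoing the qualitative structure of an immune
stimulation experiment where donor is the largest component, then stimulus.

Proportions are simulated either directly on the proportion scale
(gaussian mode: baseline + shifts + donor/batch/noise deviations, default
sds 0.02/0.01/0.01, renormalized) or as multinomial counts with logit-scale
shifts.  Optional corruptions add mitochondrial genes (~5% baseline
content, a configurable fraction of cells boosted above threshold) and
inconsistent per-run cluster labels to exercise the QC filters.

What the generator does **not** emulate: cell-type-specific expression
effects (effect draws are shared across cell types), empirical gene-level
means of any particular dataset, doublets, ambient RNA, or batch-dependent
library-size shifts.  Passing tests therefore demonstrate correctness of
the pipeline's accounting on data satisfying its assumptions, not
robustness to those artifacts.

## Numerical choices and problem sizes

* REML: responses standardized to unit variance before optimization
  (scale-equivariance is tested); convergence declared at max |gradient|
  < 1e-6 over free parameters after Newton polishing (tolerance 1e-10 when
  attainable); variance parameters bounded at 0.
* Satterthwaite df clipped to [1, 1e6]; if the delta-method variance is
  non-positive the residual df n − p is used.
* QC outlier statistics are computed once on the pre-filter population
  (single manual pass, not iterative); the mito threshold is strict (>),
  so a cell at exactly 15% is retained; removed cells are attributed to one
  reason in the fixed order mito → outlier → consistency.
* Tests and the acceptance script use scaled-down problem sizes chosen as
  the package's own defaults for desk-scale validation: 100–300 genes,
  80–200 cells per sample, 160 pseudocells per fit, 200-gene recovery
  blocks, 1,000 null proportion simulations.
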