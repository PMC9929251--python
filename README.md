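# scpool

Iterated pseudocell pooling and variance partitioning for single-cell
RNA-seq.

Single cells are noisy, sparse observations, and treating them as biological
replicates inflates significance in case–control comparisons.  `scpool`
takes the opposite route: within each sample (one donor under one culture
condition) and each cell cluster, cells are **randomly pooled into
fixed-size pseudocells** whose UMI counts are summed and normalized to
counts per 100,000 (CP100K).  The resulting pseudo-bulk profiles support
mixed-model variance decomposition of every expressed gene into experimental
components — stimulus, disease status, processing batch, individual donor,
and the stimulus × status interaction — in designs like an ex vivo
TNF-stimulation study of juvenile idiopathic arthritis PBMCs (8 donors × 2
conditions, 4 batches, ~17 cell types).  Because the pooling is random, the
whole procedure is iterated to give pseudo-replicates, and the stability of
the resulting gene rankings is quantified by the area under the concordance
curve (AUCC).

The package is aimed at analysts of small, deeply phenotyped stimulation
studies who need honest variance attribution (how much is donor? how much is
stimulus?) rather than per-cell p-values.

## What it computes

Per stratum (donor × stimulus × cluster) with *n* cells and pool size *k*:
⌊n/k⌋ pseudocells per iteration, members drawn as a uniform random
partition; leftover cells sit out that iteration.  Pseudocell expression is
`CP100K = counts / total · 10⁵`.

Per expressed gene (mean CP100K ≥ 1 across a cell type's pseudocells), a
crossed random-intercepts model is fitted to `log₂(CP100K + 1)`:

```
y = μ + u_Stimulus + u_Status + u_Batch + u_Donor + u_Stimulus:Status + ε
```

with each `u ~ N(0, σ²_effect)`, estimated by non-negativity-constrained
REML (method-of-moments / expected-mean-squares fallback and oracle).
Reported per gene: `σ²_e` and fractions `σ²_e / Σσ²`; per cell type: mean
fractions and the share of genes with a fraction > 5%, plus top-*K* gene
rankings per effect.

AUCC between two top-*K* rankings is `Σᵢ |topᵢ(a) ∩ topᵢ(b)| / (K²/2)`
(the published convention; an `exact` normalization dividing by `K(K+1)/2`,
under which identical lists score exactly 1, is also available).

Cell-type proportions per sample are tested with a linear mixed ANOVA —
fixed Stimulus, Status and their interaction (sum-to-zero coding), random
Donor and Batch — with Satterthwaite denominator degrees of freedom.

QC filters (computed on the unfiltered input, attribution in fixed order):
mitochondrial fraction strictly > 15%, detected-gene count > mean + 3 SD,
and cluster-label consistency (total-dataset label reproduced in ≥ 2 of 4
per-batch clusterings).

A calibrated negative-binomial simulator (`scpool.synthetic`) generates
datasets with this exact design and known generative variance fractions,
and is the test bed for everything above.

## Worked example

```python
from scpool import (SimulationConfig, BlockConfig, ProportionSimConfig,
                    simulate_dataset, run_scpool, compute_proportions,
                    fit_proportion_model, varpart)

cfg = SimulationConfig(
    n_cell_types=2, cells_per_sample=120, n_genes=150,
    blocks=(BlockConfig(75, {"donor": 0.4, "stimulus": 0.2}), BlockConfig(75, {})),
    proportions=ProportionSimConfig(stimulus_shift={"CT01": 0.06}),
    seed=2024,
)
matrix, annotation, truth = simulate_dataset(cfg)
pools = run_scpool(matrix, annotation, sizes=[10], iterations=3, seed=11)
results, summary = varpart.partition_cell_type(pools[(10, 1)], "CT01")
pt = compute_proportions(annotation)
anova = fit_proportion_model(pt, "CT01")
```

This prints (via the obvious `print` statements):

```
cells x genes: 1899 x 150
pseudocells (k=10, iteration 1): 176
expressed genes: 150
  mean fraction Donor            0.141
  mean fraction Stimulus         0.094
  mean fraction Status           0.026
  mean fraction Batch            0.044
  mean fraction Stimulus:Status  0.010
  mean fraction Residual         0.684
top-5 donor-variance genes: G00071, G00064, G00046, G00066, G00017
CT01 stimulus: F=6.4 (df 1,8.9), p=3.21e-02; donor variance fraction=0.00
```

Half the genes carry donor and stimulus expression variance, so the mean
donor fraction (0.141) and stimulus fraction (0.094) stand clearly above
status/batch/interaction; the residual dominates because the other half of
the genes are pure noise.  The +0.06 proportion shift of CT01 under
stimulation is detected by the mixed ANOVA at p ≈ 0.03 with ≈ 9
Satterthwaite denominator df; the donor variance fraction is ~0 because
this config gave every donor the same composition distribution.

The same pipeline is available from the shell:

```sh
scpool --seed 3 --out-dir out simulate --n-genes 200 --cells-per-sample 100
scpool --seed 3 --out-dir out qc   --matrix-dir out/matrix --annotation out/annotation.tsv
scpool --seed 3 --out-dir out pool --matrix-dir out/matrix --annotation out/annotation.tsv
scpool --seed 3 --out-dir out proportions --matrix-dir out/matrix --annotation out/annotation.tsv
```

Every subcommand writes a `*_provenance.json` echoing its full
parameterization and seed.

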