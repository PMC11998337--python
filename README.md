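# phenoscreen

Screening mutagenized plant populations by eye is slow and unreliable: in
benchmark trials of ~100 *Arabidopsis thaliana* plants containing 8–14
radiation-induced mutants, trained observers detected only about 64% of the
true mutants on average. High-throughput imaging platforms produce, for
every plant, a "phenotypic fingerprint" of ~45 morphometric and colour
traits plus a leaf-area time series — and a simple multivariate workflow on
that output detects mutants far more sensitively. `phenoscreen` is a tested,
reusable implementation of that workflow for anyone screening mutant
populations from plate-based phenotyping data.

## The method

1. **Factor extraction.** The trait matrix is z-scored and decomposed by
   correlation-matrix PCA; components with eigenvalue > 1 are retained and
   each plant's unit-variance factor scores (FAC1..FACk) become the
   screening variables. Ward/Euclidean hierarchical clustering provides the
   complementary dendrogram view.
2. **Confidence-ellipse screening.** For every pair of factors, a bivariate
   confidence ellipse is fitted from the sample mean and covariance: a
   plant is outside at level *α* iff its squared Mahalanobis distance
   exceeds the χ²(2 df) quantile at *α* (5.991 at 95%). A plant outside in
   any panel of the scatter matrix is a mutant candidate.
3. **Growth-curve screening.** Each plant's leaf-area series is fitted by
   the logistic growth curve *A(t) = h / (1 + x₁·e^(−x₂·t))* (*h* =
   asymptotic area, x₂ = growth rate), with correction offsets *k*, *s*
   read at a mid-series and a final anchor time. The fitted
   (h, k, s, x₁, x₂) cloud is screened with the same pairwise-ellipse
   procedure.
4. **Combination and evaluation.** Scatter and growth calls are combined
   (union by default) and scored against known labels: accuracy
   P = correct/actual mutants, FNR = missed/actual (so P + FNR = 1), and
   FPR in both the per-predicted and per-total-plants normalizations.

A synthetic-data module generates populations with the workflow's assumed
structure (latent-factor WT baseline, line-specific mutant effects,
logistic growth), and a small image module renders and measures synthetic
plates for end-to-end image→table testing.

## Worked example

```python
from phenoscreen import ScreeningConfig, generate_population, generate_growth_series
from phenoscreen.cli import run_screen

cfg = ScreeningConfig(seed=1)              # 102 plants, 8 mutants in 5 lines
pheno, truth = generate_population(cfg)
series, _ = generate_growth_series(cfg, truth)
res = run_screen(pheno, series, truth=truth, seed=1)
print(res["metrics"][["level", "n_flagged", "accuracy", "fnr", "fpr_per_plant"]].round(3))
```

```
 level  n_flagged  accuracy  fnr  fpr_per_plant
 0.750         88      1.00 0.00          0.784
 0.800         83      1.00 0.00          0.735
 0.850         78      1.00 0.00          0.686
 0.900         67      1.00 0.00          0.578
 0.950         45      1.00 0.00          0.363
 0.990         12      1.00 0.00          0.039
 0.999          7      0.75 0.25          0.010
```

At low confidence levels the screen flags most of the plate (perfect
sensitivity, high false-positive rate); raising the level shrinks the
flagged set until mutants start to be missed — the practical operating
point sits near 99%, where all 8 planted mutants are caught with ~4 false
calls per 102 plants. The same pipeline is available from the shell:

```bash
phenoscreen simulate --seed 1 --out run/
phenoscreen screen --phenotypes run/phenotypes.csv --growth run/growth.csv \
    --truth run/truth.csv --out run/screen/
phenoscreen table1 --out run/table1/   # the visual-screening worked example
```

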