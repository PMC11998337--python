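# Methods

## Scope and model overview

`phenoscreen` implements a mutant-screening workflow for plate-based plant
phenotyping output. Its inputs are (a) a static per-plant trait table
(plant id, plate/well, line id, ~45 numeric traits in mixed units) and
(b) a per-plant leaf-area time series sampled every other day. Its outputs
are per-confidence-level candidate sets and, when ground truth is
available, screening metrics. Because the imaging platform that motivated
the workflow is proprietary and no real dataset is distributable, the
package includes a synthetic-data generator that defines the study
conditions under which the workflow is validated.

## Factor model

Traits mix units (mm², mm, unitless indices), so PCA is run on the
correlation scale: each trait is z-scored (sample SD, n−1 denominator) and
the sample correlation matrix is eigendecomposed. Zero-variance columns are
dropped with a warning — they carry no information on the correlation
scale and would make it singular. Components with eigenvalue > 1 (the
Kaiser–Guttman rule; `retention_threshold` is configurable) are retained,
and scores are rescaled to unit sample variance per component so all
retained axes enter the ellipse screen equally weighted. Signs follow the
convention that each component's largest-magnitude loading is positive.

No rotation is applied by default — the factor scores are unrotated
principal-component scores; an orthogonal varimax option exists for users
who want interpretable loadings, and it leaves communalities (and hence
any rotation-invariant screen) unchanged.

The factor model is fitted on the **full population, mutants included**.
This matches practice — labels do not exist at screening time — but means
strong mutant effects can themselves form a retained component: with 8
mutants carrying 4-SD shifts among 102 plants, an extra above-1 eigenvalue
appears in some replicates. The latent-structure recovery checks therefore
run on a mutant-free baseline; on contaminated populations the retained
count may exceed the latent count by one, which is harmless for screening
(an extra axis only adds panels).

Hierarchical clustering uses Ward linkage on Euclidean distances
(`scipy.cluster.hierarchy`); the test suite cross-checks the linkage
heights against an independent Lance–Williams recurrence implemented
brute-force.

## Confidence-ellipse screen

For each unordered pair of screening variables the classical ellipse is
fitted: center = sample mean, shape = sample covariance (ddof = 1), and a
point is outside at confidence level α iff its squared Mahalanobis
distance exceeds the χ² quantile with 2 df at α. Under bivariate normality
the ellipse contains probability mass α; the null flag rate per panel
converges to 1 − α (verified at n = 10⁵ within Monte-Carlo error).

A plant is flagged overall if it is outside in at least `min_panels`
panels (default 1, the sensitive choice). The union over k(k−1)/2 panels
inflates the per-plant null rate well above 1 − α — with 8 factors at the
95% level roughly a quarter of a null population is flagged. This is a
feature of the workflow, not a defect: it trades false positives (cheap to
re-inspect) for few misses, and the confidence level is the operating
knob. Flagged sets are nested across levels (higher level ⊆ lower level),
which makes FNR non-decreasing and flagged-set size non-increasing in the
level; panel calls are equivariant under affine maps of the pair.

The classical estimate is used on the full, contaminated sample by
default, mirroring how the ellipses are drawn in practice. A robust
minimum-covariance-determinant option (`robust=True`,
`sklearn.covariance.MinCovDet`) is provided for heavily contaminated data.
With a single retained factor the screen falls back to a two-sided normal
quantile interval on that axis.

Two level presets ship: the default sweep {75, 80, 85, 90, 95, 99, 99.9}%
and an alternate narrower preset {95, 97, 99, 99.5, 99.9}%; both appear in
the originating protocol descriptions and the discrepancy between them is
preserved as two presets rather than resolved.

## Logistic growth model

Each plant's projected rosette area follows
A(t) = h / (1 + x₁·e^(−x₂·t)): h is the asymptotic (maximum) leaf area
(mm²), x₂ the intrinsic growth rate (day⁻¹), x₁ a unitless shape/offset
(initial area h/(1+x₁); half-maximum at t = ln(x₁)/x₂). Fitting is bounded
nonlinear least squares (`scipy.optimize.least_squares`, trf) with bounds
h ∈ (0, 10·max area], x₁ ∈ (1e−6, 1e6], x₂ ∈ (1e−4, 5], one heuristic
start (h₀ = 1.05·max area; x₂₀ from the log-slope of the sub-half-maximum
phase; x₁₀ from the first observation) plus 4 log-normally jittered
restarts from a fixed RNG stream, keeping the lowest RSS. Ill-conditioned
series return `converged=False` with diagnostics; strictly constant series
are flagged `degenerate`. Series with fewer than 4 points or all-zero area
are ineligible (skipped with a warning at pipeline level).

The correction offsets k and s are model-minus-observed residuals at two
anchor times: p₁ = median observed day and p₂ = last observed day. The
two-asymptote form of the original model description is interpreted as one
logistic fit per plant with residual corrections read at the two anchors —
a single plant has a single trajectory. The alternative reading (two
windowed fits giving an early asymptote h and a full-series asymptote H)
is available via `two_window=True`, which additionally reports the
early-window asymptote `h_window`; on well-sampled logistic data the two
interpretations agree on (h, x₂) and differ only in the poorly constrained
early-window asymptote, so the single-fit form is the default screening
statistic.

Growth screening standardizes the converged (h, k, s, x₁, x₂) columns and
reuses the pairwise-ellipse procedure. Parameters with zero spread (e.g.
k = s = 0 exactly on noiseless data) are dropped with a warning, mirroring
the standardization policy; if fewer than two parameters vary, the cloud
is degenerate and an error names the constant columns. Unconverged or
ineligible plants are reported separately as fit-failure candidates, never
silently merged into the flagged set.

## Combination and metrics

The final machine call is the union (default) or intersection of the
scatter and growth call sets, with provenance retained. Union is the
default because the workflow is built for sensitivity and the combination
step is described only as "combining" the two analyses.

Metrics, from set-theoretic counts against ground truth:

- accuracy P = correctly predicted mutants / actual mutants,
- FNR = undetected mutants / actual mutants (so P + FNR = 1 always),
- FPR in two normalizations: prediction errors / predicted mutants
  ("per predicted") and prediction errors / total plants ("per plant").

Both FPR variants are computed because published benchmark tables state
the per-predicted formula while their printed values follow the per-plant
one. The packaged three-trial visual-screening fixture reproduces the
printed accuracy (0.875, 0.429, 0.625; mean 0.643) and FNR (0.125, 0.571,
0.375; mean 0.357) columns exactly at 3 decimals, and the per-plant FPR
for the first two trials (0.069, 0.046); the third trial's printed FPR
(0.058) follows from neither normalization applied to its own counts
(8/102 = 0.078; 8/13 = 0.615), and `compare_methods` detects and reports
that inconsistency rather than matching it. Trial means are means of
per-trial ratios. Ratios are computed at full precision and displayed at
3 decimals. A trial with zero actual mutants reports accuracy and FNR as
not-applicable (NaN); an empty call set scores P = 0, FNR = 1 and both
FPRs 0.

## Synthetic data: what it emulates, and what it does not

The generator defines the validation conditions:

- **Scale** (defaults): 102 plants on six-well plates, 8 mutant plants
  from 5 lines (a line may occupy several wells — plants of one line share
  the identical effect via a per-line sub-seed), 45 traits, imaging days
  0, 2, …, 28. The 28-day horizon stands in for a flowering-stage stop, and
  one plant per well is modeled (well-level seedling redundancy/thinning is
  out of scope).
- **WT trait baseline**: 8 latent morphological factors, each trait
  loading 0.95 on exactly one factor (communality 0.9) plus independent
  unique noise, then mapped to plausible per-trait units (areas ~900 mm²,
  lengths ~25 mm, indices ~0.6). The construction makes eigenvalue>1
  retention recover 8 components carrying >90% of the variance on clean
  data.
- **Mutant effects**: per line, 3 traits (configurable) shifted by 4 SD
  (configurable) with random sign, applied on the SD scale before unit
  scaling; growth parameters (h, x₂) multiplied by `growth_effect`
  (default 2 — a doubled asymptote and faster rate).
- **Growth**: WT parameters drawn log-normally (h: mean 1200 mm², CV 10%;
  x₁: mean 80, CV 15%; x₂: mean 0.35 day⁻¹, CV 8% — initial area ~15 mm²,
  half-maximum near day 12.5); measurement noise is multiplicative
  Gaussian with CV 2%, truncated at zero. True parameters are returned
  alongside the series for recovery studies.

Everything is reproducible from a single integer seed; identical configs
yield byte-identical CSVs.

What the generator does **not** emulate: real trait catalogs and their
names (the platform's ~50 parameters are not publicly enumerated, so
traits are generic `trait_1..trait_45`), non-Gaussian trait distributions,
spatial plate effects, measurement dropout, genetic segregation within
lines, and irradiation dose–response. Passing tests therefore demonstrate
that the workflow's statistics behave as designed under its own model
assumptions — calibration, monotonicity, parameter recovery, detection of
planted effects — not that real populations satisfy those assumptions.
Real-data performance figures from the motivating experiments are not
reproducible without the original plants and are used only as qualitative
property targets (e.g. FPR falling and FNR rising with the confidence
level).

The image module is likewise an invented emulation of a top-view imaging
front end (rendered rosettes as lobed disks, excess-green segmentation
with a 50 px minimum-object filter, region-to-nearest-well assignment,
`skimage.regionprops` morphometry at a fixed mm/px scale). It exists to
test the image→table path; the screening pipeline accepts CSV trait tables
from any source.

## Numerical choices and problem sizes

- χ²(2 df) thresholds from `scipy.stats.chi2.ppf`; 5.991 at 95%.
- Ellipse covariance singularity detected via a determinant at or below
  the smallest positive normal float; the error names the failing pair.
- PCA via symmetric eigendecomposition (`numpy.linalg.eigh`), eigenvalues
  clipped at 0; eigenvalue sum equals the retained trait count to 1e−8.
- Validation problem sizes: ellipse calibration at 10⁵ draws; parameter
  recovery at 100 plants per noise condition; detection power at 20
  replicate trials of 102 plants; these sizes give stable Monte-Carlo
  estimates while keeping a full validation run under a minute.

## Known limitations

- Classical ellipses on contaminated samples can mask clustered outliers
  (several plants of one line pulling the covariance); the `robust` option
  mitigates this but is off by default to match the reference workflow.
- The union-over-panels rule's false-positive rate grows with the retained
  component count; comparisons across populations with different k should
  fix k or use `min_panels`.
- Growth screening assumes most plants fit the logistic family; systematic
  model misfit inflates k/s spread and dulls the ellipse screen.
- Accuracy/FNR are undefined (reported NaN) for mutant-free populations.
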