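# Methods

This note documents the statistical procedures implemented in `malnut`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot demonstrate.

## Outcomes and classification

The outcomes are WHO growth-reference Z-scores: height-for-age (HAZ,
stunting), weight-for-age (WAZ, underweight) and weight-for-height (WHZ,
wasting), taken as input columns — the package does not compute Z-scores
from raw height/weight. A child fails a criterion when the score is
**strictly** below −2.0 SD; a score of exactly −2.0 does not fail, and the
boundary is covered by a dedicated test. The composite index of
anthropometric failure (CIAF) is used in its binary form — at least one of
the three criteria failed; the finer CIAF taxonomy (which combination
failed) is out of scope.

Excess prevalence subtracts the 2.3 percentage points of anthropometric
failure expected in a well-nourished reference population from natural
variation, floored at zero. All prevalences are carried at full precision;
report-level rounding is decimal round-half-up (so 58.75% prints as 59%,
which plain banker's rounding would not give). Complete case means all
three Z-scores present; records are either fully observed or have all three
scores missing, and the missingness report is
100·(total − complete)/total at one decimal.

## The geographic link

Attribute maps are handled on regular latitude/longitude grids (WGS84) at a
default 30-arcsecond resolution (~1 km). The registration convention is
fixed explicitly because no standard forces one: the origin is the
upper-left *corner*, latitude decreases with row index, and cell (i, j) has
center (origin_lat − (i+0.5)·res, origin_lon + (j+0.5)·res).

The link proceeds in three steps: (1) every map is nearest-neighbor
resampled onto one reference grid (each output cell takes the value of the
input cell containing its center; centers outside the input become nodata);
(2) each grid is exported to three flat vectors — cell-center latitude,
longitude, value — one entry per valid cell in row-major order; (3) each
survey point links to the vector entry minimizing great-circle distance.
Linking points rather than crossing rasters means several points may share
one cell, so no observation is lost to cell collisions.

Distance is haversine on a sphere of radius 6371.0088 km (IUGG mean
radius). At 1-km grids a planar approximation would rarely differ, but the
spherical metric is correct near the antimeridian at negligible cost. Ties
break deterministically on the smallest row-major cell ordinal. The search
is an exhaustive scan computed in memory-bounded chunks; any accelerated
index must be behaviorally identical, and the test suite holds the scan to
an independently coded oracle (chord-length argmin on the unit sphere,
which orders identically to arc length).

Harmonization drops rows with any missing analysis value and reports the
count; it is idempotent, and a failure (nothing survives) carries a
per-column missingness diagnostic. GeoTIFF I/O is implemented on
`tifffile` with the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL nodata); rasters that are not geographic WGS84 are
rejected with a message rather than silently reprojected — reprojection is
out of scope.

## Bivariate screening

Tests are matched to variable type. For continuous candidates the
historical practice was a visual scatterplot check before choosing Pearson
or Spearman; reproducibility demands a deterministic surrogate, so the rule
here is: Pearson iff both samples pass D'Agostino's K² normality test at
α = 0.05, Spearman otherwise, with a per-variable override. The K²
statistic depends only on standardized moments, so the decision is
invariant under affine rescaling. Confidence intervals use the Fisher-z
transform (for Spearman, as the standard large-sample approximation). A
correlation is *reportable* when |r| ≥ 0.10 and p < 0.05 — both conditions,
neither alone.

Dichotomous candidates use the independent-samples t test preceded by the
folded F test: F = (larger sample variance)/(smaller), numerator df from
the larger-variance group, two-sided p = 2·P(F > F_obs) capped at 1. When
that p < 0.05 the Welch–Satterthwaite branch is reported, otherwise the
pooled branch. Simulations in the test suite hold the combined procedure's
type-I error at ≤ 6% under a nominal 5%.

Categorical candidates use the one-way fixed-effects F test computed from
sums of squares directly (valid on unbalanced data), reporting
R² = SS_between/SS_total and the lowest-mean level. Effect modification is
screened by adding an interaction block to the two-factor model and testing
it with a partial F; interaction cells unobserved in the data are dropped
from the block and flagged. Continuous variables get categorical versions
first (built-in cut-point schemes for household size, altitude, population
density, slope, agricultural land; quartiles otherwise; bins are
left-open/right-closed so a cut-point belongs to the lower class); the
continuous original enters later stages only when the categorical version
shows no association. **No multiple-testing correction is applied at the
screening stage** — the screen is deliberately permissive and the report
header says so; pruning is the job of model selection.

## Model selection

Models are ordinary least squares of one Z-score on screened candidates.
The numerical core is a Cholesky solve of the normal equations with
classical t-based p-values; it is held to 1e-8 agreement with an explicit
(XᵀX)⁻¹Xᵀy oracle and cross-checked against an independent OLS
implementation in the tests. Rank deficiency is detected (Cholesky failure
or condition number > 1e12) and reported with the names of the collinear
effects found by pivoted QR.

Backwards elimination removes the single worst effect with p ≥ 0.05 per
iteration until all survivors are significant. Categorical variables are
reference-coded and individual dummy levels leave the model independently
of their parent variable ("split" semantics) — the level-wise reading of
the procedure; a variable-wise partial-F alternative would also be
defensible but is not what the split phrasing describes. Ties in p break on
the lexicographically smallest effect name so runs are reproducible. A hard
sample-size floor of 10 observations per candidate effect (configurable
upward to 15) rejects overfitted specifications before any fit. If every
effect is eliminated, the intercept-only model is returned with a warning.

Stability selection repeats the backward procedure on 100 subsets, each a
uniformly drawn 75% of the rows **without replacement**, independent across
subsets; membership is logged for audit. An effect's selection frequency is
its share of successful subset fits; retention requires frequency ≥ 0.20
(20 of 100 survives, 19 does not). The averaged model takes the mean of
each retained effect's estimates over the subsets where it was selected.
Averaged p-values are deliberately not produced — averaging p-values across
different models has no defensible interpretation — so the stability output
is frequencies plus averaged estimates only. Failed subset fits are
recorded and excluded; more than 10% failures aborts the run. A comparison
report flags any effect whose full-data estimate differs from its averaged
estimate by more than twice the resampling SD, with verdict "robust" when
nothing is flagged.

## Impact evaluation

Exposure is district-level intent-to-treat: every child in an intervention
district counts as exposed, since individual program participation is
unobserved. For each exposure group, Δ = mean(endline) − mean(baseline) and
the relative change is 100·Δ/|baseline mean| — the absolute value in the
denominator is stated as a formula here because reverse-engineering the
convention from worked figures (0.37/1.32 → 28%, 0.30/0.66 → 45%) is the
only way to pin it down; a zero baseline mean makes the relative change
undefined and is flagged while the absolute change is still reported.
Impact is Δ(JP) − Δ(non-JP), positive meaning the intervention group
improved more.

Because exposure was not randomized and baselines differ (the synthetic
generator builds this imbalance in), the same contrast is repeated within
strata of the determinant covariates, using identical stratum definitions
in both groups and waves. Any stratum with fewer than 50 children in any
exposure×wave cell is flagged unreliable. Per-wave JP-vs-non-JP mean
differences with CIs (pooled or Welch per the folded-F branch) are reported
as a baseline diagnostic without gating the analysis. No inferential CI is
attached to the impact difference itself; the `se_impact` field — the
independent-samples standard error combining the four cell variances — is a
descriptive aid used by the recovery checks. Report tables print changes at
two implied decimals and impact differences with one decimal on that scale
(rounding half-up in decimal space to avoid binary-float artifacts); the
machine CSV always carries full precision.

## The synthetic generator

The generator emulates the study conditions the pipeline assumes: two waves
("2009", "2016") of 5,000 children each by default; 13 districts as
axis-aligned rectangles tiling a Timor-Leste-sized extent (rectangles make
the point-in-district test trivially invertible for oracle checks), four of
them intervention districts; outcomes from

y = intercept + Σ β·x + district effect + ε,  ε ~ N(0, σ),

with default σ of 1.95 (HAZ), 1.25 (WAZ), 1.61 (WHZ) — realistic survey-
scale dispersions — and default coefficients at the scale of published
explanatory models (sex +0.35 HAZ, measurement in the hungry season +0.28
HAZ / −0.13 WHZ, child-age effects −0.6…−1.2, maternal-BMI and wealth
effects on WAZ/WHZ). District effects are N(0, 0.3). Intervention districts
carry a baseline offset (+0.78 HAZ, −0.66 WHZ by default — the unequal
starting conditions that motivate the difference-of-changes design) and an
additive endline program effect (+0.37 WHZ, −0.20 HAZ, +0.12 WAZ) that
serves as recovery ground truth only, not as a claim about any real
program. Three pure-noise Bernoulli covariates are included by default so
selection procedures can demonstrate specificity.

Missingness masks the three Z-scores jointly, completely at random, at
24.8% (baseline) and 29.6% (endline) by default. Covariate marginals are
not dictated by any source: binaries are Bernoulli(0.5), categoricals
uniform, continuous Normal — the simplest structure exercising every
screening branch, all configurable. One seed feeds three documented
sub-streams (landscape / records / missingness), so identical seeds give
byte-identical fixtures and each part regenerates independently.

What the generator does **not** emulate: survey design weights and cluster
displacement, realistic spatial autocorrelation, inter-covariate
correlation, and informative missingness. Passing recovery tests therefore
shows the procedures are correct and well-calibrated under the stated
generating model — not that they are robust to design effects or missing-
not-at-random data.

## Problem sizes and numerical choices

Unit tests run on bundles of a few hundred children per wave and coarse
(300–600 arcsecond) rasters; the recovery checks use the full default
conditions (5,000 per wave, 20 pipeline seeds × 100 resamples), which the
package computes in seconds thanks to the lean least-squares core. The
nearest-neighbor oracle check uses 1,000 points against 10,000 cells.
Degenerate inputs are rejected with named errors rather than coerced:
zero-variance correlation samples, single-level ANOVA, empty attribute
vectors, degenerate raster extents, non-increasing cut-points, missing
Z-scores at classification. Known report-level subtleties — e.g. an excess
prevalence that floors at zero, or formatting of negative implied-decimal
changes — are handled in decimal arithmetic and covered by boundary tests.

## Limitations

The pipeline reproduces an analysis design, not a causal-inference
framework: no propensity adjustment, no clustered standard errors, no
multiple-testing control at the screen, and no inferential interval on the
impact difference. The stability-selection retention threshold (20%) and
resampling scheme (100 × 75% without replacement) are the procedure's
defining constants, not tuned quantities. District-level exposure means
within-district spillover or partial coverage is invisible. These are
faithful properties of the implemented design; extending beyond it (e.g.
bootstrap CIs for impact) is possible but clearly labeled as an extension.
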