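# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the synthetic landscapes do and do not emulate,
and the design decisions taken where more than one defensible option
existed.

## Coordinates and grids

All coordinates are decimal degrees, longitude in [−180, 180]. Grids are
regular lon/lat rasters indexed row-major with 0-based (row, col) from the
north-west corner; a point exactly on a cell edge belongs to the cell to
its south-east. Gridded layers are exchanged as ESRI ASCII grids (NODATA
cells become NaN in memory); tables are UTF-8 CSV with a header row. The
reference resolution is 0.5° per cell.

Productivity is production (tons) divided by harvested area (hectares),
averaged per municipality over the years with positive area. A year with
zero harvested area is excluded from the mean rather than counted as zero:
0/0 is undefined and such a year did not produce. Histogram bins are
half-open (lo, hi] multiples of the bin width, so a value of exactly 2.50
falls in the 2.01–2.50 bin, matching census-style bin labels and ensuring
no value can fall in two bins. Standardization (Z-transform) uses the
sample standard deviation (n − 1 denominator), is order-preserving, and
refuses constant vectors.

## Niche models

Five classical models sit behind one contract — `fit(X[, y])`,
`score_samples(X)` returning one suitability score per row, higher = more
suitable. Scores are comparable only within a model: the ensemble
protocol thresholds each model on its own ROC curve, which makes every
downstream binary product invariant to strictly monotone transforms of a
model's scores. Any estimator honouring the contract can be registered by
name (`register_model`) and used by the protocol unchanged; the heavier
machine-learning families are deliberately not built in, since the
ensemble protocol rather than the model zoo is the analytical core.

* **Climate envelope (BIOCLIM).** Per variable, the two-tailed percentile
  score `t_j = min(1, 2·min(#{p ≤ x}, #{p ≥ x})/n)` over the n presence
  values: 1 at the presence median, 0 strictly outside the presence
  min–max; the model score is `min_j t_j`. The inclusive-count form needs
  no special case for a degenerate (constant) variable — equality scores
  1, anything else 0 — and yields a continuous score for ROC thresholding.
  An optional `trim` percentile tightens the envelope.
* **Distance models.** Score = 1/(1 + d), monotone and bounded.
  *Euclidean*: distance to the presence centroid in per-variable
  standardized space. *Mahalanobis*: distance to the centroid under the
  presence covariance (ridge-regularized if singular; equals Euclidean
  under identity covariance). *Gower*: range-scaled mean absolute
  difference to the **nearest** presence (Domain-style), so the three
  models probe different niche geometries (central tendency with and
  without correlation structure, and local envelope).
* **Logistic GLM.** Presence vs pseudo-absence by hand-rolled IRLS on
  internally standardized predictors, quadratic terms on by default so the
  response can be unimodal. Stops at gradient max-norm 1e-8 or 100
  iterations (flagged); diverging coefficients (complete separation)
  trigger one refit with a small ridge (1e-6), flagged. The fitted
  probabilities average to the observed prevalence (score equation), which
  the tests check against the statsmodels maximum-likelihood fit.

## Ensemble protocol

Defaults are the reference study conditions: 50 replicates, 75/25
calibration/evaluation split (stratified by label, counts rounded),
prevalence 0.5 (one pseudo-absence per presence, sampled without
replacement from the background = all complete-data cells minus presence
cells). Pseudo-absences are resampled inside every replicate, so
background uncertainty propagates into the frequency maps. Per replicate
and method, the binarization threshold is the midpoint between consecutive
distinct evaluation scores that maximizes sensitivity + specificity
(smallest such threshold on ties; predicted presence ⇔ score ≥ threshold),
and the TSS at that threshold on the evaluation split is the replicate's
skill. Binary maps stack into per-(method × scenario) frequency maps
(entries are multiples of 1/n_replicates); the consensus is their weighted
mean with weights max(mean TSS, 0) — negative-skill maps are excluded
rather than allowed to subtract, keeping the consensus in [0, 1]. Future
scenarios reuse the fitted replicates and thresholds re-projected onto the
future layers; no re-fitting. Change maps report future − current per cell
with the fractions of cells losing/unchanged/gaining.

The evaluation split here does double duty (threshold selection and skill
scoring), which makes the reported TSS mildly optimistic; an inner split
would remove the bias at the cost of smaller calibration sets. With one
shared current-climate stack, current-scenario frequency maps are
per-method; the per-(method × climate model) accounting of the full design
(50 × 12 × 4 = 2,400 instances, 48 maps) is exposed by `run_plan`, which
enumerates the plan without fitting.

## Extrapolation detection

The reference sample is the model training domain: environmental values at
the presence cells plus one seeded pseudo-absence draw.
`NT1 = Σ_j min(x_j − min_j, max_j − x_j, 0)/(max_j − min_j)` is 0 inside
every univariate range and negative outside (translation- and
positive-scale-invariant per variable). Where NT1 = 0,
`NT2 = D²/D²_max` with D² the Mahalanobis distance to the reference mean
under the reference covariance and D²_max its maximum within the reference
sample; NT2 > 1 flags a type-2-novel combination. A zero-variance
reference variable (e.g. soil pH held constant across periods) acts as a
hard range: equality contributes 0, any departure contributes −1 (one full
range) — finite by choice, so NT1 stays additive. Constant variables are
excluded from the covariance, and a singular covariance receives a ridge
of 1e-8·trace/p. The class partition (type-1 / type-2 / analog) is
exhaustive and mutually exclusive over valid cells; missing cells
propagate as missing.

## GWR, diagnostics and partitioning

At each focal location i, weighted least squares
`β̂(u_i) = (XᵀW_iX)⁻¹XᵀW_i y` with bisquare weights
`w = (1 − (d/b)²)²` for d < b (default bandwidth b = 5°, fixed). Distances
are planar in decimal degrees by default — so "bandwidth of 5°" is literal
— with great-circle kilometres behind a switch. A locally singular normal
matrix receives a 1e-8 ridge and the location is flagged; locations with
fewer in-kernel neighbours than parameters raise "bandwidth too small".

Fit statistics: effective parameters v1 = tr(S) (hat-matrix trace; the
simplest convention consistent with the AICc used), global
R² = 1 − RSS/TSS, adjusted R² = 1 − (1 − R²)(n − 1)/(n − v1), and
`AICc = 2n·ln(σ̂) + n·ln(2π) + n(n + v1)/(n − 2 − v1)` with σ̂² = RSS/n
(OLS uses v1 = p). Local R² at u_i uses the focal model's predictions and
the weighted mean of y under W_i; it is exactly the global R² in the
infinite-bandwidth limit, where every GWR output converges to OLS
(tested at bandwidth 10⁶° to 1e-6).

**F test.** The improvement of GWR over OLS is tested ANOVA-style with the
linear-smoother residual degrees of freedom
δ = n − 2tr(S) + tr(SᵀS): `F = [(RSS_OLS − RSS_GWR)/(n − p − δ)] /
[RSS_GWR/δ]` on (n − p − δ, δ) df. The simpler variant that uses n − tr(S)
as residual df is measurably anticonservative (rejection rate ≈ 0.2 at
nominal 0.05 under a stationary truth, because E[RSS] = σ²δ for a linear
smoother), so the δ form is used; measured type-I error is 0.01–0.04
across seeds, slightly conservative, within the 3σ binomial band of 0.05
at 200 replicates. When δ ≥ n − p to within 1e-6 (fits indistinguishable),
F = 0 and p = 1 by convention.

**Forward selection** of technology covariates is greedy on global-OLS
AICc from an intercept-only start, entering the largest AICc decrease and
stopping when none remains (ties to the earlier candidate). The criterion
and model frame are exposed rather than hard-coded into the GWR. Note the
AICc cost of one extra parameter is ≈ 2, so among k pure-noise candidates
the best of k chi-square(1) gains exceeds it fairly often (≈ 57% for
k = 5): selection under the null is *sparse* (almost never more than one
spurious term), not empty.

**Variation partitioning.** From the full, suitability-only and
technology-only fits: pure_climate = R²_all − R²_tec, pure_technology =
R²_all − R²_suit, shared = R²_all − pure_climate − pure_technology (the
residual form makes closure exact to one rounding step; algebraically it
is R²_suit + R²_tec − R²_all). The global partition uses adjusted R²
(degrees-of-freedom aware, as required when comparing fits of different
size); per-location maps use the unadjusted local R², because local
effective degrees of freedom are ill-defined — the mismatch is accepted
and documented. Components may be negative (suppression) and are reported
unclamped; `clamped()` offers a floor-at-zero rendering for maps, never
applied silently.

## Synthetic landscapes

The generator emulates the three real inputs. Climate: each variable is a
deterministic latitudinal/longitudinal gradient plus kernel-smoothed
seeded white noise (Gaussian filter, radius 2 cells — smoothing chosen
over spectral synthesis for dependency-free, adequate smoothness control);
the future stack adds per-variable trends (+2 °C mean temperature, +1 °C
range, reduced precipitation, soil pH constant). Suitability is a
product-Gaussian niche `s = exp(−½Σ((x_j − c_j)/w_j)²)` — the simplest
smooth unimodal niche with a closed form for recovery tests; widths are
set so the species occupies roughly a quarter of the default 20×20, 0.5°
domain (≈ 100 presence cells), leaving ample background for prevalence-0.5
pseudo-absence draws. Presences are independent Bernoulli draws with
probability scale·s (scale 1 by default). Technology: eleven covariates as
affine loadings on one latent "development" gradient (increasing away from
the equator) plus independent noise, so a known subset truly drives
productivity and selection has a recoverable truth. Productivity:
`y(u) = β0(u) + β_suit(u)·s(u) + Σγ_k(u)·tech_k(u) + ε` with
affine-in-coordinates coefficient surfaces (default β_suit = 1 + lat/10,
three nonzero γ surfaces) and Gaussian noise (sd 0.1). One master seed
streams into named sub-seeds (climate/occurrence/technology/noise), so the
whole landscape is bit-reproducible and stages can be re-randomized
independently.

What the generator does **not** emulate: spatial autocorrelation of
occurrence errors, sampling bias, municipality polygons (cells are the
unit), realistic climate downscaling or any specific circulation model,
and census measurement error. Passing tests therefore demonstrate the
correctness and statistical behaviour of the machinery under a known
data-generating process, not the field validity of any particular
real-data conclusion.

## Problem sizes and reproducibility

Tests and the acceptance script run at deliberately compact sizes chosen
to exercise every property well inside interactive budgets: 20×20
landscapes (n = 400) for ensemble and GWR recovery checks, 2–10 ensemble
replicates where the protocol's arithmetic (not its variance) is under
test, n = 400 for coefficient-surface recovery, 200 replicates at n = 100
for the F-test calibration study, and the full 50 × 12 × 4 design touched
through the run-plan accounting only. The synthetic census-layout table
(2,304 municipalities, 2,493 occurrence rows, 17 years) is generated
programmatically, never stored. The pipeline writes a manifest with
content hashes of every stage output; identical configuration and seed
reproduce all hashes bit-for-bit.

## Known limitations

* Out-of-sample GWR prediction (coefficients at unfitted locations) is not
  implemented; the estimator is an in-sample smoother by design.
* The evaluation-split TSS is mildly optimistic (threshold and skill share
  a split), consistently across methods, so ensemble weights are
  comparable even though absolute skill is flattered.
* Per-location partition components mix an adjusted global quantity with
  unadjusted local R²; local components should be read as maps of relative
  structure, not as unbiased local variance fractions.
* The pairwise-distance matrix is dense O(n²) memory; comfortable to a few
  thousand municipalities, not built for continental point sets at fine
  resolution.
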