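# Methods

`grasshab` implements a presence-only maximum-entropy (MaxEnt) habitat-
suitability analysis for grassland pest species, end to end: covariate
preparation, collinearity screening, candidate-model calibration and
selection, and replicated suitability mapping. Because real survey and
remote-sensing data for such studies are typically not redistributable,
the package ships a first-class synthetic-landscape generator so every
stage is testable.

## The model

Let `f_1 … f_n` be features derived from environmental covariates and
let the *background* be a sample of up to 10,000 valid grid cells
representing available environment. The model is the Gibbs distribution
over background cells

    P_w(x) = exp(Σ_i w_i f_i(x)) / Z_w,   Z_w = Σ_bg exp(Σ_i w_i f_i),

the maximum-entropy distribution subject to (regularized) constraints
that model feature expectations match presence-sample means. Weights
minimise the convex objective

    L(w) = log Z_w − mean_presence(Σ_i w_i f_i) + Σ_j RM·β_j |w_j|,

where RM is the global regularization multiplier and β_j a per-feature
penalty. At the optimum the Karush–Kuhn–Tucker conditions give the
*regularization certificate*

    |E_model f_j − mean_presence f_j| ≤ RM·β_j,  equality when w_j ≠ 0,

which the test suite verifies numerically (±1e-6) for every converged
fit.

**Features.** Continuous covariates are scaled to [0, 1] by their
background min/max (projection inputs are clamped to that range). The
feature classes are linear (L), quadratic (Q), pairwise product (P),
threshold (T: step indicators at K knots), and hinge (H: forward and
reverse piecewise-linear ramps at K knots); categorical covariates
always contribute one indicator per observed level. K defaults to 20
knots per variable at uniform background quantiles (tests use 6–10 for
speed); features constant across presence+background are dropped.

**Regularization.** β_j = β_class(m) · max(sd_presence(f_j), 0.05) / √m,
with m the presence count and β_class interpolated from per-class
schedules versus sample size (linear/quadratic/product: 1.0 → 0.05 as m
grows from 10 to 100; categorical 0.65 → 0.25; threshold 2.0 → 1.0;
hinge 0.5). These follow the published MaxEnt defaults in spirit and
are configurable; the 0.05 standard-deviation floor keeps every β_j
strictly positive.

**Optimizer.** Proximal-Newton coordinate descent with soft
thresholding: each sweep computes all KKT residuals with one matrix
product and visits only violating coordinates, largest first, with
backtracking on the true objective. Near the optimum (worst violation
< 3e-2, or every fifth sweep) an orthant-wise Newton phase solves the
dense system on the working set (support plus up to 50 worst
violators), with Levenberg-style ridge escalation when a step is
rejected. Convergence is declared when the maximum KKT residual falls
below 1e-8 (configurable); if no step can improve the objective the fit
is accepted only when the residual is still ≤ 1e-7, otherwise a
`ConvergenceError` with the objective trace is raised. Very small RM
(≲ 0.1) combined with all five feature classes is the slow regime —
many nearly-collinear threshold/hinge features become active — and can
take tens of seconds on moderate fixtures.

**Outputs.** Raw scores are normalized to sum to 1 over the training
background. The logistic suitability output is r·e^H / (1 + r·e^H)
with H the entropy of the fitted background distribution, so a cell
with raw score e^{−H} ("typical" habitat) maps to 0.5. Logistic and raw
outputs are rank-identical.

**Variable importance.** Three complementary readouts: percent
contribution (objective improvements during coordinate descent
attributed to the updated feature's variable, products split equally,
normalized to 100); permutation ("exchange") importance (drop in
training AUC after permuting one variable across presence+background
rows, drops floored at 0 and normalized to 100); and jackknife gains
(regularized training gain — log m_bg minus the *penalized* objective —
for each variable in isolation and omitted). Using the penalized
objective makes the nested-model property (full-model gain ≥ any
leave-one-out gain) hold exactly, which the suite asserts.

## Calibration and selection

Candidates are the Cartesian grid of RM values × feature-class
combinations. The full published-style grid is RM 0.1–4 in steps of 0.1
against 29 combinations (all non-empty subsets of {L,Q,P,T,H} except
the bare P and T singletons); the pipeline default is a reduced grid
(RM 0.5–4 step 0.5 × {L, LQ, LQH, LQPH}) sized for a single CPU.
Each candidate is fitted on one fixed seeded 75/25 presence split
(replication is reserved for the selected model) and scored by:

- **Partial-ROC significance** — bootstrap AUC-ratio restricted to
  omission ≤ E (default E = 5%, 500 iterations, resampling 50% of test
  points with replacement); p = fraction of bootstrap ratios ≤ 1. The
  sensitivity curve uses interpolated empirical quantiles and the
  sens = 1−E boundary crossing is interpolated; with a step ECDF the
  small-sample ratio is biased above 1 because sensitivity near 1−E is
  quantized. Even so, the bootstrap p is intrinsically unstable when
  E × (resampled test size) falls below a handful of points: with 25
  resampled points the 5% tolerance rests on ~1 point and p collapses
  to {0, ~0.5} regardless of estimator. Type-I control experiments
  therefore use test sets of ~200 points (800 presences at a 25% test
  fraction); at that size the screen is approximately calibrated
  (~2–3% of null candidates at α = 0.05). Users applying the screen to
  small occurrence sets should treat its p-values as descriptive.
- **Omission rate** — fraction of test presences scoring below the
  E-quantile of training presence scores (default E = 5%); acceptance
  cut 8%.
- **AICc** — −2·Σ ln(raw at presences) + 2k + 2k(k+1)/(n−k−1), with
  k = number of non-zero weights and raw normalized over the background
  universe; candidates with n ≤ k+1 are ineligible (AICc = ∞).

Selection filters to p < α (default 0.05), then omission ≤ 8%, then
minimum AICc; ties break by smaller k, then smaller RM. If nothing
survives, a `SelectionError` carries the least-bad candidate and the
per-stage survivor counts.

## Evaluation and mapping

The selected candidate is re-fitted on replicated seeded 75/25
subsamples (default 100 in the API; the pipeline default is 10 and the
test suite uses 1–3, sized for a single CPU). The suitability map is
the cell-wise arithmetic mean of the replicates' logistic surfaces.
Probabilities are classified with half-open upward-inclusive breaks —
[0, 0.25) unsuitable, [0.25, 0.5) low, [0.5, 0.75) moderate,
[0.75, 1] high — so boundary values are assigned upward and the classes
partition [0, 1] with no gaps. Areas are cell² km² on planar grids and
per-row cosine-latitude-corrected on geographic grids; class
percentages are reported to two decimals with largest-remainder
rounding so they always sum to exactly 100.00 (the denominator is the
total classified area).

## Preprocessing

- **FVC** (dimidiate pixel model): (NDVI − NDVI0)/(NDVIv − NDVI0)
  clipped to [0, 1]; endmembers default to the 5th/95th percentiles of
  the NDVI layer when not supplied.
- **Maximum-value compositing**: per-cell max over a raster series,
  nodata only where every input is nodata.
- **Ordinary kriging** of station values: exponential variogram by
  default with range = ⅓ of the domain diagonal, sill = sample
  variance, nugget = 0, all overridable; the Lagrange system enforces
  unit-sum weights, and with zero nugget the surface interpolates
  stations exactly. A singular system raises with a hint to add a
  nugget.
- **Alignment**: bilinear resampling for continuous layers, nearest
  neighbour for categorical (so no new levels can appear); a target
  cell is nodata if any contributing source cell is nodata. Slope and
  aspect from a DEM (3×3 Horn stencil) are provided as an optional
  utility.
- Raster convention: row 0 = north, cell-center registration. GeoTIFFs
  are written via tifffile with ModelPixelScale/ModelTiepoint/
  GDAL_NODATA tags (float32 continuous, int16 categorical).

## Screening

Pearson correlations among continuous layers over all (or a seeded
sample of) valid cells; categorical layers bypass the screen and are
always retained. Greedy pruning: while any pair has |r| strictly above
the threshold (default 0.8 — a pair at exactly 0.8 is kept), the member
of the worst pair with the larger mean absolute correlation to the
remaining variables is dropped (ties by variable name). |r| rather than
signed r is compared because strong negative correlation is equally
collinear. The post-condition (max pairwise |r| ≤ threshold) is
re-verified independently in the tests, and every drop is logged with
its justifying pair.

## Synthetic landscapes

The generator emulates what the analysis assumes about real data:

- **Continuous layers** are seeded white noise convolved with a
  Gaussian kernel (length-scale default 6 cells) and rank-mapped to
  realistic marginal ranges (surface temperature −10–40 °C, vegetation
  cover 0–1, precipitation 0–120 mm, air temperature −15–25 °C,
  elevation 900–1600 m).
- **Correlated pairs** mix independent Gaussian fields with Cholesky
  weights; because rank-mapping makes marginals uniform, the Gaussian
  mixing correlation is pre-adjusted (ρ_g = 2·sin(πr/6)) so the
  post-mapping Pearson r hits the target (tolerance ±0.05; the default
  pairs air temperature with surface temperature at r = 0.85). A
  non-positive-definite target structure fails with the offending pair
  named.
- **Categorical layers** (vegetation type, 5 levels; soil type, 6
  levels) are quantile-binned smooth latent fields, giving contiguous
  regions.
- **Occurrences**: cell density = suitability × 60 per m² × mean-one
  log-normal noise (σ = 0.3); cells above 15 per m² (the survey
  convention for marking a quadrat as a distribution point) form the
  presence pool, from which the requested count (default 200) is drawn
  without replacement; coordinates are cell centers.
- A border fraction (default 5%) is masked nodata on every edge; grids
  default to 80×80 local-planar 1-km cells (tests use 40–60).

Two ground truths ship with the package. The default truth makes
vegetation cover (hinge) and soil type (level effects) the drivers with
broadly distributed suitable habitat. `strong_signal_truth` sharpens
the contrast (steeper hinge at a higher knot, larger balanced soil
effects, lower intercept) so suitable habitat is rare; it is the
fixture for parameter-recovery experiments, where mean held-out AUC
reaches ~0.85–0.89 and the two drivers rank top-2 in permutation
importance in ≥ 9/10 seeds.

What the generator does *not* emulate: anisotropy, non-stationary
spatial covariance, sensor/retrieval artefacts, spatially clustered
survey effort, or detection error. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated assumptions,
not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- Duplicate presences in a cell are collapsed to one; points outside
  the grid or on nodata are rejected, both with counts reported.
- A covariate constant over the background loses its features with a
  warning; a feature constant over presence+background is silently
  dropped.
- Degenerate (all-equal) score sets give partial-ROC p = 1 with a
  warning; a zero-variance variable gets NaN correlation entries and is
  exempt from pruning.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration and seeds
  reproduce byte-identical fixtures and pipeline tables.

## Known limitations

- The optimizer's slow regime (RM ≲ 0.1 with all five feature classes)
  makes the full 1,160-candidate grid expensive; the pipeline default
  grid is the practical envelope on one CPU.
- The β schedules are "compatible with" the published MaxEnt defaults,
  not bit-identical to them; fitted weights will differ in detail from
  MaxEnt 3.4.1 on the same data.
- AICc normalizes the presence likelihood over the background sample
  rather than every grid cell; with ≤ 10,000 background points the
  difference is a constant offset per candidate of the same background,
  so rankings are unaffected.
- Percent contribution is path-dependent (it attributes objective
  improvements in visit order), as in MaxEnt itself; permutation
  importance is the more robust readout.
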