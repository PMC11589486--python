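# Methods

## The hysteresis decomposition

A seasonal trajectory is the time-ordered sequence of (CI, oil) pairs for
one cultivar and one candidate predictor, with replicates kept as
independent rows and undefined CI cells removed pairwise. The decomposition
finds the turning point (first occurrence of the CI maximum; the first-of-
ties rule keeps the descending arm maximal and deterministic), reflects the
descending arm about CI_max (an involution, so distances to the maximum are
preserved), fits one curve through all points — ascending arm at its
original abscissae, descending arm at the reflected ones — and integrates
that single curve over two ranges: the full abscissa span (`Tot_area`) and
the reflected-arm span `[CI_max, max CI_syn]` (`hyst_area`). Then

    Hyst = (hyst_area − (Tot_area − hyst_area)) / Tot_area.

Because the fitted curve is clamped at zero before integration and the
hysteresis range is a sub-interval of the total range, 0 ≤ hyst_area ≤
Tot_area always, so Hyst ∈ [−1, 1] by construction. An empty descending arm
gives hyst_area = 0 and Hyst = −1 *exactly* (in IEEE arithmetic,
(0 − t)/t = −1). A trajectory that declines from its first sample is all
descending arm and scores +1 exactly.

The integration baseline y = 0 is a deliberate choice: oil concentration is
strictly positive, the source material names no baseline, and zero is the
only choice that guarantees the printed [−1, 1] range.

## Curve fitting and numerical choices

The fitted curve is a cubic smoothing spline with its smoothing parameter
chosen by generalized cross-validation (scipy's `make_smoothing_spline`);
a fixed smoothing value can be passed instead, and `spline=False` replaces
the curve with the piecewise-linear interpolant of the sorted points — an
assumption-free route kept as an independent cross-check (the two agree to
within 5% on smooth, low-noise trajectories).

Details that matter for correctness:

- duplicate abscissae are collapsed by averaging their ordinates before
  fitting (splines need strictly increasing knots);
- the abscissa is affinely mapped to [0, 1] inside the fit. This makes Hyst
  exactly invariant to positive affine rescaling of the CI axis (indexes
  spanning hundreds of pixel units and ratios spanning hundredths behave
  identically) and conditions the GCV problem, which otherwise becomes
  ill-posed when reflected-arm knots nearly coincide;
- GCV needs ≥5 distinct abscissae; with exactly 4 a natural interpolating
  cubic spline is used, below that the linear interpolant. A numerically
  ill-posed GCV falls back to a small fixed smoothing, then to the
  interpolant;
- integration is a composite trapezoid on a 1024-point grid of the
  zero-clamped curve; hyst_area is additionally capped at Tot_area to
  absorb grid-level round-off.

Spearman's ρ uses mean ranks at ties (scipy); constant inputs yield an
undefined marker rather than an exception. The Fitness Index FI = |Hyst| +
|ρ| selects candidates whose FI reaches the empirical 80th percentile of
the finite FIs (linear-interpolation quantile, the numpy default, documented
because quintile boundaries differ by convention); threshold ties are all
included, and undefined FIs participate in neither threshold nor selection.
The candidate pool is the 35 CIs plus the three raw bands (38) by default,
since color bands compete as predictors in their own right;
`include_bands=False` restricts to the 35.

## The index registry

Exactly 35 colorimetric indexes. The attested members (NGRDI, VARI, GLI,
NDGBI, NG, GR, GB, BplusG) carry their standard formulas; the bespoke
`mio_stRGB` and `mio_ndRGB` ship documented placeholder formulas (R+G+B and
(R−B)/(R+B)) because their original definitions are not public — both, and
the whole roster, can be replaced verbatim from a YAML file of
`name: expression` entries. The remaining slots are standard RGB indexes
from the vegetation/fruit-color literature (chromatic coordinates, excess-
color indexes, CIVE, MGRVI, RGBVI, band sums/differences/ratios). Zero
denominators produce NaN — an explicit "undefined" marker that excludes the
affected (sample, CI) pair downstream, never the whole sample row.

## Models and benchmarking

Ordinary least squares with intercept throughout. Per-term p-values come
from two-sided t-tests; AIC uses the Gaussian profile form
n·ln(RSS/n) + 2k with k = predictors + 2 (slopes, intercept, error
variance) — comparable within this package only. The variance inflation
factor is computed from the auxiliary regression of each predictor on the
others (with intercept); VIF > 5 triggers iterative removal of the single
worst predictor (ties break by column order). Single-predictor models have
no VIF by construction.

The benchmark contract: within a cultivar, every model is trained and
tested on byte-identical random 70/30 partitions, five iterations. The
training size is round(0.7·n) with exact round-half-even arithmetic via
rational numbers — binary floating point would turn 0.7·45 = 31.5 into
31.4999… and round the wrong way.

Test-set R² is the squared Pearson correlation of predicted vs true (the
scatter-plot convention); the 1 − RSS/TSS variant is reported alongside as
`r2_rss`. RMSE and MAE are in %FW.

## GPI ranking

Per cultivar, each metric is min–max normalized over the pooled set of all
models × iterations, and

    GPI_m = Σ_{i ∈ {R², RMSE, MAE}} Σ_{j=1..5} α_i (Ō_i − O_ij),

with α = −1 for R² and +1 for the error metrics and Ō_i the *pooled* median
of metric i. The pooled median is a deliberate reading: taking each model's
own five-iteration median instead makes every model's deviations cancel
around its own center, driving all GPIs to ≈0 and destroying the ranking
(the degenerate variant is available as `median_scope="model"` for
sensitivity analysis, and a unit test demonstrates its degeneracy). Ranks
descend by GPI with ties sharing the minimum rank.

The model built from the highest-FI predictor is flagged. Indexes that are
monotone transforms of one another (G/R, (G−R)/(G+R), MGRVI, R/G, …) have
identical Spearman ρ by rank invariance and identical Hyst (±1 exactly)
when monotone in time, so the FI maximum is frequently an exact tie; every
exactly-tied maximum is flagged, because FI carries no information that
could separate the tied candidates.

## The synthetic-data generator

The generator emulates a seasonal olive sampling campaign:

- **oil(t)** = oil_min + (oil_max − oil_min)·logistic(rate·(t − midpoint)),
  clipped above 0.1 %FW. Defaults put the curve already rising at the first
  sampling date and asymptotic only near the season's end, matching the
  reported near-linear accumulation from ~5 %FW to cultivar-specific
  asymptotes (15.5 %FW for four cultivars, ~20 for Maiatica, ~24 for
  Frantoio). Time is an integer date index 0..n_dates−1 at a nominal 8-day
  spacing; calendar dates are cosmetic.
- **bands**: base + rise_amp·logistic − fall_amp·logistic, clipped to
  [0, 255]. The rise phase is synchronized with the oil logistic (the
  visible color change and oil accumulation are two faces of the same
  ripening process) with per-band rate multipliers (red fastest, blue most
  sluggish); the fall phase is centred on `band_fall_onset`, the parameter
  that controls how much of the hysteresis loop the observed season
  expresses. Red rises proportionally more than green early while green
  loses proportionally more late (the green-to-purple shift), so ratio
  indexes decline near-monotonically as oil accumulates even though every
  raw band rises then falls.
- **noise**: independent Gaussian per cell, truncated by the physical
  clipping. Defaults: 0.5 %FW on oil (NIR-scale repeatability) and
  (1.0, 1.0, 2.5) px on R, G, B — per-image means pool 40–200 fruits, so
  replicate scatter is sub-pixel to a few pixels, with the blue channel
  noisiest (sensor noise plus blue-background contamination at fruit
  edges).
- **cultivar presets** give row counts 45, 40, 40, 45, 45, 30
  (n_dates × replicates); the two 40-row cultivars use 20 dates × 2
  replicates since 40 is not divisible by the campaign's 3 subsamples.
  Leccino's decline onset is ~3 sampling intervals earlier than the
  late-ripening cultivars; Koroneiki's and Maiatica's red band never
  declines; Maiatica's green stays nearly flat; blue declines less than
  red/green everywhere.
- **images**: elliptical fruits on a uniform blue background (B > max(R,G)
  + margin), jittered per-fruit colors re-centred so the exact foreground
  mean matches the tabulated band values within 0.5 per channel after 8-bit
  quantization; placement is a jittered grid, which guarantees capacity for
  the late-season fruit counts (~100 per image). Stored fixtures are PNG;
  no JPEG loss, lighting gradients, ColorChecker charts or fruit-weight
  curves are simulated.

What passing tests on this generator do and do not show: they validate the
pipeline's mechanics and the qualitative regimes reported for the original
campaign (|ρ| up to ~0.98 for selected predictors, FI quintiles near 2,
three-band R² ≈ 0.85–0.98, collinearity-triggered reduced models, the
co-occurrence of extreme Hyst with strong rank correlation). They do not
show that the specific fitted coefficients or error magnitudes transfer to
real images, which carry illumination structure, per-fruit color variance
and camera processing that the generator deliberately omits.

## Known limitations

- FI has limited discriminating power *within* a set of co-monotone
  indexes: their Spearman components agree up to sampling noise and their
  Hyst components saturate at ±1, while the accuracy of the corresponding
  linear models still differs through the curvature of each CI–oil
  relation, which a rank-based score cannot see. The top-quintile *set* is
  stable; the identity of the single top-FI candidate is not, and the exact-
  tie flagging in the ranking is the honest treatment of that degeneracy.
- The true formulas of the bespoke mio-indexes and the exact original
  35-index roster are not public; the registry is faithful in count and
  attested members and overridable for the rest.
- Hysteresis is quantified for incomplete (open) seasonal loops; closed-
  loop diagnostics and loop-shape taxonomies are out of scope.
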