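# Methods

This note records the models, conventions and numerical choices behind
`ricepheno`, in the order data flows through the pipeline.

## Imaging model and segmentation

Input images are side views of single potted plants against a uniform
low-saturation background. Segmentation is purely colour-rule based:

* **plant vs background** — pixel saturation above `background_sat_max`
  (default 0.25) in HSV space;
* **morphological cleanup** — one binary opening followed by one closing
  with a square structuring element (default 3×3, configurable, on by
  default) to suppress speckle before any area is counted;
* **green vs yellow** — hue bands, default green [60°, 180°) and yellow
  [20°, 60°). Plant pixels outside both bands are assigned to the nearer
  band boundary by circular hue distance, so the green/yellow masks always
  partition the plant mask exactly — area conservation
  (GPA + YPA = TPA) then holds by construction, not approximately;
* **panicle** — the topmost connected component (8-connectivity, minimum
  25 px) of *yellow-leaning* plant pixels (hue < 75°; ripe panicles are
  yellow, unripe ones straw/yellow-green, while rice foliage sits near
  95–130°) within the upper 40% of the plant bounding box. Panicles sit
  atop the canopy, and basal leaf senescence stays low in the frame, which
  is what makes this rule separable. An empty result is legal
  (pre-heading). Externally produced masks can be injected unchanged
  (`source="external"`).

These defaults are this package's own; no claim is made that they match
any particular commercial platform's internal rules. Mask quality is
scored with IoU = |P∩T|/|P∪T|, precision, recall, and
F = 2pr/(p+r), with precision defined as 0 for an empty prediction.

## Traits

Heights are bounding-box row extents × scale (mm/px); widths the column
extents; areas are pixel counts × scale². Height deliberately uses the
full bounding box rather than a skeleton or convex hull — it is the
operator a raster pipeline can compute exactly and monotonically. Grain
traits are never computed from images (they come from a bench yield-traits
scorer); `load_grain_traits` only validates them: hard errors for
impossible values (spikelet fertility outside [0,1], filled grains
exceeding spikelets), soft warnings + row flags for internal
inconsistencies (SF vs GN/TFN, W vs GN·Wper1000/1000 beyond 10%, length/
width ratio beyond 5%).

Per-image organ observables are scalarized into season-level registry
columns as **seasonal maxima** (for PlantH…PanicleYPA), consistent with
using the peak projected panicle area as the yield correlate; the one
exception is PaicleEndTPA, defined as the last pre-harvest panicle
observation. The registry name "PaicleEndTPA" preserves the catalogue's
historical spelling.

Temporal traits, per plant:

* **Quadratic trajectory fits** y(t) = a·t² + b·t + c by OLS on
  {t², t, 1} (≥ 4 observations required). The quadratic family is the
  package's canonical growth/senescence trend model (see model selection
  below); its coefficients are themselves traits for plant TPA, plant
  Ypar, panicle TPA and panicle Ypar, the panicle fits using the
  post-heading subseries only.
* **Daily growth** = (value at the observed maximum − value at the first
  observation) / (days between), i.e. the mean daily increase over the
  ascending phase. The alternative (steepest single-interval slope) was
  rejected as far more noise-sensitive. A maximum at the first observation
  yields 0 with a warning.
* **Phenology**: argmax days of the observed series, earliest day on
  ties; panicle argmax days are reported relative to heading. Heading
  (HS) is the first imaging day whose panicle area exceeds 100 mm² on two
  consecutive imaging days (single-day spikes are not heading); the
  threshold is configurable, and a plant that never heads keeps its row
  with panicle cells missing. Senescence onset (PlantSD) is the vertex
  day −b/2a of the fitted plant-Ypar parabola, clamped into the
  observation window (for a degenerate a = 0 fit the window edge on the
  slope's side is used).

## Growth/biomass model families

Six candidate families: linear, quadratic (OLS); exponential p·e^{qx},
power p·x^q (x > 0 required), Gaussian A·exp(−(x−μ)²/2σ²), and sine
A·sin(Bx+C)+D by Levenberg–Marquardt. Initialisation: log-linearised
regression for exponential/power; (max, argmax, range/4) for the
Gaussian; data mean/half-range plus the dominant FFT frequency of the
detrended, uniformly resampled series for the sine. Non-convergence gets
five seeded multiplicative-jitter restarts and then a *flagged* failure
result — never silently wrong parameters, never an exception from a
single family inside a comparison. Ranking is by training R² (ties by
lower RMSE; failures and undefined-R² fits last). MAPE is reported in
percent; `score()` refuses zero responses and constant targets, while the
internal training/CV metrics tolerate them (MAPE over nonzero y, NaN R²
for a constant fold) because trajectory data legitimately contain zeros
before heading. k-fold CV (default k = 5) uses a seeded unstratified
random partition in which every point is held out exactly once.

## Yield and population statistics

* **Stepwise regression**: forward selection with backward elimination on
  partial-F probabilities (coefficient t-test p-values, an equivalent
  formulation), entry p ≤ 0.05 and removal p ≥ 0.10 by default. Ties are
  broken by trait-registry order for determinism, and every add/remove is
  logged in a replayable trace. Once the model's residual sum of squares
  falls below 1e−10 of the total (an exact fit), forward stepping stops:
  beyond that point partial-F probabilities are floating-point noise and
  would admit spurious variables. Zero-variance or incomplete candidates
  are dropped with a warning. Yield is modelled per trait group (the six
  non-grain groups; grain traits contain the yield itself) and pooled.
* **Mantel tests**: r is the Pearson correlation of lower-triangle
  vectors of two Euclidean distance matrices (columns standardised before
  distances so trait scale does not dominate); the permutation p-value is
  upper-tail, p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), permuting rows
  and columns of the second matrix jointly (default 9,999 permutations).
  The partial variant residualises both triangle vectors on a third
  matrix and re-residualises the permuted matrix each draw. The plain
  test is the pipeline default; the controlled matrix is always an
  explicit argument.
* **Kruskal–Wallis / Wilcoxon**: scipy's tie-corrected H with a χ²
  p-value; all-tied data return H = 0, p = 1 with a warning. Pairwise
  two-sided rank-sum tests run only when the omnibus p < 0.05, and both
  unadjusted and Holm-adjusted p-values are reported (the multiplicity
  correction is deliberately shown alongside the uncorrected convention).
* **PCA**: columns standardised (ddof = 1, the R `scale = TRUE`
  convention), eigendecomposition of the correlation matrix; variance
  fractions therefore sum to exactly 1. Component signs are fixed so each
  loading column's largest-magnitude entry is positive. Constant columns
  and missing values are rejected by name — callers filter to
  complete-case, non-degenerate submatrices first (the pipeline does this
  automatically).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *design* of a whole-season greenhouse
screen: weekly side views from day 42 to day 182 after sowing; plant TPA
following a concave quadratic (default peak ≈ 110,000 mm² near day 130
from ≈ 8,000 mm² at day 42); plant Ypar a convex quadratic rising from
≈ 0.01 at onset (day ≈ 70) to ≈ 0.5 at day 182, clipped to [0, 1];
heading near day 85 with panicle area and panicle Ypar quadratics
anchored at zero at heading; height rising linearly to a plateau
(≈ 1,100 mm by day 120). A 93-plant cohort (the scale of a modest
diversity panel, split ≈ 1:2 into indica/japonica-like subpopulations
with a planted +0.05 PlantYpar and −5 d heading offset for indica) draws
per-plant parameters with 5–8% jitter, adds per-observable Gaussian
measurement noise (truncated so areas stay positive and ratios in
[0, 1]; defaults ≈ 1–2% of typical signal), and plants a linear yield
y = β·traits + ε routed mainly through panicle growth and maturation.
Noise scales are chosen for test power and plausibility, not calibrated
to any instrument.

The renderer draws a tapering stack of centred pixel rows (flat 3-row
base, minimum width 3 px) topped by a rectangular panicle blob, with
foliage, straw (unripe panicle) and yellow pixels in disjoint hue bands.
Its guarantees: plant pixel count and height extent exact to rounding,
yellow fraction within one quantization unit, panicle area within
(blob width + height) px. The yellow budget goes to the panicle first
(top-down ripening) and then to the canopy base (basal senescence). The
geometry is deliberately stable under the default 3×3 opening.

What passing tests therefore show: the *operators* — segmentation rules,
trait arithmetic, trajectory fits, stepwise/Mantel/KW/PCA machinery —
are correct on data whose truth is known exactly. What they do not show:
performance on real canopies (overlapping leaves, specular highlights,
shadows, occluded panicles, photometric drift), for which the rule
thresholds would need re-tuning and no accuracy figure here transfers.

Two degeneracies of the generator are worth knowing: the rendered
panicle saturates toward fully yellow late in the season (so the
panicle-maturation trend is informative only on series-level synthetic
data, and the analysis stage skips constant trends), and PlantYparD
(day of maximum Ypar) is nearly always the last imaging day because the
planted senescence index is monotone — cohort-level PCA paths drop
zero-variance columns before decomposition.

## Problem sizes and determinism

Default analysis sizes — 93-plant cohorts, 500-replicate Mantel and
1,000-replicate Kruskal–Wallis null calibrations with 999 permutations
each, and a 5-plant × 20-timepoint rendered round trip — were chosen so
the full check suite runs in a few minutes on one CPU while keeping
Monte-Carlo standard errors below a third of the tolerances tested
against. Every stochastic step (generator, restarts, CV folds,
permutations) consumes an explicit seed; identical configs reproduce
CSV outputs byte for byte, and each pipeline CSV carries a config-hash
provenance comment.
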