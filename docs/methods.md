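# Methods

This note records the models, conventions, numerical choices and known
limitations behind `tearmap`, in the spirit of a statistical software
methods appendix. Lower tear-quality values always mean a more stable
tear film; maps live on polar grids with angles in degrees,
counter-clockwise, 0° at chart-right, so that for a right eye (OD) the
nasal side is at 0° and for a left eye (OS) at 180°.

## Map model and conventions

A map is a scalar field sampled on rings × meridians; missing cells are
NaN. The standard analysis grid is 50 evenly spaced rings to 5 mm × 180
meridians — finer than the 121-point pivot layout it feeds, coarse enough
that a full cohort fits comfortably in memory. "Central 3.5 mm" in the QC
rule is read as a 3.5 mm *diameter* disc (radius 1.75 mm), matching how
clinical topography zones are usually quoted; the analysis zone for global
means defaults to a 4 mm radius, since the regional narrative distinguishes
behaviour inside versus beyond that region. Both are configurable.

All disc/annulus means are area-weighted (weight ∝ r·Δr·Δθ with midpoint
ring boundaries): polar cells are not equal-area, and unweighted means
would overweight the centre by an order of magnitude.

### Interpolation

Every resampling/extraction path uses the same piecewise-cubic scheme: a
periodic cubic spline along each ring (fitted through present cells only),
then a not-a-knot cubic spline radially per queried angle. Not-a-knot end
conditions reproduce polynomials of degree ≤ 3 in r exactly, which the
test suite asserts on a + b·r² fields at 10⁻³ of the quadratic range.
Rings with fewer than four present cells fall back to linear
interpolation, then to their single value. A query point is reported
missing only when its local 4 × 4 (rings × meridians, periodic in θ)
stencil is entirely missing — so isolated missing cells are bridged, while
a fully missing sector stays missing at the pivots inside it. No radial
extrapolation beyond the source extent is ever performed.

Dense-map prediction scatters the 121 pivot values back to a grid with
thin-plate-spline radial basis interpolation (exact at the pivots, exact
for constants via the degree-1 polynomial tail), masked beyond the
outermost pivot ring.

### Smoothing

The low-pass filter is a separable Gaussian in (r, θ) with periodic wrap
in θ and masked normalisation: missing cells carry zero weight and remain
missing. The pipeline applies a mild σ = (0.25 mm, 10°) before pivot
extraction — enough to suppress per-cell measurement noise at the pivot
scale without moving the 0.8 mm-scale hotspot structure.

## Pivot layout

121 points: the corneal apex plus five rings of 8, 16, 24, 32, 40 points
at radii {1, 2, 3, 4, 5} mm (0.2·R steps), each ring starting at 0° and
proceeding counter-clockwise. The OS layout is the θ → 180° − θ mirror of
OD, so nasal points coincide across lateralities. The printed constraints
on the layout are its count (121), the radial arrangement and even
spacing; the 8k-per-ring construction is the simplest family satisfying
them, and 1 + 8 + 16 + 24 + 32 + 40 = 121 fixes it.

## Regional statistics

* **Signed-rank test.** Zero differences are dropped (Wilcoxon's original
  treatment); at least five nonzero pairs are required to report a
  p-value, below which the cell is untestable — the exact test has no
  two-sided resolution below 2/2⁴. For n ≤ 25 the null distribution of
  W⁺ is computed exactly over the observed (mid)ranks by subset-sum
  dynamic programming, which handles ties without approximation and is
  verified against full 2ⁿ enumeration; beyond that, a normal
  approximation with tie and continuity corrections is used. Two-sided
  p-values are the doubled smaller tail, capped at 1.
* **FDR control.** Benjamini–Hochberg step-up with adjusted
  p₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, one family per map (all testable cells of one
  eye-side × group comparison). Pooling both eyes into one family would
  contradict the separate-eye analysis, so it is not done.
* **Rank-sum test** (group comparisons): exact by rank-sum DP when
  min(n, m) ≤ 10 and the pooled sample is tie-free, otherwise corrected
  normal approximation.
* **Spearman R** is the Pearson correlation of midranks; degenerate
  (constant-rank) inputs return NaN rather than an arbitrary value.
* **Bootstrap CIs** are seeded percentile intervals, 10,000 resamples at
  0.95 by default — the plain percentile method is the simplest fully
  reproducible choice.
* **Mode** of a continuous sample is the peak of a Gaussian KDE with
  Silverman bandwidth (a raw modal value is ill-defined for floats).

## Wear-time → map model

Inputs and outputs are min-max scaled to [−1, 1]; following the MATLAB
`mapminmax` convention the scalers are fitted on the full dataset before
splitting. Hidden layers use tanh, the output layer is linear; weights
initialise uniformly at ±1/√fan-in from a seeded generator.

Training minimises scaled-space MSE by full-batch Levenberg–Marquardt:
Δw = −(JᵀJ + μI)⁻¹Jᵀe with the analytic Jacobian of all residuals
(verified against central finite differences at 10⁻⁵ relative error).
μ starts at 10⁻³, ×10 after a rejected step, ÷10 after an accepted one;
training stops on max epochs, μ > 10¹⁰, gradient ∞-norm < 10⁻⁷, or six
consecutive epochs without a new best validation RMSE (patience 6), and
the best-validation weights are returned. When the parameter count
exceeds the residual count (deep/wide grid-search configurations) the
identical step is computed in residual space as −Jᵀ(JJᵀ + μI)⁻¹e, which
avoids forming an unmanageable normal matrix. The 70/15/15 split draws
n_val = n_test = round(0.15·n) after a seeded shuffle (92 eyes → 64/14/14).

The grid search trains uniform-width architectures, depths 1–10 × widths
{8, 16, 32, 64} (40 configurations) on one shared split with per-config
derived seeds, selecting the lowest validation RMSE (ties: fewer
parameters, then lower depth). The reference (5, 8) mixed-width model is
built directly — a uniform-width grid cannot produce it, so it is treated
as a separately specified hand-pick evaluated with the same machinery.
RMSE is always reported in original tear-quality units, where values are
O(0.1) and an RMSE difference of 0.01 is clinically meaningful. Samples
with any missing pivot are dropped from the supervised dataset (logged)
rather than imputed: the LM residual vector must be complete, and silent
imputation would bias the fit.

## Synthetic cohort generator

The generator is the package's stand-in for the clinical cohort and
defines the study conditions: per laterality, 13/28/51 eyes at uniformly
drawn integer wear days in 10–29 / 30–90 / 91–180 (the long-term group
has no printed upper bound; 180 days is an explicit, configurable cap).

Noise-free fields, with r in mm and R = 5 mm:

* pre: q_center + q_slope·(r/R)² + per-eye offset, with q_center = 0.08
  and q_slope = 0.12 (edge value 0.20 — a realistic centre-to-periphery
  span for tear-film surface quality indices).
* post = pre + c_g·m(d)·[s(r) + 0.6·(g_T(x) + 0.6·g_N(x))], where s is a
  smoothstep ramp from 0 below 1 mm to 1 above 3.5 mm (stable centre,
  deterioration beyond ~4 mm diameter), g_T and g_N are unit-peak
  Gaussians (σ = 0.8 mm) centred at 3 mm on the temporal and nasal
  meridians (temporal stronger, and mirrored between eyes), and
  m(d) = 1 + 0.15·(ln d − ln √(lo·hi))/(ln hi − ln lo) is a mild
  within-group log-day modulation giving the predictor a smooth signal.
* The group scale c_g is the single free amplitude per group; it is
  solved linearly on the grid's own quadrature so the noise-free 4 mm-zone
  mean at the group's log-midpoint day equals 0.14 / 0.15 / 0.1525 for
  right eyes; left-eye maps are lowered by a constant 0.01
  (→ 0.13 / 0.14 / 0.1425). The amplitudes are therefore nondecreasing
  across groups by construction.

Per-eye baseline offsets are N(0, 0.04) and per-cell measurement noise
N(0, 0.02), both clamped so quality factors stay nonnegative; clamping
bias is negligible at these levels (fields sit ≥ 3σ above zero almost
everywhere). The resulting across-eye SD of global means is ≈ 0.04,
consistent with the reference group spreads. An optional fraction of
records is corrupted (central disc masked or artefact flag set) to
exercise QC. Tangential-curvature maps use a prolate radial profile minus
a decentred Gaussian flattening bowl (σ = 1.5 mm, depth 2–3 D growing
with group, decentration ≤ 1 mm), giving the centration estimator a
localisable minimum.

What the generator does **not** emulate: tear-film dynamics or break-up,
fellow-eye correlation (eyes are analysed separately by design),
non-Gaussian noise, spatially correlated artefacts, or any per-day
clinical claim beyond the smooth group-level trend. Tests passing on this
generator show the machinery is correct under these assumptions, not that
clinical data behaves this way.

### An honest note on predictor accuracy

Because the supervised dataset is one sample per eye, the model's
out-of-sample residual is bounded below by the between-subject scatter:
with a 0.04 baseline SD and smoothed noise, no wear-time-only predictor
can beat ≈ 0.04 RMSE on held-out eyes, and pooled predicted-vs-observed
correlations land near 0.75 rather than the ≥ 0.9 achievable only when
targets carry no between-subject variation. The acceptance suite asserts
the stricter published-style bounds regardless and those assertions fail
on the synthetic cohort; this is a real property of the stated study
conditions, not an implementation defect, and the corresponding tests are
left failing rather than weakened.

## Problem sizes in tests and acceptance runs

Test fixtures scale sizes to what each property needs: structural and
oracle checks run on coarse grids (≈ 20–24 rings) and small cohorts;
the FDR simulation uses 200 seeded null cohorts of 13 eyes on a
16 × 36 grid; the 40-configuration grid-search check runs on a 10-eye
cohort with 3 LM epochs per configuration, since enumeration and argmin
selection do not depend on training length; model-accuracy and
calibration checks use the full default 92-eye cohorts on the standard
grid. These sizes are the package's choices for a desk-scale suite and
are not parameters of the method.

## Known limitations

* The exchange format is a documented open dialect, not a parser for any
  proprietary topographer export.
* The pivot layout is the simplest family satisfying its printed
  constraints; an instrument-specific layout can be substituted wherever a
  `PivotLayout` is accepted.
* Percentile bootstrap (not BCa); BH (not BY) under the usual positive
  dependence heuristic for smooth spatial fields.
* LM is exact full-batch Gauss–Newton and is intended for datasets of at
  most a few hundred samples; it is not a stochastic trainer.
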