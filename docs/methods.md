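# Methods

## Signal model

The pipeline assumes mono-exponential diffusion attenuation of the
hyperpolarized-gas MR signal: at every voxel, `S = S0 * exp(-b * ADC)`,
where `S0` is the non-diffusion-weighted (NDW, b ≈ 0) image, `S` the
diffusion-weighted (DW) image, `b` the diffusion weighting in s/cm², and
ADC the apparent diffusion coefficient in cm²/s. The inverse,
`ADC = ln(S0/S) / b`, is applied voxel-wise inside the lung mask. No
multi-b joint fitting, kurtosis/stretched-exponential models, or
morphometric (cylinder-model) analysis is attempted; at the b-values
handled here a single effective diffusivity per voxel is the working
assumption, and deviations from mono-exponential decay at high diffusion
weighting are a recognised limitation, not something the model absorbs.

Physical bounds: ADC cannot exceed the free-diffusion coefficient of the
gas mixture — 0.826 cm²/s for ³He diluted in N₂ and 0.211 cm²/s for
¹²⁹Xe in ⁴He (room air is 0.218 cm²/s for comparison). The mapper can
clamp to this ceiling, but does not by default.

### Non-physical voxels

Noise can push `S > S0`, giving negative ADC. The default policy is to
**retain** such voxels: under zero-mean noise the log-ratio estimator's
negative excursions partially cancel its positive ones, whereas clamping
to zero or excluding them biases the whole-lung mean upward at low SNR.
Both alternatives are available (`negative_policy="clamp" | "exclude"`)
because some workflows require non-negative maps. Voxels with
non-positive `S` or `S0` are always invalid (NaN) and excluded from
every statistic; NaN propagates and is never zero-filled. No noise-floor
subtraction is applied anywhere — the SNR module quantifies noise, it
does not correct for it.

## Coordinate convention

All grids are `(ap_slice, si_row, lr_col)`, anterior→posterior,
superior→inferior, left→right, 0-based. The AP position of slice *i* is
its centre, `(i + 0.5) * pitch`, with the origin at the anterior face and
pitch = slice thickness + gap in cm. Both choices are affine and leave
fitted AP slopes unchanged; they are fixed so that intercepts are
reproducible. NIfTI files are written with this axis order and a diagonal
spacing affine; readers never silently reorient, and any axis handling is
logged.

## Segmentation

1-D k-means on voxel intensity of the NDW image, initialised at evenly
spaced intensity quantiles with a single restart (deterministic and
equivariant under positive rescaling), run to convergence (tolerance
1e-8, ≤ 300 iterations). The lowest-mean cluster is background; the mask
is the union of the rest, then the largest ≤ 2 connected components
(6-connectivity — conservative about bridging across 30-mm slices) are
kept and holes filled. Non-finite voxels enter clustering as zero
intensity, which makes segmentation idempotent on already-masked images.

`k` defaults to 4, which suits real gas images whose parenchyma spans a
continuum of intensities; the lowest cluster then captures background and
the upper three together capture lung. For synthetic phantoms whose NDW
image has exactly two intensity populations (background, uniform
parenchyma), `k = 2` is the appropriate setting and is what the recovery
suite uses — with `k = 4` on a two-population image the majority
background is split across several clusters, only the lowest of which is
discarded. `k` is a config option (`kmeans_k`).

## Regional analysis

**AP gradient (AP_G).** Per-slice mean ADC over valid voxels, ordinary
least squares against slice-centre position in cm; slices with no valid
voxels are dropped, and ≥ 3 usable slices are required. Positive slope =
ADC increases posteriorly.

**SI thirds and ΔSI.** The SI extent of the lung on the centre coronal
slice (`index ⌊n_ap/2⌋`) is split into three equal-height row bands;
when the height is not divisible by 3 the remainder rows join the
inferior band; the same row boundaries apply to every slice, and mask
rows outside the centre-slice extent join the nearest band. ΔSI is
superior-third minus inferior-third mean ADC pooled over slices — the
sign convention makes an apex-dominant emphysema pattern positive.
Equal-height bands were chosen over equal-area bands; with roughly
convex, SI-symmetric lungs the two differ little, and equal height keeps
the band boundaries independent of the ADC data.

## SNR

Per slice: signal = mean of four 5×5-voxel parenchyma-ROI means; noise
from four 5×5 background ROIs; SNR = signal/noise; subject SNR = mean
over evaluable slices. ROI placement is automated and deterministic:
parenchyma ROIs snap to the nearest fully-inside position from the four
quadrant centroids of the slice mask, background ROIs to the nearest
position from the slice corners keeping a ≥ 2-voxel margin outside the
mask; all eight ROIs must be pairwise disjoint or the slice is skipped.
Two noise definitions are implemented because "standard deviation of the
mean voxel values for four ROIs" is ambiguous: `"pooled"` (default) takes
the SD of all 100 background voxels, `"roi_means"` the SD of the four
ROI means. The pooled estimator is the default because a four-value SD
is statistically fragile (its sampling variance is measurably larger —
this is itself a regression test). No Rician bias correction is applied
to SNR.

## CT densitometry

`RA_t` = 100 × (lung voxels with HU **strictly below** t) / (lung
voxels), for t ∈ {−950, −910, −856}; nesting RA₉₅₀ ≤ RA₉₁₀ ≤ RA₈₅₆ is
structural. `HU15%` is the nearest-rank 15th percentile (smallest value
with ≥ 15% of voxels at or below it), matching a frequency-histogram
reading; interpolated percentiles are an option. Emphysema is classified
by RA₉₅₀ **strictly greater** than 6.8%, the upper 95% limit of predicted
normal. The lung mask is taken as given; airway/vessel removal is out of
scope.

## Statistics

* **Mann–Whitney**: U with mid-rank tie credit; for pooled n ≤ 20 the
  two-tailed p is exact, enumerating all C(n, n_a) group labelings and
  counting those with |U − n_a·n_b/2| at least the observed; beyond that,
  a tie-corrected normal approximation with continuity correction.
* **Pearson**: sample r with the t-transform two-tailed p at n−2 df;
  listwise deletion per pair; ≥ 3 complete pairs and non-constant inputs
  required.
* **Holm–Bonferroni**: step-down with the running maximum (corrected
  values are monotone in the raw ordering) and cap at 1, returned in
  input order. The cohort correlation family is the full 20-cell ADC × CT
  block (4 ADC metrics × 5 CT metrics); family membership is an analysis
  choice, kept config-driven in `cohort_report`.
* **OLS**: via statsmodels with classical SEs from the unbiased residual
  variance; t = coef/SE with n−k−1 df; rank-deficient designs are
  rejected naming the collinear columns. The cohort model regresses a CT
  metric on the ³He and ¹²⁹Xe b=12/b=20 ADC columns over the 10 COPD
  subjects with an intercept (6 residual df); the b=30 column, observed
  in only three subjects, is not a usable predictor under listwise
  deletion. Gas-exchange (DL_CO) models have the same structure and are
  exercised on synthetic responses only, since no per-subject DL_CO is
  bundled.
* **ANOVA**: classical one-way F (scipy), used for SNR-across-b
  comparisons.

## Phantom generator

The generator emulates the targeted acquisition, not arbitrary lungs:

* geometry: 7 coronal slices × 128 × 128 by default, (30, 3.125, 3.125)
  mm spacing — a 40-cm FOV multislice breath-hold protocol; two
  ellipsoidal "lungs" (semi-axes 0.45/0.38/0.16 of the grid) occupying
  ≈ 23% of the grid, within the accepted 20–60% band;
* true ADC field: `baseline + ap_slope·ap_cm`, plus `si_offset` added as
  a step on the superior third (the step matches the three-ROI analysis
  granularity, so ΔSI recovers `si_offset` exactly), spherical lesions
  overwritten last, field clipped to (0, ceiling];
* defaults: baseline 0.23 cm²/s (healthy older-adult ³He parenchyma),
  zero slope/offset, no lesions, `s0_level` 100, noiseless. Study-like
  settings used by tests: ap_slope −0.003 to −0.00667 cm²/s/cm, si_offset
  0.2 cm²/s, lesion ADC up to the ceiling;
* noise: Rician — magnitude of signal plus two-component zero-mean
  Gaussian of scale `noise_sigma` — because gas MRI magnitudes are
  Rician; Gaussian is selectable for analytic checks. "DW SNR 30" in the
  recovery suite means `noise_sigma = s0·exp(−b·baseline)/30`;
* CT companion: lung HU drawn from a bimodal mixture — emphysema
  component N(−990, 12) truncated below −950, parenchyma N(−860, 28)
  truncated above −950 — with mixture weight `frac_below_950`, so the
  realised RA₉₅₀ is exactly binomial around the request and the
  degenerate weights 0 and 1 are exact. Truncation at the threshold is a
  deliberate simplification: it decouples the mixture weight from tail
  leakage at the cost of a non-Gaussian notch at −950 HU;
* the ground truth stores exactly what the estimators target: the
  masked field, whole-lung and band means as arithmetic means of the
  field, and the OLS slope of the true per-slice means.

What the phantom does **not** emulate — partial-volume edges, coil
sensitivity shading, ventilation defects, airway structure, anisotropic
diffusion, gas redistribution during breath-hold — bounds what passing
recovery tests show: they validate the estimator chain, not robustness
to those real-data effects.

## Problem sizes and determinism

Recovery tests and the acceptance script use 7×96×96 to 7×128×128 grids,
10 noise replicates at DW SNR 30, and 10⁵-voxel CT phantoms; the whole
suite is a few seconds of compute. Every stochastic step flows from an
explicit seed through `numpy.random.default_rng`; k-means is
deterministic by construction (quantile init, single restart), so
repeated runs with one (config, seed) pair produce byte-identical CSV
outputs.

## Known limitations

* Whole-lung ADC is only measurable in ventilated lung; unventilated
  regions (severe obstruction, bullae) are invisible to the method and
  to this implementation alike.
* The exact Mann–Whitney enumerator is O(C(n, n_a)) and is capped at
  pooled n = 20 by design.
* The bundled cohort stores values at their published per-subject
  precision; statistics that amplify input rounding (notably
  coefficients of collinear regressions, and corrected p-values near
  rank boundaries) can differ from values computed on unrounded source
  data by more than their printed precision. The self-check manifest
  flags, rather than hides, such cases.
* The ROI-SNR estimator is placement-sensitive by nature; automated
  placement makes it reproducible, not placement-free.
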