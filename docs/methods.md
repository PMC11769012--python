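# Methods

## Overview

marshphen maps four salt-marsh cover classes — *Phragmites australis*
(PA), *Suaeda salsa* (SS), *Tamarix chinensis* (TC) and bare tidal flat
(TF) — from two complementary time series per pixel: an optical surface
reflectance year (green, red, NIR, SWIR1) and a dual-polarization SAR
backscatter year (VV, VH in dB). The analysis is strictly per pixel; no
spatial context enters the features or the classifier.

## Tidal filter

Intertidal pixels are intermittently flooded, which collapses NDVI and
corrupts any seasonal fit. Each observation with
MNDWI = (ρ_green − ρ_SWIR1)/(ρ_green + ρ_SWIR1) strictly above −0.1 is
treated as inundated. The inundation frequency is the inundated fraction
of *cloud-free* observations — cloudy acquisitions carry no MNDWI
evidence, so they are left out of the denominator. A pixel with
frequency strictly above 0.66 is excluded outright (it is water-dominated
and has no recoverable phenology); otherwise the inundated observations
are removed. Both inequalities are strict by convention; the filter is
idempotent and the exclusion verdict is monotone in the flooded count.
Pixels that survive with fewer than 10 observations are flagged
"insufficient for fitting", since the 6-parameter model below needs
headroom.

## Double-logistic phenology model

The filtered NDVI year is modelled as

    f(t) = c0 + c1 · [ 1/(1 + exp((x1 − t)/x2)) − 1/(1 + exp((x3 − t)/x4)) ]

with t in day-of-year (1-based, single non-leap year, no multi-year
stitching). x1/x3 position the green-up and senescence inflections, x2/x4
set their steepness (days). The bracketed basis alone has no baseline or
amplitude, so c0 and c1 are fitted explicitly — otherwise the curve
minimum and maximum (the BV/MV features) would be fixed at 0 and ~1.

Fitting uses `scipy.optimize.least_squares` (trust-region reflective)
with box bounds x1 ∈ [30, 250], x3 ∈ [150, 365], x2, x4 ∈ [1, 60],
c0 ∈ [−0.2, 0.5], c1 ∈ [0.05, 1.2]. The ordering constraint
x3 ≥ x1 + 10 cannot be a box bound; it is enforced with a hinge penalty
residual (weight 10) plus post-fit validation. Initialisation comes from
the data: c0 from the 10th percentile, c1 from the 10–90 percentile
range, x1/x3 from the first/last half-range crossing of the raw series,
x2 = x4 = 15 days. A fit is flagged not-converged when the optimizer
fails, the inflection ordering is violated, or the fitted curve's annual
range is below 0.02 NDVI ("no seasonality" — e.g. a constant series,
where c1 simply pins at its lower bound).

### Metrics

On a daily grid over days 1–365: BV = min f, MV = max f. SOS is the
earliest ascending-limb day where f reaches BV + θ·(MV − BV) and EOS the
latest such descending-limb day, with θ = 0.5 by default (the threshold
is configurable; values from 0.1 to 0.9 are accepted). ROI and ROD are
the secant slopes of f between its 20% and 80% amplitude crossings on
the ascending and descending limb, both reported positive. Crossings are
located on the daily grid and refined by bisection to 0.1 day — robust,
and checkable against the closed-form logistic crossing times (the
20→80% span of a lone logistic limb is x2·ln16 on each side of x1). A
curve that never crosses a required level inside the year (flat or
truncated season) yields an explicit unfit verdict rather than a number.

## SAR polarization features

Backscatter arrives in dB. Per image the polarization difference is
VV − VH (dB); the polarization ratio is VH/VV computed in linear power,
10^((VH−VV)/10), because a ratio of logarithmic quantities is
ill-defined — the two carry identical information
(ratio = 10^(−difference/10)), just in conventional units. Per calendar
month (non-leap calendar) the per-image values are averaged — the mean of
per-image ratios, not the ratio of means — giving 12 + 12 features.
Months without acquisitions are explicitly missing (NaN), never silently
zero, and are median-imputed from the pixel's observed months only when
a fixed-length vector is required for classification.

## Feature plans and classifier

Plan 1 = six phenological metrics; plan 2 = 24 SAR features; plan 3 =
phenology + 12 ratios; plan 4 = phenology + 12 differences; plan 5 = all
30. Samples landing on excluded/unfit pixels are dropped (logged); in the
end-to-end experiment the sample set is first restricted to pixels where
all 30 features are defined, so every plan sees identical samples and
the comparison across plans is paired.

The classifier is a 500-tree random forest, unlimited depth, with a
stratified 5-fold cross-validated grid search over the per-split feature
subsampling rule {sqrt, log2}. Reported: per-fold and mean ± sd CV
accuracy, and macro-averaged precision/recall/F1 from cross-validated
predictions (macro, because per-plan single values are wanted and the
synthetic classes are balanced). Held-out assessment uses a stratified
70/30 train/test split; the confusion matrix is built on the test split
only. All splits and the forest share one explicit seed, recorded in the
report.

## Accuracy metrics

Confusion-matrix orientation is fixed in one place: rows = reference i,
columns = predicted j. Producer's accuracy PA_i = n_ii/n_i+ (row total),
user's accuracy UA_i = n_ii/n_+i (column total), OA = Σn_ii/N,
pe = Σ(n_i+·n_+i)/N², κ = (OA − pe)/(1 − pe). Classes with an empty row
or column report PA/UA as explicit nulls — silent zeros would corrupt
macro averages. κ is undefined (null) when pe = 1.

## Synthetic scene generator

The generator emulates the statistical structure the analysis assumes,
not radiometry:

* **Class layout**: contiguous equal blocks over the flattened grid, or
  uniform random with every class guaranteed at least one pixel.
* **Optical**: each pixel follows its class's double-logistic NDVI curve.
  The basis is affinely rescaled so the curve's annual minimum/maximum
  equal the configured BV/MV exactly, making the configured values
  recoverable oracles for the fitting stage. NDVI (plus Gaussian noise,
  default sd 0.03) is inverted into red/NIR reflectances with a fixed
  band sum of 0.3 so the index round-trips exactly; dry observations get
  green/SWIR1 = 0.10/0.30 (MNDWI −0.5), flooded ones 0.5-band-sum values
  giving MNDWI +0.5 and NDVI ≈ 0.02. Flooding is Bernoulli per optical
  acquisition — default probability 0.85 in a 4-column shoreline band
  (those pixels nearly always trip the 0.66 exclusion rule) and 0.08
  inland. Clouds are a per-observation Bernoulli validity flag (default
  0.1); scene-classification rasters are upstream preprocessing and out
  of scope.
* **Default phenology** (day-of-year / NDVI): PA season 150–300, MV 0.72,
  BV 0.10, fast green-up and the fastest senescence; TC 180–320, MV 0.80,
  BV 0.12, slow senescence; SS 200–260, MV 0.20, BV 0.05, lowest rates;
  TF nearly flat at low NDVI (BV 0.03, MV 0.10). TF carries weak rather
  than zero seasonality: a perfectly flat class would fail the
  double-logistic fit everywhere and silently vanish from every
  phenology-based plan, turning the four-class experiment into three
  classes.
* **SAR**: per class a 12-month table of expected VV and VH (dB); each
  acquisition takes its month's value plus Gaussian noise (default sd
  0.7 dB). The tables are qualitative: polarization difference ordered
  PA ≈ TC > SS > TF, a June peak for TC, a late-season rise for PA.
  No quantitative dB tables exist for this system, so these values are
  invented emulations of the reported seasonal orderings.
* **Calendars**: optical defaults to 39 day-of-year values matching a
  realistic 5-day-revisit acquisition year after cloud screening
  (winter-sparse); SAR defaults to 44 evenly spaced dates covering all
  12 months.
* **Samples**: stratified without replacement, deterministic given seed.

All randomness derives from `SceneConfig.seed` via named substreams, so
identical configs give bit-identical stacks; the pipeline fans the one
run seed out to scene, split and forest.

What the generator does **not** emulate: spatial autocorrelation beyond
the block layout, mixed pixels, radiative transfer, real tide forcing,
speckle statistics, sensor noise covariance. Passing tests therefore
demonstrate the correctness of the algorithms and the internal
consistency of the pipeline — not classification accuracy attainable on
real imagery, where class overlap is far larger.

## Problem sizes and runtime choices

The default experiment uses a 24×24 grid (576 pixels), 50 samples per
class, and five plans; one run takes about a minute on a single CPU,
dominated by the per-pixel least-squares fits. Examples and the
determinism checks use smaller grids (10×10–14×14) and fewer trees —
determinism and contract properties do not depend on scale.

## Known limitations

* The double-logistic model is unimodal; double-cropping or bimodal
  marsh phenologies are out of scope, as are alternative smoothers.
* Pixels excluded by the tidal filter get no phenology and are nodata in
  classified maps; no gap-filling from neighbours is attempted.
* Raster I/O is plain multi-band TIFF with CSV sidecars; georeferencing
  metadata is not carried (inputs and outputs are index-gridded).
* Accuracy assessment is sample-based; no area-weighted estimation or
  significance testing between plans.
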