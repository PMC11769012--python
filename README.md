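# marshphen

Classification of salt-marsh vegetation from fused optical phenology and
dual-polarization SAR time series.

Coastal salt marshes — the reed *Phragmites australis*, the succulent
*Suaeda salsa*, the shrub *Tamarix chinensis*, and bare tidal flat — are
hard to separate with a single optical image: the species overlap
spectrally, and tides flood the scene irregularly. This package
implements a time-series approach for pixel-based mapping of these
classes, aimed at researchers working with Sentinel-2-like surface
reflectance and Sentinel-1-like dual-polarization (VV/VH) backscatter
stacks:

1. **Tidal filter.** Per acquisition, MNDWI = (ρ_green − ρ_SWIR1)/(ρ_green + ρ_SWIR1)
   flags inundated observations (MNDWI > −0.1). Per pixel, observations
   flooded in a fraction > 0.66 of cloud-free acquisitions exclude the
   pixel; otherwise flooded observations are dropped.
2. **Phenology.** The filtered NDVI year is fitted with a double-logistic
   curve

   f(t) = c0 + c1·[ 1/(1 + e^{(x1−t)/x2}) − 1/(1 + e^{(x3−t)/x4}) ],

   and six metrics are extracted: base and maximum value (BV, MV), start
   and end of season (SOS, EOS — 50%-amplitude crossings), and rates of
   increase/decrease (ROI, ROD — 20→80%-amplitude secant slopes).
3. **SAR features.** Per image, the polarization difference VV−VH (dB)
   and ratio VH/VV (linear power); per calendar month, their means — 12 +
   12 features covering the year.
4. **Fusion and classification.** Five feature plans (phenology only,
   SAR only, phenology + ratios, phenology + differences, all 30
   features) are classified with a 500-tree random forest tuned by
   stratified 5-fold cross-validated grid search.
5. **Accuracy.** Confusion matrix on held-out samples with producer's and
   user's accuracy, overall accuracy, and κ = (p_o − p_e)/(1 − p_e).

A synthetic-scene generator produces gridded optical/SAR stacks and
labeled samples with the class-specific seasonal structure this analysis
assumes (unimodal NDVI trajectories, tidal flooding in a shoreline band,
cloud gaps, seasonal VV/VH patterns), so the whole pipeline is testable
without satellite downloads.

## Worked example

Fit one noisy pixel and extract its phenology
(`examples/02_phenology_fit.py`):

```
converged: True  (rss 0.0333 over 39 obs)
inflections x1/x3    :  149.2 /  299.7  (true 150 / 300)
SOS / EOS            :  149.2 /  299.7 days
BV / MV              :  0.102 /  0.660 NDVI
ROI / ROD            : 0.01505 / 0.01170 NDVI/day
```

With observation noise of 0.04 NDVI the season's start and end are
recovered within a day of the generating curve; BV/MV bracket the annual
NDVI range, and ROI/ROD quantify green-up and senescence speed.

Run the fusion experiment on a small synthetic scene
(`examples/04_fusion_experiment.py`):

```
plan 1 ( 6 features): CV 1.000 +/- 0.000 | held-out OA 94.44%  kappa 0.926  (n=18)
plan 5 (30 features): CV 1.000 +/- 0.000 | held-out OA 100.00%  kappa 1.000  (n=18)
```

Plan 1 classifies with the six phenological metrics alone; plan 5 adds
the 24 monthly polarization features and resolves the residual
confusion. The other examples cover the tidal filter, the monthly SAR
aggregation, and the confusion-matrix metrics.

There is also a thin CLI mirroring the stages:

```sh
marshphen simulate --out scene --seed 42
marshphen phenology --optical scene/optical.tif --out scene
marshphen sarfeat --sar scene/sar.tif --out scene
marshphen classify --plan 5 --pheno scene/phenology.tif \
    --sar scene/sar_features.tif --samples scene/samples.csv --seed 42 --out scene
marshphen run-all --out run --seed 42
```

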