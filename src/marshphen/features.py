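"""Grid-level feature extraction: phenology rasters and SAR feature rasters.

Bridges the per-pixel operations (tidal filter, double-logistic fit,
monthly SAR aggregation) and the raster world the classifier consumes.
Pixels that are tidally excluded, have too few observations, or fail
the fit carry NaN in every phenology band and are recorded in the QC
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenology import PHENO_FEATURE_NAMES, fit_and_extract
from .sar import SAR_FEATURE_NAMES, monthly_features, pol_difference, pol_ratio, month_of_doy
from .spectral import (
    ObservationSeries,
    TidalFilterConfig,
    apply_tidal_filter,
    mndwi,
    ndvi,
)
from .synthetic import OpticalStack, SarStack
from .errors import EmptyInputError, UnfitPixelError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenologyResult:
    """Per-pixel phenology rasters plus masks and QC records.

    ``stack`` is (6, rows, cols) in :data:`PHENO_FEATURE_NAMES` order
    with NaN for unusable pixels; ``excluded`` flags tidally excluded
    pixels; ``qc`` has one row per pixel.
    """

    stack: np.ndarray
    excluded: np.ndarray
    qc: pd.DataFrame


def pixel_series(optical: OpticalStack, row: int, col: int) -> ObservationSeries:
    """Dated NDVI/MNDWI series of one pixel of an optical stack."""
    return ObservationSeries(
        day_of_year=optical.dates,
        ndvi=ndvi(optical.nir[:, row, col], optical.red[:, row, col]),
        mndwi=mndwi(optical.green[:, row, col], optical.swir1[:, row, col]),
        valid=optical.valid[:, row, col],
    )


def extract_phenology_rasters(
    optical: OpticalStack,
    filter_config: TidalFilterConfig | None = None,
    threshold: float = 0.5,
) -> PhenologyResult:
    """Tidal-filter, fit and extract the six metrics for every pixel."""
    filter_config = filter_config or TidalFilterConfig()
    rows, cols = optical.shape
    stack = np.full((len(PHENO_FEATURE_NAMES), rows, cols), np.nan)
    excluded = np.zeros((rows, cols), dtype=bool)
    records = []
    for r in range(rows):
        for c in range(cols):
            rec = {"row": r, "col": c, "status": "ok", "rss": np.nan,
                   "n_obs": 0, "inundation_freq": np.nan}
            try:
                result = apply_tidal_filter(pixel_series(optical, r, c), filter_config)
            except EmptyInputError:
                rec["status"] = "no_valid_observations"
                excluded[r, c] = True
                records.append(rec)
                continue
            rec["inundation_freq"] = result.inundation_freq
            if result.excluded:
                rec["status"] = "tidal_excluded"
                excluded[r, c] = True
            elif result.insufficient_for_fit:
                rec["status"] = "insufficient_observations"
                rec["n_obs"] = len(result.series)
            else:
                try:
                    fit, metrics = fit_and_extract(result.series, threshold=threshold)
                    rec["rss"] = fit.rss
                    rec["n_obs"] = fit.n_obs
                    if metrics is None:
                        rec["status"] = f"unfit:{fit.flag}"
                    else:
                        stack[:, r, c] = metrics.as_array()
                except UnfitPixelError as exc:
                    rec["status"] = f"unfit:{exc}"
            records.append(rec)
    qc = pd.DataFrame.from_records(records)
    n_bad = int(qc["status"].ne("ok").sum())
    if n_bad:
        logger.info("phenology extraction: %d/%d pixels without metrics", n_bad, rows * cols)
    return PhenologyResult(stack=stack, excluded=excluded, qc=qc)


def sar_feature_rasters(sar: SarStack, impute: bool = True) -> np.ndarray:
    """Monthly polarization features for every pixel, (24, rows, cols).

    Band order matches :data:`~marshphen.sar.SAR_FEATURE_NAMES`
    (12 VV-VH differences in dB, then 12 VH/VV linear ratios).  Months
    without acquisitions are NaN, or median-imputed from the pixel's
    observed months when ``impute`` is set.
    """
    months = month_of_doy(sar.dates)
    diff = pol_difference(sar.vv_db, sar.vh_db)
    ratio = pol_ratio(sar.vv_db, sar.vh_db)
    rows, cols = sar.shape
    out = np.full((24, rows, cols), np.nan)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            out[m - 1] = diff[sel].mean(axis=0)
            out[12 + m - 1] = ratio[sel].mean(axis=0)
    if impute:
        for block in (out[:12], out[12:]):
            missing = np.isnan(block[:, 0, 0])
            if missing.any() and not missing.all():
                med = np.nanmedian(block, axis=0)
                block[missing] = med
    return out


def pixel_monthly_features(sar: SarStack, row: int, col: int):
    """Monthly feature vector of a single pixel (no imputation)."""
    return monthly_features(sar.dates, sar.vv_db[:, row, col], sar.vh_db[:, row, col])
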