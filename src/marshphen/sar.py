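"""Dual-polarization SAR features: per-image difference/ratio and monthly means.

Backscatter arrives calibrated in decibels for the co-polarized (VV) and
cross-polarized (VH) channels.  Two derived quantities carry the
vegetation-structure signal:

* polarization difference VV - VH, in dB, and
* polarization ratio VH/VV, in linear power (10^((VH-VV)/10)).

The ratio is computed in linear power because a ratio of dB values is
ill-defined; difference in dB and linear ratio carry the same
information (ratio = 10^(-difference/10)).  Per-image values are
averaged within each calendar month (non-leap calendar), giving 12
difference and 12 ratio features per pixel for a year of acquisitions.
Months without acquisitions are marked missing, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError

# cumulative days before each month, non-leap year
_MONTH_STARTS = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 365])

#: Band/column names in the order features are laid out in tables and stacks.
SAR_DIFF_NAMES = tuple(f"VVminusVH_{m:02d}" for m in range(1, 13))
SAR_RATIO_NAMES = tuple(f"VHoverVV_{m:02d}" for m in range(1, 13))
SAR_FEATURE_NAMES = SAR_DIFF_NAMES + SAR_RATIO_NAMES


def month_of_doy(day_of_year):
    """Calendar month (1-12) of a day-of-year, non-leap calendar."""
    doy = np.asarray(day_of_year)
    if np.any(doy < 1) or np.any(doy > 365):
        raise ValueError("day_of_year must lie in [1, 365]")
    return np.searchsorted(_MONTH_STARTS, doy, side="left").astype(int)


def pol_difference(vv_db, vh_db):
    """Polarization difference VV - VH in dB."""
    return np.asarray(vv_db, dtype=float) - np.asarray(vh_db, dtype=float)


def pol_ratio(vv_db, vh_db):
    """Polarization ratio VH/VV in linear power: 10^((VH - VV)/10)."""
    return np.power(10.0, (np.asarray(vh_db, dtype=float) - np.asarray(vv_db, dtype=float)) / 10.0)


@dataclass(frozen=True)
class PolFeatureVector:
    """12 monthly VV-VH differences (dB) + 12 monthly VH/VV ratios (linear).

    Unobserved months hold NaN and are listed in ``months_missing``.
    """

    diff_by_month: np.ndarray
    ratio_by_month: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diff_by_month, dtype=float)
        r = np.asarray(self.ratio_by_month, dtype=float)
        if d.shape != (12,) or r.shape != (12,):
            raise ValueError("monthly feature vectors must have exactly 12 entries")
        object.__setattr__(self, "diff_by_month", d)
        object.__setattr__(self, "ratio_by_month", r)

    @property
    def months_observed(self) -> tuple[int, ...]:
        return tuple(int(m) for m in np.nonzero(np.isfinite(self.diff_by_month))[0] + 1)

    @property
    def months_missing(self) -> tuple[int, ...]:
        return tuple(int(m) for m in np.nonzero(~np.isfinite(self.diff_by_month))[0] + 1)

    def imputed(self) -> "PolFeatureVector":
        """Median-impute missing months from the observed ones."""
        d, r = self.diff_by_month.copy(), self.ratio_by_month.copy()
        for arr in (d, r):
            miss = ~np.isfinite(arr)
            if miss.any():
                if miss.all():
                    raise EmptyInputError("cannot impute: no month observed")
                arr[miss] = np.median(arr[~miss])
        return PolFeatureVector(d, r)

    def as_array(self) -> np.ndarray:
        """Concatenated (diff_01..12, ratio_01..12), matching SAR_FEATURE_NAMES."""
        return np.concatenate([self.diff_by_month, self.ratio_by_month])


def monthly_features(day_of_year, vv_db, vh_db) -> PolFeatureVector:
    """Average per-image polarization difference and ratio within each month.

    The mean is taken over per-image values (difference in dB, ratio in
    linear power); input order is irrelevant.
    """
    doy = np.atleast_1d(np.asarray(day_of_year))
    vv = np.atleast_1d(np.asarray(vv_db, dtype=float))
    vh = np.atleast_1d(np.asarray(vh_db, dtype=float))
    if doy.size == 0:
        raise EmptyInputError("monthly_features requires at least one observation")
    if not doy.shape == vv.shape == vh.shape:
        raise ValueError("day_of_year, vv_db, vh_db must have equal length")

    months = month_of_doy(doy)
    diffs = pol_difference(vv, vh)
    ratios = pol_ratio(vv, vh)
    diff_out = np.full(12, np.nan)
    ratio_out = np.full(12, np.nan)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            diff_out[m - 1] = diffs[sel].mean()
            ratio_out[m - 1] = ratios[sel].mean()
    return PolFeatureVector(diff_out, ratio_out)
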