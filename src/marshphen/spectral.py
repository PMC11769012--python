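"""Spectral indices and the tidal inundation filter.

NDVI and MNDWI are computed per observation from surface reflectance.
The tidal filter works per pixel on a dated series of observations: an
observation is flagged *inundated* when MNDWI exceeds a threshold
(default -0.1, the conventional open-water cutoff for turbid coastal
water), and the pixel's inundation frequency is the fraction of
cloud-free observations that are inundated.  Pixels flooded in more
than ``freq_threshold`` (default 0.66) of their observations are
excluded outright; otherwise the flooded observations are removed and
the remaining series is passed on to curve fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyInputError, UndefinedIndexError

logger = logging.getLogger(__name__)

#: MNDWI above this value marks an observation as inundated.
DEFAULT_MNDWI_THRESHOLD = -0.1
#: Pixels inundated in more than this fraction of valid observations are excluded.
DEFAULT_FREQ_THRESHOLD = 0.66

#: Pixels surviving the filter with fewer observations than this are
#: flagged as insufficient for the 6-parameter double-logistic fit.
MIN_OBS_FOR_FIT = 10


def ndvi(rho_nir, rho_red):
    """Normalized difference vegetation index, (NIR - red)/(NIR + red).

    Scalar inputs with a zero denominator raise
    :class:`~marshphen.errors.UndefinedIndexError`; array inputs return
    NaN at those positions (callers drop them with a logged warning).
    """
    return _normalized_difference(rho_nir, rho_red, "NDVI")


def mndwi(rho_green, rho_swir1):
    """Modified normalized difference water index, (green - SWIR1)/(green + SWIR1)."""
    return _normalized_difference(rho_green, rho_swir1, "MNDWI")


def _normalized_difference(a, b, name: str):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    if a.ndim == 0:
        if denom == 0:
            raise UndefinedIndexError(f"{name} undefined: zero denominator")
        return float((a - b) / denom)
    bad = denom == 0
    if bad.any():
        logger.warning("%s undefined for %d observation(s); set to NaN", name, int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(bad, np.nan, (a - b) / np.where(bad, 1.0, denom))
    return out


@dataclass(frozen=True)
class TidalFilterConfig:
    """Thresholds of the tidal filter."""

    mndwi_threshold: float = DEFAULT_MNDWI_THRESHOLD
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.freq_threshold <= 1.0:
            raise ValueError(f"freq_threshold must be in (0, 1], got {self.freq_threshold}")


@dataclass(frozen=True)
class ObservationSeries:
    """Dated per-pixel observations with derived indices.

    ``valid`` marks cloud-free observations; NaN indices are treated as
    invalid as well.  Days must be strictly increasing within [1, 365].
    """

    day_of_year: np.ndarray
    ndvi: np.ndarray
    mndwi: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        days = np.asarray(self.day_of_year, dtype=float)
        ndvi_ = np.asarray(self.ndvi, dtype=float)
        mndwi_ = np.asarray(self.mndwi, dtype=float)
        valid = self.valid
        if valid is None:
            valid = np.ones(days.shape, dtype=bool)
        valid = np.asarray(valid, dtype=bool) & np.isfinite(ndvi_) & np.isfinite(mndwi_)
        if not (days.shape == ndvi_.shape == mndwi_.shape == valid.shape):
            raise ValueError("day_of_year, ndvi, mndwi, valid must have equal length")
        if days.size and (np.any(np.diff(days) <= 0) or days[0] < 1 or days[-1] > 365):
            raise ValueError("day_of_year must be strictly increasing within [1, 365]")
        object.__setattr__(self, "day_of_year", days)
        object.__setattr__(self, "ndvi", ndvi_)
        object.__setattr__(self, "mndwi", mndwi_)
        object.__setattr__(self, "valid", valid)

    def __len__(self) -> int:
        return int(self.day_of_year.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def take(self, mask: np.ndarray) -> "ObservationSeries":
        return ObservationSeries(
            self.day_of_year[mask], self.ndvi[mask], self.mndwi[mask], self.valid[mask]
        )


@dataclass(frozen=True)
class TidalFilterResult:
    """Outcome of the tidal filter for one pixel."""

    excluded: bool
    inundation_freq: float
    series: ObservationSeries | None
    n_removed: int
    insufficient_for_fit: bool

    @property
    def usable(self) -> bool:
        """Pixel survived the filter with enough observations to fit."""
        return not self.excluded and not self.insufficient_for_fit


def apply_tidal_filter(
    series: ObservationSeries, config: TidalFilterConfig | None = None
) -> TidalFilterResult:
    """Apply the per-pixel tidal filter.

    An observation is inundated iff MNDWI > ``mndwi_threshold`` (strict).
    The inundation frequency is taken over cloud-valid observations only;
    if it exceeds ``freq_threshold`` (strict) the pixel is excluded,
    otherwise inundated observations are dropped and the rest returned in
    chronological order.  Filtering is idempotent.
    """
    config = config or TidalFilterConfig()
    if len(series) == 0 or series.n_valid == 0:
        raise EmptyInputError("tidal filter requires at least one valid observation")

    inundated = series.valid & (series.mndwi > config.mndwi_threshold)
    freq = float(inundated.sum() / series.valid.sum())
    if freq > config.freq_threshold:
        return TidalFilterResult(
            excluded=True,
            inundation_freq=freq,
            series=None,
            n_removed=len(series),
            insufficient_for_fit=True,
        )
    keep = series.valid & ~inundated
    filtered = series.take(keep)
    return TidalFilterResult(
        excluded=False,
        inundation_freq=freq,
        series=filtered,
        n_removed=int(len(series) - len(filtered)),
        insufficient_for_fit=len(filtered) < MIN_OBS_FOR_FIT,
    )
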