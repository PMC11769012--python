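"""Double-logistic curve fitting and phenological metric extraction.

A pixel's tidally filtered NDVI year is modelled as

    f(t) = c0 + c1 * [ 1/(1 + exp((x1 - t)/x2)) - 1/(1 + exp((x3 - t)/x4)) ]

where x1/x3 are the left/right inflection days, x2/x4 the corresponding
rate scales (days), c0 a baseline offset and c1 the seasonal amplitude.
The bracketed basis is the classic difference of two logistics used for
unimodal annual NDVI trajectories; baseline and amplitude are fitted
explicitly so that the curve's minimum (BV) and maximum (MV) are
meaningful.

Six metrics summarise the fitted curve: BV, MV, SOS, EOS (days where the
curve crosses 50% of the BV-to-MV amplitude on the ascending/descending
limb) and ROI/ROD (slopes between the 20% and 80% amplitude crossings on
each limb, both reported positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import UnfitPixelError
from .spectral import MIN_OBS_FOR_FIT, ObservationSeries

logger = logging.getLogger(__name__)

# Parameter order: x1, x2, x3, x4, c0, c1
LOWER_BOUNDS = np.array([30.0, 1.0, 150.0, 1.0, -0.2, 0.05])
UPPER_BOUNDS = np.array([250.0, 60.0, 365.0, 60.0, 0.5, 1.2])

#: Minimum separation (days) enforced between the two inflection points.
MIN_INFLECTION_GAP = 10.0

#: Fitted curves whose total range is below this are flagged "no seasonality".
MIN_SEASONAL_AMPLITUDE = 0.02

_PENALTY_WEIGHT = 10.0


def double_logistic(t, x1, x2, x3, x4):
    """Unit-amplitude double-logistic basis g(t; x1..x4)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> sigmoid saturates to 0
        return 1.0 / (1.0 + np.exp((x1 - t) / x2)) - 1.0 / (1.0 + np.exp((x3 - t) / x4))


@dataclass(frozen=True)
class DoubleLogisticFit:
    """Fitted parameters of c0 + c1*g(t; x1..x4) for one pixel."""

    x1: float
    x2: float
    x3: float
    x4: float
    c0: float
    c1: float
    rss: float
    n_obs: int
    converged: bool
    flag: str = "ok"

    @property
    def params(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4, self.c0, self.c1])


def dl_evaluate(t, fit: DoubleLogisticFit):
    """Evaluate the fitted curve f(t) = c0 + c1*g(t)."""
    return fit.c0 + fit.c1 * double_logistic(t, fit.x1, fit.x2, fit.x3, fit.x4)


def _initial_guess(days: np.ndarray, values: np.ndarray) -> np.ndarray:
    c0 = np.percentile(values, 10)
    c1 = max(np.percentile(values, 90) - c0, 0.05)
    half = c0 + 0.5 * c1
    above = values >= half
    if above.any():
        x1 = float(days[above][0])
        x3 = float(days[above][-1])
    else:
        x1, x3 = 120.0, 280.0
    x1 = float(np.clip(x1, LOWER_BOUNDS[0], UPPER_BOUNDS[0]))
    x3 = float(np.clip(x3, LOWER_BOUNDS[2], UPPER_BOUNDS[2]))
    if x3 < x1 + MIN_INFLECTION_GAP:
        mid = 0.5 * (x1 + x3)
        x1 = max(LOWER_BOUNDS[0], mid - MIN_INFLECTION_GAP)
        x3 = min(UPPER_BOUNDS[2], mid + MIN_INFLECTION_GAP)
    c0 = float(np.clip(c0, LOWER_BOUNDS[4], UPPER_BOUNDS[4]))
    c1 = float(np.clip(c1, LOWER_BOUNDS[5], UPPER_BOUNDS[5]))
    return np.array([x1, 15.0, x3, 15.0, c0, c1])


def _residuals(p: np.ndarray, days: np.ndarray, values: np.ndarray) -> np.ndarray:
    x1, x2, x3, x4, c0, c1 = p
    r = c0 + c1 * double_logistic(days, x1, x2, x3, x4) - values
    # hinge keeps the right inflection at least MIN_INFLECTION_GAP days after the left
    gap_violation = max(0.0, MIN_INFLECTION_GAP - (x3 - x1))
    return np.append(r, _PENALTY_WEIGHT * gap_violation)


def fit_double_logistic(
    series: ObservationSeries | None = None,
    *,
    days: np.ndarray | None = None,
    values: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> DoubleLogisticFit:
    """Least-squares fit of the 6-parameter double-logistic model.

    Accepts either a filtered :class:`ObservationSeries` or raw
    ``days``/``values`` arrays.  Requires at least
    :data:`~marshphen.spectral.MIN_OBS_FOR_FIT` observations.  The
    ``converged`` flag is False for optimizer failure or a near-constant
    fitted curve (flag ``"no_seasonality"``).
    """
    if series is not None:
        mask = series.valid
        days = series.day_of_year[mask]
        values = series.ndvi[mask]
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size < MIN_OBS_FOR_FIT:
        raise UnfitPixelError(
            f"need >= {MIN_OBS_FOR_FIT} observations to fit, got {days.size}"
        )

    p0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(days, values)
    p0 = np.clip(p0, LOWER_BOUNDS, UPPER_BOUNDS)
    try:
        res = least_squares(
            _residuals,
            p0,
            bounds=(LOWER_BOUNDS, UPPER_BOUNDS),
            args=(days, values),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
        )
        params = res.x
        success = bool(res.success)
    except Exception as exc:  # pragma: no cover - optimizer hard failure
        logger.warning("double-logistic fit failed: %s", exc)
        params, success = p0, False

    x1, x2, x3, x4, c0, c1 = params
    model = c0 + c1 * double_logistic(days, x1, x2, x3, x4)
    rss = float(np.sum((model - values) ** 2))

    grid = np.arange(1.0, 366.0)
    curve = c0 + c1 * double_logistic(grid, x1, x2, x3, x4)
    amplitude = float(curve.max() - curve.min())

    flag = "ok"
    converged = success
    if not success:
        flag = "optimizer_failure"
    elif amplitude < MIN_SEASONAL_AMPLITUDE:
        flag = "no_seasonality"
        converged = False
    elif x3 - x1 < MIN_INFLECTION_GAP - 1e-6:
        flag = "inflection_order"
        converged = False
    return DoubleLogisticFit(
        x1=float(x1), x2=float(x2), x3=float(x3), x4=float(x4),
        c0=float(c0), c1=float(c1),
        rss=rss, n_obs=int(days.size), converged=converged, flag=flag,
    )


@dataclass(frozen=True)
class PhenoMetrics:
    """The six phenological metrics of one pixel's fitted curve."""

    bv: float
    mv: float
    sos: float
    eos: float
    roi: float
    rod: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sos, self.eos, self.mv, self.bv, self.roi, self.rod])


#: Column order used everywhere phenological features appear in a table.
PHENO_FEATURE_NAMES = ("SOS", "EOS", "MV", "BV", "ROI", "ROD")


def _crossing(f, lo: float, hi: float, level: float, ascending: bool, tol: float = 0.1) -> float:
    """Bisect f(t) = level on [lo, hi] where f is monotone, to `tol` days."""
    a, b = lo, hi
    while b - a > tol:
        m = 0.5 * (a + b)
        if (f(m) < level) == ascending:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def extract_pheno_metrics(
    fit: DoubleLogisticFit,
    threshold: float = 0.5,
    rate_band: tuple[float, float] = (0.2, 0.8),
) -> PhenoMetrics:
    """Extract BV, MV, SOS, EOS, ROI, ROD from a converged fit.

    BV/MV are the curve extrema on a daily grid over days 1..365.  SOS is
    the earliest ascending-limb day where the curve reaches
    BV + threshold*(MV - BV); EOS the latest such descending-limb day.
    ROI and ROD are secant slopes between the ``rate_band`` amplitude
    crossings on each limb; crossings are refined by bisection to 0.1 d.

    Raises :class:`UnfitPixelError` when a required level is never
    crossed inside the year (e.g. a truncated or flat season).
    """
    if not fit.converged:
        raise UnfitPixelError(f"metrics require a converged fit (flag={fit.flag})")
    lo_frac, hi_frac = rate_band
    if not 0.0 < lo_frac < hi_frac < 1.0:
        raise ValueError("rate_band fractions must satisfy 0 < lo < hi < 1")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")

    grid = np.arange(1.0, 366.0)
    curve = dl_evaluate(grid, fit)
    i_max = int(np.argmax(curve))
    bv = float(curve.min())
    mv = float(curve.max())
    if mv - bv <= 0:
        raise UnfitPixelError("flat curve: amplitude is zero")

    f = lambda t: float(dl_evaluate(t, fit))

    def ascending_crossing(frac: float) -> float:
        level = bv + frac * (mv - bv)
        idx = np.nonzero(curve[: i_max + 1] >= level)[0]
        if idx.size == 0 or idx[0] == 0:
            raise UnfitPixelError(f"{frac:.0%} level not crossed on ascending limb")
        j = int(idx[0])
        return _crossing(f, grid[j - 1], grid[j], level, ascending=True)

    def descending_crossing(frac: float) -> float:
        level = bv + frac * (mv - bv)
        tail = curve[i_max:]
        idx = np.nonzero(tail >= level)[0]
        if idx.size == 0 or idx[-1] == tail.size - 1:
            raise UnfitPixelError(f"{frac:.0%} level not crossed on descending limb")
        j = i_max + int(idx[-1])
        return _crossing(f, grid[j], grid[j + 1], level, ascending=False)

    sos = ascending_crossing(threshold)
    eos = descending_crossing(threshold)
    t20_up = ascending_crossing(lo_frac)
    t80_up = ascending_crossing(hi_frac)
    t80_dn = descending_crossing(hi_frac)
    t20_dn = descending_crossing(lo_frac)

    roi = (f(t80_up) - f(t20_up)) / (t80_up - t20_up)
    rod = abs(f(t80_dn) - f(t20_dn)) / (t20_dn - t80_dn)
    return PhenoMetrics(bv=bv, mv=mv, sos=sos, eos=eos, roi=float(roi), rod=float(rod))


def fit_and_extract(
    series: ObservationSeries, threshold: float = 0.5
) -> tuple[DoubleLogisticFit, PhenoMetrics | None]:
    """Convenience: fit a filtered series and extract metrics if possible."""
    fit = fit_double_logistic(series)
    if not fit.converged:
        return fit, None
    try:
        return fit, extract_pheno_metrics(fit, threshold=threshold)
    except UnfitPixelError:
        return fit, None
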