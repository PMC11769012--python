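"""Synthetic salt-marsh scene generator.

Builds gridded optical and SAR time-series stacks plus labeled sample
points with the statistical structure the downstream analysis assumes:

* four classes — *Phragmites australis* (PA), *Suaeda salsa* (SS),
  *Tamarix chinensis* (TC) and bare tidal flat (TF) — laid out in
  contiguous blocks or random patches;
* per-class unimodal annual NDVI trajectories (double-logistic shape)
  observed on an irregular optical acquisition calendar, with Gaussian
  noise, Bernoulli cloud gaps, and sporadic tidal inundation events that
  depress NDVI and raise MNDWI above the water threshold inside a
  shoreline band;
* per-class seasonal VV/VH backscatter (dB) sampled on a dense SAR
  calendar, with the cross-polarization gap ordered PA ≈ TC > SS > TF
  and a June peak in the TC polarization difference.

Default class parameters encode the study system's reported phenology
(PA season ≈ days 150-300 peaking near NDVI 0.72; TC ≈ 180-320 peaking
near 0.80; SS ≈ 200-260 peaking near 0.20; tidal flat nearly flat at
low NDVI).  All SAR dB levels are qualitative emulations — the
underlying study reports no numeric backscatter tables.

Everything is deterministic given ``SceneConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SampleShortageError
from .phenology import double_logistic
from .sar import month_of_doy

#: Class-code convention used across the pipeline (0 = nodata/excluded).
CLASS_CODES = {"PA": 1, "SS": 2, "TC": 3, "TF": 4}
CLASS_NAMES = {
    "PA": "Phragmites australis",
    "SS": "Suaeda salsa",
    "TC": "Tamarix chinensis",
    "TF": "tidal flat",
}
NODATA_CODE = 0

# Sentinel-2-like acquisition calendar: day-of-year, non-leap, ~36-39
# usable scenes spread over the year with a winter/summer imbalance.
DEFAULT_OPTICAL_DATES = (
    2, 12, 17, 22, 57, 76, 81, 86, 96, 101, 111, 121, 126, 141,
    156, 171, 191, 196, 201, 216, 226, 231, 237, 242, 251, 257,
    261, 272, 291, 296, 301, 306, 311, 326, 329, 331, 351, 356, 361,
)

# Sentinel-1-like calendar: 44 acquisitions evenly covering all 12 months.
DEFAULT_SAR_DATES = tuple(int(d) for d in np.round(np.linspace(6.0, 360.0, 44)))


@dataclass(frozen=True)
class ClassPhenoProfile:
    """Parameters of one class's annual NDVI trajectory."""

    class_label: str
    sos_day: float
    eos_day: float
    mv: float
    bv: float
    green_up_scale: float = 10.0
    senescence_scale: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.sos_day < self.eos_day <= 365:
            raise ConfigError(f"{self.class_label}: need 1 <= sos < eos <= 365")
        if not 0 <= self.bv < self.mv <= 1:
            raise ConfigError(f"{self.class_label}: need 0 <= bv < mv <= 1")
        if self.green_up_scale <= 0 or self.senescence_scale <= 0:
            raise ConfigError(f"{self.class_label}: logistic scales must be > 0")
        if self.noise_sd < 0:
            raise ConfigError(f"{self.class_label}: noise_sd must be >= 0")

    def ndvi_curve(self, days) -> np.ndarray:
        """Noise-free NDVI at the given days.

        The double-logistic basis is rescaled so the curve's annual
        minimum and maximum equal ``bv`` and ``mv`` exactly.
        """
        grid = np.arange(1.0, 366.0)
        g_grid = double_logistic(grid, self.sos_day, self.green_up_scale,
                                 self.eos_day, self.senescence_scale)
        g = double_logistic(np.asarray(days, dtype=float), self.sos_day,
                            self.green_up_scale, self.eos_day, self.senescence_scale)
        g_min, g_max = g_grid.min(), g_grid.max()
        return self.bv + (self.mv - self.bv) * (g - g_min) / (g_max - g_min)


@dataclass(frozen=True)
class ClassSarProfile:
    """Monthly expected VV/VH backscatter (dB) for one class."""

    class_label: str
    monthly_vv_db: tuple
    monthly_vh_db: tuple
    noise_sd_db: float = 0.0

    def __post_init__(self) -> None:
        if len(self.monthly_vv_db) != 12 or len(self.monthly_vh_db) != 12:
            raise ConfigError(f"{self.class_label}: need exactly 12 monthly values per polarization")
        if self.noise_sd_db < 0:
            raise ConfigError(f"{self.class_label}: noise_sd_db must be >= 0")


@dataclass(frozen=True)
class TideModel:
    """Bernoulli tidal-inundation model over a shoreline band.

    The rightmost ``shore_cols`` columns of the grid form the shoreline
    band; each optical acquisition there is flooded with probability
    ``shore_prob`` (``inland_prob`` elsewhere).  A flooded observation's
    NDVI is replaced by ``inundated_ndvi`` and its MNDWI raised above
    the water threshold (``inundated_mndwi`` > -0.1 so the filter trips).
    """

    shore_prob: float = 0.85
    inland_prob: float = 0.08
    shore_cols: int = 4
    inundated_ndvi: float = 0.02
    inundated_mndwi: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.shore_prob, self.inland_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("inundation probabilities must be in [0, 1]")
        if self.inundated_mndwi <= -0.1:
            raise ConfigError("inundated_mndwi must exceed -0.1 to trip the tidal filter")

    def prob_map(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        probs = np.full((rows, cols), self.inland_prob)
        if self.shore_cols > 0:
            probs[:, max(cols - self.shore_cols, 0):] = self.shore_prob
        return probs


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, calendars and stochastic settings of a synthetic scene."""

    grid_shape: tuple[int, int] = (24, 24)
    optical_dates: tuple = DEFAULT_OPTICAL_DATES
    sar_dates: tuple = DEFAULT_SAR_DATES
    classes: tuple = ("PA", "SS", "TC", "TF")
    class_layout: str = "blocks"
    cloud_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ConfigError(f"grid_shape must be positive, got {self.grid_shape}")
        for name, dates in (("optical_dates", self.optical_dates), ("sar_dates", self.sar_dates)):
            arr = np.asarray(dates, dtype=float)
            if arr.size == 0 or arr[0] < 1 or arr[-1] > 365 or np.any(np.diff(arr) <= 0):
                raise ConfigError(f"{name} must be strictly increasing within [1, 365]")
        if len(self.classes) < 2:
            raise ConfigError("at least 2 classes are required")
        if self.class_layout not in ("blocks", "random"):
            raise ConfigError(f"unknown class_layout {self.class_layout!r}")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ConfigError("cloud_prob must be in [0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        """Named deterministic substream for one generation stage."""
        tag = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng([self.seed, tag])


@dataclass(frozen=True)
class OpticalStack:
    """Dated reflectance stack (green/red/nir/swir1) with a validity mask.

    Arrays are shaped (n_dates, rows, cols); ``valid`` is False for
    cloud-masked observations.
    """

    dates: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir1: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape[1:]

    def ndvi(self) -> np.ndarray:
        return (self.nir - self.red) / (self.nir + self.red)

    def mndwi(self) -> np.ndarray:
        return (self.green - self.swir1) / (self.green + self.swir1)


@dataclass(frozen=True)
class SarStack:
    """Dated dual-polarization backscatter stack in dB, (n_dates, rows, cols)."""

    dates: np.ndarray
    vv_db: np.ndarray
    vh_db: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.vv_db.shape[1:]


def default_pheno_profiles(noise_sd: float = 0.03) -> dict[str, ClassPhenoProfile]:
    """Class NDVI profiles matching the study system's reported phenology."""
    return {
        "PA": ClassPhenoProfile("PA", sos_day=150, eos_day=300, mv=0.72, bv=0.10,
                                green_up_scale=8.0, senescence_scale=7.0, noise_sd=noise_sd),
        "TC": ClassPhenoProfile("TC", sos_day=180, eos_day=320, mv=0.80, bv=0.12,
                                green_up_scale=12.0, senescence_scale=18.0, noise_sd=noise_sd),
        "SS": ClassPhenoProfile("SS", sos_day=200, eos_day=260, mv=0.20, bv=0.05,
                                green_up_scale=6.0, senescence_scale=6.0, noise_sd=noise_sd),
        # near-flat low-NDVI flat; weak seasonality keeps the curve fittable
        "TF": ClassPhenoProfile("TF", sos_day=170, eos_day=260, mv=0.10, bv=0.03,
                                green_up_scale=10.0, senescence_scale=10.0, noise_sd=noise_sd),
    }


def _sar_profile(label, vv, diff, noise):
    vh = tuple(v - d for v, d in zip(vv, diff))
    return ClassSarProfile(label, tuple(vv), vh, noise)


def default_sar_profiles(noise_sd_db: float = 0.7) -> dict[str, ClassSarProfile]:
    """Qualitative monthly VV/VH tables: PA ≈ TC > SS > TF in VV-VH, TC peaks in June."""
    return {
        "PA": _sar_profile(
            "PA",
            (-11.5, -11.4, -11.2, -11.0, -10.8, -10.6, -10.5, -10.4, -10.3, -10.4, -10.9, -11.3),
            (7.2, 7.2, 7.3, 7.4, 7.5, 7.6, 7.7, 8.1, 8.4, 8.5, 7.8, 7.4),
            noise_sd_db,
        ),
        "TC": _sar_profile(
            "TC",
            (-12.5, -12.4, -12.2, -11.8, -11.4, -11.0, -11.2, -11.5, -11.9, -12.1, -12.3, -12.4),
            (6.4, 6.5, 6.7, 7.2, 8.2, 9.4, 8.8, 8.0, 7.2, 6.8, 6.6, 6.4),
            noise_sd_db,
        ),
        "SS": _sar_profile(
            "SS",
            (-14.5, -14.4, -14.3, -14.2, -14.0, -13.8, -13.7, -13.8, -14.0, -14.2, -14.3, -14.4),
            (3.6, 3.5, 3.6, 3.7, 3.9, 4.1, 4.2, 4.1, 3.9, 3.7, 3.6, 3.5),
            noise_sd_db,
        ),
        "TF": _sar_profile(
            "TF",
            (-15.5, -15.4, -15.5, -15.6, -15.5, -15.4, -15.5, -15.6, -15.5, -15.4, -15.5, -15.6),
            (2.1, 2.0, 2.1, 2.2, 2.1, 2.0, 2.1, 2.2, 2.1, 2.0, 2.1, 2.2),
            noise_sd_db,
        ),
    }


def generate_class_map(config: SceneConfig) -> np.ndarray:
    """Assign a class code to every grid cell.

    ``blocks`` splits the flattened grid into contiguous near-equal
    chunks (a 2x2 grid with 4 classes gets one cell each); ``random``
    scatters codes uniformly while guaranteeing every class at least one
    cell.  Deterministic given the config seed.
    """
    rows, cols = config.grid_shape
    n = rows * cols
    codes = [CLASS_CODES[c] for c in config.classes]
    if len(codes) > n:
        raise ConfigError(f"{len(codes)} classes cannot fit a {rows}x{cols} grid")
    flat = np.empty(n, dtype=np.uint8)
    if config.class_layout == "blocks":
        for chunk, code in zip(np.array_split(np.arange(n), len(codes)), codes):
            flat[chunk] = code
    else:
        rng = config.rng("class_map")
        flat[:] = rng.choice(codes, size=n)
        missing = [c for c in codes if c not in flat]
        if missing:
            spots = rng.choice(n, size=len(missing), replace=False)
            flat[spots] = missing
    return flat.reshape(rows, cols)


# Reflectance synthesis: NDVI and MNDWI are inverted into band pairs with a
# fixed band sum so the indices round-trip exactly.
_NDVI_BAND_SUM = 0.3
_DRY_GREEN, _DRY_SWIR1 = 0.10, 0.30  # MNDWI = -0.5, safely below the water threshold


def generate_optical_stack(
    config: SceneConfig,
    profiles: dict[str, ClassPhenoProfile],
    tide: TideModel,
    labels: np.ndarray,
) -> OpticalStack:
    """Simulate the dated reflectance stack for a labeled grid.

    Each pixel follows its class's double-logistic NDVI curve plus
    Gaussian noise; flooded observations (Bernoulli per acquisition,
    shoreline-banded probability) get NDVI ≈ ``tide.inundated_ndvi`` and
    MNDWI above the water threshold; cloudy observations are flagged
    invalid.
    """
    _check_profiles(labels, profiles)
    dates = np.asarray(config.optical_dates, dtype=float)
    rows, cols = labels.shape
    nt = dates.size
    rng = config.rng("optical")

    ndvi = np.empty((nt, rows, cols))
    for short, profile in profiles.items():
        mask = labels == CLASS_CODES[short]
        if not mask.any():
            continue
        curve = profile.ndvi_curve(dates)  # (nt,)
        vals = curve[:, None] + profile.noise_sd * rng.standard_normal((nt, int(mask.sum())))
        ndvi[:, mask] = vals

    flooded = rng.random((nt, rows, cols)) < tide.prob_map((rows, cols))[None, :, :]
    if flooded.any():
        water_noise = 0.01 * rng.standard_normal(int(flooded.sum()))
        ndvi[flooded] = tide.inundated_ndvi + water_noise
    ndvi = np.clip(ndvi, -0.99, 0.99)

    red = 0.5 * _NDVI_BAND_SUM * (1.0 - ndvi)
    nir = 0.5 * _NDVI_BAND_SUM * (1.0 + ndvi)

    green = np.full_like(ndvi, _DRY_GREEN)
    swir1 = np.full_like(ndvi, _DRY_SWIR1)
    mndwi_target = tide.inundated_mndwi
    band_sum = _DRY_GREEN + _DRY_SWIR1
    green[flooded] = 0.5 * band_sum * (1.0 + mndwi_target)
    swir1[flooded] = 0.5 * band_sum * (1.0 - mndwi_target)

    valid = rng.random((nt, rows, cols)) >= config.cloud_prob
    return OpticalStack(dates=dates, green=green, red=red, nir=nir, swir1=swir1, valid=valid)


def generate_sar_stack(
    config: SceneConfig,
    profiles: dict[str, ClassSarProfile],
    labels: np.ndarray,
) -> SarStack:
    """Simulate the dated VV/VH stack: monthly class value + Gaussian noise (dB)."""
    _check_profiles(labels, profiles)
    dates = np.asarray(config.sar_dates, dtype=float)
    months = month_of_doy(dates)  # validates the date range
    rows, cols = labels.shape
    nt = dates.size
    rng = config.rng("sar")

    vv = np.empty((nt, rows, cols))
    vh = np.empty((nt, rows, cols))
    for short, profile in profiles.items():
        mask = labels == CLASS_CODES[short]
        if not mask.any():
            continue
        npx = int(mask.sum())
        vv_mean = np.asarray(profile.monthly_vv_db)[months - 1]
        vh_mean = np.asarray(profile.monthly_vh_db)[months - 1]
        vv[:, mask] = vv_mean[:, None] + profile.noise_sd_db * rng.standard_normal((nt, npx))
        vh[:, mask] = vh_mean[:, None] + profile.noise_sd_db * rng.standard_normal((nt, npx))
    return SarStack(dates=dates, vv_db=vv, vh_db=vh)


def generate_samples(
    labels: np.ndarray,
    n_per_class: int,
    seed: int,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a stratified sample of pixels without replacement.

    Returns a DataFrame with columns (row, col, class_code), ``n_per_class``
    rows per class present in ``labels`` (optionally restricted to
    ``mask``).  Raises :class:`SampleShortageError` when a class is too
    small.
    """
    rng = np.random.default_rng([int(seed), 0x5A3])
    eligible = np.ones(labels.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    out = []
    for code in sorted(int(c) for c in np.unique(labels) if c != NODATA_CODE):
        rr, cc = np.nonzero((labels == code) & eligible)
        if rr.size < n_per_class:
            raise SampleShortageError(
                f"class {code}: requested {n_per_class} samples from {rr.size} pixels"
            )
        pick = rng.choice(rr.size, size=n_per_class, replace=False)
        out.append(pd.DataFrame({"row": rr[pick], "col": cc[pick], "class_code": code}))
    if not out:
        return pd.DataFrame(columns=["row", "col", "class_code"])
    return pd.concat(out, ignore_index=True)


def _check_profiles(labels: np.ndarray, profiles: dict) -> None:
    have = {CLASS_CODES[k] for k in profiles}
    present = {int(c) for c in np.unique(labels) if c != NODATA_CODE}
    missing = present - have
    if missing:
        raise ConfigError(f"no profile for class code(s) {sorted(missing)}")


def generate_scene(
    config: SceneConfig,
    pheno_profiles: dict[str, ClassPhenoProfile] | None = None,
    sar_profiles: dict[str, ClassSarProfile] | None = None,
    tide: TideModel | None = None,
):
    """Generate labels, optical stack and SAR stack in one call."""
    pheno_profiles = pheno_profiles or default_pheno_profiles()
    sar_profiles = sar_profiles or default_sar_profiles()
    tide = tide if tide is not None else TideModel()
    labels = generate_class_map(config)
    optical = generate_optical_stack(config, pheno_profiles, tide, labels)
    sar = generate_sar_stack(config, sar_profiles, labels)
    return labels, optical, sar
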