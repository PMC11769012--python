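"""Raster stack I/O: multi-band TIFF with a CSV date sidecar.

A :class:`DatedStack` is a (bands, rows, cols) array where each band is
one (variable, acquisition-day) pair.  The sidecar CSV has columns
``band_index, day_of_year, variable`` and one row per band; reading
validates that its row count matches the TIFF band count.  NaN is the
nodata value for float stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .synthetic import OpticalStack, SarStack

_OPTICAL_VARS = ("green", "red", "nir", "swir1", "valid")
_SAR_VARS = ("vv_db", "vh_db")


@dataclass(frozen=True)
class DatedStack:
    """Raster stack with per-band acquisition day and variable name."""

    data: np.ndarray
    days: np.ndarray
    variables: tuple

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        days = np.asarray(self.days, dtype=float)
        if data.ndim != 3:
            raise SchemaError("stack data must be (bands, rows, cols)")
        if not (data.shape[0] == days.size == len(self.variables)):
            raise SchemaError("band count, days and variables must agree")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "variables", tuple(self.variables))

    def select(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """(days, data) of all bands carrying one variable, in date order."""
        idx = [i for i, v in enumerate(self.variables) if v == variable]
        if not idx:
            raise SchemaError(f"variable {variable!r} not in stack")
        order = np.argsort(self.days[idx], kind="stable")
        idx = [idx[i] for i in order]
        return self.days[idx], self.data[idx]


def write_stack(stack: DatedStack, path, sidecar_path=None) -> Path:
    """Write the TIFF plus its CSV sidecar (default: path with .csv suffix)."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".csv")
    tifffile.imwrite(path, np.asarray(stack.data, dtype=np.float32), photometric="minisblack")
    pd.DataFrame(
        {
            "band_index": np.arange(stack.data.shape[0]),
            "day_of_year": stack.days,
            "variable": stack.variables,
        }
    ).to_csv(sidecar_path, index=False)
    return path


def read_stack(path, sidecar_path=None) -> DatedStack:
    """Read a TIFF + sidecar pair back into a :class:`DatedStack`."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".csv")
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    sidecar = pd.read_csv(sidecar_path)
    required = {"band_index", "day_of_year", "variable"}
    if not required.issubset(sidecar.columns):
        raise SchemaError(f"sidecar must have columns {sorted(required)}")
    if len(sidecar) != data.shape[0]:
        raise SchemaError(
            f"sidecar has {len(sidecar)} rows but TIFF has {data.shape[0]} bands"
        )
    sidecar = sidecar.sort_values("band_index")
    if not np.array_equal(sidecar["band_index"].to_numpy(), np.arange(data.shape[0])):
        missing = sorted(set(range(data.shape[0])) - set(sidecar["band_index"]))
        raise SchemaError(f"sidecar band_index mismatch; first missing: {missing[:1]}")
    return DatedStack(
        data=data.astype(float),
        days=sidecar["day_of_year"].to_numpy(dtype=float),
        variables=tuple(sidecar["variable"]),
    )


def optical_to_stack(optical: OpticalStack) -> DatedStack:
    """Flatten an optical stack to one band per (variable, date)."""
    arrays = {
        "green": optical.green, "red": optical.red, "nir": optical.nir,
        "swir1": optical.swir1, "valid": optical.valid.astype(float),
    }
    data = np.concatenate([arrays[v] for v in _OPTICAL_VARS], axis=0)
    days = np.concatenate([optical.dates] * len(_OPTICAL_VARS))
    variables = tuple(v for v in _OPTICAL_VARS for _ in optical.dates)
    return DatedStack(data=data, days=days, variables=variables)


def stack_to_optical(stack: DatedStack) -> OpticalStack:
    parts = {v: stack.select(v) for v in _OPTICAL_VARS}
    days = parts["green"][0]
    for v in _OPTICAL_VARS:
        if not np.array_equal(parts[v][0], days):
            raise SchemaError(f"variable {v!r} has a different acquisition calendar")
    return OpticalStack(
        dates=days,
        green=parts["green"][1],
        red=parts["red"][1],
        nir=parts["nir"][1],
        swir1=parts["swir1"][1],
        valid=parts["valid"][1] > 0.5,
    )


def sar_to_stack(sar: SarStack) -> DatedStack:
    data = np.concatenate([sar.vv_db, sar.vh_db], axis=0)
    days = np.concatenate([sar.dates, sar.dates])
    variables = tuple(v for v in _SAR_VARS for _ in sar.dates)
    return DatedStack(data=data, days=days, variables=variables)


def stack_to_sar(stack: DatedStack) -> SarStack:
    days_vv, vv = stack.select("vv_db")
    days_vh, vh = stack.select("vh_db")
    if not np.array_equal(days_vv, days_vh):
        raise SchemaError("VV and VH acquisition calendars differ")
    return SarStack(dates=days_vv, vv_db=vv, vh_db=vh)


def write_class_map(labels: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8), photometric="minisblack")
    return path


def read_class_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.uint8)


def write_feature_stack(stack: np.ndarray, names, path) -> Path:
    """Write a named feature raster (e.g. 6-band phenology, 24-band SAR)."""
    if stack.shape[0] != len(tuple(names)):
        raise SchemaError("feature count must match names")
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")
    pd.DataFrame(
        {"band_index": np.arange(stack.shape[0]), "day_of_year": np.nan, "variable": tuple(names)}
    ).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_feature_stack(path, expected_names=None) -> np.ndarray:
    stack = read_stack(path)
    if expected_names is not None and stack.variables != tuple(expected_names):
        raise SchemaError("feature band names do not match the expected layout")
    return stack.data
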