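"""Average-to-extreme climate corrections.

Expert tolerance limits are stated as climatic extremes (the 20th-percentile
annual precipitation at the driest station; the record January minimum
temperature), while gridded climatologies are multi-decadal averages.  To
compare the two, a linear gain/offset model ``extreme = gain * average +
offset`` is fitted on calibration time series and applied grid-wide:

* minimum precipitation — calibrated on per-location annual-precipitation
  year series (20th percentile vs mean of the same series);
* minimum temperature — calibrated on station daily January minima (record
  minimum vs long-term mean), with corrected values capped below at -60 C,
  roughly the coldest temperature ever measured in the USA;
* maximum precipitation — expert values are themselves station means, so an
  explicit identity (no-op) model is used.

Corrected precipitation is floored at 0 mm (a physical constraint), with
the number of floored values reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ClimateGrid

__all__ = [
    "CorrectionModel",
    "ExtremeSeriesSummary",
    "MIN_TEMP_CAP_C",
    "summarize_precip_series",
    "summarize_temp_stations",
    "sample_calibration_points",
    "fit_correction",
    "identity_correction",
    "apply_correction",
    "apply_correction_to_grid",
    "save_models",
    "load_models",
]

#: Lower bound for corrected minimum temperature, in degrees Celsius.
MIN_TEMP_CAP_C = -60.0

#: Quantile defining "minimum precipitation" tolerance (driest-station 20th
#: percentile of annual totals).
PRECIP_EXTREME_QUANTILE = 0.20

MIN_YEARS_PER_LOCATION = 5
MIN_DAYS_PER_STATION = 5

CORRECTABLE_VARIABLES = ("min_precip", "min_temp", "max_precip")


@dataclass(frozen=True)
class ExtremeSeriesSummary:
    """One calibration pair: a location's average and extreme value."""

    location_id: str
    average: float
    extreme: float


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted (or identity) linear map from average to extreme climate."""

    variable: str
    gain: float
    offset: float
    n_points: int = 0
    fit_r2: float = float("nan")
    cap: float | None = None
    identity_flag: bool = False

    def __post_init__(self) -> None:
        if self.variable not in CORRECTABLE_VARIABLES:
            raise ValueError(f"unknown correction variable {self.variable!r}")
        if self.identity_flag and not (
            self.gain == 1.0 and self.offset == 0.0 and self.cap is None
        ):
            raise ValueError("identity model must have gain=1, offset=0, no cap")
        if not self.identity_flag and self.n_points < 2:
            raise ValueError("fitted model needs at least 2 calibration points")


def identity_correction(variable: str = "max_precip") -> CorrectionModel:
    """The explicit no-op model (used for maximum precipitation)."""
    return CorrectionModel(variable, gain=1.0, offset=0.0, n_points=0,
                           fit_r2=float("nan"), cap=None, identity_flag=True)


# ----------------------------------------------------------------------
# Calibration-series summaries
# ----------------------------------------------------------------------

def summarize_precip_series(series: pd.DataFrame) -> list[ExtremeSeriesSummary]:
    """Per-location 20th-percentile and mean annual precipitation.

    ``series`` has columns ``location_id, year, annual_precip_mm`` (extra
    columns such as lat/lon are ignored).  The extreme is the linearly
    interpolated 20th percentile of the location's annual totals; locations
    with fewer than 5 years are dropped with a warning.
    """
    need = {"location_id", "year", "annual_precip_mm"}
    if not need <= set(series.columns):
        raise ValueError(f"precip series must have columns {sorted(need)}")
    out: list[ExtremeSeriesSummary] = []
    dropped = 0
    for loc, grp in series.groupby("location_id", sort=True):
        vals = grp["annual_precip_mm"].to_numpy(dtype=float)
        if len(vals) < MIN_YEARS_PER_LOCATION:
            dropped += 1
            continue
        out.append(ExtremeSeriesSummary(
            str(loc),
            average=float(np.mean(vals)),
            extreme=float(np.quantile(vals, PRECIP_EXTREME_QUANTILE)),
        ))
    if dropped:
        warnings.warn(f"dropped {dropped} location(s) with < "
                      f"{MIN_YEARS_PER_LOCATION} years", stacklevel=2)
    return out


def summarize_temp_stations(daily: pd.DataFrame) -> list[ExtremeSeriesSummary]:
    """Per-station record minimum and mean of daily January minima.

    ``daily`` has columns ``station_id, tmin_c`` (``date`` and coordinates
    optional).  Stations with fewer than 5 daily values are dropped.
    """
    need = {"station_id", "tmin_c"}
    if not need <= set(daily.columns):
        raise ValueError(f"station series must have columns {sorted(need)}")
    out: list[ExtremeSeriesSummary] = []
    dropped = 0
    for sid, grp in daily.groupby("station_id", sort=True):
        vals = grp["tmin_c"].to_numpy(dtype=float)
        if len(vals) < MIN_DAYS_PER_STATION:
            dropped += 1
            continue
        out.append(ExtremeSeriesSummary(
            str(sid), average=float(np.mean(vals)), extreme=float(np.min(vals))
        ))
    if dropped:
        warnings.warn(f"dropped {dropped} station(s) with < "
                      f"{MIN_DAYS_PER_STATION} daily values", stacklevel=2)
    return out


# ----------------------------------------------------------------------
# Calibration point sampling
# ----------------------------------------------------------------------

def sample_calibration_points(
    grid: ClimateGrid,
    n: int = 50_000,
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Uniform random points over the non-NoData cells of ``grid``.

    Cells are drawn uniformly (restricted to ``mask`` if given) and each
    point is placed uniformly within its cell, so every point lands on a
    valid cell by construction.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    valid = ~grid.mask
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise ValueError("mask selects no valid cells")
    pick = rng.integers(0, rows.size, size=n)
    u = rng.random(n)
    v = rng.random(n)
    cs = grid.cellsize
    lons = grid.xllcorner + (cols[pick] + u) * cs
    lats = grid.ytopcorner - (rows[pick] + v) * cs
    return list(zip(lons.tolist(), lats.tolist()))


# ----------------------------------------------------------------------
# Fit and apply
# ----------------------------------------------------------------------

def fit_correction(
    pairs: Sequence[ExtremeSeriesSummary],
    variable: str,
) -> CorrectionModel:
    """Ordinary least squares of extreme on average.

    Returns a :class:`CorrectionModel` with the fitted gain (slope), offset
    (intercept) and R^2; the -60 C cap is attached for ``min_temp``.
    """
    if variable == "max_precip":
        raise ValueError("max_precip uses identity_correction(), not a fit")
    avg = np.array([p.average for p in pairs], dtype=float)
    ext = np.array([p.extreme for p in pairs], dtype=float)
    if len(avg) < 2:
        raise ValueError("need at least 2 calibration pairs")
    if np.ptp(avg) == 0:
        raise ValueError("degenerate design: all average values identical")
    res = stats.linregress(avg, ext)
    return CorrectionModel(
        variable=variable,
        gain=float(res.slope),
        offset=float(res.intercept),
        n_points=len(avg),
        fit_r2=float(res.rvalue**2),
        cap=MIN_TEMP_CAP_C if variable == "min_temp" else None,
    )


def apply_correction(model: CorrectionModel, values) -> np.ndarray | float:
    """``gain * v + offset``, then the cap (values below it report the cap).

    The identity model returns its input unchanged.  Corrected minimum
    precipitation is additionally floored at 0 by
    :func:`apply_correction_to_grid` / the niche-estimation stage, not here,
    so the pure linear map stays testable.
    """
    arr = np.asarray(values, dtype=float)
    scalar = arr.ndim == 0
    if model.identity_flag:
        out = arr.copy()
    else:
        out = model.gain * arr + model.offset
        if model.cap is not None:
            out = np.maximum(out, model.cap)
    return float(out) if scalar else out


def apply_correction_to_grid(model: CorrectionModel, grid: ClimateGrid,
                             variable: str | None = None) -> ClimateGrid:
    """Apply a correction cell-wise, preserving NoData.

    For precipitation variables, corrected values below 0 mm are floored at
    0 and the count is reported with a warning.
    """
    mask = grid.mask
    corrected = apply_correction(model, grid.values)
    if model.variable in ("min_precip", "max_precip"):
        neg = (~mask) & (corrected < 0)
        if neg.any():
            warnings.warn(f"floored {int(neg.sum())} negative corrected "
                          "precipitation cell(s) at 0", stacklevel=2)
            corrected = np.where(neg, 0.0, corrected)
    values = np.where(mask, grid.nodata, corrected)
    return ClimateGrid(variable or grid.variable, values, grid.xllcorner,
                       grid.yllcorner, grid.cellsize, grid.nodata, grid.crs)


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def save_models(models: Iterable[CorrectionModel], path: str | Path) -> Path:
    path = Path(path)
    payload = [asdict(m) for m in models]
    for m in payload:
        if isinstance(m["fit_r2"], float) and np.isnan(m["fit_r2"]):
            m["fit_r2"] = None
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_models(path: str | Path) -> list[CorrectionModel]:
    payload = json.loads(Path(path).read_text())
    models = []
    for m in payload:
        if m.get("fit_r2") is None:
            m["fit_r2"] = float("nan")
        models.append(CorrectionModel(**m))
    return models
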