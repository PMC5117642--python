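"""Occurrence-based climatic niche estimation.

Per species: filter occurrence records (region clip, duplicate removal,
minimum-record rule), attach corrected climate values extracted from the
grids, compute niche limits in two flavours — percentile-trimmed (trimming
the most extreme 5% of values in the direction of the limit, robust to
inaccurate outliers) and absolute (true min/max) — and compute range size
as the spherical area of the convex hull of the records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .correction import CorrectionModel, apply_correction, identity_correction
from .grids import ClimateGrid, extract_at_points

__all__ = [
    "EARTH_RADIUS_KM",
    "MIN_RECORDS",
    "FilterReport",
    "NicheEstimate",
    "filter_occurrences",
    "climate_at_occurrences",
    "niche_limits",
    "convex_hull_vertices",
    "range_size",
    "estimate_niches",
    "NICHE_COLUMNS",
]

EARTH_RADIUS_KM = 6371.0088

#: A species needs at least this many surviving records to be analysed
#: (species with five or fewer records are excluded).
MIN_RECORDS = 6

#: Variables with a lower-tail niche limit; max_precip has an upper-tail one.
LOWER_TAIL_VARIABLES = ("min_precip", "min_temp")
UPPER_TAIL_VARIABLES = ("max_precip",)
NICHE_VARIABLES = LOWER_TAIL_VARIABLES + UPPER_TAIL_VARIABLES

NICHE_COLUMNS = [
    "species", "n_records_raw", "n_records_used",
    "min_precip_mm_trim", "min_precip_mm_abs",
    "max_precip_mm_trim", "max_precip_mm_abs",
    "min_temp_c_trim", "min_temp_c_abs",
    "range_area_km2",
]


@dataclass
class FilterReport:
    """Record-conservation accounting for one filtering pass."""

    n_raw: int
    n_out_of_region: int
    n_duplicates: int
    n_missing_climate: int
    n_in_excluded_species: int
    n_used: int

    def reconciles(self) -> bool:
        return self.n_raw == (self.n_out_of_region + self.n_duplicates
                              + self.n_missing_climate
                              + self.n_in_excluded_species + self.n_used)


@dataclass
class NicheEstimate:
    """Empirical niche limits and range size for one species."""

    species: str
    n_records_raw: int
    n_records_used: int
    limits_trimmed: dict[str, float]
    limits_absolute: dict[str, float]
    range_area_km2: float


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

def _in_region(df: pd.DataFrame, region_mask) -> np.ndarray:
    if region_mask is None:
        return np.ones(len(df), dtype=bool)
    if isinstance(region_mask, ClimateGrid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # misses here ARE the clip
            vals = extract_at_points(region_mask,
                                     df[["lon", "lat"]].itertuples(index=False))
        return np.array([v is not None for v in vals])
    # shapely geometry (e.g. loaded from a GeoJSON polygon)
    from shapely.geometry import Point

    return np.array([region_mask.covers(Point(lon, lat))
                     for lon, lat in df[["lon", "lat"]].itertuples(index=False)])


def filter_occurrences(
    table: pd.DataFrame,
    region_mask=None,
    min_records: int = MIN_RECORDS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Region clip, duplicate removal and the minimum-record rule.

    ``region_mask`` may be None (keep all), a :class:`ClimateGrid` (inside =
    non-NoData cell) or a shapely geometry.  Exact duplicate rows are
    presumed database duplicates and dropped.  Species with fewer than
    ``min_records`` surviving records are removed entirely.  Returns the
    filtered table and a :class:`FilterReport`; per-species survivor counts
    are ``filtered.groupby("species").size()``.
    """
    n_raw = len(table)
    inside = _in_region(table, region_mask)
    clipped = table.loc[inside]
    n_out = n_raw - len(clipped)

    deduped = clipped.drop_duplicates(subset=["species", "lon", "lat"])
    n_dup = len(clipped) - len(deduped)
    if n_dup:
        warnings.warn(f"dropped {n_dup} exact duplicate record(s)", stacklevel=2)

    counts = deduped.groupby("species")["species"].transform("size")
    kept = deduped.loc[counts >= min_records].reset_index(drop=True)
    n_excluded = len(deduped) - len(kept)

    report = FilterReport(
        n_raw=n_raw, n_out_of_region=n_out, n_duplicates=n_dup,
        n_missing_climate=0, n_in_excluded_species=n_excluded,
        n_used=len(kept),
    )
    if len(kept) == 0:
        warnings.warn("no records survive filtering", stacklevel=2)
    return kept, report


# ----------------------------------------------------------------------
# Climate attachment
# ----------------------------------------------------------------------

def climate_at_occurrences(
    table: pd.DataFrame,
    grids: Mapping[str, ClimateGrid],
    corrections: Mapping[str, CorrectionModel] | None = None,
    min_records: int = MIN_RECORDS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Annotate records with corrected climate values.

    ``grids`` must provide ``annual_precip`` and ``min_temp`` layers.  Each
    record gains three columns: ``min_precip`` (corrected annual
    precipitation, floored at 0 mm), ``max_precip`` (uncorrected annual
    precipitation) and ``min_temp`` (corrected minimum temperature, capped
    at -60 C by the model).  Records with missing climate in any layer are
    dropped and counted, and the minimum-record rule is re-applied.
    """
    for key in ("annual_precip", "min_temp"):
        if key not in grids:
            raise KeyError(f"missing required grid {key!r}")
    corrections = dict(corrections or {})
    corrections.setdefault("min_precip", identity_correction("min_precip"))
    corrections.setdefault("min_temp", identity_correction("min_temp"))
    corrections.setdefault("max_precip", identity_correction("max_precip"))

    pts = list(table[["lon", "lat"]].itertuples(index=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precip_raw = extract_at_points(grids["annual_precip"], pts)
        temp_raw = extract_at_points(grids["min_temp"], pts)

    out = table.copy().reset_index(drop=True)
    out["_precip_raw"] = [np.nan if v is None else v for v in precip_raw]
    out["_temp_raw"] = [np.nan if v is None else v for v in temp_raw]
    has_climate = out["_precip_raw"].notna() & out["_temp_raw"].notna()
    n_missing = int((~has_climate).sum())
    if n_missing:
        warnings.warn(f"dropped {n_missing} record(s) with missing climate",
                      stacklevel=2)
    out = out.loc[has_climate].reset_index(drop=True)

    out["min_precip"] = np.maximum(
        apply_correction(corrections["min_precip"], out["_precip_raw"].to_numpy()), 0.0
    )
    out["max_precip"] = apply_correction(
        corrections["max_precip"], out["_precip_raw"].to_numpy()
    )
    out["min_temp"] = apply_correction(
        corrections["min_temp"], out["_temp_raw"].to_numpy()
    )
    out = out.drop(columns=["_precip_raw", "_temp_raw"])

    counts = out.groupby("species")["species"].transform("size") if len(out) else pd.Series(dtype=int)
    kept = out.loc[counts >= min_records].reset_index(drop=True) if len(out) else out
    n_excluded = len(out) - len(kept)

    report = FilterReport(
        n_raw=len(table), n_out_of_region=0, n_duplicates=0,
        n_missing_climate=n_missing, n_in_excluded_species=n_excluded,
        n_used=len(kept),
    )
    return kept, report


# ----------------------------------------------------------------------
# Niche limits
# ----------------------------------------------------------------------

def niche_limits(
    values: Mapping[str, np.ndarray] | pd.DataFrame,
    trim: float = 0.05,
    trim_direction: str = "limitward",
) -> dict[str, dict[str, float]]:
    """Trimmed and absolute niche limits per variable.

    With ``trim_direction='limitward'`` (default) the most extreme
    ``trim``-fraction of values is trimmed in the direction of the limit:
    the 5th percentile for the lower-tail variables (min_precip, min_temp)
    and the 95th for max_precip.  ``'upper'`` applies the (1-trim) quantile
    to every variable (the literal reading of a single "95th percentile").
    Quantiles use linear interpolation between order statistics.  Returns
    ``{variable: {"trimmed": x, "absolute": y}}``.
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    if trim_direction not in ("limitward", "upper"):
        raise ValueError("trim_direction must be 'limitward' or 'upper'")
    out: dict[str, dict[str, float]] = {}
    for var in NICHE_VARIABLES:
        if var not in values:
            continue
        v = np.asarray(values[var], dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"no values for variable {var!r}")
        lower_tail = var in LOWER_TAIL_VARIABLES
        if trim_direction == "limitward" and lower_tail:
            q = trim
        else:
            q = 1.0 - trim
        trimmed = float(np.quantile(v, q))
        absolute = float(np.min(v) if lower_tail else np.max(v))
        out[var] = {"trimmed": trimmed, "absolute": absolute}
    return out


# ----------------------------------------------------------------------
# Range size
# ----------------------------------------------------------------------

def convex_hull_vertices(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise hull vertices of 2-D points; empty if degenerate.

    Degenerate inputs (fewer than 3 distinct points, or all collinear)
    return an empty array — their hull has zero area.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return np.empty((0, 2))
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return np.empty((0, 2))  # collinear
    return pts[hull.vertices]


def _lonlat_to_xyz(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def _spherical_triangle_excess(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Spherical excess of the triangle a-b-c (unit vectors), via L'Huilier."""
    def side(u, v):
        return 2 * math.asin(min(1.0, np.linalg.norm(u - v) / 2))

    sa, sb, sc = side(b, c), side(a, c), side(a, b)
    s = (sa + sb + sc) / 2
    inner = (math.tan(s / 2) * math.tan((s - sa) / 2)
             * math.tan((s - sb) / 2) * math.tan((s - sc) / 2))
    return 4 * math.atan(math.sqrt(max(0.0, inner)))


def spherical_polygon_area_km2(vertices: np.ndarray,
                               radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area of a convex spherical polygon given ordered (lon, lat) vertices.

    The polygon is fanned into spherical triangles from its first vertex;
    valid because hull vertices are in convex position.
    """
    if len(vertices) < 3:
        return 0.0
    xyz = _lonlat_to_xyz(vertices[:, 0], vertices[:, 1])
    excess = sum(
        _spherical_triangle_excess(xyz[0], xyz[i], xyz[i + 1])
        for i in range(1, len(xyz) - 1)
    )
    return excess * radius_km**2


def range_size(points: np.ndarray | pd.DataFrame) -> float:
    """Convex-hull range size in km^2 on the sphere (R = 6371.0088 km).

    ``points`` is an (n, 2) array or DataFrame of (lon, lat) records.  If
    the longitudinal spread exceeds 180 degrees the points are recentred
    (longitudes shifted mod 360) before hulling, so ranges spanning the
    dateline do not wrap around the globe.  Degenerate point sets have
    area exactly 0.
    """
    if isinstance(points, pd.DataFrame):
        points = points[["lon", "lat"]].to_numpy(dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2).copy()
    if len(pts) == 0:
        return 0.0
    lon = pts[:, 0]
    if np.ptp(lon) > 180:
        pts[:, 0] = (lon + 360) % 360
    hull = convex_hull_vertices(pts)
    return spherical_polygon_area_km2(hull)


# ----------------------------------------------------------------------
# Per-species assembly
# ----------------------------------------------------------------------

def estimate_niches(
    climate_table: pd.DataFrame,
    raw_counts: Mapping[str, int] | None = None,
    trim: float = 0.05,
    trim_direction: str = "limitward",
) -> pd.DataFrame:
    """Per-species niche limits (both flavours) and range size.

    ``climate_table`` is the output of :func:`climate_at_occurrences`;
    ``raw_counts`` maps species to pre-filter record counts (defaults to
    the used counts).  Returns a DataFrame with :data:`NICHE_COLUMNS`,
    the empirical-column schema of the per-species output tables.
    """
    rows = []
    for species, grp in climate_table.groupby("species", sort=True):
        lim = niche_limits(grp, trim=trim, trim_direction=trim_direction)
        n_used = len(grp)
        n_raw = int(raw_counts.get(species, n_used)) if raw_counts else n_used
        rows.append({
            "species": species,
            "n_records_raw": n_raw,
            "n_records_used": n_used,
            "min_precip_mm_trim": lim["min_precip"]["trimmed"],
            "min_precip_mm_abs": lim["min_precip"]["absolute"],
            "max_precip_mm_trim": lim["max_precip"]["trimmed"],
            "max_precip_mm_abs": lim["max_precip"]["absolute"],
            "min_temp_c_trim": lim["min_temp"]["trimmed"],
            "min_temp_c_abs": lim["min_temp"]["absolute"],
            "range_area_km2": range_size(grp),
        })
    return pd.DataFrame(rows, columns=NICHE_COLUMNS)
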