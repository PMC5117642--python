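"""Gridded climate layers and tabular inputs.

A :class:`ClimateGrid` is a single georeferenced 2-D field (row 0 = northern
edge, as in the ESRI ASCII convention) with a NoData sentinel and a simple
north-up affine transform derived from the lower-left corner and a square
cell size.  Supported on-disk dialects are the ESRI ASCII grid
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header) and a
plain CSV of ``lon,lat,value`` cell-centre triplets for hand-written test
fixtures.  Reprojection is out of scope; all coordinates are geographic
degrees (WGS84 by label).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateGrid",
    "GridFormatError",
    "GridAlignmentError",
    "read_grid",
    "write_grid",
    "annual_precip_from_monthly",
    "coldest_month_min",
    "extract_at_points",
    "read_occurrences",
    "write_occurrences",
    "read_expert_table",
    "write_expert_table",
    "GROWTH_FORMS",
]

GROWTH_FORMS = ("forb", "grass", "shrub", "tree", "vine")

#: Variables a grid may carry (units in the name).
GRID_VARIABLES = (
    "min_temp_C",
    "annual_precip_mm",
    "monthly_precip_mm",
    "monthly_min_temp_C",
)

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised when a grid file cannot be parsed or georeferenced."""


class GridAlignmentError(ValueError):
    """Raised when grids that must share a transform do not."""


@dataclass
class ClimateGrid:
    """One climate variable on a regular geographic grid.

    ``values`` is (nrows, ncols) with row 0 at the northern edge.  Cells
    equal to ``nodata`` are missing.  ``xllcorner``/``yllcorner`` are the
    lower-left corner of the lower-left *cell* (not its centre), matching
    the ESRI ASCII header.
    """

    variable: str
    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = DEFAULT_NODATA
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridFormatError("grid must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise GridFormatError("cellsize must be positive")
        body = self.values[~self.mask]
        if body.size and not np.all(np.isfinite(body)):
            raise GridFormatError("non-NoData cells must be finite")

    # ------------------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def ytopcorner(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a cell is NoData."""
        with np.errstate(invalid="ignore"):
            return (self.values == self.nodata) | ~np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def same_geometry(self, other: "ClimateGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.xllcorner, other.xllcorner, abs_tol=1e-9)
            and math.isclose(self.yllcorner, other.yllcorner, abs_tol=1e-9)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12)
        )

    # ------------------------------------------------------------------
    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the cell containing (lon, lat), or None if outside.

        Half-open convention: a point on a shared vertical edge belongs to
        the cell to its east; on a shared horizontal edge, to the cell to
        its south.  The grid's own north and west edges are inside; the
        south and east edges are outside.
        """
        col = math.floor((lon - self.xllcorner) / self.cellsize)
        row = math.floor((self.ytopcorner - lat) / self.cellsize)
        if 0 <= col < self.ncols and 0 <= row < self.nrows:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.ytopcorner - (row + 0.5) * self.cellsize
        return lon, lat


# ----------------------------------------------------------------------
# Grid I/O
# ----------------------------------------------------------------------

def read_grid(path: str | Path, variable: str = "annual_precip_mm") -> ClimateGrid:
    """Read an ESRI ASCII grid (``.asc``) or lon,lat,value CSV (``.csv``)."""
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"grid file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".asc", ".agr", ".grd", ".txt"):
        return _read_ascii_grid(path, variable)
    if suffix == ".csv":
        return _read_csv_grid(path, variable)
    raise GridFormatError(
        f"unsupported grid dialect {suffix!r}; use ESRI ASCII (.asc) or CSV"
    )


def write_grid(grid: ClimateGrid, path: str | Path) -> Path:
    """Write a grid in the dialect implied by the path suffix."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv_grid(grid, path)
    else:
        _write_ascii_grid(grid, path)
    return path


_ASCII_HEADER_KEYS = {
    "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
    "cellsize", "nodata_value",
}


def _read_ascii_grid(path: Path, variable: str) -> ClimateGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS:
                try:
                    header[key] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise GridFormatError(f"bad header line {line!r}") from exc
            else:
                data_lines.append(line)
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise GridFormatError(f"missing header keys in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header and "yllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header and "yllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise GridFormatError(f"no georeferencing (xll/yll) in {path}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.array(" ".join(data_lines).split(), dtype=float)
        values = values.reshape(nrows, ncols)
    except ValueError as exc:
        raise GridFormatError(f"grid body of {path} is not {nrows}x{ncols}") from exc
    return ClimateGrid(variable, values, xll, yll, cellsize, nodata)


def _write_ascii_grid(grid: ClimateGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {float(grid.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(grid.yllcorner)!r}\n")
        fh.write(f"cellsize {float(grid.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_csv_grid(path: Path, variable: str) -> ClimateGrid:
    df = pd.read_csv(path)
    need = {"lon", "lat", "value"}
    if not need <= set(df.columns):
        raise GridFormatError(f"CSV grid {path} must have columns lon,lat,value")
    lons = np.sort(df["lon"].unique())
    lats = np.sort(df["lat"].unique())
    if len(lons) > 1:
        steps = np.diff(lons)
    elif len(lats) > 1:
        steps = np.diff(lats)
    else:
        steps = np.array([1.0])
    cellsize = float(steps[0])
    if not np.allclose(steps, cellsize):
        raise GridFormatError(f"CSV grid {path} is not regular")
    nrows, ncols = len(lats), len(lons)
    values = np.full((nrows, ncols), DEFAULT_NODATA)
    col_of = {v: i for i, v in enumerate(lons)}
    row_of = {v: nrows - 1 - i for i, v in enumerate(lats)}  # row 0 = north
    for lon, lat, val in df[["lon", "lat", "value"]].itertuples(index=False):
        values[row_of[lat], col_of[lon]] = DEFAULT_NODATA if pd.isna(val) else val
    xll = float(lons[0]) - cellsize / 2
    yll = float(lats[0]) - cellsize / 2
    return ClimateGrid(variable, values, xll, yll, cellsize, DEFAULT_NODATA)


def _write_csv_grid(grid: ClimateGrid, path: Path) -> None:
    rows = []
    mask = grid.mask
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            lon, lat = grid.cell_center(r, c)
            val = "" if mask[r, c] else repr(float(grid.values[r, c]))
            rows.append((repr(float(lon)), repr(float(lat)), val))
    with open(path, "w") as fh:
        fh.write("lon,lat,value\n")
        for lon, lat, val in rows:
            fh.write(f"{lon},{lat},{val}\n")


# ----------------------------------------------------------------------
# Derived layers
# ----------------------------------------------------------------------

def _stack(months: Sequence[ClimateGrid]) -> np.ndarray:
    if len(months) != 12:
        raise GridAlignmentError(f"expected 12 monthly grids, got {len(months)}")
    first = months[0]
    for g in months[1:]:
        if not first.same_geometry(g):
            raise GridAlignmentError("monthly grids are not co-registered")
    return np.stack([np.where(g.mask, np.nan, g.values) for g in months])


def annual_precip_from_monthly(months: Sequence[ClimateGrid]) -> ClimateGrid:
    """Per-cell sum of 12 monthly precipitation grids.

    A cell is NoData in the annual layer if any month is NoData there:
    partial sums would understate the annual total.
    """
    stack = _stack(months)
    total = stack.sum(axis=0)  # NaN propagates
    first = months[0]
    values = np.where(np.isnan(total), first.nodata, total)
    return ClimateGrid("annual_precip_mm", values, first.xllcorner,
                       first.yllcorner, first.cellsize, first.nodata, first.crs)


def coldest_month_min(months: Sequence[ClimateGrid]) -> ClimateGrid:
    """Per-cell minimum across 12 monthly minimum-temperature grids."""
    stack = _stack(months)
    coldest = stack.min(axis=0)  # NaN propagates (any-month NoData rule)
    first = months[0]
    values = np.where(np.isnan(coldest), first.nodata, coldest)
    return ClimateGrid("min_temp_C", values, first.xllcorner,
                       first.yllcorner, first.cellsize, first.nodata, first.crs)


def extract_at_points(
    grid: ClimateGrid,
    points: Iterable[tuple[float, float]],
) -> list[float | None]:
    """Nearest-cell value at each (lon, lat) point; None when missing.

    No interpolation: each record takes the value of the cell containing
    it.  Points outside the grid extent or on NoData cells yield None; the
    number of misses is reported with a warning so the caller can log it.
    """
    mask = grid.mask
    pts = np.asarray([(lon, lat) for lon, lat in points], dtype=float)
    if pts.size == 0:
        return []
    cols = np.floor((pts[:, 0] - grid.xllcorner) / grid.cellsize).astype(int)
    rows = np.floor((grid.ytopcorner - pts[:, 1]) / grid.cellsize).astype(int)
    inside = (cols >= 0) & (cols < grid.ncols) & (rows >= 0) & (rows < grid.nrows)
    found = np.full(len(pts), np.nan)  # non-NoData cells are finite, so NaN is free
    r_in, c_in = rows[inside], cols[inside]
    ok = ~mask[r_in, c_in]
    found[np.nonzero(inside)[0][ok]] = grid.values[r_in[ok], c_in[ok]]
    out: list[float | None] = [None if math.isnan(v) else v for v in found.tolist()]
    n_missing = sum(v is None for v in out)
    if n_missing:
        warnings.warn(
            f"{n_missing} point(s) outside extent or on NoData cells",
            stacklevel=2,
        )
    return out


# ----------------------------------------------------------------------
# Tabular inputs
# ----------------------------------------------------------------------

def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Occurrence CSV with required columns ``species,lon,lat``."""
    df = pd.read_csv(path)
    need = {"species", "lon", "lat"}
    if not need <= set(df.columns):
        raise GridFormatError(f"occurrence file {path} must have columns {sorted(need)}")
    bad_lon = ~df["lon"].between(-180, 180)
    bad_lat = ~df["lat"].between(-90, 90)
    bad_sp = df["species"].isna() | (df["species"].astype(str).str.strip() == "")
    bad = bad_lon | bad_lat | bad_sp
    if bad.any():
        raise GridFormatError(
            f"{int(bad.sum())} invalid occurrence row(s) in {path} "
            "(lon/lat out of range or empty species)"
        )
    return df[["species", "lon", "lat"]].copy()


def write_occurrences(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[["species", "lon", "lat"]].to_csv(path, index=False)
    return path


EXPERT_COLUMNS = ["species", "growth_form", "min_precip_mm", "max_precip_mm", "min_temp_c"]


def read_expert_table(path: str | Path) -> pd.DataFrame:
    """Expert tolerance CSV; empty fields are missing limits.

    Columns: ``species,growth_form,min_precip_mm,max_precip_mm,min_temp_c``.
    Checks the invariant min_precip <= max_precip where both are present.
    """
    df = pd.read_csv(path)
    if not set(EXPERT_COLUMNS) <= set(df.columns):
        raise GridFormatError(f"expert file {path} must have columns {EXPERT_COLUMNS}")
    df = df[EXPERT_COLUMNS].copy()
    known = df["growth_form"].isna() | df["growth_form"].isin(GROWTH_FORMS)
    if not known.all():
        bad = sorted(df.loc[~known, "growth_form"].unique())
        raise GridFormatError(f"unknown growth form(s) {bad} in {path}")
    both = df["min_precip_mm"].notna() & df["max_precip_mm"].notna()
    if (df.loc[both, "min_precip_mm"] > df.loc[both, "max_precip_mm"]).any():
        raise GridFormatError(f"min_precip_mm > max_precip_mm for some rows of {path}")
    return df


def write_expert_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[EXPERT_COLUMNS].to_csv(path, index=False)
    return path
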