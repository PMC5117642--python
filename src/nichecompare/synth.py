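"""Ground-truthed synthetic study generator.

Builds a complete virtual study — gridded climate, virtual species with
known true climatic niches, an expert tolerance table narrowed inward by a
known fraction, occurrence samples drawn from inside the true niche, and
the calibration time series for the average-to-extreme corrections — so
every downstream stage of the pipeline has a recoverable answer.

The generator encodes the study conditions rather than exposing free
knobs: growth-form shares default to the observed mixture (28% forb, 27%
tree, 23% grass, 19% shrub, 3% vine), records per species are log-uniform
on [6, 2000], and grasses/forbs receive wider niches than shrubs/trees so
the qualitative growth-form patterns are recoverable (a flag disables the
coupling for null tests).  Climate values are quantized to 0.1 units to
mimic gridded products; the quantization step is the principled
convergence tolerance for limit recovery.

Ground truth lets the expected dCN of every species be written down
analytically: with dense, untruncated sampling the occurrence limit
converges to the true limit, and the expert limit sits delta * width
inside it, so E[dCN] = delta * width for each variable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import (
    ClimateGrid,
    GROWTH_FORMS,
    annual_precip_from_monthly,
    coldest_month_min,
    write_grid,
    write_occurrences,
    write_expert_table,
)

__all__ = [
    "ScenarioConfig",
    "TrueNiche",
    "make_climate_fields",
    "make_true_niches",
    "sample_occurrences",
    "make_expert_table",
    "make_correction_series",
    "make_scenario",
    "load_ground_truth",
]

#: Deterministic substream labels (mixed into the seed per operation).
_STREAMS = {"fields": 0, "niches": 1, "occurrences": 2, "expert": 3, "series": 4}

#: Relative niche-width baseline per growth form (fraction of the realized
#: climate range).  Grass >= forb > shrub > tree mirrors the observed
#: range-size ordering; vine sits in between.
WIDTH_FRACTIONS = {"grass": 0.55, "forb": 0.50, "shrub": 0.40,
                   "tree": 0.33, "vine": 0.36}


@dataclass
class ScenarioConfig:
    """All knobs of one synthetic study, with the default study conditions."""

    seed: int = 0
    # grid geometry (degrees)
    nrows: int = 80
    ncols: int = 80
    xllcorner: float = -110.0
    yllcorner: float = 30.0
    cellsize: float = 0.25
    # species
    n_species: int = 200
    growth_form_props: dict = field(default_factory=lambda: {
        "forb": 0.28, "tree": 0.27, "grass": 0.23, "shrub": 0.19, "vine": 0.03,
    })
    couple_width_to_form: bool = True
    # records per species: log-uniform on [records_min, records_max], or a
    # fixed count when records_fixed is set
    records_min: int = 6
    records_max: int = 2000
    records_fixed: int | None = None
    #: fraction of species with truncated (non-equilibrium) sampling
    truncated_fraction: float = 0.0
    # expert narrowing delta (fraction of niche width removed per end);
    # drawn U(delta_low, delta_high) per species/variable unless fixed
    delta_low: float = 0.05
    delta_high: float = 0.25
    delta_fixed: float | None = None
    #: probability an expert field is missing
    missing_rate: float = 0.0
    # climate-field shape
    temp_south_c: float = 10.0
    temp_north_c: float = -30.0
    precip_west_mm: float = 3000.0
    precip_east_mm: float = 400.0
    temp_noise_amp_c: float = 2.0
    precip_noise_amp_mm: float = 150.0
    nodata_fraction: float = 0.05
    quantization: float = 0.1
    # true average-to-extreme relations
    precip_gain: float = 0.70
    precip_offset: float = -20.0
    precip_noise_sd: float = 30.0
    temp_gain: float = 1.30
    temp_offset: float = -12.0
    temp_noise_sd: float = 1.5
    # calibration series sizes
    n_precip_locations: int = 500
    precip_years: tuple[int, int] = (1981, 2013)
    n_stations: int = 80
    station_years: tuple[int, int] = (1950, 2000)

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.growth_form_props.values()), 1.0, abs_tol=1e-9):
            raise ValueError("growth-form proportions must sum to 1")
        lo = self.delta_fixed if self.delta_fixed is not None else self.delta_low
        hi = self.delta_fixed if self.delta_fixed is not None else self.delta_high
        if not (0 <= lo <= hi < 0.5):
            raise ValueError("expert narrowing delta must lie in [0, 0.5)")
        if self.nrows < 2 or self.ncols < 2 or self.cellsize <= 0:
            raise ValueError("degenerate grid extent")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class TrueNiche:
    """One species' true climatic niche.

    Raw-scale intervals (``precip_raw``, ``temp_raw``) bound the gridded
    average climate the species occupies; comparison-scale limits are what
    the expert table and the corrected occurrence pipeline both estimate:
    ``min_precip`` (extreme scale, = gain*p_low+offset), ``max_precip``
    (average scale, = p_high) and ``min_temp`` (extreme scale).  Limits are
    snapped to climate values attained on the grid, so they are exactly
    recoverable in the dense-sampling limit.
    """

    species: str
    growth_form: str
    precip_raw: tuple[float, float]
    temp_raw: tuple[float, float]
    limits: dict[str, float]
    widths: dict[str, float]
    truncated: bool = False


def _quantize(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(values / step) * step


def _smooth_noise(rng: np.random.Generator, nrows: int, ncols: int,
                  amplitude: float, n_modes: int = 6) -> np.ndarray:
    """Low-frequency random field: a sum of random 2-D cosine modes."""
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    out = np.zeros((nrows, ncols))
    for _ in range(n_modes):
        fx, fy = rng.uniform(0.5, 3.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.normal(0, 1) * np.cos(
            2 * np.pi * (fx * xx / ncols + fy * yy / nrows) + phase
        )
    if out.std() > 0:
        out *= amplitude / out.std()
    return out


# ----------------------------------------------------------------------
# Climate fields
# ----------------------------------------------------------------------

def make_climate_fields(config: ScenarioConfig) -> dict:
    """Gridded climate: monthly stacks plus their derived annual/coldest layers.

    Minimum temperature follows a latitudinal gradient (cold north), annual
    precipitation a longitudinal one (wet west), each with low-frequency
    noise; a smooth 'ocean' region is NoData in every layer.  The returned
    ``annual_precip`` and ``min_temp`` grids are *derived* from the monthly
    stacks (sum, minimum), so internal consistency is exact.
    """
    rng = config.rng("fields")
    nrows, ncols = config.nrows, config.ncols
    lat_frac = np.linspace(1.0, 0.0, nrows)[:, None] * np.ones((1, ncols))  # 1 = north edge
    lon_frac = np.ones((nrows, 1)) * np.linspace(0.0, 1.0, ncols)[None, :]

    t_jan = (config.temp_south_c
             + (config.temp_north_c - config.temp_south_c) * lat_frac
             + _smooth_noise(rng, nrows, ncols, config.temp_noise_amp_c))
    annual_target = (config.precip_west_mm
                     + (config.precip_east_mm - config.precip_west_mm) * lon_frac
                     + _smooth_noise(rng, nrows, ncols, config.precip_noise_amp_mm))
    annual_target = np.maximum(annual_target, 200.0)

    # NoData 'ocean': cells where an independent smooth field is lowest
    ocean_field = _smooth_noise(rng, nrows, ncols, 1.0)
    thresh = np.quantile(ocean_field, config.nodata_fraction)
    ocean = ocean_field < thresh

    geo = dict(xllcorner=config.xllcorner, yllcorner=config.yllcorner,
               cellsize=config.cellsize)
    nodata = -9999.0

    # winter-wet seasonal profile for precipitation
    month_idx = np.arange(12)
    weights = 1.0 + 0.6 * np.cos(2 * np.pi * month_idx / 12)
    weights /= weights.sum()
    monthly_precip = []
    for m in range(12):
        vals = _quantize(annual_target * weights[m], config.quantization)
        vals = np.where(ocean, nodata, vals)
        monthly_precip.append(ClimateGrid("monthly_precip_mm", vals,
                                          nodata=nodata, **geo))

    # January is the structurally coldest month; later months sit above it
    seasonal = 20.0 * (1 - np.cos(2 * np.pi * month_idx / 12)) / 2
    monthly_tmin = []
    for m in range(12):
        jitter = 0.0 if m == 0 else rng.uniform(0.0, 1.0)
        vals = _quantize(t_jan + seasonal[m] + jitter, config.quantization)
        vals = np.where(ocean, nodata, vals)
        monthly_tmin.append(ClimateGrid("monthly_min_temp_C", vals,
                                        nodata=nodata, **geo))

    return {
        "monthly_precip": monthly_precip,
        "monthly_tmin": monthly_tmin,
        "annual_precip": annual_precip_from_monthly(monthly_precip),
        "min_temp": coldest_month_min(monthly_tmin),
    }


# ----------------------------------------------------------------------
# True niches
# ----------------------------------------------------------------------

def _comparison_limits(config: ScenarioConfig, p_low, p_high, t_low, t_high):
    limits = {
        "min_precip": config.precip_gain * p_low + config.precip_offset,
        "max_precip": p_high,
        "min_temp": config.temp_gain * t_low + config.temp_offset,
    }
    widths = {
        "min_precip": config.precip_gain * (p_high - p_low),
        "max_precip": p_high - p_low,
        "min_temp": config.temp_gain * (t_high - t_low),
    }
    return limits, widths


def _in_niche_cells(fields: dict, niche_or_bounds) -> np.ndarray:
    """Boolean cell mask of valid cells inside the raw-scale niche box."""
    precip = fields["annual_precip"]
    temp = fields["min_temp"]
    if isinstance(niche_or_bounds, TrueNiche):
        (pl, ph), (tl, th) = niche_or_bounds.precip_raw, niche_or_bounds.temp_raw
    else:
        (pl, ph), (tl, th) = niche_or_bounds
    valid = ~precip.mask & ~temp.mask
    return (valid
            & (precip.values >= pl) & (precip.values <= ph)
            & (temp.values >= tl) & (temp.values <= th))


def make_true_niches(config: ScenarioConfig, fields: dict) -> list[TrueNiche]:
    """Draw species niches, snapped to climate values attained on the grid.

    Each species gets a growth form from the configured mixture and a
    rectangular niche in (annual precipitation, minimum temperature) whose
    relative width follows the form (unless coupling is disabled).  Bounds
    are snapped to the extrema actually realized on the in-niche cell set,
    so every limit is attained somewhere on the grid.
    """
    rng = config.rng("niches")
    precip = fields["annual_precip"]
    temp = fields["min_temp"]
    valid = ~precip.mask & ~temp.mask
    pvals, tvals = precip.values[valid], temp.values[valid]
    p_lo, p_hi = float(pvals.min()), float(pvals.max())
    t_lo, t_hi = float(tvals.min()), float(tvals.max())

    forms = list(config.growth_form_props)
    probs = np.array([config.growth_form_props[f] for f in forms])
    assigned = rng.choice(forms, size=config.n_species, p=probs)

    niches: list[TrueNiche] = []
    for i in range(config.n_species):
        form = str(assigned[i])
        base = WIDTH_FRACTIONS[form] if config.couple_width_to_form else 0.45
        for _attempt in range(20):
            wf = min(0.9, base * rng.uniform(0.85, 1.15))
            pw = wf * (p_hi - p_lo)
            tw = wf * (t_hi - t_lo)
            pc = rng.uniform(p_lo + pw / 2, p_hi - pw / 2)
            tc = rng.uniform(t_lo + tw / 2, t_hi - tw / 2)
            bounds = ((pc - pw / 2, pc + pw / 2), (tc - tw / 2, tc + tw / 2))
            cells = _in_niche_cells(fields, bounds)
            if cells.sum() >= 10:
                break
            base = min(0.9, base * 1.3)  # widen and retry
        pin = precip.values[cells]
        tin = temp.values[cells]
        p_low, p_high = float(pin.min()), float(pin.max())
        t_low, t_high = float(tin.min()), float(tin.max())
        limits, widths = _comparison_limits(config, p_low, p_high, t_low, t_high)
        niches.append(TrueNiche(
            species=f"species_{i:04d}", growth_form=form,
            precip_raw=(p_low, p_high), temp_raw=(t_low, t_high),
            limits=limits, widths=widths,
        ))
    return niches


# ----------------------------------------------------------------------
# Occurrences
# ----------------------------------------------------------------------

def sample_occurrences(
    niches: list[TrueNiche],
    fields: dict,
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Occurrence records drawn uniformly from in-niche grid cells.

    Per species, the record count is log-uniform on [records_min,
    records_max] (or ``records_fixed``); points are placed uniformly within
    their cell.  A ``truncated_fraction`` of species is sampled only from
    the warm half of its niche, emulating a distribution not at climatic
    equilibrium; the affected species are flagged in the niches.
    """
    rng = config.rng("occurrences")
    temp = fields["min_temp"]
    n_trunc = int(round(config.truncated_fraction * len(niches)))
    trunc_idx = set(rng.choice(len(niches), size=n_trunc, replace=False).tolist()) if n_trunc else set()

    rows = []
    for i, niche in enumerate(niches):
        cells = _in_niche_cells(fields, niche)
        niche.truncated = i in trunc_idx
        if niche.truncated:
            tmid = (niche.temp_raw[0] + niche.temp_raw[1]) / 2
            cells = cells & (temp.values >= tmid)
        rr, cc = np.nonzero(cells)
        if config.records_fixed is not None:
            n = config.records_fixed
        else:
            n = int(np.exp(rng.uniform(np.log(config.records_min),
                                       np.log(config.records_max + 1))))
            n = int(np.clip(n, config.records_min, config.records_max))
        if rr.size == 0:
            warnings.warn(f"{niche.species}: niche matches no grid cell; "
                          "zero records", stacklevel=2)
            continue
        pick = rng.integers(0, rr.size, size=n)
        u, v = rng.random(n), rng.random(n)
        cs = temp.cellsize
        lons = temp.xllcorner + (cc[pick] + u) * cs
        lats = temp.ytopcorner - (rr[pick] + v) * cs
        for lon, lat in zip(lons, lats):
            rows.append((niche.species, float(lon), float(lat)))
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


# ----------------------------------------------------------------------
# Expert table
# ----------------------------------------------------------------------

def make_expert_table(
    niches: list[TrueNiche],
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Expert limits = true limits shrunk inward by delta * width per end.

    delta is drawn per species and variable (or fixed); with delta = 0 the
    expert table equals the true limits exactly.  Returns the table and
    the drawn deltas (ground truth).
    """
    rng = config.rng("expert")
    rows = []
    deltas: dict[str, dict[str, float]] = {}
    for niche in niches:
        d: dict[str, float] = {}
        rec: dict[str, object] = {"species": niche.species,
                                  "growth_form": niche.growth_form}
        for var, sign in (("min_precip", +1), ("max_precip", -1), ("min_temp", +1)):
            if config.delta_fixed is not None:
                d[var] = config.delta_fixed
            else:
                d[var] = float(rng.uniform(config.delta_low, config.delta_high))
            value = niche.limits[var] + sign * d[var] * niche.widths[var]
            col = {"min_precip": "min_precip_mm", "max_precip": "max_precip_mm",
                   "min_temp": "min_temp_c"}[var]
            if config.missing_rate and rng.random() < config.missing_rate:
                rec[col] = np.nan
            else:
                rec[col] = value
        deltas[niche.species] = d
        rows.append(rec)
    df = pd.DataFrame(rows, columns=["species", "growth_form", "min_precip_mm",
                                     "max_precip_mm", "min_temp_c"])
    both = df["min_precip_mm"].notna() & df["max_precip_mm"].notna()
    if (df.loc[both, "min_precip_mm"] > df.loc[both, "max_precip_mm"]).any():
        raise RuntimeError("generated expert table violates min <= max precip")
    return df, deltas


# ----------------------------------------------------------------------
# Calibration series
# ----------------------------------------------------------------------

def _affine_to_targets(draws: np.ndarray, mean_target: float,
                       extreme_target: float, extreme_of) -> np.ndarray:
    """Affinely rescale draws so their mean and extreme hit the targets.

    Works because both the mean and any linear-interpolation quantile (and
    the minimum) are affine-equivariant; requires the extreme target to
    lie below the mean target.
    """
    m = draws.mean()
    e = extreme_of(draws)
    if e >= m:
        raise ValueError("draws have no spread below the mean")
    beta = (extreme_target - mean_target) / (e - m)
    if beta <= 0:
        raise ValueError("extreme target must lie below the mean target")
    return mean_target + beta * (draws - m)


def make_correction_series(
    fields: dict,
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibration tables whose extremes follow the true linear relations.

    Precipitation: per-location annual series (one value per year) built so
    the location's 20th percentile equals ``gain*avg + offset + noise``
    exactly, with avg the location's gridded annual precipitation.
    Temperature: per-station daily January minima whose record minimum
    equals ``gain*avg + offset + noise``.  Schemas:
    ``location_id,lat,lon,year,annual_precip_mm`` and
    ``station_id,lat,lon,date,tmin_c``.
    """
    rng = config.rng("series")
    precip, temp = fields["annual_precip"], fields["min_temp"]

    def pick_cells(grid: ClimateGrid, n: int):
        rr, cc = np.nonzero(~grid.mask)
        idx = rng.choice(rr.size, size=min(n, rr.size), replace=False)
        return rr[idx], cc[idx]

    def target_below_mean(mu: float, gain: float, offset: float, sd: float,
                          margin: float) -> float:
        # the extreme must lie below the mean; redraw the (rare) noise
        # values that would violate the ordering
        for _ in range(100):
            t = gain * mu + offset + rng.normal(0, sd)
            if t < mu - margin:
                return t
        return min(gain * mu + offset, mu - margin)

    y0, y1 = config.precip_years
    years = np.arange(y0, y1 + 1)
    rr, cc = pick_cells(precip, config.n_precip_locations)
    precip_rows = []
    for k, (r, c) in enumerate(zip(rr, cc)):
        mu = float(precip.values[r, c])
        # right-skewed year shape (dry years clustered, long wet tail) keeps
        # the rescaled series non-negative, so the affine construction that
        # pins the mean and 20th percentile stays exact (no clipping)
        n_low = max(2, round(0.3 * years.size))
        template = np.concatenate([np.linspace(-1.0, -0.9, n_low),
                                   np.linspace(-0.7, 2.0, years.size - n_low)])
        for _ in range(100):
            q_target = target_below_mean(mu, config.precip_gain,
                                         config.precip_offset,
                                         config.precip_noise_sd, margin=1.0)
            series = _affine_to_targets(rng.permutation(template), mu, q_target,
                                        lambda v: float(np.quantile(v, 0.20)))
            if series.min() >= 0:
                break
        else:
            series = np.maximum(series, 0.0)
        lon, lat = precip.cell_center(int(r), int(c))
        for year, val in zip(years, series):
            precip_rows.append((f"loc_{k:05d}", lat, lon, int(year), float(val)))
    precip_df = pd.DataFrame(precip_rows, columns=[
        "location_id", "lat", "lon", "year", "annual_precip_mm"])

    sy0, sy1 = config.station_years
    station_rows = []
    rr, cc = pick_cells(temp, config.n_stations)
    for k, (r, c) in enumerate(zip(rr, cc)):
        mu = float(temp.values[r, c])
        r_target = target_below_mean(mu, config.temp_gain, config.temp_offset,
                                     config.temp_noise_sd, margin=0.1)
        n_days = (sy1 - sy0 + 1) * 31
        draws = rng.normal(mu, 4.0, size=n_days)
        series = _affine_to_targets(draws, mu, r_target, lambda v: float(v.min()))
        lon, lat = temp.cell_center(int(r), int(c))
        day = 0
        for year in range(sy0, sy1 + 1):
            for dom in range(1, 32):
                station_rows.append((f"stn_{k:03d}", lat, lon,
                                     f"{year}-01-{dom:02d}", float(series[day])))
                day += 1
    station_df = pd.DataFrame(station_rows, columns=[
        "station_id", "lat", "lon", "date", "tmin_c"])
    return precip_df, station_df


# ----------------------------------------------------------------------
# On-disk bundle
# ----------------------------------------------------------------------

def make_scenario(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full input bundle plus ground-truth JSON.

    Grids go out as ESRI ASCII, tables as CSV, ground truth (true niches,
    expert deltas, correction parameters) as JSON, and the configuration as
    a flat key=value text file.  Byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fields = make_climate_fields(config)
    niches = make_true_niches(config, fields)
    occurrences = sample_occurrences(niches, fields, config)
    expert, deltas = make_expert_table(niches, config)
    precip_series, station_series = make_correction_series(fields, config)

    paths: dict[str, Path] = {}
    for m, grid in enumerate(fields["monthly_precip"], start=1):
        paths[f"monthly_precip_{m:02d}"] = write_grid(
            grid, outdir / f"monthly_precip_{m:02d}.asc")
    for m, grid in enumerate(fields["monthly_tmin"], start=1):
        paths[f"monthly_tmin_{m:02d}"] = write_grid(
            grid, outdir / f"monthly_tmin_{m:02d}.asc")
    paths["annual_precip"] = write_grid(fields["annual_precip"],
                                        outdir / "annual_precip.asc")
    paths["min_temp"] = write_grid(fields["min_temp"], outdir / "min_temp.asc")
    paths["occurrences"] = write_occurrences(occurrences,
                                             outdir / "occurrences.csv")
    paths["expert"] = write_expert_table(expert, outdir / "expert.csv")
    precip_series.to_csv(outdir / "precip_series.csv", index=False)
    paths["precip_series"] = outdir / "precip_series.csv"
    station_series.to_csv(outdir / "station_series.csv", index=False)
    paths["station_series"] = outdir / "station_series.csv"

    truth = {
        "seed": config.seed,
        "quantization": config.quantization,
        "correction_truth": {
            "min_precip": {"gain": config.precip_gain,
                           "offset": config.precip_offset,
                           "noise_sd": config.precip_noise_sd},
            "min_temp": {"gain": config.temp_gain,
                         "offset": config.temp_offset,
                         "noise_sd": config.temp_noise_sd},
        },
        "species": {
            n.species: {
                "growth_form": n.growth_form,
                "precip_raw": list(n.precip_raw),
                "temp_raw": list(n.temp_raw),
                "limits": n.limits,
                "widths": n.widths,
                "deltas": deltas[n.species],
                "truncated": n.truncated,
            }
            for n in niches
        },
    }
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))

    cfg_lines = []
    for key, val in asdict(config).items():
        if isinstance(val, dict):
            val = ",".join(f"{k}:{v}" for k, v in val.items())
        elif isinstance(val, tuple):
            val = ",".join(str(v) for v in val)
        cfg_lines.append(f"{key} = {val}")
    paths["config"] = outdir / "scenario_config.txt"
    paths["config"].write_text("\n".join(cfg_lines) + "\n")
    return paths


def load_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
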