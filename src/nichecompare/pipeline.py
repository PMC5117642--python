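"""End-to-end orchestration: filter -> extract -> correct -> estimate -> dCN -> stats.

The pipeline reads the interchange files written by the synthetic generator
(or assembled from real downloads with the same schemas), runs every stage
with a single seed, and writes a reproducible output bundle: the
per-species niche table, the long-format dCN table, a stats JSON, a run
log accounting for every dropped record, and a human-readable report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, correction, grids, niche, synth

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report"]

log = logging.getLogger("nichecompare")


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    Either ``scenario_dir`` points at a generated (or hand-assembled)
    input bundle, or ``scenario_seed`` asks the pipeline to generate one
    under ``outdir/scenario`` first.
    """

    outdir: Path
    scenario_dir: Path | None = None
    scenario_seed: int | None = None
    scenario_config: synth.ScenarioConfig | None = None
    trim: float = 0.05
    trim_direction: str = "limitward"
    flavor: str = "both"          # trimmed | absolute | both
    nemenyi_dist: str = "tukey"
    log_area: bool = False
    exclude_growth_forms: frozenset = frozenset({"vine"})
    min_records: int = niche.MIN_RECORDS
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not 0 <= self.trim < 0.5:
            raise ValueError("trim must be in [0, 0.5)")
        if self.flavor not in ("trimmed", "absolute", "both"):
            raise ValueError("flavor must be trimmed, absolute or both")
        if self.scenario_dir is None and self.scenario_seed is None:
            raise ValueError("provide scenario_dir or scenario_seed")


_REQUIRED_INPUTS = ("occurrences.csv", "expert.csv", "annual_precip.asc",
                    "min_temp.asc", "precip_series.csv", "station_series.csv")


def _load_inputs(scenario_dir: Path) -> dict:
    missing = [f for f in _REQUIRED_INPUTS if not (scenario_dir / f).exists()]
    if missing:
        raise PipelineError(f"[inputs] missing input file(s) in {scenario_dir}: "
                            f"{missing}")
    return {
        "occurrences": grids.read_occurrences(scenario_dir / "occurrences.csv"),
        "expert": grids.read_expert_table(scenario_dir / "expert.csv"),
        "annual_precip": grids.read_grid(scenario_dir / "annual_precip.asc",
                                         "annual_precip_mm"),
        "min_temp": grids.read_grid(scenario_dir / "min_temp.asc", "min_temp_C"),
        "precip_series": pd.read_csv(scenario_dir / "precip_series.csv"),
        "station_series": pd.read_csv(scenario_dir / "station_series.csv"),
    }


def fit_corrections(precip_series: pd.DataFrame,
                    station_series: pd.DataFrame) -> dict[str, correction.CorrectionModel]:
    """Fit both linear corrections; maximum precipitation stays identity."""
    precip_pairs = correction.summarize_precip_series(precip_series)
    temp_pairs = correction.summarize_temp_stations(station_series)
    return {
        "min_precip": correction.fit_correction(precip_pairs, "min_precip"),
        "min_temp": correction.fit_correction(temp_pairs, "min_temp"),
        "max_precip": correction.identity_correction("max_precip"),
    }


def _stats_block(cfg: RunConfig, expert: pd.DataFrame, niches: pd.DataFrame,
                 delta: pd.DataFrame, flavor: str) -> dict:
    """The comparative battery for one dCN flavor."""
    suffix = "_trim" if flavor == "trimmed" else "_abs"
    merged = expert.merge(niches, on="species")
    tests: dict[str, object] = {}
    mw = {}
    for var, ecol, ncol in (("min_precip", "min_precip_mm", "min_precip_mm"),
                            ("min_temp", "min_temp_c", "min_temp_c"),
                            ("max_precip", "max_precip_mm", "max_precip_mm")):
        sub = merged.loc[merged[ecol].notna()]
        if len(sub) == 0:
            continue
        mw[var] = compare.mann_whitney(sub[ecol], sub[ncol + suffix]).to_jsonable()
    tests["mann_whitney"] = mw
    tests["range_size_regression"] = {
        var: res.to_jsonable()
        for var, res in compare.range_size_regression(delta, log_area=cfg.log_area).items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gf = compare.growth_form_tests(delta, exclude=cfg.exclude_growth_forms,
                                       nemenyi_dist=cfg.nemenyi_dist)
    tests["growth_form"] = {
        var: {name: res.to_jsonable() for name, res in block.items()}
        for var, block in gf.items()
    }
    tests["summary"] = compare.summarize_delta(delta).to_dict(orient="records")
    return tests


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the output bundle; returns its paths."""
    logging.basicConfig(level=cfg.log_level)
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    scenario_dir = cfg.scenario_dir
    if scenario_dir is None:
        scen_cfg = cfg.scenario_config or synth.ScenarioConfig(seed=cfg.scenario_seed)
        scenario_dir = outdir / "scenario"
        log.info("generating synthetic scenario (seed=%d)", scen_cfg.seed)
        synth.make_scenario(scen_cfg, scenario_dir)

    try:
        inputs = _load_inputs(Path(scenario_dir))
    except grids.GridFormatError as exc:
        raise PipelineError(f"[inputs] {exc}") from exc

    try:
        models = fit_corrections(inputs["precip_series"], inputs["station_series"])
    except ValueError as exc:
        raise PipelineError(f"[calibrate] {exc}") from exc
    log.info("fitted corrections: min_precip gain=%.4f offset=%.2f r2=%.4f; "
             "min_temp gain=%.4f offset=%.2f r2=%.4f",
             models["min_precip"].gain, models["min_precip"].offset,
             models["min_precip"].fit_r2, models["min_temp"].gain,
             models["min_temp"].offset, models["min_temp"].fit_r2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, filt_report = niche.filter_occurrences(
            inputs["occurrences"], region_mask=inputs["annual_precip"],
            min_records=cfg.min_records)
        climate, clim_report = niche.climate_at_occurrences(
            filtered, {"annual_precip": inputs["annual_precip"],
                       "min_temp": inputs["min_temp"]},
            models, min_records=cfg.min_records)
    raw_counts = inputs["occurrences"].groupby("species").size().to_dict()
    niches = niche.estimate_niches(climate, raw_counts, trim=cfg.trim,
                                   trim_direction=cfg.trim_direction)
    if niches.empty:
        raise PipelineError("[estimate] no species survive filtering")

    flavors = ["trimmed", "absolute"] if cfg.flavor == "both" else [cfg.flavor]
    paths: dict[str, Path] = {}
    correction.save_models(models.values(), outdir / "corrections.json")
    paths["corrections"] = outdir / "corrections.json"
    niches.to_csv(outdir / "niches.csv", index=False)
    paths["niches"] = outdir / "niches.csv"

    stats_payload: dict[str, object] = {}
    delta_frames = []
    for flavor in flavors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            delta = compare.compute_delta_cn(inputs["expert"], niches, flavor)
        delta_frames.append(delta)
        stats_payload[flavor] = _stats_block(cfg, inputs["expert"], niches,
                                             delta, flavor)
    delta_all = pd.concat(delta_frames, ignore_index=True)
    delta_all.to_csv(outdir / "delta_cn.csv", index=False)
    paths["delta_cn"] = outdir / "delta_cn.csv"
    (outdir / "stats.json").write_text(json.dumps(stats_payload, indent=1,
                                                  sort_keys=True))
    paths["stats"] = outdir / "stats.json"

    run_log = {
        "seed": cfg.seed,
        "scenario_dir": str(scenario_dir),
        "trim": cfg.trim,
        "trim_direction": cfg.trim_direction,
        "flavors": flavors,
        "corrections": {
            name: {"gain": m.gain, "offset": m.offset, "n_points": m.n_points,
                   "fit_r2": None if np.isnan(m.fit_r2) else m.fit_r2,
                   "cap": m.cap, "identity": m.identity_flag}
            for name, m in models.items()
        },
        "record_accounting": {
            "n_raw": filt_report.n_raw,
            "n_out_of_region": filt_report.n_out_of_region,
            "n_duplicates": filt_report.n_duplicates,
            "n_excluded_species_stage1": filt_report.n_in_excluded_species,
            "n_missing_climate": clim_report.n_missing_climate,
            "n_excluded_species_stage2": clim_report.n_in_excluded_species,
            "n_used": clim_report.n_used,
        },
        "n_species_estimated": int(len(niches)),
    }
    acc = run_log["record_accounting"]
    assert acc["n_raw"] == sum(v for k, v in acc.items() if k != "n_raw"), \
        "record conservation violated"
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1,
                                                    sort_keys=True))
    paths["run_log"] = outdir / "run_log.json"

    paths["report"] = report(outdir)
    return paths


# ----------------------------------------------------------------------
# Report
# ----------------------------------------------------------------------

def report(outdir: str | Path) -> Path:
    """Regenerate the markdown summary from a completed output bundle.

    A pure function of the bundle files; includes a ground-truth recovery
    block when the scenario's ground_truth.json is available.
    """
    outdir = Path(outdir)
    needed = ["stats.json", "run_log.json", "delta_cn.csv", "niches.csv"]
    missing = [f for f in needed if not (outdir / f).exists()]
    if missing:
        raise PipelineError(f"[report] incomplete bundle, missing {missing}")
    stats_payload = json.loads((outdir / "stats.json").read_text())
    run_log = json.loads((outdir / "run_log.json").read_text())
    delta = pd.read_csv(outdir / "delta_cn.csv")
    niches = pd.read_csv(outdir / "niches.csv")

    lines = ["# Niche comparison report", ""]
    acc = run_log["record_accounting"]
    lines += [
        "## Records",
        f"- raw records: {acc['n_raw']}",
        f"- outside region: {acc['n_out_of_region']}",
        f"- duplicates: {acc['n_duplicates']}",
        f"- missing climate: {acc['n_missing_climate']}",
        f"- in excluded species (<{run_log.get('min_records', 6)} records): "
        f"{acc['n_excluded_species_stage1'] + acc['n_excluded_species_stage2']}",
        f"- used: {acc['n_used']} across {run_log['n_species_estimated']} species",
        "",
        "## Fitted corrections",
    ]
    for name, m in sorted(run_log["corrections"].items()):
        if m["identity"]:
            lines.append(f"- {name}: identity (no transformation)")
        else:
            lines.append(f"- {name}: extreme = {m['gain']:.4f} x average "
                         f"{m['offset']:+.2f} (r2 = {m['fit_r2']:.4f}, "
                         f"n = {m['n_points']}"
                         + (f", cap {m['cap']} C)" if m["cap"] is not None else ")"))
    for flavor, block in sorted(stats_payload.items()):
        lines += ["", f"## dCN summary ({flavor} limits)"]
        for row in block["summary"]:
            lines.append(
                f"- {row['variable']}: mean {row['mean_delta_cn']:.1f}, "
                f"median {row['median_delta_cn']:.1f}, "
                f"{row['pct_broader']:.1f}% of species broader (n={row['n']})"
            )
        lines.append("")
        for var, mw in sorted(block["mann_whitney"].items()):
            lines.append(f"- Mann-Whitney {var}: W = {mw['statistic']:.0f}, "
                         f"p = {mw['p_value']:.3g}")
        for var, reg in sorted(block["range_size_regression"].items()):
            lines.append(f"- dCN ~ range size, {var}: slope = "
                         f"{reg['statistic']:.3g}, df = {reg['df']}, "
                         f"p = {reg['p_value']:.3g}")
        for var, gf in sorted(block["growth_form"].items()):
            kw = gf["kruskal_wallis"]
            lines.append(f"- Kruskal-Wallis by growth form, {var}: chi2 = "
                         f"{kw['statistic']:.1f}, df = {kw['df']}, "
                         f"p = {kw['p_value']:.3g}")

    truth_path = Path(run_log["scenario_dir"]) / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        lines += ["", "## Ground-truth recovery"]
        for var in ("min_precip", "min_temp"):
            t = truth["correction_truth"][var]
            m = run_log["corrections"][var]
            lines.append(f"- {var} correction: fitted gain {m['gain']:.4f} vs "
                         f"true {t['gain']:.4f}; offset {m['offset']:.2f} vs "
                         f"true {t['offset']:.2f}")
        sp = truth["species"]
        sub = delta.loc[delta["flavor"] == "absolute"]
        if len(sub):
            for var in ("min_precip", "max_precip", "min_temp"):
                d = sub.loc[sub["variable"] == var]
                exp = [sp[s]["deltas"][var] * sp[s]["widths"][var]
                       for s in d["species"] if s in sp]
                if exp:
                    err = d["delta_cn"].to_numpy() - np.array(exp)
                    lines.append(f"- {var}: median (dCN - expected delta*width) "
                                 f"= {np.median(err):.3g} {('mm', 'C')[var == 'min_temp']}")
    lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
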