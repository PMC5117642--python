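"""The signed comparative-niche statistic (dCN) and group comparisons.

For each species and climate variable, dCN is the signed difference between
the expert-based tolerance limit and the occurrence-derived limit, oriented
so that *positive values mean the occurrence data imply a broader niche*:

* minimum precipitation: dCN = expert_min - occurrence_min
* minimum temperature:   dCN = expert_min - occurrence_min
* maximum precipitation: dCN = occurrence_max - expert_max

The comparative statistics are the field-standard nonparametric battery:
a two-sample Mann-Whitney-Wilcoxon test of the expert vs occurrence limit
distributions, an OLS regression of dCN on range size, and Kruskal-Wallis
with Nemenyi post-hoc pairwise tests across growth forms (vines excluded
by default — too few species).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DELTA_VARIABLES",
    "TestResult",
    "compute_delta_cn",
    "summarize_delta",
    "mann_whitney",
    "wilcoxon_paired",
    "range_size_regression",
    "kruskal_wallis",
    "nemenyi_posthoc",
    "growth_form_tests",
]

DELTA_VARIABLES = ("min_precip", "min_temp", "max_precip")

#: expert column, niche column stem, sign of (expert - herbarium)
_DELTA_SPEC = {
    "min_precip": ("min_precip_mm", "min_precip_mm", +1),
    "min_temp": ("min_temp_c", "min_temp_c", +1),
    "max_precip": ("max_precip_mm", "max_precip_mm", -1),
}

DELTA_COLUMNS = ["species", "growth_form", "variable", "delta_cn",
                 "range_area_km2", "flavor"]


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``statistic`` and ``p_value`` are scalars for single tests and
    DataFrames for pairwise (post-hoc) matrices.
    """

    test: str
    statistic: float | pd.DataFrame
    p_value: float | pd.DataFrame
    df: float | None = None
    n: Mapping[str, int] | tuple[int, ...] | int | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        def conv(x):
            if isinstance(x, pd.DataFrame):
                return {c: {r: float(x.loc[r, c]) for r in x.index} for c in x.columns}
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            return x
        return {
            "test": self.test,
            "statistic": conv(self.statistic),
            "p_value": conv(self.p_value),
            "df": self.df,
            "n": dict(self.n) if isinstance(self.n, Mapping) else self.n,
            "method": self.method,
            **{k: conv(v) for k, v in self.extra.items()},
        }


# ----------------------------------------------------------------------
# dCN
# ----------------------------------------------------------------------

def compute_delta_cn(
    expert: pd.DataFrame,
    niche: pd.DataFrame,
    flavor: str = "trimmed",
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species, per-variable signed dCN records (long format).

    ``expert`` follows the expert-table schema, ``niche`` the per-species
    niche schema.  ``flavor`` selects the occurrence limit: ``"trimmed"``
    (percentile-trimmed) or ``"absolute"``.  Species names in ``niche`` are
    first passed through ``synonym_map`` (occurrence name -> expert name)
    when given; the join itself is exact-match.  A missing expert field
    yields no record for that variable; species present in only one table
    are skipped with a warning.
    """
    if flavor not in ("trimmed", "absolute"):
        raise ValueError("flavor must be 'trimmed' or 'absolute'")
    suffix = "_trim" if flavor == "trimmed" else "_abs"
    niche = niche.copy()
    if synonym_map:
        niche["species"] = niche["species"].map(lambda s: synonym_map.get(s, s))
    merged = expert.merge(niche, on="species", how="inner", validate="one_to_one")
    n_skipped = (len(expert) - len(merged)) + (len(niche) - len(merged))
    if n_skipped:
        warnings.warn(f"{n_skipped} species present in only one table were "
                      "skipped", stacklevel=2)
    rows = []
    for _, rec in merged.iterrows():
        for var, (ecol, ncol, sign) in _DELTA_SPEC.items():
            e = rec[ecol]
            if pd.isna(e):
                continue
            h = rec[ncol + suffix]
            rows.append({
                "species": rec["species"],
                "growth_form": rec["growth_form"],
                "variable": var,
                "delta_cn": sign * (e - h),
                "range_area_km2": rec["range_area_km2"],
                "flavor": flavor,
            })
    return pd.DataFrame(rows, columns=DELTA_COLUMNS)


def summarize_delta(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean/median dCN, % of species broader, and n.

    "Broader" is strict: dCN > 0; ties count as not broader.
    """
    out = []
    for var, grp in records.groupby("variable", sort=True):
        d = grp["delta_cn"].to_numpy(dtype=float)
        out.append({
            "variable": var,
            "mean_delta_cn": float(np.mean(d)),
            "median_delta_cn": float(np.median(d)),
            "pct_broader": float(100.0 * np.mean(d > 0)),
            "n": len(d),
        })
    return pd.DataFrame(out, columns=["variable", "mean_delta_cn",
                                      "median_delta_cn", "pct_broader", "n"])


# ----------------------------------------------------------------------
# Rank tests
# ----------------------------------------------------------------------

def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
) -> TestResult:
    """Two-sided unpaired Mann-Whitney-Wilcoxon test.

    The statistic is W, the U of the first sample computed from rank sums
    with midranks for ties.  ``method='auto'`` uses the exact null
    distribution when min(n, m) <= 8 and the pooled sample is tie-free,
    otherwise the tie-corrected normal approximation.  No continuity
    correction is applied in the asymptotic branch, so the two-group
    Kruskal-Wallis reduction (chi2 = z^2) holds exactly.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        small = min(a.size, b.size) <= 8
        method = "exact" if small and not _has_ties(np.concatenate([a, b])) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return TestResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n=(int(a.size), int(b.size)),
        method=method,
    )


def wilcoxon_paired(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Paired Wilcoxon signed-rank alternative (the data are species-paired)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return TestResult("wilcoxon_paired", float(res.statistic), float(res.pvalue),
                      n=int(a.size), method="signed-rank")


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Kruskal-Wallis H with midrank ties and tie correction; df = k - 1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    stat, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p),
                      df=len(arrays) - 1, n=tuple(len(g) for g in arrays),
                      method="tie-corrected chi-square approximation")


def nemenyi_posthoc(
    groups: Mapping[str, Sequence[float]],
    dist: str = "tukey",
) -> TestResult:
    """Nemenyi all-pairs post-hoc test on mean ranks.

    ``dist='tukey'`` (default) compares the standardized mean-rank
    difference against the studentized-range distribution with infinite
    degrees of freedom; ``dist='chi'`` uses the tie-corrected chi-square
    form.  Returns symmetric statistic and p-value matrices.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(arrays)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    splits = np.cumsum([a.size for a in arrays])[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    sizes = [a.size for a in arrays]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    tie_factor = 1.0 - tie_term / (n_tot**3 - n_tot) if n_tot > 1 else 1.0

    stat = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    pval = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(mean_ranks[i] - mean_ranks[j])
        var = n_tot * (n_tot + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
        if dist == "tukey":
            q = diff / np.sqrt(var)
            p = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            s = q
        elif dist == "chi":
            s = diff**2 / var / tie_factor
            p = float(stats.chi2.sf(s, k - 1))
        else:
            raise ValueError("dist must be 'tukey' or 'chi'")
        stat.iloc[i, j] = stat.iloc[j, i] = s
        pval.iloc[i, j] = pval.iloc[j, i] = p
    return TestResult(
        test="nemenyi_pairwise", statistic=stat, p_value=pval,
        n={nm: sz for nm, sz in zip(names, sizes)},
        method=f"nemenyi-{dist}",
        extra={"mean_ranks": {nm: float(r) for nm, r in zip(names, mean_ranks)}},
    )


# ----------------------------------------------------------------------
# Regressions and growth-form battery
# ----------------------------------------------------------------------

def range_size_regression(
    records: pd.DataFrame,
    log_area: bool = False,
) -> dict[str, TestResult]:
    """OLS of dCN on range size, per variable.

    Range size enters untransformed by default (``log_area=True`` uses
    log10 area).  Reports the slope, its two-sided t-test p-value and the
    residual degrees of freedom n - 2.
    """
    out: dict[str, TestResult] = {}
    for var, grp in records.groupby("variable", sort=True):
        x = grp["range_area_km2"].to_numpy(dtype=float)
        y = grp["delta_cn"].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"need >= 3 species for regression ({var})")
        if np.ptp(x) == 0:
            raise ValueError(f"zero variance in range size ({var})")
        if log_area:
            x = np.log10(x)
        res = stats.linregress(x, y)
        out[var] = TestResult(
            test="ols_slope", statistic=float(res.slope),
            p_value=float(res.pvalue), df=len(x) - 2, n=len(x),
            method="OLS dCN ~ range_area" + ("(log10)" if log_area else ""),
            extra={"intercept": float(res.intercept),
                   "r2": float(res.rvalue**2),
                   "stderr": float(res.stderr)},
        )
    return out


def growth_form_tests(
    records: pd.DataFrame,
    exclude: frozenset[str] | set[str] = frozenset({"vine"}),
    nemenyi_dist: str = "tukey",
) -> dict[str, dict[str, TestResult]]:
    """Kruskal-Wallis + Nemenyi across growth forms, per variable.

    Vines are excluded by default (too few species to compare).  Also runs
    the Kruskal-Wallis test on range size, with one observation per
    species.  Returns ``{variable: {"kruskal_wallis": ..., "nemenyi": ...},
    ..., "range_size": {"kruskal_wallis": ...}}``.
    """
    kept = records.loc[~records["growth_form"].isin(exclude)]
    n_dropped = records["growth_form"].isin(exclude).sum()
    if n_dropped:
        warnings.warn(f"excluded {int(n_dropped)} record(s) of growth forms "
                      f"{sorted(exclude)}", stacklevel=2)
    out: dict[str, dict[str, TestResult]] = {}
    for var, grp in kept.groupby("variable", sort=True):
        groups = {gf: sub["delta_cn"].to_numpy(dtype=float)
                  for gf, sub in grp.groupby("growth_form", sort=True)
                  if len(sub) >= 2}
        if len(groups) < 2:
            warnings.warn(f"fewer than 2 usable growth forms for {var}; "
                          "skipped", stacklevel=2)
            continue
        out[var] = {
            "kruskal_wallis": kruskal_wallis(*groups.values()),
            "nemenyi": nemenyi_posthoc(groups, dist=nemenyi_dist),
        }
        out[var]["kruskal_wallis"].n = {k: len(v) for k, v in groups.items()}
    per_species = kept.drop_duplicates("species")
    area_groups = {gf: sub["range_area_km2"].to_numpy(dtype=float)
                   for gf, sub in per_species.groupby("growth_form", sort=True)
                   if len(sub) >= 2}
    if len(area_groups) >= 2:
        kw = kruskal_wallis(*area_groups.values())
        kw.n = {k: len(v) for k, v in area_groups.items()}
        out["range_size"] = {"kruskal_wallis": kw}
    return out
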