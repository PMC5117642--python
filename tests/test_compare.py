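"""dCN computation and the nonparametric comparison battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import brute_force_u, hand_kruskal_h

from nichecompare import (
    compute_delta_cn,
    growth_form_tests,
    kruskal_wallis,
    mann_whitney,
    nemenyi_posthoc,
    range_size_regression,
    summarize_delta,
)


def expert_row(species, gf="tree", minp=np.nan, maxp=np.nan, mint=np.nan):
    return {"species": species, "growth_form": gf, "min_precip_mm": minp,
            "max_precip_mm": maxp, "min_temp_c": mint}


def niche_row(species, minp=0.0, maxp=0.0, mint=0.0, area=1000.0):
    return {"species": species, "n_records_raw": 10, "n_records_used": 10,
            "min_precip_mm_trim": minp, "min_precip_mm_abs": minp,
            "max_precip_mm_trim": maxp, "max_precip_mm_abs": maxp,
            "min_temp_c_trim": mint, "min_temp_c_abs": mint,
            "range_area_km2": area}


class TestDeltaCN:
    def test_white_mangrove_worked_example(self):
        # expert maximum precipitation 2337 mm vs 1255 mm from records
        expert = pd.DataFrame([expert_row("Laguncularia racemosa", maxp=2337.0)])
        niche = pd.DataFrame([niche_row("Laguncularia racemosa", maxp=1255.0)])
        delta = compute_delta_cn(expert, niche, "trimmed")
        assert len(delta) == 1
        assert delta.iloc[0]["variable"] == "max_precip"
        assert delta.iloc[0]["delta_cn"] == -1082.0

    def test_equal_limits_give_zero(self):
        expert = pd.DataFrame([expert_row("a", minp=100, maxp=900, mint=-20)])
        niche = pd.DataFrame([niche_row("a", minp=100, maxp=900, mint=-20)])
        delta = compute_delta_cn(expert, niche, "trimmed")
        assert len(delta) == 3 and (delta["delta_cn"] == 0).all()

    def test_sign_convention_broader_is_positive(self):
        # records reach 7 C colder than the expert limit -> +7
        expert = pd.DataFrame([expert_row("a", mint=-20)])
        niche = pd.DataFrame([niche_row("a", mint=-27)])
        delta = compute_delta_cn(expert, niche, "trimmed")
        assert delta.iloc[0]["delta_cn"] == 7.0
        # widening the occurrence-side limit outward increases dCN
        wider = compute_delta_cn(expert, pd.DataFrame([niche_row("a", mint=-30)]), "trimmed")
        assert wider.iloc[0]["delta_cn"] > delta.iloc[0]["delta_cn"]
        # widening the expert limit outward decreases it
        expert2 = pd.DataFrame([expert_row("a", mint=-25)])
        assert compute_delta_cn(expert2, niche, "trimmed").iloc[0]["delta_cn"] < 7.0

    def test_missing_expert_field_yields_no_record(self):
        expert = pd.DataFrame([expert_row("a", minp=100.0)])  # only one field
        niche = pd.DataFrame([niche_row("a", minp=50, maxp=900, mint=-20)])
        delta = compute_delta_cn(expert, niche, "trimmed")
        assert list(delta["variable"]) == ["min_precip"]

    def test_unmatched_species_skipped_and_synonyms_applied(self):
        expert = pd.DataFrame([expert_row("Accepted name", maxp=500.0)])
        niche = pd.DataFrame([niche_row("Synonym name", maxp=600.0),
                              niche_row("Orphan", maxp=1.0)])
        with pytest.warns(UserWarning, match="skipped"):
            delta = compute_delta_cn(expert, niche, "trimmed",
                                     synonym_map={"Synonym name": "Accepted name"})
        assert len(delta) == 1 and delta.iloc[0]["delta_cn"] == 100.0

    def test_summary_mean_median_percent(self):
        records = pd.DataFrame({
            "species": list("abc"), "growth_form": ["forb"] * 3,
            "variable": ["min_temp"] * 3, "delta_cn": [1.0, 1.0, -1.0],
            "range_area_km2": [1.0] * 3, "flavor": ["trimmed"] * 3,
        })
        s = summarize_delta(records).iloc[0]
        assert s["mean_delta_cn"] == pytest.approx(1 / 3)
        assert s["median_delta_cn"] == 1.0
        assert s["pct_broader"] == pytest.approx(100 * 2 / 3)
        assert s["n"] == 3

    def test_zero_delta_counts_as_not_broader(self):
        records = pd.DataFrame({
            "species": list("ab"), "growth_form": ["forb"] * 2,
            "variable": ["min_temp"] * 2, "delta_cn": [0.0, 0.0],
            "range_area_km2": [1.0] * 2, "flavor": ["trimmed"] * 2,
        })
        assert summarize_delta(records).iloc[0]["pct_broader"] == 0.0


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0 and res.method == "exact"

    def test_u_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n, m = rng.integers(1, 31, size=2)
            a = rng.integers(0, 15, size=n).astype(float)  # ties likely
            b = rng.integers(0, 15, size=m).astype(float)
            res = mann_whitney(a, b)
            assert res.statistic == pytest.approx(brute_force_u(a, b))

    def test_identical_samples_exact_p_is_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_auto_switches_to_asymptotic_on_ties_or_size(self):
        assert mann_whitney([1, 1, 2], [3, 4, 5]).method == "asymptotic"
        big = list(range(20))
        assert mann_whitney(big, [x + 0.5 for x in big]).method == "asymptotic"


class TestKruskalWallis:
    def test_statistic_matches_hand_rank_formula(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 8, size=rng.integers(2, 7)).astype(float)
                      for _ in range(k)]
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                continue  # scipy rejects all-identical data
            res = kruskal_wallis(*groups)
            assert res.statistic == pytest.approx(hand_kruskal_h(groups), abs=1e-9)
            assert res.df == k - 1

    def test_two_groups_reduce_to_mann_whitney(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = rng.integers(0, 10, size=15).astype(float)
            b = rng.integers(0, 10, size=12).astype(float)
            kw = kruskal_wallis(a, b)
            mw = mann_whitney(a, b, method="asymptotic")
            assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)


class TestNemenyi:
    def test_pairwise_matrix_against_hand_computation(self):
        groups = {"a": [1.0, 3.0, 5.0, 7.0], "b": [2.0, 4.0, 6.0, 8.0],
                  "c": [10.0, 11.0, 12.0, 13.0]}
        res = nemenyi_posthoc(groups)
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        mr = {"a": ranks[0:4].mean(), "b": ranks[4:8].mean(), "c": ranks[8:12].mean()}
        n_tot, k = 12, 3
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            q = abs(mr[x] - mr[y]) / np.sqrt(n_tot * (n_tot + 1) / 12 * (1 / 4 + 1 / 4))
            p = stats.studentized_range.sf(q * np.sqrt(2), k, np.inf)
            assert res.statistic.loc[x, y] == pytest.approx(q)
            assert res.p_value.loc[x, y] == pytest.approx(p)
        # separated group has a small p, interleaved groups a large one
        assert res.p_value.loc["a", "c"] < 0.05 < res.p_value.loc["a", "b"]

    def test_chi_square_variant_symmetry_and_range(self):
        rng = np.random.default_rng(37)
        groups = {g: rng.normal(i, 1, size=8) for i, g in enumerate("wxyz")}
        res = nemenyi_posthoc(groups, dist="chi")
        pv = res.p_value.to_numpy()
        assert np.allclose(pv, pv.T)
        assert ((pv >= 0) & (pv <= 1)).all()


class TestRegressionAndGrowthForms:
    @staticmethod
    def records(deltas, areas, forms=None, var="min_temp"):
        n = len(deltas)
        return pd.DataFrame({
            "species": [f"s{i}" for i in range(n)],
            "growth_form": forms or ["forb"] * n,
            "variable": [var] * n,
            "delta_cn": deltas, "range_area_km2": areas,
            "flavor": ["trimmed"] * n,
        })

    def test_exact_line_recovered(self):
        x = np.arange(1.0, 11.0)
        rec = self.records(2.5 * x - 1.0, x)
        res = range_size_regression(rec)["min_temp"]
        assert res.statistic == pytest.approx(2.5)
        assert res.extra["r2"] == pytest.approx(1.0)
        assert res.p_value < 1e-12
        assert res.df == 8  # n - 2

    def test_slope_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0, 12.0, 15.0, 18.0, 20.0])
        y = np.array([3.0, 1.0, 4.0, 1.5, 5.9, 2.6, 5.3, 5.8, 9.7, 9.3])
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        res = range_size_regression(self.records(y, x))["min_temp"]
        assert res.statistic == pytest.approx(slope, rel=1e-12)

    def test_zero_variance_range_size_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            range_size_regression(self.records([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))

    def test_vines_excluded_and_battery_runs(self):
        rng = np.random.default_rng(41)
        forms = ["forb"] * 10 + ["grass"] * 10 + ["shrub"] * 10 + ["tree"] * 10 + ["vine"] * 3
        rec = self.records(rng.normal(size=43), rng.uniform(1, 100, size=43), forms)
        with pytest.warns(UserWarning, match="vine"):
            out = growth_form_tests(rec)
        kw = out["min_temp"]["kruskal_wallis"]
        assert "vine" not in kw.n and kw.df == 3
        assert set(out["min_temp"]["nemenyi"].p_value.columns) == {"forb", "grass", "shrub", "tree"}
        assert "range_size" in out and out["range_size"]["kruskal_wallis"].df == 3

    def test_group_emptied_by_exclusion_proceeds(self):
        forms = ["forb"] * 6 + ["vine"] * 6
        rec = self.records(np.arange(12.0), np.arange(12.0) + 1, forms)
        with pytest.warns(UserWarning):
            out = growth_form_tests(rec)
        assert "min_temp" not in out  # only one usable group left
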