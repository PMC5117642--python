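"""Synthetic-study generator: determinism, consistency, ground truth."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from conftest import sort_quantile

from nichecompare import (
    ScenarioConfig,
    annual_precip_from_monthly,
    coldest_month_min,
    extract_at_points,
    filter_occurrences,
    fit_correction,
    make_climate_fields,
    make_correction_series,
    make_expert_table,
    make_scenario,
    make_true_niches,
    read_expert_table,
    read_grid,
    read_occurrences,
    sample_occurrences,
    summarize_precip_series,
    summarize_temp_stations,
)
from nichecompare.synth import TrueNiche, _in_niche_cells


TINY = dict(n_species=5, nrows=20, ncols=20, n_precip_locations=25,
            n_stations=6, station_years=(1996, 2000), precip_years=(2001, 2013))


class TestClimateFields:
    def test_deterministic_under_seed(self, small_config, small_fields):
        again = make_climate_fields(small_config)
        np.testing.assert_array_equal(small_fields["annual_precip"].values,
                                      again["annual_precip"].values)
        np.testing.assert_array_equal(small_fields["min_temp"].values,
                                      again["min_temp"].values)

    def test_monthly_stacks_consistent_with_derived_layers(self, small_fields):
        annual = annual_precip_from_monthly(small_fields["monthly_precip"])
        np.testing.assert_array_equal(annual.values,
                                      small_fields["annual_precip"].values)
        coldest = coldest_month_min(small_fields["monthly_tmin"])
        np.testing.assert_array_equal(coldest.values,
                                      small_fields["min_temp"].values)

    def test_gradients_and_nodata_present(self, small_fields):
        temp = small_fields["min_temp"]
        vals = np.where(temp.mask, np.nan, temp.values)
        north = np.nanmean(vals[:10])
        south = np.nanmean(vals[-10:])
        assert north < south  # colder toward the north edge
        assert 0 < temp.mask.sum() < temp.values.size

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(nrows=1)


class TestTrueNiches:
    def test_limits_attained_on_grid(self, small_fields, small_niches):
        precip = small_fields["annual_precip"]
        temp = small_fields["min_temp"]
        pvals = precip.values[~precip.mask]
        tvals = temp.values[~temp.mask]
        for n in small_niches:
            assert n.precip_raw[0] < n.precip_raw[1]
            assert n.temp_raw[0] < n.temp_raw[1]
            for bound in n.precip_raw:
                assert np.any(np.isclose(pvals, bound))
            for bound in n.temp_raw:
                assert np.any(np.isclose(tvals, bound))

    def test_growth_form_width_ordering_at_1000_species(self):
        cfg = ScenarioConfig(seed=11, n_species=1000, nrows=40, ncols=40)
        fields = make_climate_fields(cfg)
        niches = make_true_niches(cfg, fields)
        widths = {}
        for form in ("grass", "forb", "shrub", "tree"):
            ws = [n.widths["max_precip"] for n in niches if n.growth_form == form]
            widths[form] = float(np.mean(ws))
        assert widths["grass"] >= widths["forb"] >= widths["shrub"] >= widths["tree"]

    def test_single_species(self, small_fields):
        cfg = ScenarioConfig(seed=2, n_species=1, nrows=60, ncols=60)
        niches = make_true_niches(cfg, small_fields)
        assert len(niches) == 1

    def test_mixture_proportions_at_2000_species(self):
        cfg = ScenarioConfig(seed=5, n_species=2000, nrows=30, ncols=30)
        fields = make_climate_fields(cfg)
        niches = make_true_niches(cfg, fields)
        counts = pd.Series([n.growth_form for n in niches]).value_counts(normalize=True)
        for form, share in cfg.growth_form_props.items():
            assert counts.get(form, 0.0) == pytest.approx(share, abs=0.02)


class TestOccurrenceSampling:
    def test_seed_fixed_gives_identical_tables(self, small_config, small_fields,
                                               small_niches):
        a = sample_occurrences(small_niches, small_fields, small_config)
        b = sample_occurrences(small_niches, small_fields, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_five_record_species_later_excluded(self, small_fields):
        cfg = ScenarioConfig(seed=4, n_species=3, nrows=60, ncols=60,
                             records_fixed=5)
        niches = make_true_niches(cfg, small_fields)
        occ = sample_occurrences(niches, fields=small_fields, config=cfg)
        assert (occ.groupby("species").size() == 5).all()
        with pytest.warns(UserWarning):
            kept, _ = filter_occurrences(occ)
        assert kept.empty

    def test_impossible_niche_warns_and_yields_zero_records(self, small_fields,
                                                            small_config):
        bad = TrueNiche("ghost", "forb", precip_raw=(1e6, 2e6),
                        temp_raw=(100.0, 200.0),
                        limits={"min_precip": 0, "max_precip": 0, "min_temp": 0},
                        widths={"min_precip": 1, "max_precip": 1, "min_temp": 1})
        with pytest.warns(UserWarning, match="no grid cell"):
            occ = sample_occurrences([bad], small_fields, small_config)
        assert occ.empty

    def test_dense_sampling_converges_to_true_interval(self):
        cfg = ScenarioConfig(seed=3, n_species=15, nrows=60, ncols=60,
                             records_fixed=2000, truncated_fraction=0.0)
        fields = make_climate_fields(cfg)
        niches = make_true_niches(cfg, fields)
        occ = sample_occurrences(niches, fields, cfg)
        precip, temp = fields["annual_precip"], fields["min_temp"]
        for n in niches:
            sub = occ[occ.species == n.species]
            pts = list(sub[["lon", "lat"]].itertuples(index=False))
            p = np.asarray(extract_at_points(precip, pts), dtype=float)
            t = np.asarray(extract_at_points(temp, pts), dtype=float)
            cells = _in_niche_cells(fields, n)
            # gap bound: with n draws over k cells, the chance of missing all
            # of the j lowest-valued cells is < (1 - j/k)^n; pick j for < 1e-3
            k = int(cells.sum())
            j = max(1, math.ceil(k * math.log(1000) / len(sub)))
            pv = np.unique(precip.values[cells])
            tv = np.unique(temp.values[cells])
            tol_p = max(cfg.quantization, pv[min(j, len(pv) - 1)] - pv[0],
                        pv[-1] - pv[max(-1 - j, -len(pv))])
            tol_t = max(cfg.quantization, tv[min(j, len(tv) - 1)] - tv[0],
                        tv[-1] - tv[max(-1 - j, -len(tv))])
            assert p.min() - n.precip_raw[0] <= tol_p + 1e-9
            assert n.precip_raw[1] - p.max() <= tol_p + 1e-9
            assert t.min() - n.temp_raw[0] <= tol_t + 1e-9
            assert n.temp_raw[1] - t.max() <= tol_t + 1e-9

    def test_truncated_species_undersample_cold_half(self, small_fields):
        cfg = ScenarioConfig(seed=6, n_species=8, nrows=60, ncols=60,
                             records_fixed=500, truncated_fraction=1.0)
        niches = make_true_niches(cfg, small_fields)
        occ = sample_occurrences(niches, small_fields, cfg)
        temp = small_fields["min_temp"]
        for n in niches:
            sub = occ[occ.species == n.species]
            t = np.asarray(extract_at_points(
                temp, list(sub[["lon", "lat"]].itertuples(index=False))), dtype=float)
            tmid = (n.temp_raw[0] + n.temp_raw[1]) / 2
            assert t.min() >= tmid - 1e-9  # cold half never sampled


class TestExpertTable:
    def test_zero_delta_equals_true_limits(self, small_niches):
        cfg = ScenarioConfig(seed=7, delta_fixed=0.0)
        table, deltas = make_expert_table(small_niches, cfg)
        for n in small_niches:
            row = table.loc[table.species == n.species].iloc[0]
            assert row["min_precip_mm"] == pytest.approx(n.limits["min_precip"])
            assert row["max_precip_mm"] == pytest.approx(n.limits["max_precip"])
            assert row["min_temp_c"] == pytest.approx(n.limits["min_temp"])
            assert all(v == 0.0 for v in deltas[n.species].values())

    def test_delta_shrinks_interval_by_delta_times_width(self):
        niche = TrueNiche("sp", "forb", precip_raw=(100.0, 200.0),
                          temp_raw=(-10.0, 0.0),
                          limits={"min_precip": 50.0, "max_precip": 200.0,
                                  "min_temp": -25.0},
                          widths={"min_precip": 100.0, "max_precip": 100.0,
                                  "min_temp": 13.0})
        cfg = ScenarioConfig(seed=0, delta_fixed=0.1)
        table, _ = make_expert_table([niche], cfg)
        row = table.iloc[0]
        assert row["min_precip_mm"] == pytest.approx(60.0)   # low + 10
        assert row["max_precip_mm"] == pytest.approx(190.0)  # high - 10
        assert row["min_temp_c"] == pytest.approx(-25.0 + 1.3)

    def test_deltas_drawn_within_configured_range(self, small_niches, small_config):
        _, deltas = make_expert_table(small_niches, small_config)
        for d in deltas.values():
            for v in d.values():
                assert small_config.delta_low <= v <= small_config.delta_high


class TestCorrectionSeries:
    def test_station_count_matches_config(self, small_series):
        _, stations = small_series
        assert stations["station_id"].nunique() == 30

    def test_location_quantile_matches_sort_oracle(self, small_series):
        precip_df, _ = small_series
        pairs = summarize_precip_series(precip_df)
        by_loc = dict(list(precip_df.groupby("location_id")))
        for p in pairs[:20]:
            vals = by_loc[p.location_id]["annual_precip_mm"].tolist()
            assert p.extreme == pytest.approx(sort_quantile(vals, 0.20), abs=1e-9)

    def test_noiseless_series_recover_true_relation_exactly(self, small_fields):
        cfg = ScenarioConfig(seed=9, nrows=60, ncols=60, n_precip_locations=40,
                             n_stations=10, station_years=(1998, 2000),
                             precip_noise_sd=0.0, temp_noise_sd=0.0)
        precip_df, station_df = make_correction_series(small_fields, cfg)
        mp = fit_correction(summarize_precip_series(precip_df), "min_precip")
        assert mp.gain == pytest.approx(cfg.precip_gain, rel=1e-9)
        assert mp.offset == pytest.approx(cfg.precip_offset, rel=1e-9)
        mt = fit_correction(summarize_temp_stations(station_df), "min_temp")
        assert mt.gain == pytest.approx(cfg.temp_gain, rel=1e-9)
        assert mt.offset == pytest.approx(cfg.temp_offset, rel=1e-9)


class TestScenarioBundle:
    def test_bundle_round_trip_and_determinism(self, tmp_path):
        cfg = ScenarioConfig(seed=13, **TINY)
        paths_a = make_scenario(cfg, tmp_path / "a")
        paths_b = make_scenario(cfg, tmp_path / "b")
        for name in paths_a:
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes(), name

        # re-read reproduces the in-memory objects
        fields = make_climate_fields(cfg)
        annual = read_grid(paths_a["annual_precip"], "annual_precip_mm")
        np.testing.assert_array_equal(annual.values, fields["annual_precip"].values)
        occ = read_occurrences(paths_a["occurrences"])
        pd.testing.assert_frame_equal(
            occ, sample_occurrences(make_true_niches(cfg, fields), fields, cfg))
        read_expert_table(paths_a["expert"])  # schema-valid
        truth = json.loads(paths_a["ground_truth"].read_text())
        assert set(truth["species"]) == set(occ["species"].unique())

    def test_different_seeds_differ(self, tmp_path):
        a = make_scenario(ScenarioConfig(seed=1, **TINY), tmp_path / "s1")
        b = make_scenario(ScenarioConfig(seed=2, **TINY), tmp_path / "s2")
        assert a["occurrences"].read_bytes() != b["occurrences"].read_bytes()
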