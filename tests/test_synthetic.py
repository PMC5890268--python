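"""Synthetic campaign generator: ground truth, moments, determinism."""

import numpy as np
import pandas as pd
import pytest

from catenaflux.fluxes import QcPolicy, estimate_fluxes
from catenaflux.synthetic import (CatenaConfig, ConfigurationError,
                                  FluxRegimeSpec, MalfunctionSpec,
                                  PERIODS, RegimeSpec,
                                  default_chem_means,
                                  generate_chamber_traces, generate_rainfall,
                                  generate_sensor_series, generate_soil_chem,
                                  rainfall_anomaly, sample_flux_table)


class TestCatenaConfig:
    def test_breakpoints_must_be_inside_span(self):
        with pytest.raises(ConfigurationError):
            CatenaConfig(breakpoint_dates=(pd.Timestamp("2014-01-01").date(),
                                           pd.Timestamp("2015-08-24").date(),
                                           pd.Timestamp("2015-11-24").date()))

    def test_period_of_is_half_open(self, catena):
        labels = catena.period_of(pd.to_datetime(
            ["2015-04-24", "2015-04-25", "2015-11-24", "2016-01-01"]))
        assert list(labels) == ["pre_drought", "drought", "post_drought",
                                "post_drought"]


class TestSensorSeries:
    def test_zero_noise_hits_period_means_exactly(self):
        cfg = CatenaConfig(seed=0, transition_days=0.0, n_transects=1)
        reg = RegimeSpec.default(cfg)
        reg.cells["moisture_sd"] = 0.0
        reg.cells["o2_sd"] = 0.0
        table, _ = generate_sensor_series(cfg, reg)
        table["period"] = cfg.period_of(table["timestamp"]).to_numpy()
        ridge = table[table["position"] == 1]
        for period, expect in zip(PERIODS, (0.36, 0.13, 0.25, 0.36)):
            vals = ridge.loc[ridge["period"] == period, "moisture"]
            assert np.allclose(vals, expect, atol=1e-9)

    def test_ridge_period_means_match_configured_anchors(self):
        # configured: ridge moisture 0.36 pre-drought, 0.13 during drought
        cfg = CatenaConfig(seed=1)
        reg = RegimeSpec.default(cfg)
        table, truth = generate_sensor_series(cfg, reg)
        table["period"] = cfg.period_of(table["timestamp"]).to_numpy()
        ridge = table[table["position"] == 1]
        for period, expect in (("pre_drought", 0.36), ("drought", 0.13)):
            sub = ridge[ridge["period"] == period]
            n_h = sub["timestamp"].nunique()
            cell = reg.cell(period, 1)
            # shared AR(1) weather dominates the s.e. of the period mean
            se = cell["moisture_sd"] * np.sqrt(
                reg.shared_frac * (1 + reg.ar1) / (1 - reg.ar1) / n_h)
            assert abs(sub["moisture"].mean() - expect) < 2 * se + 0.005

    def test_o2_gradient_ridge_to_valley(self, catena):
        table, _ = generate_sensor_series(catena)
        by_pos = table.groupby("position")["o2_pct"].mean()
        assert by_pos.loc[1] > by_pos.loc[7]

    def test_seed_determinism_and_seed_sensitivity(self):
        cfg = CatenaConfig(seed=9, n_transects=1, n_positions=1,
                           zone_map={1: "ridge"})
        t1, _ = generate_sensor_series(cfg)
        t2, _ = generate_sensor_series(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        t3, _ = generate_sensor_series(CatenaConfig(
            seed=10, n_transects=1, n_positions=1, zone_map={1: "ridge"}))
        assert not np.allclose(t1["moisture"], t3["moisture"])

    def test_missing_regime_cell_names_cell(self, catena):
        reg = RegimeSpec.default(catena)
        reg.cells = reg.cells.drop(("drought", 4))
        with pytest.raises(ConfigurationError, match="drought.*4"):
            generate_sensor_series(catena, reg)

    def test_monotonic_invariants_enforced(self, catena):
        reg = RegimeSpec.default(catena)
        cells = reg.cells.copy()
        cells.loc[("drought", 1), "moisture_mean"] = 0.9  # ridge wetter than valley
        with pytest.raises(ConfigurationError, match="non-decreasing"):
            RegimeSpec(cells=cells)


class TestRainfall:
    def test_drought_year_total_exact(self, catena):
        study, baseline, clim = generate_rainfall(
            catena, drought_annual_mm=2035.0)
        y2015 = study[study["date"].dt.year == 2015]["mm"].sum()
        assert 2034.0 <= y2015 <= 2036.0
        assert (study["mm"] >= 0).all()
        assert baseline["date"].dt.year.nunique() >= 10

    def test_null_anomaly_when_totals_equal(self, catena):
        study, _, clim = generate_rainfall(
            catena, baseline_annual_mm=4219.0, drought_annual_mm=4219.0)
        anom = rainfall_anomaly(study, clim)
        y2015 = anom[anom["date"].dt.year == 2015]["anomaly_mm"]
        assert abs(y2015.mean()) < 0.5  # mm/day

    def test_deterministic_under_seed(self, catena):
        s1, b1, _ = generate_rainfall(catena)
        s2, b2, _ = generate_rainfall(catena)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_negative_total_rejected(self, catena):
        with pytest.raises(ConfigurationError):
            generate_rainfall(catena, baseline_annual_mm=-1.0)


class TestChamberTraces:
    def test_zero_flux_no_noise_flat_trace(self, catena):
        spec = FluxRegimeSpec.default()
        spec.cells["mean"] = 0.0
        spec.cells["sd"] = 0.0
        spec.cells["hot_weight"] = 0.0
        traces, truth = generate_chamber_traces(
            catena, spec, MalfunctionSpec.none(),
            dates=[catena.start_date], closures_per_day=1,
            noise_ppm=0.0, noise_ppb=0.0)
        for tr in traces:
            assert np.allclose(tr.ch4_ppb, tr.ch4_ppb[0])
            assert np.allclose(tr.co2_ppm, tr.co2_ppm[0])

    def test_linear_mode_analytic_inversion(self, catena):
        traces, truth = generate_chamber_traces(
            catena, malfunctions=MalfunctionSpec.none(),
            dates=[catena.start_date], closures_per_day=1, mode="linear",
            noise_ppm=0.0, noise_ppb=0.0)
        flux_df = estimate_fluxes(traces, QcPolicy())
        merged = flux_df[flux_df["gas"] == "co2"].merge(
            truth, on=["chamber_id", "closure_start"])
        rel = np.abs(merged["flux"] - merged["true_co2_flux"]) \
            / np.abs(merged["true_co2_flux"])
        assert (rel < 1e-9).all()

    def test_no_malfunctions_all_retained(self, catena):
        traces, truth = generate_chamber_traces(
            catena, malfunctions=MalfunctionSpec.none(),
            dates=[catena.start_date], closures_per_day=2)
        assert (truth["malfunctions"] == "").all()
        assert all(tr.duration_s == 600.0 for tr in traces)
        flux_df = estimate_fluxes(traces, QcPolicy())
        co2 = flux_df[flux_df["gas"] == "co2"]
        assert co2["retained"].all()

    def test_missing_zone_regime_errors(self, catena):
        spec = FluxRegimeSpec.default()
        spec.cells = spec.cells.drop(("drought", "valley", "ch4"))
        with pytest.raises(ConfigurationError, match="valley"):
            generate_chamber_traces(catena, spec,
                                    dates=[catena.start_date])

    def test_flux_moments_converge(self):
        # sample moments approach configured moments at ~1/sqrt(n)
        spec = FluxRegimeSpec.default()
        rng = np.random.default_rng(3)
        n = 10_000
        draws = spec.draw(rng, "drought", "slope", "co2", n)
        cell = spec.cell("drought", "slope", "co2")
        assert abs(draws.mean() - cell["mean"]) < 3 * cell["sd"] / np.sqrt(n)

    def test_hot_moment_mixture_fattens_right_tail(self):
        spec = FluxRegimeSpec.default()
        rng = np.random.default_rng(4)
        hot = spec.draw(rng, "pre_drought", "valley", "ch4", 20_000)
        cold_spec = FluxRegimeSpec.default()
        cold_spec.cells["hot_weight"] = 0.0
        cold = cold_spec.draw(rng, "pre_drought", "valley", "ch4", 20_000)
        assert np.percentile(hot, 99) > np.percentile(cold, 99)


class TestFluxTable:
    def test_table_shape_and_periods(self, catena):
        tab = sample_flux_table(catena, rng=np.random.default_rng(0),
                                days_per_period=3, closures_per_day=2)
        assert set(tab["period"]) == set(PERIODS)
        assert set(tab["zone"]) == {"ridge", "slope", "valley"}
        # 4 periods x 3 days x 9 chambers x 2 closures x 2 gases
        assert len(tab) == 4 * 3 * 9 * 2 * 2


class TestSoilChem:
    def test_zero_noise_equals_cell_means(self, catena):
        df = generate_soil_chem(catena, cv=0.0, ph_sd=0.0)
        means = default_chem_means()
        row = df[(df["period"] == "drought") & (df["zone"] == "valley")]
        assert np.allclose(row["organic_p"],
                           means[("drought", "valley")]["organic_p"])

    def test_valley_organic_p_drought_ratio(self, catena):
        # configured +301%: drought mean = 4.01 x pre-drought mean
        df = generate_soil_chem(catena, cv=0.0)
        pre = df[(df["period"] == "pre_drought")
                 & (df["zone"] == "valley")]["organic_p"].mean()
        dr = df[(df["period"] == "drought")
                & (df["zone"] == "valley")]["organic_p"].mean()
        assert dr / pre == pytest.approx(4.01, rel=0.01)

    def test_six_replicates_per_cell_nonnegative(self, catena):
        df = generate_soil_chem(catena, rng=np.random.default_rng(0))
        counts = df.groupby(["period", "zone"])["replicate"].count()
        assert (counts == 6).all()
        for col in ("inorganic_p", "organic_p", "fe2", "fe3"):
            assert (df[col] >= 0).all()
        assert df["ph"].between(2, 9).all()

    def test_non_finite_mean_rejected(self, catena):
        means = default_chem_means()
        means[("drought", "valley")]["fe2"] = float("nan")
        with pytest.raises(ConfigurationError):
            generate_soil_chem(catena, means)

    def test_deterministic_under_seed(self, catena):
        d1 = generate_soil_chem(catena)
        d2 = generate_soil_chem(catena)
        pd.testing.assert_frame_equal(d1, d2)
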