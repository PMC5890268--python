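"""Upscaling: weighting, CO2e conversion, Monte Carlo, offset statistic."""

import numpy as np
import pandas as pd
import pytest

from catenaflux.synthetic import FluxRegimeSpec
from catenaflux.upscaling import (CumulativeEmissions, UpscalingConfig,
                                  ch4_offset, flux_to_daily_co2e,
                                  offset_fraction, run_monte_carlo,
                                  zone_weighted_mean)

WEIGHTS = {"ridge": 0.17, "slope": 0.65, "valley": 0.18}


def _summaries(cells):
    rows = [{"period": p, "zone": z, "gas": g, "mean": m, "sd": s}
            for (p, z, g), (m, s) in cells.items()]
    return pd.DataFrame(rows)


def _full_summaries(mean=1.0, sd=0.0, gases=("co2", "ch4")):
    cells = {}
    for p in ("pre_drought", "drought", "recovery", "post_drought"):
        for z in WEIGHTS:
            for g in gases:
                cells[(p, z, g)] = (mean, sd)
    return _summaries(cells)


class TestZoneWeightedMean:
    def test_equal_values_passthrough(self):
        assert zone_weighted_mean({z: 2.5 for z in WEIGHTS},
                                  WEIGHTS) == pytest.approx(2.5)

    def test_hand_arithmetic(self):
        # printed drought CH4 zone means: net ecosystem sink
        v = {"ridge": -1.13, "slope": -1.93, "valley": 1.67}
        assert zone_weighted_mean(v, WEIGHTS) == pytest.approx(-1.146, abs=1e-4)
        assert zone_weighted_mean(v, WEIGHTS) < 0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            zone_weighted_mean({"a": 1.0, "b": 2.0}, {"a": 0.5, "b": 0.6})
        with pytest.raises(ValueError, match="match"):
            zone_weighted_mean({"a": 1.0}, {"a": 0.5, "b": 0.5})


class TestCo2eConversion:
    def test_zero_flux_zero_co2e(self):
        assert flux_to_daily_co2e(0.0, "ch4") == 0.0

    def test_ch4_dimensional_oracle(self):
        # independent one-line computation
        expected = 86400 * 1e4 * 1e-9 * 16.04 * 34 / 1000
        got = flux_to_daily_co2e(1.0, "ch4")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.4713, abs=5e-4)

    def test_sign_preserved(self):
        assert flux_to_daily_co2e(-2.0, "ch4") < 0

    def test_co2_unchanged_by_unit_gwp(self):
        base = flux_to_daily_co2e(1.0, "co2")
        assert base == pytest.approx(86400 * 1e4 * 1e-6 * 44.01 / 1000,
                                     rel=1e-12)

    def test_unknown_gas_rejected(self):
        with pytest.raises(KeyError):
            flux_to_daily_co2e(1.0, "n2o")


class TestMonteCarlo:
    def test_zero_variance_equals_closed_form(self):
        cfg = UpscalingConfig(n_sims=200)
        mc = run_monte_carlo(_full_summaries(mean=2.0, sd=0.0), cfg,
                             rng=np.random.default_rng(0))
        for gas in ("co2", "ch4"):
            e = mc[gas]
            expected = 326 * flux_to_daily_co2e(2.0, gas)
            assert e.total == pytest.approx(expected, rel=1e-12)
            assert e.ci_high - e.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_linearity_in_flux_scale(self):
        cfg = UpscalingConfig(n_sims=50)
        a = run_monte_carlo(_full_summaries(mean=1.0), cfg,
                            rng=np.random.default_rng(0))["ch4"]
        b = run_monte_carlo(_full_summaries(mean=3.0), cfg,
                            rng=np.random.default_rng(0))["ch4"]
        assert b.total == pytest.approx(3 * a.total, rel=1e-12)

    def test_additivity_of_period_decomposition(self):
        summaries = _full_summaries(mean=1.5, sd=0.4)
        cfg = UpscalingConfig(n_sims=500)
        e = run_monte_carlo(summaries, cfg,
                            rng=np.random.default_rng(3))["co2"]
        assert sum(e.per_period.values()) == pytest.approx(e.total, rel=1e-9)
        draw_totals = e.per_period_draws.sum(axis=1)
        assert e.total == pytest.approx(float(draw_totals.mean()), rel=1e-12)

    def test_seeded_determinism(self):
        summaries = _full_summaries(mean=1.0, sd=0.5)
        cfg = UpscalingConfig(n_sims=100)
        a = run_monte_carlo(summaries, cfg, rng=np.random.default_rng(9))
        b = run_monte_carlo(summaries, cfg, rng=np.random.default_rng(9))
        assert a["co2"].total == b["co2"].total
        assert a["ch4"].ci_low == b["ch4"].ci_low

    def test_baseline_scenario_uses_pre_drought_everywhere(self):
        cells = {}
        for z in WEIGHTS:
            cells[("pre_drought", z, "co2")] = (1.0, 0.0)
            for p in ("drought", "recovery", "post_drought"):
                cells[(p, z, "co2")] = (9.0, 0.0)
        cfg = UpscalingConfig(n_sims=10)
        e = run_monte_carlo(_summaries(cells), cfg, scenario="baseline",
                            rng=np.random.default_rng(0),
                            gases=("co2",))["co2"]
        assert e.total == pytest.approx(326 * flux_to_daily_co2e(1.0, "co2"),
                                        rel=1e-12)

    def test_missing_cell_named(self):
        summaries = _full_summaries().query(
            "~(period == 'recovery' and zone == 'valley' and gas == 'ch4')")
        with pytest.raises(KeyError, match="recovery.*valley.*ch4"):
            run_monte_carlo(summaries, UpscalingConfig(n_sims=10),
                            rng=np.random.default_rng(0))

    def test_co2_draws_truncated_at_zero(self):
        summaries = _full_summaries(mean=0.3, sd=2.0)
        cfg = UpscalingConfig(n_sims=50)
        e = run_monte_carlo(summaries, cfg, rng=np.random.default_rng(1),
                            gases=("co2",))["co2"]
        assert (e.per_period_draws >= 0).all()


class TestOffset:
    def test_rebound_equals_sink_is_100pct(self):
        sink = np.full(100, 40.0)
        off = offset_fraction(sink, sink.copy())
        assert off.offset_pct == pytest.approx(100.0)
        assert off.ci_low_pct == pytest.approx(100.0)
        assert off.ci_high_pct == pytest.approx(100.0)

    def test_nonpositive_sink_draws_excluded(self):
        sink = np.array([10.0, -1.0, 0.0, 20.0])
        rebound = np.array([5.0, 5.0, 5.0, 5.0])
        off = offset_fraction(sink, rebound)
        assert off.n_excluded == 2

    def test_ci_can_straddle_100pct(self, catena):
        # drought-time CH4 sink vs. wide post-drought rebound distribution
        spec = FluxRegimeSpec.default()
        cells = {(p, z, "ch4"):
                 (spec.cell(p, z, "ch4")["mean"], spec.cell(p, z, "ch4")["sd"])
                 for p in ("pre_drought", "drought", "recovery",
                           "post_drought") for z in WEIGHTS}
        cfg = UpscalingConfig(n_sims=2000)
        e = run_monte_carlo(_summaries(cells), cfg,
                            rng=np.random.default_rng(4),
                            gases=("ch4",))["ch4"]
        off = ch4_offset(e)
        assert off.ci_high_pct > 100.0
        assert off.ci_high_pct > off.offset_pct > off.ci_low_pct

    def test_all_nonpositive_sinks_rejected(self):
        with pytest.raises(ValueError):
            offset_fraction(np.array([-1.0, 0.0]), np.array([1.0, 1.0]))


class TestInvariants:
    def test_ci_brackets_total(self):
        summaries = _full_summaries(mean=1.0, sd=0.8)
        e = run_monte_carlo(summaries, UpscalingConfig(n_sims=400),
                            rng=np.random.default_rng(2))["ch4"]
        assert e.ci_low <= e.total <= e.ci_high

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            UpscalingConfig(zone_weights={"ridge": 0.5, "slope": 0.6})
        with pytest.raises(ValueError):
            UpscalingConfig(gwp={"co2": 1.0, "ch4": -34.0})
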