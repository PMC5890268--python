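"""Chamber flux estimation: fits, unit bridge, model selection, QC."""

import math

import numpy as np
import pytest

from catenaflux.fluxes import (ChamberGeometry, FluxEstimate, QcPolicy,
                               R_GAS, UnusableTraceError,
                               concentration_rate_to_flux, estimate_flux,
                               fit_exponential, fit_linear, qc_filter,
                               select_model)

from conftest import make_trace


class TestLinearFit:
    def test_flat_trace_zero_slope_zero_se(self):
        tr = make_trace([0, 300, 600], [400, 400, 400])
        fit = fit_linear(tr, "co2")
        assert fit.slope == 0.0
        assert fit.slope_se == 0.0

    def test_noiseless_line_exact(self):
        t = np.arange(0, 601, 60)
        tr = make_trace(t, 400 + 0.02 * t)
        fit = fit_linear(tr, "co2")
        assert fit.slope == pytest.approx(0.02, abs=1e-12)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 601, 10.0)
        c = 410 + 0.015 * t + rng.normal(0, 0.5, t.size)
        tr = make_trace(t, c)
        fit = fit_linear(tr, "co2")
        # independent closed-form OLS
        a = np.column_stack([np.ones(t.size), t])
        beta, res, *_ = np.linalg.lstsq(a, c, rcond=None)
        assert fit.slope == pytest.approx(beta[1], rel=1e-12)
        sigma2 = float(res[0]) / (t.size - 2)
        se = math.sqrt(sigma2 / np.sum((t - t.mean()) ** 2))
        assert fit.slope_se == pytest.approx(se, rel=1e-10)

    def test_too_few_samples_raises(self):
        with pytest.raises(UnusableTraceError):
            make_trace([0, 10], [400, 401])

    def test_unordered_samples_hard_error(self):
        with pytest.raises(UnusableTraceError):
            make_trace([0, 20, 10], [400, 401, 402])


class TestExponentialFit:
    def test_recovers_forward_simulated_curve(self):
        c_inf, c0, k = 500.0, 400.0, 0.005
        t = np.arange(0, 601, 10.0)
        c = c_inf + (c0 - c_inf) * np.exp(-k * t)
        fit = fit_exponential(make_trace(t, c), "co2")
        assert fit.converged
        # initial tangent slope = k * (c_inf - c0) = 0.5 ppm/s
        assert fit.initial_slope == pytest.approx(0.5, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-4)

    def test_degenerates_to_linear_at_small_curvature(self):
        # k * t_max = 0.006 << 1: both models must agree within 1%
        k, s0 = 1e-5, 0.02
        t = np.arange(0, 601, 10.0)
        c = 400 + s0 * (1 - np.exp(-k * t)) / k
        tr = make_trace(t, c)
        lin = fit_linear(tr, "co2")
        exp = fit_exponential(tr, "co2")
        assert exp.initial_slope == pytest.approx(lin.slope, rel=0.01)

    def test_constant_trace_zero_slope(self):
        t = np.arange(0, 601, 60.0)
        fit = fit_exponential(make_trace(t, np.full(t.size, 400.0)), "co2")
        assert fit.initial_slope == pytest.approx(0.0, abs=1e-9)

    def test_uptake_trace_negative_slope_both_models(self):
        t = np.arange(0, 601, 30.0)
        c = 1900 - 0.05 * t * np.exp(-0.0005 * t)  # decreasing
        tr = make_trace(t, 400 - 0.01 * t, ch4=c)
        assert fit_linear(tr, "ch4").slope < 0
        assert fit_exponential(tr, "ch4").initial_slope < 0
        assert fit_linear(tr, "co2").slope < 0


class TestUnitBridge:
    def test_zero_slope_zero_flux(self, geometry):
        tr = make_trace([0, 300, 600], [400, 400, 400], geometry=geometry)
        assert concentration_rate_to_flux(0.0, tr) == 0.0

    def test_dimensional_analysis_oracle(self, geometry):
        tr = make_trace([0, 300, 600], [400, 403, 406], geometry=geometry,
                        temp_c=25.0, press_kpa=101.325)
        # independent hand computation of P*V/(R*T*A)
        expected = 0.01 * (101325.0 * 0.02951
                           / (R_GAS * 298.15 * 0.1964))
        assert concentration_rate_to_flux(0.01, tr) == pytest.approx(
            expected, rel=1e-12)

    def test_flux_linear_in_volume(self):
        tr1 = make_trace([0, 300, 600], [400, 403, 406],
                         geometry=ChamberGeometry(0.02, 0.2))
        tr2 = make_trace([0, 300, 600], [400, 403, 406],
                         geometry=ChamberGeometry(0.04, 0.2))
        f1 = concentration_rate_to_flux(0.01, tr1)
        assert concentration_rate_to_flux(0.01, tr2) == pytest.approx(2 * f1)

    def test_nonphysical_state_raises(self):
        tr = make_trace([0, 300, 600], [400, 403, 406], temp_c=-300.0)
        with pytest.raises(ValueError):
            concentration_rate_to_flux(0.01, tr)


def _est(ratio, model="linear", flux=1.0):
    return FluxEstimate(chamber_id="S1", zone="slope",
                        closure_start=None, gas="co2", flux=flux,
                        standard_error=abs(ratio * flux), model=model,
                        uncertainty_ratio=ratio)


class TestModelSelection:
    def test_smaller_ratio_wins(self):
        chosen = select_model(_est(0.1), _est(0.4, "exponential"), QcPolicy())
        assert chosen.model == "linear"
        chosen = select_model(_est(0.5), _est(0.2, "exponential"), QcPolicy())
        assert chosen.model == "exponential"

    def test_both_uncertain_not_retained(self):
        chosen = select_model(_est(1.5), _est(2.0, "exponential"), QcPolicy())
        assert not chosen.retained
        assert "both_uncertain" in chosen.qc_flags

    def test_exact_tie_prefers_linear(self):
        chosen = select_model(_est(0.3), _est(0.3, "exponential"), QcPolicy())
        assert chosen.model == "linear"


class TestQcFilter:
    def test_short_deployment_flagged(self):
        t = np.arange(0, 481, 60.0)  # 8-minute closure
        tr = make_trace(t, 400 + 0.02 * t)
        est = qc_filter(tr, _est(0.1), QcPolicy())
        assert "short_deployment" in est.qc_flags
        assert not est.retained

    def test_clean_closure_unflagged(self):
        t = np.arange(0, 601, 60.0)
        tr = make_trace(t, 400 + 0.02 * t)
        est = qc_filter(tr, _est(0.1), QcPolicy())
        assert est.qc_flags == set()
        assert est.retained

    def test_flush_failure_flagged(self):
        t = np.arange(0, 601, 60.0)
        tr = make_trace(t, 800 + 0.02 * t, ambient={"co2": 400.0,
                                                    "ch4": 1900.0})
        est = qc_filter(tr, _est(0.1), QcPolicy(ambient_band=0.25))
        assert "flush_failure" in est.qc_flags

    def test_covariate_bounds_flagged(self):
        t = np.arange(0, 601, 60.0)
        tr = make_trace(t, 400 + 0.02 * t, temp_c=60.0)
        est = qc_filter(tr, _est(0.1), QcPolicy())
        assert "temperature_out_of_bounds" in est.qc_flags

    def test_loosening_policy_monotone_in_retained(self):
        from catenaflux.synthetic import (CatenaConfig, MalfunctionSpec,
                                          generate_chamber_traces)
        from catenaflux.fluxes import estimate_fluxes

        cfg = CatenaConfig(seed=11)
        traces, _ = generate_chamber_traces(
            cfg, malfunctions=MalfunctionSpec(0.2, 0.2, 0.2, 0.1, 0.0),
            dates=[cfg.start_date], closures_per_day=6)
        strict = QcPolicy()
        loose = QcPolicy(min_duration_s=200, max_duration_s=1000,
                         ambient_band=2.0, temp_c_bounds=(-20, 100),
                         press_kpa_bounds=(50, 200),
                         max_uncertainty_ratio=50.0)
        n_strict = int(estimate_fluxes(traces, strict)["retained"].sum())
        n_loose = int(estimate_fluxes(traces, loose)["retained"].sum())
        assert n_loose >= n_strict


class TestEndToEnd:
    def test_estimate_flux_retains_clean_trace(self, geometry):
        t = np.arange(0, 601, 10.0)
        tr = make_trace(t, 410 + 0.02 * t, geometry=geometry,
                        ambient={"co2": 410.0, "ch4": 1900.0})
        est = estimate_flux(tr, "co2")
        assert est.retained
        assert est.flux > 0
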