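"""Chamber-based soil greenhouse-gas flux estimation with quality control.

A closed dynamic chamber of known volume and basal area sits on the soil
surface; the surface flux of CO2 or CH4 is inferred from the concentration
change inside the headspace during a ~10-minute closure.  Two rate models are
fitted to every trace:

* a straight line ``c(t) = c0 + s*t`` (ordinary least squares), and
* a saturating exponential ``c(t) = c_inf + (c0 - c_inf) * exp(-k*t)``,
  whose reported rate is the tangent slope at ``t = 0`` — the rate before
  the headspace build-up starts suppressing the diffusion gradient.

The model with the smaller relative uncertainty (standard error divided by
the absolute rate) wins; if both are too uncertain the flux is discarded.
Closures that were too short or too long, started away from ambient
concentration (failed flush), or carry anomalous temperature / humidity /
pressure readings are flagged and removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GAS_UNITS",
    "R_GAS",
    "ChamberGeometry",
    "ChamberTrace",
    "ExponentialFit",
    "FluxEstimate",
    "LinearFit",
    "QcPolicy",
    "UnusableTraceError",
    "concentration_rate_to_flux",
    "estimate_flux",
    "estimate_fluxes",
    "fit_exponential",
    "fit_linear",
    "qc_filter",
    "select_model",
]

#: Ideal gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Reported flux units per gas.  Concentrations are mole fractions (ppm for
#: CO2, ppb for CH4), so a concentration rate in ppm/s maps to a surface flux
#: in umol m^-2 s^-1 and ppb/s to nmol m^-2 s^-1 through the same molar
#: bridge; no extra factor is needed.
GAS_UNITS: Mapping[str, str] = {
    "co2": "umol m-2 s-1",
    "ch4": "nmol m-2 s-1",
}


class UnusableTraceError(ValueError):
    """Raised when a trace cannot support a fit at all (too few samples,
    degenerate time axis, unordered samples)."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber headspace volume (m^3) and basal area (m^2)."""

    volume_m3: float
    area_m2: float

    def __post_init__(self) -> None:
        if not (self.volume_m3 > 0 and self.area_m2 > 0):
            raise ValueError("chamber volume and area must be positive")


@dataclass
class ChamberTrace:
    """One chamber closure: concentration samples plus covariates.

    ``t_s`` holds seconds since closure, strictly increasing from 0.
    ``ambient`` holds the pre-closure concentration per gas, in the gas's
    native unit (ppm for CO2, ppb for CH4).
    """

    chamber_id: str
    zone: str
    closure_start: datetime
    t_s: np.ndarray
    co2_ppm: np.ndarray
    ch4_ppb: np.ndarray
    temp_c: float
    rh_pct: float
    press_kpa: float
    geometry: ChamberGeometry
    ambient: Mapping[str, float]

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        self.ch4_ppb = np.asarray(self.ch4_ppb, dtype=float)
        n = self.t_s.size
        if n < 3:
            raise UnusableTraceError(
                f"trace {self.chamber_id} @ {self.closure_start}: "
                f"{n} samples (< 3)"
            )
        if self.co2_ppm.size != n or self.ch4_ppb.size != n:
            raise UnusableTraceError("concentration arrays must match t_s length")
        if self.t_s[0] < 0 or np.any(np.diff(self.t_s) <= 0):
            raise UnusableTraceError(
                "sample times must be non-negative and strictly increasing"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def concentrations(self, gas: str) -> np.ndarray:
        if gas == "co2":
            return self.co2_ppm
        if gas == "ch4":
            return self.ch4_ppb
        raise KeyError(f"unknown gas {gas!r}")


@dataclass(frozen=True)
class QcPolicy:
    """Quality-control thresholds for chamber closures.

    Defaults: closures shorter than 9 min or longer than 11 min are
    rejected; the initial concentration may deviate from ambient by at most
    25% (relative); chamber temperature, relative humidity and pressure must
    sit inside plausible field ranges; and a flux whose best model still has
    se/|flux| above ``max_uncertainty_ratio`` is discarded.  The first
    ``deadband_s`` seconds of each closure are excluded from fitting
    (headspace mixing artifact).
    """

    min_duration_s: float = 540.0
    max_duration_s: float = 660.0
    ambient_band: float = 0.25
    temp_c_bounds: tuple[float, float] = (10.0, 45.0)
    rh_max_pct: float = 100.0
    press_kpa_bounds: tuple[float, float] = (85.0, 110.0)
    max_uncertainty_ratio: float = 1.0
    deadband_s: float = 30.0
    min_samples: int = 8

    def __post_init__(self) -> None:
        if not self.min_duration_s < self.max_duration_s:
            raise ValueError("min_duration_s must be < max_duration_s")
        if self.ambient_band <= 0 or self.max_uncertainty_ratio <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class LinearFit:
    slope: float          # concentration units per second
    slope_se: float
    intercept: float
    rss: float
    n: int


@dataclass(frozen=True)
class ExponentialFit:
    initial_slope: float  # tangent rate at t = 0, concentration units per second
    slope_se: float
    k: float              # 1/s
    c_inf: float
    c0: float
    converged: bool


@dataclass
class FluxEstimate:
    """QC-flagged surface flux for one gas from one closure."""

    chamber_id: str
    zone: str
    closure_start: datetime
    gas: str
    flux: float
    standard_error: float
    model: str                      # "linear" | "exponential"
    uncertainty_ratio: float
    qc_flags: set[str] = field(default_factory=set)
    retained: bool = True

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise ValueError("standard_error must be >= 0")
        if self.retained and self.qc_flags:
            raise ValueError("retained estimate cannot carry QC flags")


def _fit_window(trace: ChamberTrace, gas: str, deadband_s: float):
    t = trace.t_s
    c = trace.concentrations(gas)
    keep = t >= deadband_s
    t, c = t[keep], c[keep]
    if t.size < 3:
        raise UnusableTraceError(
            f"fewer than 3 samples after {deadband_s:g}s deadband"
        )
    if np.ptp(t) == 0:
        raise UnusableTraceError("zero time variance in fit window")
    return t, c


def fit_linear(trace: ChamberTrace, gas: str, deadband_s: float = 0.0) -> LinearFit:
    """OLS of concentration on elapsed time; slope SE from residual variance.

    A perfect fit (or n == 2 residual dof == 0) yields slope_se == 0.
    """
    t, c = _fit_window(trace, gas, deadband_s)
    n = t.size
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ c) / sxx
    intercept = float(c.mean() - slope * t.mean())
    resid = c - (intercept + slope * t)
    rss = float(resid @ resid)
    dof = n - 2
    sigma2 = rss / dof if dof > 0 else 0.0
    slope_se = math.sqrt(max(sigma2, 0.0) / sxx)
    return LinearFit(slope=slope, slope_se=slope_se, intercept=intercept,
                     rss=rss, n=n)


def _exp_model(t: np.ndarray, c0: float, s0: float, k: float) -> np.ndarray:
    # c(t) = c0 + s0 * (1 - exp(-k t)) / k, stable as k -> 0 via expm1.
    return c0 + s0 * (-np.expm1(-k * t)) / k


def fit_exponential(
    trace: ChamberTrace, gas: str, deadband_s: float = 0.0
) -> ExponentialFit:
    """Nonlinear least squares of the saturating chamber model.

    Parametrised as ``c(t) = c0 + s0*(1 - exp(-k t))/k`` so the reported
    flux rate ``s0`` (the t=0 tangent slope, equal to ``k*(c_inf - c0)``)
    carries its standard error directly from the parameter covariance.
    Non-convergence after bounded restarts returns a flagged estimate with
    infinite standard error rather than raising.
    """
    t, c = _fit_window(trace, gas, deadband_s)
    if t.size < 4:
        raise UnusableTraceError("exponential fit needs >= 4 samples")
    lin = fit_linear(trace, gas, deadband_s)
    scale = max(abs(lin.slope) * np.ptp(t), np.std(c), 1e-6)
    bounds = ([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, 1.0])
    for k0 in (1e-3, 1e-4, 1e-2, 1e-1):
        try:
            popt, pcov = curve_fit(
                _exp_model, t, c,
                p0=[float(c[0]), lin.slope if lin.slope != 0 else 1e-9 * scale, k0],
                bounds=bounds, maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        c0_hat, s0_hat, k_hat = (float(v) for v in popt)
        var_s0 = float(pcov[1, 1])
        se = math.sqrt(var_s0) if np.isfinite(var_s0) and var_s0 >= 0 else math.inf
        c_inf = c0_hat + s0_hat / k_hat
        return ExponentialFit(initial_slope=s0_hat, slope_se=se, k=k_hat,
                              c_inf=c_inf, c0=c0_hat, converged=True)
    return ExponentialFit(initial_slope=lin.slope, slope_se=math.inf, k=math.nan,
                          c_inf=math.nan, c0=float(c[0]), converged=False)


def concentration_rate_to_flux(slope: float, trace: ChamberTrace) -> float:
    """Convert a headspace concentration rate to a surface molar flux.

    flux = slope * P*V / (R*T*A).  With ``slope`` as a mole-fraction rate
    (ppm/s or ppb/s) the result is in umol m^-2 s^-1 or nmol m^-2 s^-1
    respectively; the ppm->umol and ppb->nmol bridges cancel.
    """
    t_k = trace.temp_c + 273.15
    p_pa = trace.press_kpa * 1000.0
    if t_k <= 0:
        raise ValueError(f"non-physical temperature {trace.temp_c} degC")
    if p_pa <= 0:
        raise ValueError(f"non-physical pressure {trace.press_kpa} kPa")
    g = trace.geometry
    return slope * p_pa * g.volume_m3 / (R_GAS * t_k * g.area_m2)


def _uncertainty_ratio(flux: float, se: float) -> float:
    if flux == 0:
        return math.inf if se > 0 else 0.0
    return abs(se / flux)


def select_model(
    linear_est: FluxEstimate,
    exp_est: FluxEstimate,
    policy: QcPolicy,
) -> FluxEstimate:
    """Pick the candidate with the smaller uncertainty ratio (tie -> linear).

    If both ratios exceed ``policy.max_uncertainty_ratio`` the winning
    candidate is returned flagged ``both_uncertain`` and not retained.
    """
    chosen = linear_est if linear_est.uncertainty_ratio <= exp_est.uncertainty_ratio \
        else exp_est
    chosen = replace(chosen, qc_flags=set(chosen.qc_flags))
    if (linear_est.uncertainty_ratio > policy.max_uncertainty_ratio
            and exp_est.uncertainty_ratio > policy.max_uncertainty_ratio):
        chosen.qc_flags.add("both_uncertain")
        chosen.retained = False
    return chosen


def qc_filter(
    trace: ChamberTrace, estimate: FluxEstimate, policy: QcPolicy
) -> FluxEstimate:
    """Apply closure-level QC flags; ``retained`` is False iff any flag set."""
    est = replace(estimate, qc_flags=set(estimate.qc_flags))
    dur = trace.duration_s
    if dur < policy.min_duration_s:
        est.qc_flags.add("short_deployment")
    elif dur > policy.max_duration_s:
        est.qc_flags.add("long_deployment")
    if trace.n_samples < policy.min_samples:
        est.qc_flags.add("too_few_samples")
    ambient = trace.ambient.get(est.gas)
    if ambient is not None and ambient != 0:
        initial = float(trace.concentrations(est.gas)[0])
        if abs(initial - ambient) / abs(ambient) > policy.ambient_band:
            est.qc_flags.add("flush_failure")
    lo_t, hi_t = policy.temp_c_bounds
    if not (lo_t <= trace.temp_c <= hi_t):
        est.qc_flags.add("temperature_out_of_bounds")
    if trace.rh_pct > policy.rh_max_pct or trace.rh_pct < 0:
        est.qc_flags.add("humidity_out_of_bounds")
    lo_p, hi_p = policy.press_kpa_bounds
    if not (lo_p <= trace.press_kpa <= hi_p):
        est.qc_flags.add("pressure_out_of_bounds")
    est.retained = not est.qc_flags
    return est


def estimate_flux(
    trace: ChamberTrace, gas: str, policy: QcPolicy | None = None
) -> FluxEstimate:
    """Full per-closure pipeline: fit both models, convert to surface units,
    select by uncertainty ratio, then apply closure QC."""
    policy = policy or QcPolicy()

    def _candidate(slope: float, se: float, model: str) -> FluxEstimate:
        flux = concentration_rate_to_flux(slope, trace)
        flux_se = abs(concentration_rate_to_flux(se, trace))
        return FluxEstimate(
            chamber_id=trace.chamber_id, zone=trace.zone,
            closure_start=trace.closure_start, gas=gas,
            flux=flux, standard_error=flux_se, model=model,
            uncertainty_ratio=_uncertainty_ratio(flux, flux_se),
        )

    lin = fit_linear(trace, gas, policy.deadband_s)
    exp = fit_exponential(trace, gas, policy.deadband_s)
    lin_est = _candidate(lin.slope, lin.slope_se, "linear")
    exp_est = _candidate(
        exp.initial_slope,
        exp.slope_se if math.isfinite(exp.slope_se) else math.inf,
        "exponential",
    )
    if math.isinf(exp_est.standard_error):
        exp_est.uncertainty_ratio = math.inf
    chosen = select_model(lin_est, exp_est, policy)
    if not exp.converged and chosen.model == "exponential":
        chosen.qc_flags.add("nonconvergent_fit")
        chosen.retained = False
    return qc_filter(trace, chosen, policy)


def estimate_fluxes(
    traces: Iterable[ChamberTrace],
    policy: QcPolicy | None = None,
    gases: Sequence[str] = ("co2", "ch4"),
) -> pd.DataFrame:
    """Estimate fluxes for every closure x gas; one row each.

    Columns: chamber_id, zone, closure_start, date, gas, flux, standard_error,
    model, uncertainty_ratio, qc_flags (';'-joined), retained.
    """
    policy = policy or QcPolicy()
    rows = []
    for trace in traces:
        for gas in gases:
            est = estimate_flux(trace, gas, policy)
            rows.append({
                "chamber_id": est.chamber_id,
                "zone": est.zone,
                "closure_start": est.closure_start,
                "date": pd.Timestamp(est.closure_start).normalize(),
                "gas": gas,
                "flux": est.flux,
                "standard_error": est.standard_error,
                "model": est.model,
                "uncertainty_ratio": est.uncertainty_ratio,
                "qc_flags": ";".join(sorted(est.qc_flags)),
                "retained": est.retained,
            })
    return pd.DataFrame(rows)
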