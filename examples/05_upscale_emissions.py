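"""Ecosystem-scale cumulative CO2e by Monte Carlo upscaling.

Takes the period x zone flux distribution (the reported zone means where
printed, interpolations elsewhere), weights zones by their landscape share
(ridge 17% / slope 65% / valley 18%), and simulates 5000 daily-time-step
campaigns to get cumulative kg CO2e per hectare with 95% CIs, for the
observed drought year and a no-drought baseline counterfactual.
"""

import numpy as np
import pandas as pd

from catenaflux import UpscalingConfig, ch4_offset, run_monte_carlo
from catenaflux.synthetic import FluxRegimeSpec

spec = FluxRegimeSpec.default()
summaries = spec.cells.reset_index()[["period", "zone", "gas", "mean", "sd"]]

cfg = UpscalingConfig(n_sims=5000)
rng = np.random.default_rng(7)
obs = run_monte_carlo(summaries, cfg, "observed", rng=rng)
base = run_monte_carlo(summaries, cfg, "baseline", rng=rng)

for gas in ("co2", "ch4"):
    e = obs[gas]
    print(f"{gas.upper()} observed: {e.total:9.0f} kg CO2e/ha "
          f"(95% CI {e.ci_low:.0f}-{e.ci_high:.0f}) over {e.window_days} d")
    print(f"{gas.upper()} baseline: {base[gas].total:9.0f} kg CO2e/ha")

e = obs["ch4"]
sink = -(e.per_period["drought"] + e.per_period["recovery"])
off = ch4_offset(e)
print(f"\nCH4 sink during drought + recovery: {sink:.0f} kg CO2e/ha")
print(f"Post-drought rebound (first {cfg.post_drought_window_days} d): "
      f"{off.rebound:.0f} kg CO2e/ha")
print(f"Rebound offsets {off.offset_pct:.0f}% of the sink "
      f"(95% CI {off.ci_low_pct:.0f}-{off.ci_high_pct:.0f}%)")
extra = obs["co2"].total - base["co2"].total
print(f"\nExtra CO2 vs. baseline: {extra / 1000:.1f} Mg CO2e/ha")
print("\nDrought turns the catena into a stronger CH4 sink, but the "
      "post-drought\nemission burst pays that sink back within weeks, while "
      "elevated soil\nrespiration adds several Mg CO2e per hectare.")
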