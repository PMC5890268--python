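"""Estimate chamber fluxes from concentration traces, with QC.

Forward-generates one day of chamber closures from known fluxes (including
injected malfunctions), runs the linear/exponential fits with
uncertainty-ratio model selection, and compares estimates with truth.
"""

import numpy as np

from catenaflux import CatenaConfig, MalfunctionSpec, QcPolicy, estimate_fluxes
from catenaflux.synthetic import generate_chamber_traces

cfg = CatenaConfig(seed=7)
traces, truth = generate_chamber_traces(
    cfg, malfunctions=MalfunctionSpec(0.05, 0.05, 0.05, 0.03, 0.0),
    dates=[cfg.breakpoint_dates[0]],  # first day of the drought period
    closures_per_day=6)
flux_df = estimate_fluxes(traces, QcPolicy())

co2 = flux_df[flux_df["gas"] == "co2"].merge(
    truth, on=["chamber_id", "closure_start"])
ok = co2[co2["retained"]]
err = (ok["flux"] - ok["true_co2_flux"]).abs()
print(f"{len(co2)} CO2 closures, {len(ok)} retained after QC")
print(f"median |estimate - truth| = {err.median():.3f} umol m-2 s-1")
print("\nQC flags raised:")
print(co2.loc[co2['qc_flags'] != '', 'qc_flags'].value_counts())
print("\nModel choice (smaller se/|flux| wins):")
print(ok["model"].value_counts())
print("\nEvery injected malfunction should appear above as a rejection; "
      "clean closures\nare recovered to within the trace noise.")
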