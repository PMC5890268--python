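"""Period x zone flux statistics: summaries, repeated-measures ANOVA,
hot moments.

Draws a season of chamber fluxes from the period x zone regimes, summarises
each cell, runs the repeated-measures two-way ANOVA (chamber as subject),
and finds the CH4 hot-moment thresholds.
"""

import numpy as np

from catenaflux import CatenaConfig, anova_two_way, hot_moments, summarize
from catenaflux.synthetic import sample_flux_table

cfg = CatenaConfig(seed=11)
tab = sample_flux_table(cfg, rng=np.random.default_rng(11),
                        days_per_period=20, closures_per_day=6)

co2 = tab[tab["gas"] == "co2"]
print("CO2 flux (umol m-2 s-1) mean +/- sem by period x zone:")
summ = summarize(co2, "flux")
for _, r in summ.iterrows():
    print(f"  {r['period']:>12s} {r['zone']:>6s}: "
          f"{r['mean']:5.2f} +/- {r['sem']:.2f}  (n={r['n']})")

res = anova_two_way(co2, "flux", repeated=True, log_transform=True)
print("\nRepeated-measures two-way ANOVA on log CO2:")
print(res.table.round(4))

ch4 = tab[tab["gas"] == "ch4"]
thresholds, flagged = hot_moments(ch4, "flux")
print("\nCH4 hot-moment thresholds (per-period 90th percentile, "
      "nmol m-2 s-1):")
print(thresholds.round(2).to_string(index=False))
print(f"\n{int(flagged['hot'].sum())} closures flagged as hot moments. "
      "Thresholds collapse by an\norder of magnitude during drought and "
      "recovery — hot moments vanish while\nsoils are dry and aerated, and "
      "return with a vengeance post-drought.")
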