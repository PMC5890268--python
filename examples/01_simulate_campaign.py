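"""Generate a synthetic drought-year field campaign with known ground truth.

Builds the hourly sensor record (35 sensors, 5 transects x 7 positions),
the daily rainfall record with its 10-year baseline, and a soil-chemistry
survey, then prints what the drought did to each topographic zone.
"""

import numpy as np

from catenaflux import (CatenaConfig, generate_rainfall,
                        generate_sensor_series, generate_soil_chem,
                        rainfall_anomaly)

cfg = CatenaConfig(seed=42)
sensors, truth = generate_sensor_series(cfg)
rain, baseline, clim = generate_rainfall(cfg)
chem = generate_soil_chem(cfg)

sensors["period"] = cfg.period_of(sensors["timestamp"]).to_numpy()
print("Ridge (position 1) soil moisture by drought period:")
ridge = sensors[sensors["position"] == 1]
print(ridge.groupby("period", sort=False)["moisture"].mean().round(3))
print("\nValley (position 7) soil O2 % by period:")
valley = sensors[sensors["position"] == 7]
print(valley.groupby("period", sort=False)["o2_pct"].mean().round(1))

y2015 = rain[rain["date"].dt.year == 2015]["mm"].sum()
anom = rainfall_anomaly(rain, clim)
neg_days = int((anom[anom["date"].dt.year == 2015]["anomaly_mm"] < 0).sum())
print(f"\nDrought-year rainfall: {y2015:.0f} mm "
      f"({neg_days} days below the baseline climatology)")

print("\nValley organic P (mg/kg): pre-drought vs. drought means:")
vp = chem[chem["zone"] == "valley"].groupby("period")["organic_p"].mean()
print(vp.round(1))
print("\nThe ridge dries hardest, the valley aerates, rainfall is roughly "
      "half of baseline,\nand organic P accumulates in drought-stricken "
      "valley soils — the structure every\ndownstream stage is tested "
      "against (true breakpoints are in the truth dict).")
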