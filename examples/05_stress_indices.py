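"""Compute the fruit water stress index family for one measuring day.

Uses a synthetic weather series for the Eq.-style air-temperature window
(mean of the four full hours ending two hours before measurement) and a set
of detected fruit temperatures; prints FWSI_I, FWSI_N, delta-T and VPD.
"""

import numpy as np
import pandas as pd

from fruitherm import (make_weather, air_temp_avg, vpd, index_records,
                       summarize)

weather = make_weather(t_range=(12.0, 28.0), rh_range=(45.0, 95.0), seed=9)
hour = 13
t_a = air_temp_avg(weather, hour)          # hours 8..11 for a 13:00 reading
ts = pd.to_datetime(weather.timestamp)
at_hour = weather[ts.dt.hour == hour]
vpd_kpa = vpd(at_hour.t_air_c.mean(), at_hour.rh_pct.mean())
print(f"air reference T_a = {t_a:.2f} degC (window ends 2 h before {hour}:00), "
      f"VPD at {hour}:00 = {vpd_kpa:.2f} kPa")

rng = np.random.default_rng(9)
fruit = pd.DataFrame({
    "fruit_id": np.arange(1, 41),
    "t_est_c": rng.normal(24.0, 2.5, 40),
    "height_m": rng.uniform(0.8, 2.8, 40),
    "timestamp": pd.Timestamp("2022-09-21 13:00"),
})

records = index_records(fruit, t_a=t_a, vpd_kpa=vpd_kpa)
print(f"{len(records)} fruit: FWSI_I mean {records.fwsi_i.mean():.2f} "
      f"(0 = coolest fruit, 1 = air + 5 degC), "
      f"FWSI_N mean {records.fwsi_n.mean():.2f} (day-extreme normalised), "
      f"delta-T mean {records.delta_t_c.mean():+.2f} degC")

profile = summarize(records, by="height_bin", height_bin_width=0.35,
                    height_range=(0.7, 3.0))
print("height profile (bin, mean FWSI_N, n):")
for _, row in profile.iterrows():
    print(f"  {row['height_bin']}: {row['fwsi_n_mean']:.2f} (n={row['fwsi_n_n']:.0f})")
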