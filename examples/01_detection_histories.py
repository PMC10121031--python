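"""From raw photo records to stacked detection histories.

Simulates a small camera-trap study, applies the 60-minute independence
filter, and bins the surviving records into site x occasion histories with
an effort matrix.
"""

import numpy as np

from camcooccur import SimulationConfig, simulate_study
from camcooccur.detections import build_detection_data, filter_independent_records, summarize_effort

study = simulate_study(SimulationConfig(seed=42, n_stations=12, n_surveys=3))
print(f"raw photo events: {len(study.records)}")

records = filter_independent_records(study.records, window_minutes=60)
print(f"independent records after the 60-min filter: {len(records)}")

trap_nights, table = summarize_effort(records, study.deployments)
print(f"\nsurvey effort: {trap_nights} trap-nights")
print(table.to_string(index=False))
# rate_per_100_trap_nights = 100 * records / trap-nights: the standard
# relative-abundance index for camera-trap surveys

data = build_detection_data(
    records, study.deployments, study.config.design, ("tiger_cat", "jaguarundi")
)
y = data.y["tiger_cat"]
print(f"\nstacked sites (station x survey): {data.n_sites}, occasions: {data.n_occasions}")
print(f"tiger-cat detections: {int(np.nansum(y))} occasions; "
      f"missing cells (camera off): {int(np.isnan(y).sum())}")
print("sum of the effort matrix equals the trap-nights above:",
      int(data.effort.sum()) == trap_nights)
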