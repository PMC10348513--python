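"""Kernel utilization distributions of dive locations.

The smoothing bandwidth follows h = 2 ln(mean foraging range km); dive
locations are projected about the colony and smoothed with an isotropic
Gaussian kernel.  The 50% isopleth outlines core areas, the 95%
isopleth the overall range.
"""

import datetime as dt

from divehab import dives as dv
from divehab import spaceuse as su
from divehab.simulate import SimConfig, gen_environment, gen_tracks_and_dives

cfg = SimConfig(n_birds=4, date_range=(dt.date(2021, 7, 15), dt.date(2021, 8, 13)), seed=3)
env = gen_environment(cfg)
fixes, traces, _ = gen_tracks_and_dives(cfg, env)
events = dv.assign_foraging_locations(dv.process_traces(traces), fixes)

mean_range = su.foraging_range(fixes, cfg.colony)
h = su.smoothing_scale(mean_range)
print(f"mean foraging range {mean_range:.1f} km -> h = 2 ln(range) = {h:.2f} km")

for shape in ("U", "V"):
    pts = events[(events["shape"] == shape) & events["lon"].notna()]
    ud = su.kde_ud(pts["lon"], pts["lat"], cfg.colony, h_km=h, cell_km=1.0)
    core = su.isopleth(ud, 0.5).sum() * ud.cell_area
    home = su.isopleth(ud, 0.95).sum() * ud.cell_area
    print(f"{shape}: {len(pts)} dives, 50% UD {core:,.0f} km^2, 95% UD {home:,.0f} km^2")
# V dives range over a much larger area than the coastal, clustered U
# dives, so their isopleth areas are several times larger.
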