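"""Sustained-speed filtering and 1:2:1 smoothing.

Takes a bird's raw threshold/SST positions, injects one impossible
2,000-km spike, and shows the speed filter removing exactly that point
(13.9 m/s sustained over 48 h is the ceiling), then the smoothing
shrinking the day-over-day jitter.
"""
import dataclasses

import numpy as np

from xema import PipelineConfig, Track, haversine_km, simulate_cohort, smooth_track, speed_filter
from xema.pipeline import BirdInput, geolocate_bird

config = PipelineConfig()
cohort = simulate_cohort(config, 1, 0, seed=3)
bird = cohort.birds[0]
log = []
positions = geolocate_bird(
    BirdInput(bird.itinerary.bird_id, bird.twilights, bird.sst_samples), cohort.grids, config, log
)

# sabotage one mid-track day by 2,000 km
k = len(positions) // 2
positions[k] = dataclasses.replace(positions[k], lat=positions[k].lat - 2000.0 / 111.195)
track = Track(bird.itinerary.bird_id, None, None, config.colony_lat, config.colony_lon, positions)

kept, removed = speed_filter(track, config.v_max_ms, config.sustain_window_h)
print(f"speed filter removed {len(removed)} position(s): {[p.date.isoformat() for p in removed]}")
print(f"(the injected spike was on {positions[k].date.isoformat()})")

smoothed = smooth_track(kept, config)
def mean_step(t):
    return float(np.mean([
        haversine_km((t.lats[i], t.lons[i]), (t.lats[i + 1], t.lons[i + 1]))
        for i in range(len(t) - 1)
    ]))
print(f"mean day-over-day displacement before smoothing: {mean_step(kept):6.1f} km")
print(f"mean day-over-day displacement after smoothing:  {mean_step(smoothed):6.1f} km")
print("Smoothing damps observation jitter while leaving genuine relocations")
print("(moves over 4 deg lon / 6 deg lat) untouched.")
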