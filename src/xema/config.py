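"""Pipeline configuration.

All tunable constants of the processing chain live here, with the defaults
used throughout: 13.9 m/s sustained-speed ceiling over a 48 h window,
1:2:1 smoothing with the 4 deg lon / 6 deg lat no-smooth rule, the
100 km/d 3-of-5 stopover/travel rule, and 200 km / 10 km kernel density
with 25/50/75% occupancy contours.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    # colony / deployment
    colony_lat: float = 75.8
    colony_lon: float = -96.3

    # geolocation
    sun_angle_deg: float = -3.44  # conventional geolocator calibration angle
    equinox_decl_deg: float = 5.0  # |declination| below this => equinox-flagged latitude
    sst_tolerance_c: float = 0.5
    sst_search_band_deg: float = 15.0
    # when to apply the SST correction: "auto" = wherever the day-length
    # latitude is ill-conditioned (equinox window, low latitudes), "equinox" =
    # only equinox-flagged/missing days, "all" = every day with a tag sample
    sst_scope: str = "auto"
    sst_min_sensitivity: float = 4.0  # min day-length sensitivity, min/deg lat

    # track cleaning
    v_max_ms: float = 13.9
    sustain_window_h: float = 48.0
    strict_pairwise: bool = False
    smooth_weights: tuple = (1.0, 2.0, 1.0)
    jump_limit_lon_deg: float = 4.0
    jump_limit_lat_deg: float = 6.0

    # segmentation
    seg_threshold_kmd: float = 100.0
    seg_window: int = 5
    seg_count: int = 3
    seg_anchor: str = "forward"  # or "centered"
    seg_effect: str = "first_qualifying"  # or "window_start"
    burst_multiplier: float = 2.0  # centroid separation in units of seg_threshold km
    breeding_radius_km: float = 20.0
    basin_divide_lon: float = -70.0  # west of this => Pacific
    min_winter_positions: int = 30
    winter_pool_radius_km: float = 500.0  # pass-1 "post-migration" radius around the track terminus

    # space use
    kde_bandwidth_km: float = 200.0
    kde_cell_km: float = 10.0
    kde_kernel: str = "quartic"  # or "gaussian" (bandwidth then radius/2.58)
    contour_levels: tuple = (25.0, 50.0, 75.0)
    simplify_tolerance_km: float = 10.0
    include_fixed_in_kde: bool = False

    # shared numerics
    earth_radius_km: float = 6371.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        positive = (
            "equinox_decl_deg sst_tolerance_c sst_search_band_deg v_max_ms "
            "sustain_window_h jump_limit_lon_deg jump_limit_lat_deg seg_threshold_kmd "
            "burst_multiplier breeding_radius_km kde_bandwidth_km kde_cell_km "
            "earth_radius_km"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.seg_count > self.seg_window:
            raise ValueError("seg_count must be <= seg_window")
        if self.seg_window < 1 or self.seg_count < 1:
            raise ValueError("segmentation window/count must be >= 1")
        if any(not (0.0 < lv < 100.0) for lv in self.contour_levels):
            raise ValueError("contour levels must lie in (0, 100)")
        if self.seg_anchor not in ("forward", "centered"):
            raise ValueError("seg_anchor must be 'forward' or 'centered'")
        if self.seg_effect not in ("first_qualifying", "window_start"):
            raise ValueError("seg_effect must be 'first_qualifying' or 'window_start'")
        if self.sst_scope not in ("auto", "equinox", "all"):
            raise ValueError("sst_scope must be 'auto', 'equinox' or 'all'")
        if self.kde_kernel not in ("quartic", "gaussian"):
            raise ValueError("kde_kernel must be 'quartic' or 'gaussian'")
        if len(self.smooth_weights) != 3 or sum(self.smooth_weights) <= 0:
            raise ValueError("smooth_weights must be three positive weights")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smooth_weights"] = list(self.smooth_weights)
        d["contour_levels"] = list(self.contour_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "smooth_weights" in d:
            d["smooth_weights"] = tuple(d["smooth_weights"])
        if "contour_levels" in d:
            d["contour_levels"] = tuple(d["contour_levels"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
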