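"""Core data model for geolocator track processing.

One record per bird per day throughout: the tags estimate location once
daily, so dates are UTC calendar days and times are UTC times of day
expressed as decimal hours.
"""
from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Sentinel values for days on which the sun never crosses the twilight angle.
POLAR_DAY = "POLAR_DAY"
POLAR_NIGHT = "POLAR_NIGHT"
SENTINELS = (POLAR_DAY, POLAR_NIGHT)


class Source(str, enum.Enum):
    """Provenance of a position estimate."""

    FIXED_COLONY = "fixed_colony"
    THRESHOLD = "threshold"
    SST_CORRECTED = "sst_corrected"
    SMOOTHED = "smoothed"


class State(str, enum.Enum):
    STOPOVER = "STOPOVER"
    TRAVEL = "TRAVEL"


class Phase(str, enum.Enum):
    BREEDING = "BREEDING"
    FALL_MIGRATION = "FALL_MIGRATION"
    WINTER = "WINTER"
    POST = "POST"


class Basin(str, enum.Enum):
    PACIFIC = "PACIFIC"
    ATLANTIC = "ATLANTIC"


def norm_lon(lon):
    """Normalize longitude(s) to the half-open interval [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0 if np.ndim(lon) else (lon + 180.0) % 360.0 - 180.0


def wrap_diff(a: float, b: float) -> float:
    """Signed difference a - b in degrees longitude, wrapped to [-180, 180)."""
    return (a - b + 180.0) % 360.0 - 180.0


@dataclass
class TwilightRecord:
    """One day's observed sunrise/sunset pair for one bird.

    ``sunrise_h``/``sunset_h`` are UTC decimal hours in [0, 24); on polar
    days/nights both are None and ``sentinel`` holds the reason.
    """

    bird_id: str
    date: dt.date
    sunrise_h: Optional[float]
    sunset_h: Optional[float]
    sentinel: Optional[str] = None
    valid: bool = True

    def __post_init__(self):
        if self.sentinel is not None and self.sentinel not in SENTINELS:
            raise ValueError(f"unknown sentinel {self.sentinel!r}")
        if self.sentinel is None:
            if self.sunrise_h is None or self.sunset_h is None:
                raise ValueError("twilight times required when no sentinel is set")
            d = self.day_length_h
            if not (0.0 < d < 24.0):
                raise ValueError(f"day length {d} h outside (0, 24)")

    @property
    def day_length_h(self) -> Optional[float]:
        if self.sentinel is not None:
            return None
        return (self.sunset_h - self.sunrise_h) % 24.0


@dataclass
class SSTSample:
    """Minimum daily sea-surface temperature logged by the tag (deg C)."""

    bird_id: str
    date: dt.date
    min_sst: Optional[float]

    def __post_init__(self):
        if self.min_sst is not None and not (-2.0 <= self.min_sst <= 40.0):
            raise ValueError(f"min_sst {self.min_sst} outside [-2, 40] degC")


@dataclass
class SSTGrid:
    """An 8-day composite SST raster on a regular lat/lon grid."""

    period_start: dt.date
    period_days: int
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    values: np.ndarray  # shape (nlat, nlon), NaN where missing

    def __post_init__(self):
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.period_days != 8:
            raise ValueError("composite period must be 8 days")
        for ax, name in ((self.lat_axis, "lat"), (self.lon_axis, "lon")):
            d = np.diff(ax)
            if len(ax) > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} axis not strictly monotone")
        if self.lat_axis.min() < -90 or self.lat_axis.max() > 90:
            raise ValueError("lat axis outside [-90, 90]")
        if self.lon_axis.min() < -180 or self.lon_axis.max() >= 180:
            raise ValueError("lon axis outside [-180, 180)")
        if self.values.shape != (len(self.lat_axis), len(self.lon_axis)):
            raise ValueError("values shape does not match axes")

    def covers(self, date: dt.date) -> bool:
        off = (date - self.period_start).days
        return 0 <= off < self.period_days

    @property
    def fully_masked(self) -> bool:
        return bool(np.all(np.isnan(self.values)))


@dataclass
class PositionEstimate:
    """A dated position with provenance and quality flags.

    Latitude (and, for polar days, longitude) may be NaN when the estimate
    could not be formed; the flags say why.
    """

    bird_id: str
    date: dt.date
    lat: float
    lon: float
    source: Source
    equinox_flagged: bool = False
    polar_flagged: bool = False
    speed_rejected: bool = False
    unsmoothed_jump: bool = False

    def __post_init__(self):
        if np.isfinite(self.lat) and abs(self.lat) > 90:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if np.isfinite(self.lon):
            self.lon = float(norm_lon(self.lon))

    @property
    def usable(self) -> bool:
        return bool(np.isfinite(self.lat) and np.isfinite(self.lon))

    def flags(self) -> list[str]:
        return [
            name
            for name in ("equinox_flagged", "polar_flagged", "speed_rejected", "unsmoothed_jump")
            if getattr(self, name)
        ]


@dataclass
class Track:
    """An ordered daily track for one bird."""

    bird_id: str
    sex: Optional[str]
    deployment_year: Optional[int]
    colony_lat: float
    colony_lon: float
    positions: list[PositionEstimate] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        # colony stored in the same normalized form as positions
        self.colony_lat = float(self.colony_lat)
        self.colony_lon = float(norm_lon(float(self.colony_lon)))
        dates = [p.date for p in self.positions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("track dates must be strictly increasing")
        if self.positions:
            first = self.positions[0]
            if first.source is not Source.FIXED_COLONY:
                raise ValueError("first track position must be fixed_colony")
            if (first.lat, first.lon) != (self.colony_lat, self.colony_lon):
                raise ValueError("fixed_colony position must equal the colony coordinates")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def dates(self) -> list[dt.date]:
        return [p.date for p in self.positions]

    @property
    def lats(self) -> np.ndarray:
        return np.array([p.lat for p in self.positions], dtype=float)

    @property
    def lons(self) -> np.ndarray:
        return np.array([p.lon for p in self.positions], dtype=float)

    def replace_positions(self, positions: Sequence[PositionEstimate]) -> "Track":
        return Track(
            bird_id=self.bird_id,
            sex=self.sex,
            deployment_year=self.deployment_year,
            colony_lat=self.colony_lat,
            colony_lon=self.colony_lon,
            positions=list(positions),
        )


@dataclass
class DayState:
    """Per-day movement classification."""

    date: dt.date
    daily_km: float
    state: State
    burst_adjusted: bool = False
    phase: Optional[Phase] = None


@dataclass
class MigrationSummary:
    """Per-bird fall-migration metrics (Table-1 style)."""

    bird_id: str
    basin: Optional[Basin]
    departure: Optional[dt.date]
    arrival: Optional[dt.date]
    duration_days: Optional[int]
    travel_distance_km: Optional[float]
    travel_days: Optional[int]
    travel_speed_kmd: Optional[float]
    complete: bool


@dataclass
class TestResult:
    """A statistical test outcome."""

    statistic: float
    df: tuple
    p_value: float
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")
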