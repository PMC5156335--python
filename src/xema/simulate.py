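"""Synthetic Sabine's-gull cohorts with known itineraries.

The generator emulates the study conditions the pipeline was built for: a
fixed High-Arctic colony start (75.8 N, 96.3 W), fall migrations of
roughly 84 days alternating multi-day travel legs (~300-420 km/d) with
stopovers, two destination basins (a Humboldt-like wintering area in the
Pacific and a Benguela-like one in the Atlantic), and a wintering period
of mean-reverting roaming whose daily movement stays just under the
100 km/d segmentation threshold (the paper's observed mean winter
movement). From each true itinerary it synthesizes the three observables
the pipeline consumes: twilight times from the solar forward model plus
Gaussian noise, daily tag SST from an analytic meridional field plus
noise, and 8-day composite SST grids of the same field.

Every stopover day moves less than the segmentation threshold and every
travel day more (by construction), so the simulator's labels are a valid
oracle for the segmentation stage. All randomness flows from a single
seeded generator.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .solar import twilight_forward
from .stats import haversine_km
from .types import (
    Basin,
    Phase,
    SSTGrid,
    SSTSample,
    State,
    TwilightRecord,
    norm_lon,
)

KM_PER_DEG = 111.195  # mean spherical degree of latitude, R = 6371 km


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# great-circle route machinery

def _to_vec(lat, lon):
    phi, lam = math.radians(lat), math.radians(lon)
    return np.array(
        [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
    )


def _to_latlon(v):
    v = v / np.linalg.norm(v)
    return math.degrees(math.asin(np.clip(v[2], -1, 1))), math.degrees(math.atan2(v[1], v[0]))


def gc_interpolate(a: tuple, b: tuple, f: float) -> tuple:
    """Point a fraction ``f`` along the great circle from a to b (lat, lon)."""
    va, vb = _to_vec(*a), _to_vec(*b)
    omega = math.acos(np.clip(np.dot(va, vb), -1.0, 1.0))
    if omega < 1e-12:
        return a
    v = (math.sin((1 - f) * omega) * va + math.sin(f * omega) * vb) / math.sin(omega)
    return _to_latlon(v)


class Route:
    """A polyline of great-circle segments, parameterized by arc length."""

    def __init__(self, waypoints: Sequence[tuple]):
        self.waypoints = [tuple(w) for w in waypoints]
        seg = [
            haversine_km(self.waypoints[i], self.waypoints[i + 1])
            for i in range(len(self.waypoints) - 1)
        ]
        self.seg_km = np.array(seg)
        self.cum_km = np.concatenate([[0.0], np.cumsum(self.seg_km)])
        self.total_km = float(self.cum_km[-1])

    def point_at(self, s: float) -> tuple:
        s = min(max(s, 0.0), self.total_km)
        i = int(np.searchsorted(self.cum_km, s, side="right")) - 1
        i = min(i, len(self.seg_km) - 1)
        if self.seg_km[i] == 0:
            return self.waypoints[i]
        f = (s - self.cum_km[i]) / self.seg_km[i]
        return gc_interpolate(self.waypoints[i], self.waypoints[i + 1], f)


#: Basin itinerary templates: wintering-area centre plus en-route waypoints
#: sketching the oceanic corridor from the colony.
BASIN_TEMPLATES = {
    Basin.PACIFIC: {
        "center": (-10.0, -85.0),
        "waypoints": [
            (73.0, -120.0),
            (66.0, -145.0),
            (55.0, -155.0),
            (40.0, -140.0),
            (22.0, -118.0),
            (5.0, -95.0),
        ],
    },
    Basin.ATLANTIC: {
        "center": (-25.0, 10.0),
        "waypoints": [
            (70.0, -70.0),
            (58.0, -50.0),
            (42.0, -40.0),
            (22.0, -28.0),
            (2.0, -12.0),
        ],
    },
}


# ---------------------------------------------------------------------------
# parameters and containers

@dataclass
class SimulationParams:
    """Generator defaults: the study conditions being emulated."""

    season_year: int = 2010  # calendar year the simulated season is placed in
    start_month_day: tuple = (8, 3)
    departure_month_day: tuple = (8, 18)
    departure_jitter_sd_d: float = 5.0
    n_stopovers_range: tuple = (2, 4)
    stopover_total_mean_d: float = 46.0
    stopover_total_sd_d: float = 10.0
    min_stopover_d: int = 2
    speed_range_kmd: tuple = (300.0, 420.0)
    winter_days: int = 60
    winter_center_offset_sd_km: float = 25.0
    winter_roam_sd_km: float = 40.0
    winter_reversion: float = 0.15
    winter_step_cap_km: float = 95.0
    stopover_jitter_sd_km: float = 10.0
    stopover_jitter_cap_km: float = 24.0
    breeding_jitter_sd_km: float = 1.5
    max_duration_d: int = 130
    twilight_noise_sd_min: float = 4.0
    sst_noise_sd_c: float = 0.3
    sst_missing_rate: float = 0.05


@dataclass
class Leg:
    kind: str  # "stopover" | "travel"
    start_date: dt.date
    end_date: dt.date
    start_point: tuple
    end_point: tuple
    daily_speed_kmd: Optional[float] = None


@dataclass
class Itinerary:
    """Ground truth for one simulated bird."""

    bird_id: str
    sex: str
    deployment_year: int
    destination: Basin
    colony: tuple
    dates: list[dt.date]
    lats: np.ndarray
    lons: np.ndarray
    states: list[State]
    phases: list[Phase]
    departure: Optional[dt.date]
    arrival: Optional[dt.date]
    winter_center: Optional[tuple]
    legs: list[Leg] = field(default_factory=list)

    @property
    def duration_days(self) -> Optional[int]:
        if self.departure is None or self.arrival is None:
            return None
        return (self.arrival - self.departure).days

    def displacements_km(self) -> np.ndarray:
        d = np.zeros(len(self.dates))
        for i in range(1, len(self.dates)):
            d[i] = haversine_km(
                (self.lats[i - 1], self.lons[i - 1]), (self.lats[i], self.lons[i])
            )
        return d

    @property
    def true_travel_distance_km(self) -> float:
        disp = self.displacements_km()
        return float(
            sum(
                disp[i]
                for i in range(len(self.dates))
                if self.states[i] is State.TRAVEL and self.phases[i] is Phase.FALL_MIGRATION
            )
        )

    @property
    def true_travel_days(self) -> int:
        return sum(
            1
            for i in range(len(self.dates))
            if self.states[i] is State.TRAVEL and self.phases[i] is Phase.FALL_MIGRATION
        )

    @property
    def true_travel_speed_kmd(self) -> Optional[float]:
        n = self.true_travel_days
        return self.true_travel_distance_km / n if n else None


def _offset_point(lat: float, lon: float, dx_km: float, dy_km: float) -> tuple:
    new_lat = lat + dy_km / KM_PER_DEG
    new_lon = lon + dx_km / (KM_PER_DEG * math.cos(math.radians(min(abs(lat), 89.0))))
    return float(np.clip(new_lat, -89.9, 89.9)), float(norm_lon(new_lon))


def _jitter(rng, sd_km, cap_km):
    v = rng.normal(0.0, sd_km, size=2)
    r = float(np.hypot(*v))
    if r > cap_km:
        v *= cap_km / r
    return v


# ---------------------------------------------------------------------------
# itinerary simulation

def _stopover_fractions(rng, k: int, lo=0.10, hi=0.90, min_gap=0.12) -> np.ndarray:
    if k == 0:
        return np.array([])
    for _ in range(200):
        f = np.sort(rng.uniform(lo, hi, size=k))
        gaps = np.diff(np.concatenate([[0.0], f, [1.0]]))
        if np.all(gaps >= min_gap):
            return f
    return np.linspace(lo, hi, k + 2)[1:-1]  # deterministic fallback


def simulate_itinerary(
    config: PipelineConfig,
    destination: Basin,
    seed,
    params: SimulationParams = None,
    bird_id: str = "bird",
    sex: str = "F",
    deployment_year: int = 2010,
    route_waypoints: Optional[Sequence[tuple]] = None,
    winter_center: Optional[tuple] = None,
) -> Itinerary:
    """Simulate one bird's true daily itinerary.

    Travel legs follow great-circle interpolation along the basin's route
    corridor; stopovers hold position with small jitter; the winter block
    roams around a bird-specific centre. Reproducible under ``seed``.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    colony = (config.colony_lat, config.colony_lon)
    template = BASIN_TEMPLATES[destination]
    base_center = winter_center if winter_center is not None else template["center"]
    offs = rng.normal(0.0, params.winter_center_offset_sd_km, size=2)
    center = _offset_point(base_center[0], base_center[1], offs[0], offs[1])
    wps = list(route_waypoints) if route_waypoints is not None else list(template["waypoints"])
    route = Route([colony] + wps + [center])
    year = params.season_year
    start = dt.date(year, *params.start_month_day)
    departure_nominal = dt.date(year, *params.departure_month_day)
    dep_offset = int(round(rng.normal(0.0, params.departure_jitter_sd_d)))
    departure_date = departure_nominal + dt.timedelta(days=dep_offset)
    if departure_date <= start:
        departure_date = start + dt.timedelta(days=1)

    dates: list[dt.date] = []
    lats: list[float] = []
    lons: list[float] = []

    def add_day(date, lat, lon):
        dates.append(date)
        lats.append(float(lat))
        lons.append(float(norm_lon(lon)))

    # breeding residency at the colony (exact colony on day one)
    d = start
    add_day(d, *colony)
    d += dt.timedelta(days=1)
    while d < departure_date:
        j = _jitter(rng, params.breeding_jitter_sd_km, 4 * params.breeding_jitter_sd_km)
        add_day(d, *_offset_point(*colony, j[0], j[1]))
        d += dt.timedelta(days=1)

    if route.total_km < 1.0:
        # degenerate: destination at the colony; a single stopover, no travel
        states = [State.STOPOVER] * len(dates)
        phases = [Phase.BREEDING] * len(dates)
        legs = [Leg("stopover", dates[0], dates[-1], colony, colony)]
        return Itinerary(
            bird_id, sex, deployment_year, destination, colony, dates,
            np.array(lats), np.array(lons), states, phases,
            departure=None, arrival=None, winter_center=None, legs=legs,
        )

    k = int(rng.integers(params.n_stopovers_range[0], params.n_stopovers_range[1] + 1))
    total_stop = max(
        params.min_stopover_d * max(k, 1),
        int(round(rng.normal(params.stopover_total_mean_d, params.stopover_total_sd_d))),
    )
    if k > 0:
        w = rng.dirichlet(np.ones(k) * 2.0)
        dwell = np.maximum(params.min_stopover_d, np.round(w * total_stop).astype(int))
    else:
        dwell = np.array([], dtype=int)
        total_stop = 0
    feasible_days = route.total_km / params.speed_range_kmd[0] + int(dwell.sum()) + 5
    if feasible_days > params.max_duration_d:
        raise ConfigurationError(
            f"route of {route.total_km:.0f} km at >= {params.speed_range_kmd[0]} km/d with "
            f"{int(dwell.sum())} stopover days cannot fit in {params.max_duration_d} d"
        )
    fractions = _stopover_fractions(rng, k)
    targets = [(float(f) * route.total_km, int(dw)) for f, dw in zip(fractions, dwell)]
    targets.append((route.total_km, None))  # final target: the winter centre

    s = 0.0
    for target_s, dwell_days in targets:
        v = float(rng.uniform(*params.speed_range_kmd))
        while s < target_s - 1e-6:
            s = min(s + v, target_s)
            add_day(d, *route.point_at(s))
            d += dt.timedelta(days=1)
        if dwell_days is not None:
            site = route.point_at(target_s)
            for _ in range(dwell_days):
                j = _jitter(rng, params.stopover_jitter_sd_km, params.stopover_jitter_cap_km)
                add_day(d, *_offset_point(*site, j[0], j[1]))
                d += dt.timedelta(days=1)

    # winter roam: mean-reverting walk, daily step capped below the
    # segmentation threshold
    ox, oy = 0.0, 0.0
    for _ in range(params.winter_days):
        nx = ox * (1.0 - params.winter_reversion) + rng.normal(0.0, params.winter_roam_sd_km)
        ny = oy * (1.0 - params.winter_reversion) + rng.normal(0.0, params.winter_roam_sd_km)
        step = math.hypot(nx - ox, ny - oy)
        if step > params.winter_step_cap_km:
            f = params.winter_step_cap_km * 0.98 / step
            nx = ox + (nx - ox) * f
            ny = oy + (ny - oy) * f
        ox, oy = nx, ny
        add_day(d, *_offset_point(center[0], center[1], ox, oy))
        d += dt.timedelta(days=1)

    lats_a = np.array(lats)
    lons_a = np.array(lons)
    n = len(dates)
    disp = np.zeros(n)
    for i in range(1, n):
        disp[i] = haversine_km((lats_a[i - 1], lons_a[i - 1]), (lats_a[i], lons_a[i]))
    states = [State.TRAVEL if disp[i] > config.seg_threshold_kmd else State.STOPOVER for i in range(n)]
    states[0] = State.STOPOVER

    travel_idx = [i for i, st in enumerate(states) if st is State.TRAVEL]
    if not travel_idx:
        raise ConfigurationError("itinerary produced no travel days")
    dep_idx = travel_idx[0]
    # arrival: first stopover day at (or after) the end of the route
    arrive_route_idx = n - params.winter_days if params.winter_days > 0 else n - 1
    arr_idx = arrive_route_idx
    if states[arr_idx] is State.TRAVEL:
        arr_idx += 1
    arr_idx = min(arr_idx, n - 1)
    phases = []
    for i in range(n):
        if i < dep_idx:
            phases.append(Phase.BREEDING)
        elif i < arr_idx:
            phases.append(Phase.FALL_MIGRATION)
        else:
            phases.append(Phase.WINTER)

    legs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] is states[i] and phases[j + 1] is phases[i]:
            j += 1
        if phases[i] is Phase.WINTER:
            kind = "winter"  # terminal roaming block, not an en-route stopover
        else:
            kind = "travel" if states[i] is State.TRAVEL else "stopover"
        speed = float(np.mean(disp[i : j + 1])) if kind == "travel" else None
        legs.append(
            Leg(kind, dates[i], dates[j], (lats_a[i], lons_a[i]), (lats_a[j], lons_a[j]), speed)
        )
        i = j + 1

    return Itinerary(
        bird_id, sex, deployment_year, destination, colony, dates, lats_a, lons_a,
        states, phases, departure=dates[dep_idx],
        arrival=dates[arr_idx] if arr_idx < n else None,
        winter_center=center, legs=legs,
    )


# ---------------------------------------------------------------------------
# observables

def synthesize_twilights(
    itinerary: Itinerary,
    sun_angle_deg: float = -3.44,
    noise_sd_minutes: float = 4.0,
    seed=0,
) -> list[TwilightRecord]:
    """Per-day sunrise/sunset from the solar forward model plus noise."""
    if noise_sd_minutes < 0:
        raise ValueError("noise_sd_minutes must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for date, lat, lon in zip(itinerary.dates, itinerary.lats, itinerary.lons):
        fwd = twilight_forward(lat, lon, date, sun_angle_deg)
        if isinstance(fwd, str):
            out.append(TwilightRecord(itinerary.bird_id, date, None, None, sentinel=fwd))
            continue
        sr, ss = fwd
        sr = (sr + rng.normal(0.0, noise_sd_minutes) / 60.0) % 24.0
        ss = (ss + rng.normal(0.0, noise_sd_minutes) / 60.0) % 24.0
        sr = round(sr * 3600.0) / 3600.0  # 1 s resolution, like tag clocks
        ss = round(ss * 3600.0) / 3600.0
        if sr == ss:  # degenerate after rounding
            ss = (ss + 1.0 / 3600.0) % 24.0
        out.append(TwilightRecord(itinerary.bird_id, date, sr, ss))
    return out


@dataclass
class SSTFieldSpec:
    """Analytic meridional SST field standing in for satellite composites.

    The default is a tanh profile: warm and flat through the tropics, a
    steep mid-latitude gradient, and near-freezing polar water -- monotone
    decreasing in latitude everywhere it is unclipped. A ``linear`` kind
    (``base_temp + gradient * lat``) is available for controlled tests.
    """

    # The default spreads the ocean's full SST range evenly over the
    # latitudes the birds use, so the tag-to-composite match is informative
    # along the whole corridor; a two-front tanh profile is available for
    # structured fields.
    kind: str = "linear"
    base_temp: float = 21.6  # keeps the profile unclipped from 75.8 N to -45 S
    gradient: float = -0.31  # degC per degree latitude (linear kind)
    amplitude: float = 9.5
    center_lat: float = 42.0
    width_deg: float = 13.0
    amplitude2: float = 8.5
    center2_lat: float = 2.0
    width2_deg: float = 16.0
    seasonal_amplitude: float = 0.0
    noise_sd: float = 0.1
    clip: tuple = (-1.9, 39.9)

    def __post_init__(self):
        if self.kind not in ("tanh", "linear"):
            raise ValueError("kind must be 'tanh' or 'linear'")
        if self.kind == "linear" and self.gradient == 0:
            raise ValueError("linear field must have a nonzero meridional gradient")

    def temperature(self, lat, doy: int = 260):
        lat = np.asarray(lat, dtype=float)
        if self.kind == "linear":
            t = self.base_temp + self.gradient * lat
        else:
            t = (
                self.base_temp
                - self.amplitude * np.tanh((lat - self.center_lat) / self.width_deg)
                - self.amplitude2 * np.tanh((lat - self.center2_lat) / self.width2_deg)
            )
        if self.seasonal_amplitude:
            t = t + self.seasonal_amplitude * math.cos(2.0 * math.pi * (doy - 212) / 365.0)
        return np.clip(t, *self.clip)


def synthesize_sst(
    itinerary: Itinerary,
    field_spec: SSTFieldSpec = None,
    seed=0,
    params: SimulationParams = None,
    grid_lat_step: float = 0.25,
    grid_lon_step: float = 1.0,
    grid_lat_range: tuple = (-45.0, 80.0),
    grid_lon_range: tuple = (-180.0, 45.0),
) -> tuple[list[SSTSample], list[SSTGrid]]:
    """Tag SST samples along the true track plus 8-day composite grids."""
    field_spec = field_spec or SSTFieldSpec()
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    samples = []
    for date, lat in zip(itinerary.dates, itinerary.lats):
        if rng.uniform() < params.sst_missing_rate:
            samples.append(SSTSample(itinerary.bird_id, date, None))
            continue
        t = float(field_spec.temperature(lat, date.timetuple().tm_yday))
        t += rng.normal(0.0, params.sst_noise_sd_c)
        samples.append(SSTSample(itinerary.bird_id, date, float(np.clip(t, -1.9, 39.9))))
    grids = make_sst_grids(
        itinerary.dates[0], itinerary.dates[-1], field_spec, seed=rng.integers(2**31),
        lat_step=grid_lat_step, lon_step=grid_lon_step,
        lat_range=grid_lat_range, lon_range=grid_lon_range,
    )
    return samples, grids


def make_sst_grids(
    start: dt.date,
    end: dt.date,
    field_spec: SSTFieldSpec,
    seed=0,
    lat_step: float = 0.25,
    lon_step: float = 1.0,
    lat_range: tuple = (-45.0, 80.0),
    lon_range: tuple = (-180.0, 45.0),
) -> list[SSTGrid]:
    """8-day composites of the analytic field covering [start, end]."""
    rng = np.random.default_rng(seed)
    lat_axis = np.arange(lat_range[0], lat_range[1] + lat_step / 2.0, lat_step)
    lon_axis = np.arange(lon_range[0], lon_range[1] + lon_step / 2.0, lon_step)
    grids = []
    p = start
    while p <= end:
        mid = p + dt.timedelta(days=4)
        col = field_spec.temperature(lat_axis, mid.timetuple().tm_yday)
        vals = np.broadcast_to(col[:, None], (len(lat_axis), len(lon_axis))).copy()
        if field_spec.noise_sd > 0:
            vals += rng.normal(0.0, field_spec.noise_sd, size=vals.shape)
        vals = np.clip(vals, *field_spec.clip)
        grids.append(SSTGrid(p, 8, lat_axis.copy(), lon_axis.copy(), vals))
        p += dt.timedelta(days=8)
    return grids


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SimulatedBird:
    itinerary: Itinerary
    twilights: list[TwilightRecord]
    sst_samples: list[SSTSample]


@dataclass
class Cohort:
    birds: list[SimulatedBird]
    grids: list[SSTGrid]
    field_spec: SSTFieldSpec
    params: SimulationParams


def simulate_cohort(
    config: PipelineConfig,
    n_pacific: int,
    n_atlantic: int,
    seed,
    params: SimulationParams = None,
    field_spec: SSTFieldSpec = None,
) -> Cohort:
    """Simulate a mixed-destination cohort sharing one SST field."""
    params = params or SimulationParams()
    field_spec = field_spec or SSTFieldSpec()
    ss = np.random.SeedSequence(seed)
    years = [2008, 2010, 2011]
    birds = []
    destinations = [Basin.PACIFIC] * n_pacific + [Basin.ATLANTIC] * n_atlantic
    child_seeds = ss.spawn(len(destinations) + 1)
    first = None
    last = None
    for i, dest in enumerate(destinations):
        bird_rng_seed = child_seeds[i]
        sub = bird_rng_seed.spawn(3)
        itin = simulate_itinerary(
            config, dest, sub[0], params,
            bird_id=f"{dest.value[:3].lower()}{i + 1:02d}",
            sex="F" if i % 2 == 0 else "M",
            deployment_year=years[i % len(years)],
        )
        tw = synthesize_twilights(itin, config.sun_angle_deg, params.twilight_noise_sd_min, sub[1])
        sst, _ = synthesize_sst(itin, field_spec, sub[2], params)
        birds.append(SimulatedBird(itin, tw, sst))
        first = itin.dates[0] if first is None else min(first, itin.dates[0])
        last = itin.dates[-1] if last is None else max(last, itin.dates[-1])
    grids = make_sst_grids(first, last, field_spec, seed=child_seeds[-1])
    return Cohort(birds, grids, field_spec, params)


def truncate_bird(bird: SimulatedBird, n_days: int) -> SimulatedBird:
    """A tag that failed after ``n_days`` of recording (direction-only)."""
    return SimulatedBird(
        itinerary=bird.itinerary,
        twilights=bird.twilights[:n_days],
        sst_samples=[s for s in bird.sst_samples if s.date <= bird.twilights[: n_days][-1].date],
    )
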