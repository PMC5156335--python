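"""Stopover/travel segmentation, burst adjustment, and phase splitting.

Each tracked day is classified by a two-state machine: a bird starts in a
stopover period (at the breeding site) and transitions to travel when
three or more positions within a sliding window of five move more than
100 km/d, and back to stopover when three or more fail that criterion.
Short 1-2 day relocations between distinct stopover areas ("burst travel")
are relabelled travel by an automated surrogate for what was a manual
step. Tracks are then split into breeding, fall migration (departure to
arrival), and winter, with arrival defined as the first stopover position
inside the pooled 50% occupancy contour of the wintering basin.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Point

from .config import PipelineConfig
from .spaceuse import AlbersEqualArea, kernel_density, occupancy_contours, to_equal_area
from .stats import haversine_km
from .types import Basin, DayState, Phase, State, Track


def classify_days(
    daily_km: Sequence[float],
    threshold: float = 100.0,
    window: int = 5,
    count: int = 3,
    anchor: str = "forward",
    effect: str = "first_qualifying",
) -> list[State]:
    """Two-state stopover/travel machine over a daily movement series.

    Scanning forward from a stopover start: at day i the window (forward:
    [i, i+window-1]; centered: [i-window//2, i+window//2]) is evaluated;
    if at least ``count`` of its days qualify (exceed the threshold when in
    stopover, fall below it when in travel), the state flips starting at
    the first qualifying day (or the window start, per ``effect``).
    Truncated windows at the series end use the available days with the
    same count requirement.
    """
    if len(daily_km) == 0:
        raise ValueError("empty daily movement series")
    n = len(daily_km)
    v = np.asarray(daily_km, dtype=float)
    states: list[Optional[State]] = [None] * n
    state = State.STOPOVER
    i = 0
    half = window // 2
    while i < n:
        if anchor == "forward":
            lo, hi = i, min(n, i + window)
        else:
            lo, hi = max(0, i - half), min(n, i + half + 1)
        if state is State.STOPOVER:
            qual = [j for j in range(lo, hi) if v[j] > threshold]
        else:
            qual = [j for j in range(lo, hi) if v[j] < threshold]
        if len(qual) >= count:
            j0 = qual[0] if effect == "first_qualifying" else lo
            j0 = max(j0, i)
            for k in range(i, j0):
                states[k] = state
            state = State.TRAVEL if state is State.STOPOVER else State.STOPOVER
            states[j0] = state
            i = j0 + 1
        else:
            states[i] = state
            i += 1
    return states  # type: ignore[return-value]


def adjust_bursts(
    states: Sequence[State],
    daily_km: Sequence[float],
    lats: Sequence[float],
    lons: Sequence[float],
    threshold: float = 100.0,
    multiplier: float = 2.0,
) -> tuple[list[State], list[bool]]:
    """Relabel 1-2 day fast relocations inside stopovers as travel.

    A run of one or two consecutive stopover days each moving more than
    ``threshold`` km/d, flanked by stopover days on both sides, is
    relabelled TRAVEL when the centroids of the flanking stopover clusters
    are more than ``multiplier * threshold`` km apart (i.e., the bird
    genuinely relocated rather than jittered).
    """
    states = list(states)
    v = np.asarray(daily_km, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(states)
    adjusted = [False] * n

    def cluster(start: int, step: int) -> list[int]:
        out = []
        k = start
        while 0 <= k < n and states[k] is State.STOPOVER and not (v[k] > threshold):
            out.append(k)
            k += step
        return out

    i = 0
    while i < n:
        if states[i] is State.STOPOVER and v[i] > threshold:
            j = i
            while j + 1 < n and states[j + 1] is State.STOPOVER and v[j + 1] > threshold:
                j += 1
            run_len = j - i + 1
            if (
                run_len <= 2
                and i > 0
                and j < n - 1
                and states[i - 1] is State.STOPOVER
                and states[j + 1] is State.STOPOVER
            ):
                before = cluster(i - 1, -1)
                after = cluster(j + 1, +1)
                if before and after:
                    c0 = (float(np.mean(lats[before])), float(np.mean(lons[before])))
                    c1 = (float(np.mean(lats[after])), float(np.mean(lons[after])))
                    if haversine_km(c0, c1) > multiplier * threshold:
                        for k in range(i, j + 1):
                            states[k] = State.TRAVEL
                            adjusted[k] = True
            i = j + 1
        else:
            i += 1
    return states, adjusted


@dataclass
class WinteringArea:
    """The 50% occupancy polygon bounding a wintering basin."""

    basin: Basin
    polygon_geographic: MultiPolygon  # WGS84 lon/lat
    polygon_projected: MultiPolygon
    projection: AlbersEqualArea
    level: float
    captured_fraction: float
    n_positions: int

    def contains(self, lat: float, lon: float) -> bool:
        return bool(self.polygon_geographic.covers(Point(lon, lat)))


_BASIN_PRESET = {Basin.PACIFIC: "south-america", Basin.ATLANTIC: "africa"}


def define_wintering_area(
    lats: Sequence[float],
    lons: Sequence[float],
    basin: Basin,
    config: PipelineConfig = None,
    use_preset: bool = True,
) -> WinteringArea:
    """KDE 50% occupancy contour around pooled winter positions of a basin."""
    config = config or PipelineConfig()
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) < config.min_winter_positions:
        raise ValueError(
            f"{basin.value} basin has only {len(lats)} pooled winter positions "
            f"(need >= {config.min_winter_positions})"
        )
    preset = _BASIN_PRESET[basin] if use_preset else None
    x, y, proj = to_equal_area(lats, lons, preset=preset)
    surf = kernel_density(
        x, y, bandwidth_km=config.kde_bandwidth_km, cell_km=config.kde_cell_km,
        kernel=config.kde_kernel, projection=proj,
    )
    (c50,) = occupancy_contours(surf, levels=(50.0,), simplify_km=config.simplify_tolerance_km)
    return WinteringArea(
        basin=basin,
        polygon_geographic=c50.polygon_geographic,
        polygon_projected=c50.polygon_projected,
        projection=proj,
        level=50.0,
        captured_fraction=c50.captured_fraction,
        n_positions=len(lats),
    )


def infer_basin(final_lon: float, divide_lon: float = -70.0) -> Basin:
    """Wintering basin from the track's final longitude (west of the South
    American divide => Pacific, east => Atlantic)."""
    return Basin.PACIFIC if final_lon < divide_lon else Basin.ATLANTIC


@dataclass
class PhaseSplit:
    departure: Optional[dt.date]
    arrival: Optional[dt.date]
    phases: list[Phase]
    basin: Optional[Basin]
    no_migration: bool = False


def split_phases(
    track: Track,
    states: Sequence[DayState],
    wintering_area: Optional[WinteringArea],
    config: PipelineConfig = None,
) -> PhaseSplit:
    """Assign breeding / fall migration / winter phases.

    Departure is the first TRAVEL day after the initial breeding-site
    stopover run; arrival is the first STOPOVER day whose position lies
    inside the wintering polygon. Days before departure are BREEDING, days
    from departure up to (but excluding) arrival are FALL_MIGRATION, and
    days from arrival on are WINTER. Without a usable wintering polygon or
    a polygon entry the split is direction-only (arrival missing, basin
    from the final longitude).
    """
    config = config or PipelineConfig()
    if len(states) != len(track):
        raise ValueError("states must align with track positions")
    seq = [s.state for s in states]
    basin = infer_basin(track.lons[-1], config.basin_divide_lon) if len(track) else None
    try:
        dep_idx = seq.index(State.TRAVEL)
    except ValueError:
        return PhaseSplit(None, None, [Phase.BREEDING] * len(seq), basin, no_migration=True)
    departure = states[dep_idx].date
    arrival = None
    arr_idx = None
    if wintering_area is not None:
        for i in range(dep_idx + 1, len(seq)):
            if seq[i] is State.STOPOVER and wintering_area.contains(
                track.positions[i].lat, track.positions[i].lon
            ):
                arrival = states[i].date
                arr_idx = i
                break
    phases = []
    for i in range(len(seq)):
        if i < dep_idx:
            phases.append(Phase.BREEDING)
        elif arr_idx is not None and i >= arr_idx:
            phases.append(Phase.WINTER)
        else:
            phases.append(Phase.FALL_MIGRATION)
    if wintering_area is not None and arrival is not None:
        basin = wintering_area.basin
    return PhaseSplit(departure, arrival, phases, basin)
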