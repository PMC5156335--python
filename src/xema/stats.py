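"""Great-circle movement metrics and comparison statistics.

Distances are spherical great-circle (haversine) distances on a sphere of
mean radius 6371.0 km. Travel distance for fall migration sums only the
displacements arriving on travel-classified days; travel speed is travel
distance over travel days. Group comparisons use Welch's unequal-variance
t-test, one-way ANOVA, and Tukey's HSD.
"""
from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import Basin, DayState, MigrationSummary, State, TestResult, Track

EARTH_RADIUS_KM = 6371.0


def haversine_km(a, b, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees.

    Accepts scalar pairs or broadcastable arrays of shape (..., 2)-like
    tuples ``(lat, lon)``.
    """
    lat1, lon1 = np.radians(np.asarray(a[0], dtype=float)), np.radians(np.asarray(a[1], dtype=float))
    lat2, lon2 = np.radians(np.asarray(b[0], dtype=float)), np.radians(np.asarray(b[1], dtype=float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def pairwise_distances_km(lats, lons, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Distances between consecutive points of a path (length n-1)."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return haversine_km((lats[:-1], lons[:-1]), (lats[1:], lons[1:]), radius_km)


def daily_km(track: Track, radius_km: float = EARTH_RADIUS_KM) -> list[tuple[dt.date, float]]:
    """Per-day movement rate assigned to the later date of each pair.

    For a gap of d days the rate is distance / d, so sparse coverage
    cannot masquerade as fast travel.
    """
    if len(track) < 2:
        raise ValueError("daily_km needs at least 2 positions")
    dates = track.dates
    gaps = np.array([(b - a).days for a, b in zip(dates, dates[1:])], dtype=float)
    if np.any(gaps <= 0):
        raise ValueError("track dates must be strictly increasing")
    dist = pairwise_distances_km(track.lats, track.lons, radius_km)
    return list(zip(dates[1:], (dist / gaps).tolist()))


def summarize_migration(
    track: Track,
    states: Sequence[DayState],
    departure: Optional[dt.date],
    arrival: Optional[dt.date],
    basin: Optional[Basin],
    radius_km: float = EARTH_RADIUS_KM,
) -> MigrationSummary:
    """Fall-migration metrics for one bird.

    travel_distance sums adjacent-pair distances whose later day is a
    TRAVEL day within [departure, arrival); travel_days counts the elapsed
    days of those pairs; duration spans departure to arrival. Tracks
    without a resolved arrival are direction-only: basin reported, metrics
    absent.
    """
    complete = departure is not None and arrival is not None
    state_by_date = {s.date: s.state for s in states}
    travel_dist = 0.0
    travel_days = 0
    if complete:
        dist = pairwise_distances_km(track.lats, track.lons, radius_km)
        dates = track.dates
        for i in range(1, len(dates)):
            later = dates[i]
            if not (departure <= later < arrival):
                continue
            if state_by_date.get(later) is State.TRAVEL:
                travel_dist += float(dist[i - 1])
                travel_days += (dates[i] - dates[i - 1]).days
    return MigrationSummary(
        bird_id=track.bird_id,
        basin=basin,
        departure=departure,
        arrival=arrival,
        duration_days=(arrival - departure).days if complete else None,
        travel_distance_km=travel_dist if complete else None,
        travel_days=travel_days if complete else None,
        travel_speed_kmd=(travel_dist / travel_days) if complete and travel_days else None,
        complete=complete,
    )


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, (float(len(x) + len(y) - 2),), 1.0, "welch_t")
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    vx, vy = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return TestResult(float(res.statistic), (float(df),), float(res.pvalue), "welch_t")


def anova_oneway(groups: dict) -> TestResult:
    """One-way ANOVA across named groups; df = (k-1, N-k)."""
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
        return TestResult(0.0, (float(k - 1), float(n_total - k)), 1.0, "anova_oneway")
    res = sps.f_oneway(*arrays)
    return TestResult(
        float(res.statistic), (float(k - 1), float(n_total - k)), float(res.pvalue), "anova_oneway"
    )


def tukey_hsd(groups: dict) -> dict[tuple, TestResult]:
    """Tukey HSD pairwise comparisons with family-wise adjusted p-values.

    p-values come from the studentized-range distribution evaluated
    numerically (scipy's implementation).
    """
    names = list(groups.keys())
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    n_total = sum(len(a) for a in arrays)
    df_err = float(n_total - len(names))
    if np.ptp(np.concatenate(arrays)) == 0:
        return {
            (names[i], names[j]): TestResult(0.0, (df_err,), 1.0, "tukey_hsd")
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
    res = sps.tukey_hsd(*arrays)
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out[(names[i], names[j])] = TestResult(
                float(res.statistic[i, j]), (df_err,), float(res.pvalue[i, j]), "tukey_hsd"
            )
    return out


# -- printed-arithmetic helpers -------------------------------------------

def mps_to_kmh(v_ms: float) -> float:
    return v_ms * 3.6


def recovery_percent(recovered: int, deployed: int) -> float:
    return 100.0 * recovered / deployed


def anova_error_df(n_units: int, n_groups: int) -> int:
    return n_units - n_groups
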