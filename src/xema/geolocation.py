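"""Threshold geolocation and SST latitude correction.

Longitude comes from the UTC midpoint of sunrise and sunset (solar noon),
latitude from day length via the hour-angle equation. Near the equinoxes
day length is ~12 h at every latitude, so latitude from day length is
ill-conditioned; those days are flagged and, where a tag SST sample and a
satellite composite are available, latitude is re-estimated by matching
the tag temperature against the composite along the (reliable) twilight
longitude.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .config import PipelineConfig
from .solar import day_length_h, solar_ephemeris
from .types import (
    POLAR_DAY,
    POLAR_NIGHT,
    PositionEstimate,
    Source,
    SSTGrid,
    SSTSample,
    TwilightRecord,
    norm_lon,
)


def estimate_longitude(rec: TwilightRecord) -> tuple[float, bool]:
    """Longitude (deg E) from the twilight midpoint.

    Returns ``(lon, polar_flagged)``. The midpoint is taken on the shorter
    arc (a sunset that falls past midnight UTC is unwrapped before
    averaging), then ``lon = -15 deg/h * (t_mid - 12 h + EoT)``.
    """
    if rec.sentinel is not None:
        return float("nan"), True
    sr, ss = rec.sunrise_h, rec.sunset_h
    if ss < sr:
        ss += 24.0
    t_mid = ((sr + ss) / 2.0) % 24.0
    eot_h = solar_ephemeris(rec.date).equation_of_time_min / 60.0
    lon = -15.0 * (t_mid - 12.0 + eot_h)
    return float(norm_lon(lon)), False


def estimate_latitude(
    rec: TwilightRecord, sun_angle_deg: float, equinox_decl_deg: float = 5.0
) -> tuple[float, bool, bool]:
    """Latitude (deg N) from day length by bisection on [-85, 85].

    Returns ``(lat, equinox_flagged, polar_flagged)``. Latitude is NaN when
    the day length is unattainable at any latitude for the date's
    declination (polar-flagged, or equinox-flagged inside the equinox
    window where the inversion is ill-conditioned anyway).
    """
    if rec.sentinel is not None:
        return float("nan"), False, True
    delta = solar_ephemeris(rec.date).declination_deg
    equinox = abs(delta) < equinox_decl_deg
    target = rec.day_length_h

    def f(phi):
        return day_length_h(phi, delta, sun_angle_deg) - target

    lo, hi = -85.0, 85.0
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo, equinox, False
    if fhi == 0.0:
        return hi, equinox, False
    if flo * fhi > 0:
        # no latitude reproduces this day length for this declination
        return float("nan"), equinox, not equinox
    lat = brentq(f, lo, hi, xtol=1e-7)
    return float(lat), equinox, False


def daylength_sensitivity(lat: float, date: dt.date, sun_angle_deg: float) -> float:
    """|d(day length)/d(latitude)| in minutes per degree.

    The standard error of a day-length latitude is (twilight noise in
    minutes) / (this sensitivity): the inversion is ill-conditioned not
    only near the equinoxes (declination -> 0) but also at low latitudes
    generally, where day length barely varies with latitude.
    """
    delta = solar_ephemeris(date).declination_deg
    eps = 0.5
    lo, hi = max(lat - eps, -85.0), min(lat + eps, 85.0)
    d0 = day_length_h(lo, delta, sun_angle_deg)
    d1 = day_length_h(hi, delta, sun_angle_deg)
    return abs(d1 - d0) / (hi - lo) * 60.0


def estimate_positions(
    twilights: Sequence[TwilightRecord],
    config: PipelineConfig,
) -> list[PositionEstimate]:
    """Threshold-method daily positions for one bird's twilight series."""
    out = []
    for rec in twilights:
        lon, polar_lon = estimate_longitude(rec)
        lat, equinox, polar_lat = estimate_latitude(
            rec, config.sun_angle_deg, config.equinox_decl_deg
        )
        out.append(
            PositionEstimate(
                bird_id=rec.bird_id,
                date=rec.date,
                lat=lat,
                lon=lon,
                source=Source.THRESHOLD,
                equinox_flagged=equinox,
                polar_flagged=polar_lon or polar_lat,
            )
        )
    return out


def select_grid(grids: Iterable[SSTGrid], date: dt.date) -> Optional[SSTGrid]:
    """The 8-day composite whose [start, start+8d) interval contains ``date``."""
    for g in grids:
        if g.covers(date):
            return g
    return None


_MAX_INFORMATIVE_RUN_DEG = 6.0


def _candidate_latitudes(
    profile: np.ndarray, lat_axis: np.ndarray, tag_sst: float, tolerance: float
) -> list[float]:
    """Candidate latitudes where the profile matches the tag temperature.

    Contiguous runs of in-tolerance latitudes are each reduced to their
    best-matching latitude; a monotone profile therefore yields a single
    candidate (the crossing), a non-monotone one several, to be
    disambiguated by the nearest-to-previous rule. Runs wider than a few
    degrees (a flat profile) are kept whole instead, so the selection makes
    the smallest move consistent with the tag value.
    """
    diff = np.abs(profile - tag_sst)
    ok = np.isfinite(diff) & (diff <= tolerance)
    cands = []
    i, n = 0, len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            width = abs(float(lat_axis[j]) - float(lat_axis[i]))
            if width > _MAX_INFORMATIVE_RUN_DEG:
                # a very wide run means the profile is flat there: the
                # best-|dT| point is noise; report the run edges so the
                # nearest-to-previous rule stays inside it with minimal
                # movement
                cands.extend(np.asarray(lat_axis[i : j + 1], dtype=float).tolist())
            else:
                k = i + int(np.argmin(diff[i : j + 1]))
                cands.append(float(lat_axis[k]))
            i = j + 1
        else:
            i += 1
    return cands


def sst_correct_latitude(
    position: PositionEstimate,
    tag_sst: Optional[float],
    grid: Optional[SSTGrid],
    previous_lat: Optional[float],
    config: PipelineConfig,
) -> PositionEstimate:
    """Refine a position's latitude by matching tag SST to the composite.

    The composite is scanned along the fixed twilight longitude (the
    nearest column averaged with its two neighbours) within a search band
    of +/- ``sst_search_band_deg`` around the threshold latitude, or the
    whole profile when the threshold latitude is equinox-flagged or
    missing. Candidates within ``sst_tolerance_c`` of the tag value are
    disambiguated by proximity to the previous day's latitude. Longitude is
    never altered. With no tag sample, grid, or candidate the input is
    returned unchanged.
    """
    if tag_sst is None or grid is None or not np.isfinite(position.lon):
        return position
    j = int(np.argmin(np.abs(grid.lon_axis - position.lon)))
    j0, j1 = max(0, j - 1), min(len(grid.lon_axis), j + 2)
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(grid.values[:, j0:j1], axis=1)
    lat_axis = grid.lat_axis
    if position.equinox_flagged or not np.isfinite(position.lat):
        band = np.ones(len(lat_axis), dtype=bool)
    else:
        band = np.abs(lat_axis - position.lat) <= config.sst_search_band_deg
    masked = np.where(band, profile, np.nan)
    cands = _candidate_latitudes(masked, lat_axis, tag_sst, config.sst_tolerance_c)
    if not cands:
        return position
    if previous_lat is not None and np.isfinite(previous_lat):
        ref = previous_lat
    elif np.isfinite(position.lat):
        ref = position.lat
    else:
        ref = float(np.median(cands))
    best = min(cands, key=lambda c: abs(c - ref))
    return dataclasses.replace(position, lat=best, source=Source.SST_CORRECTED)


def _presmooth_sst(by_date: dict) -> dict:
    """1:2:1 smoothing of the daily tag-SST series before matching.

    Daily minimum SST readings are noisy relative to 8-day composites; a
    centred weighted average over adjacent days reduces that noise without
    lagging a moving bird. Missing days stay missing and are skipped as
    neighbours.
    """
    out = {}
    for date, val in by_date.items():
        if val is None:
            out[date] = None
            continue
        num, den = 2.0 * val, 2.0
        for off, w in ((-1, 1.0), (1, 1.0)):
            nb = by_date.get(date + dt.timedelta(days=off))
            if nb is not None:
                num += w * nb
                den += w
        out[date] = num / den
    return out


def sst_correct_track(
    positions: Sequence[PositionEstimate],
    sst_samples: Sequence[SSTSample],
    grids: Sequence[SSTGrid],
    config: PipelineConfig,
    initial_lat: Optional[float] = None,
) -> list[PositionEstimate]:
    """Apply the SST correction sequentially along one bird's positions.

    By default (``sst_scope='equinox'``) only positions whose day-length
    latitude is unusable — equinox-flagged or missing — are corrected,
    which is what SST correlation is for: retaining data around the
    equinoxes. ``sst_scope='all'`` corrects every day with a tag sample.
    The previous day's (corrected) latitude anchors the candidate choice;
    before any latitude is known the colony latitude (``initial_lat``) is
    used.
    """
    by_date = _presmooth_sst({s.date: s.min_sst for s in sst_samples})
    prev = initial_lat if initial_lat is not None else config.colony_lat
    out = []
    for pos in positions:
        if config.sst_scope == "all":
            correct = True
        elif pos.equinox_flagged or not np.isfinite(pos.lat):
            correct = True
        elif config.sst_scope == "auto":
            at = pos.lat if np.isfinite(pos.lat) else prev
            correct = (
                daylength_sensitivity(at, pos.date, config.sun_angle_deg)
                < config.sst_min_sensitivity
            )
        else:
            correct = False
        if correct:
            fixed = sst_correct_latitude(
                pos, by_date.get(pos.date), select_grid(grids, pos.date), prev, config
            )
            if fixed.source is not Source.SST_CORRECTED and config.sst_scope != "all":
                # the day-length latitude is unreliable here and no SST
                # rescue was possible: the day is invalid
                fixed = dataclasses.replace(fixed, lat=float("nan"))
            pos = fixed
        out.append(pos)
        if np.isfinite(pos.lat):
            prev = pos.lat
    return out
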