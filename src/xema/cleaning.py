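"""Track cleaning: sustained-speed filtering and 1:2:1 smoothing.

The speed filter removes positions implying flight faster than 13.9 m/s
(50 km/h) sustained over a 48 h window, in the root-mean-square sense of
the classic sustained-speed filters: each position's RMS of implied
speeds to its retained neighbours within the window is compared to the
ceiling, and the worst offender is removed iteratively. Smoothing then
replaces each interior position by the 1:2:1 weighted mean of its
previous/current/next positions, except colony-fixed positions, the track
ends, and positions moving more than 4 deg of longitude or 6 deg of
latitude to a neighbour, which would smear genuine relocations.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import numpy as np

from .config import PipelineConfig
from .stats import haversine_km
from .types import PositionEstimate, Source, Track, norm_lon, wrap_diff


@dataclass
class SpeedAssessment:
    """Implied speeds for adjacent retained pairs and the windowed metric."""

    pair_speeds_ms: np.ndarray  # length n-1, speed of pair (i, i+1)
    windowed_rms_ms: np.ndarray  # length n, RMS speed to neighbours within the window


def _epoch_days(track: Track) -> np.ndarray:
    return np.array([d.toordinal() for d in track.dates], dtype=float)


def _pair_speed_ms(lat, lon, t_days, i, j) -> float:
    km = haversine_km((lat[i], lon[i]), (lat[j], lon[j]))
    seconds = abs(t_days[j] - t_days[i]) * 86400.0
    return km * 1000.0 / seconds


def _windowed_rms(lat, lon, t_days, idx: np.ndarray, window_h: float) -> np.ndarray:
    """RMS of implied speeds from each retained position to every retained
    position within the time window."""
    out = np.zeros(len(idx))
    window_d = window_h / 24.0
    for a, i in enumerate(idx):
        sq = []
        for j in idx:
            if j == i:
                continue
            if abs(t_days[j] - t_days[i]) <= window_d + 1e-9:
                sq.append(_pair_speed_ms(lat, lon, t_days, i, j) ** 2)
        out[a] = np.sqrt(np.mean(sq)) if sq else 0.0
    return out


def implied_speeds(track: Track, window_h: float = 48.0) -> SpeedAssessment:
    """Per-pair implied speeds (m/s) and the per-position windowed RMS."""
    if len(track) < 2:
        raise ValueError("implied_speeds needs at least 2 positions")
    dates = track.dates
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("duplicate or non-increasing dates")
    lat, lon, t = track.lats, track.lons, _epoch_days(track)
    idx = np.arange(len(track))
    pair = np.array([_pair_speed_ms(lat, lon, t, i, i + 1) for i in range(len(track) - 1)])
    return SpeedAssessment(pair_speeds_ms=pair, windowed_rms_ms=_windowed_rms(lat, lon, t, idx, window_h))


def speed_filter(
    track: Track,
    v_max_ms: float = 13.9,
    window_h: float = 48.0,
    strict_pairwise: bool = False,
) -> tuple[Track, list[PositionEstimate]]:
    """Iteratively remove unrealistic-speed positions.

    The non-fixed position with the largest windowed RMS speed is removed
    and speeds recomputed, until no retained position exceeds ``v_max_ms``.
    In ``strict_pairwise`` mode a single adjacent pair exceeding the
    ceiling is itself grounds for removal. Colony-fixed positions are never
    removed; removed positions are returned flagged ``speed_rejected``.
    """
    lat, lon, t = track.lats, track.lons, _epoch_days(track)
    fixed = np.array([p.source is Source.FIXED_COLONY for p in track.positions])
    retained = list(range(len(track)))
    removed_idx: list[int] = []

    def violation_scores(idx):
        rms = _windowed_rms(lat, lon, t, np.array(idx), window_h)
        if not strict_pairwise:
            return rms
        # strict mode: any adjacent pair above v_max marks both endpoints
        scores = rms.copy()
        for a in range(len(idx) - 1):
            s = _pair_speed_ms(lat, lon, t, idx[a], idx[a + 1])
            if s > v_max_ms:
                scores[a] = max(scores[a], s)
                scores[a + 1] = max(scores[a + 1], s)
        return scores

    while len(retained) >= 2:
        scores = violation_scores(retained)
        scores[fixed[retained]] = -1.0  # fixed positions never removed
        worst = int(np.argmax(scores))
        if scores[worst] <= v_max_ms:
            break
        removed_idx.append(retained.pop(worst))

    kept = [track.positions[i] for i in retained]
    removed = [
        dataclasses.replace(track.positions[i], speed_rejected=True) for i in sorted(removed_idx)
    ]
    if not any(not fixed[i] for i in retained):
        import warnings

        warnings.warn(f"speed filter removed every non-fixed position of {track.bird_id}")
    return track.replace_positions(kept), removed


def smooth_track(track: Track, config: PipelineConfig = None) -> Track:
    """1:2:1 weighted moving average with exclusion rules.

    All positions are smoothed simultaneously from the original
    (pre-smoothing) neighbours, so the result is order-independent.
    Excluded but still used as neighbours: colony-fixed positions, the
    first and last position, and positions whose movement to either
    neighbour exceeds the 4 deg lon / 6 deg lat jump limits (these are
    flagged ``unsmoothed_jump``). Longitudes are unwrapped around each
    window so antimeridian crossings average correctly.
    """
    config = config or PipelineConfig()
    n = len(track)
    if n < 3:
        return track
    w1, w2, w3 = config.smooth_weights
    wsum = w1 + w2 + w3
    lat, lon = track.lats, track.lons
    out = []
    for i, pos in enumerate(track.positions):
        if i == 0 or i == n - 1 or pos.source is Source.FIXED_COLONY:
            out.append(pos)
            continue
        dlon_prev = abs(wrap_diff(lon[i], lon[i - 1]))
        dlon_next = abs(wrap_diff(lon[i + 1], lon[i]))
        dlat_prev = abs(lat[i] - lat[i - 1])
        dlat_next = abs(lat[i + 1] - lat[i])
        if (
            max(dlon_prev, dlon_next) > config.jump_limit_lon_deg
            or max(dlat_prev, dlat_next) > config.jump_limit_lat_deg
        ):
            out.append(dataclasses.replace(pos, unsmoothed_jump=True))
            continue
        new_lat = (w1 * lat[i - 1] + w2 * lat[i] + w3 * lat[i + 1]) / wsum
        lon_prev = lon[i] + wrap_diff(lon[i - 1], lon[i])
        lon_next = lon[i] + wrap_diff(lon[i + 1], lon[i])
        new_lon = float(norm_lon((w1 * lon_prev + w2 * lon[i] + w3 * lon_next) / wsum))
        out.append(dataclasses.replace(pos, lat=float(new_lat), lon=new_lon, source=Source.SMOOTHED))
    return track.replace_positions(out)
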