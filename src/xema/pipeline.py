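"""End-to-end track-processing pipeline.

Stage order is fixed: threshold geolocation -> SST latitude correction ->
sustained-speed filter -> 1:2:1 smoothing -> stopover/travel segmentation
(with burst adjustment) -> wintering-area definition (pooled 50%
occupancy contour, two passes) -> phase splitting -> migration metrics and
group statistics. Each stage appends a structured log entry with counts
in/removed/out, so record conservation can be asserted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cleaning import smooth_track, speed_filter
from .config import PipelineConfig
from .geolocation import estimate_positions, sst_correct_track
from .io import summaries_to_frame, write_geojson, write_stage_log, write_track
from .segmentation import (
    PhaseSplit,
    WinteringArea,
    adjust_bursts,
    classify_days,
    define_wintering_area,
    infer_basin,
    split_phases,
)
from .stats import daily_km, haversine_km, summarize_migration, welch_t
from .types import (
    Basin,
    DayState,
    MigrationSummary,
    Phase,
    PositionEstimate,
    Source,
    SSTGrid,
    SSTSample,
    State,
    TestResult,
    Track,
    TwilightRecord,
)


@dataclass
class BirdInput:
    bird_id: str
    twilights: list[TwilightRecord]
    sst_samples: list[SSTSample] = field(default_factory=list)
    sex: Optional[str] = None
    deployment_year: Optional[int] = None


@dataclass
class BirdResult:
    bird_id: str
    track: Optional[Track]
    day_states: list[DayState]
    phase_split: Optional[PhaseSplit]
    summary: Optional[MigrationSummary]
    failed: bool = False
    failure_reason: Optional[str] = None


@dataclass
class PipelineResult:
    birds: list[BirdResult]
    wintering_areas: dict
    stage_log: list[dict]
    tests: dict

    @property
    def summary_frame(self) -> pd.DataFrame:
        return summaries_to_frame([b.summary for b in self.birds if b.summary is not None])

    def phase_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.birds:
            if b.phase_split is None:
                continue
            rows.append(
                {
                    "bird_id": b.bird_id,
                    "departure": b.phase_split.departure.isoformat() if b.phase_split.departure else "",
                    "arrival": b.phase_split.arrival.isoformat() if b.phase_split.arrival else "",
                    "basin": b.phase_split.basin.value if b.phase_split.basin else "",
                }
            )
        return pd.DataFrame(rows)

    def day_state_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.birds:
            for s in b.day_states:
                rows.append(
                    {
                        "bird_id": b.bird_id,
                        "date": s.date.isoformat(),
                        "daily_km": round(s.daily_km, 3),
                        "state": s.state.value,
                        "burst_adjusted": s.burst_adjusted,
                        "phase": s.phase.value if s.phase else "",
                    }
                )
        return pd.DataFrame(rows)


def geolocate_bird(bird: BirdInput, grids: Sequence[SSTGrid], config: PipelineConfig, log: list):
    """Threshold positions + SST correction + colony fixing for one bird.

    Leading days without a usable latitude (polar twilight at the colony)
    are fixed to the colony coordinates, as are all pre-departure days up
    to the first usable estimate; remaining unusable days are dropped and
    counted.
    """
    positions = estimate_positions(bird.twilights, config)
    n_in = len(positions)
    positions = sst_correct_track(positions, bird.sst_samples, grids, config)
    # fix the leading run of unusable (polar) days to the colony
    i = 0
    while i < len(positions) and not positions[i].usable:
        positions[i] = PositionEstimate(
            bird.bird_id, positions[i].date, config.colony_lat, config.colony_lon,
            Source.FIXED_COLONY,
        )
        i += 1
    if i == 0 and positions:
        # tracks start at the breeding colony: the first day is fixed there
        positions[0] = PositionEstimate(
            bird.bird_id, positions[0].date, config.colony_lat, config.colony_lon,
            Source.FIXED_COLONY,
        )
    kept = [p for p in positions if p.usable]
    dropped = n_in - len(kept)
    log.append(
        {"stage": "geolocate", "bird": bird.bird_id, "in": n_in, "removed": dropped, "out": len(kept)}
    )
    return kept


def clean_bird(bird_id: str, positions: list, config: PipelineConfig, log: list) -> Optional[Track]:
    track = Track(
        bird_id=bird_id, sex=None, deployment_year=None,
        colony_lat=config.colony_lat, colony_lon=config.colony_lon, positions=positions,
    )
    if len(track) < 2:
        log.append({"stage": "speed_filter", "bird": bird_id, "in": len(track), "removed": 0, "out": len(track)})
        return track
    kept, removed = speed_filter(track, config.v_max_ms, config.sustain_window_h, config.strict_pairwise)
    log.append(
        {"stage": "speed_filter", "bird": bird_id, "in": len(track), "removed": len(removed), "out": len(kept)}
    )
    smoothed = smooth_track(kept, config)
    log.append(
        {"stage": "smooth", "bird": bird_id, "in": len(kept), "removed": 0, "out": len(smoothed)}
    )
    return smoothed


def segment_bird(track: Track, config: PipelineConfig) -> list[DayState]:
    rates = daily_km(track, config.earth_radius_km)
    series = [0.0] + [r for _, r in rates]
    states = classify_days(
        series, config.seg_threshold_kmd, config.seg_window, config.seg_count,
        config.seg_anchor, config.seg_effect,
    )
    states, adjusted = adjust_bursts(
        states, series, track.lats, track.lons, config.seg_threshold_kmd, config.burst_multiplier
    )
    return [
        DayState(date=d, daily_km=v, state=s, burst_adjusted=a)
        for d, v, s, a in zip(track.dates, series, states, adjusted)
    ]


def run_pipeline(
    config: PipelineConfig,
    birds: Sequence[BirdInput],
    grids: Sequence[SSTGrid],
) -> PipelineResult:
    """Run the full chain over a cohort and return the report bundle."""
    log: list[dict] = []
    prepared = []
    for bird in birds:
        try:
            positions = geolocate_bird(bird, grids, config, log)
            track = clean_bird(bird.bird_id, positions, config, log)
            if track is None or len(track) < 3:
                raise ValueError("too few usable positions")
            day_states = segment_bird(track, config)
            prepared.append((bird, track, day_states))
        except Exception as e:  # a failed bird does not stop the cohort
            log.append({"stage": "failed", "bird": bird.bird_id, "reason": str(e)})
            prepared.append((bird, None, []))

    # pass 1: pool post-migration stopover positions south of the equator.
    # Without an arrival rule yet, "post-migration" is operationalized as
    # near the track's terminus (tracks end in winter residency), which is
    # robust to occasional mid-winter state flips and excludes en-route
    # stopovers.
    pooled = {Basin.PACIFIC: ([], []), Basin.ATLANTIC: ([], [])}
    for bird, track, day_states in prepared:
        if track is None or not len(track):
            continue
        ref = (track.positions[-1].lat, track.positions[-1].lon)
        for pos, s in zip(track.positions, day_states):
            if (
                s.state is State.STOPOVER
                and pos.lat < 0.0
                and haversine_km((pos.lat, pos.lon), ref, config.earth_radius_km)
                <= config.winter_pool_radius_km
            ):
                basin = infer_basin(pos.lon, config.basin_divide_lon)
                pooled[basin][0].append(pos.lat)
                pooled[basin][1].append(pos.lon)

    wintering: dict = {}
    for basin, (lats, lons) in pooled.items():
        if len(lats) >= config.min_winter_positions:
            wintering[basin] = define_wintering_area(lats, lons, basin, config)
            log.append(
                {"stage": "wintering_area", "basin": basin.value, "in": len(lats),
                 "removed": 0, "out": len(lats)}
            )
        else:
            wintering[basin] = None
            log.append(
                {"stage": "wintering_area", "basin": basin.value, "in": len(lats),
                 "removed": len(lats), "out": 0, "reason": "too few pooled winter positions"}
            )

    # pass 2: re-derive arrival dates against the polygons, then summarize
    results = []
    for bird, track, day_states in prepared:
        if track is None:
            results.append(BirdResult(bird.bird_id, None, [], None, None, failed=True,
                                      failure_reason="stage failure (see log)"))
            continue
        basin_guess = infer_basin(track.lons[-1], config.basin_divide_lon)
        split = split_phases(track, day_states, wintering.get(basin_guess), config)
        for s, ph in zip(day_states, split.phases):
            s.phase = ph
        summary = summarize_migration(
            track, day_states, split.departure, split.arrival, split.basin, config.earth_radius_km
        )
        results.append(BirdResult(bird.bird_id, track, day_states, split, summary))

    tests = {}
    by_basin = {Basin.PACIFIC: [], Basin.ATLANTIC: []}
    for r in results:
        if r.summary is not None and r.summary.complete:
            by_basin[r.summary.basin].append(r.summary)
    if all(len(v) >= 2 for v in by_basin.values()):
        tests["travel_distance_welch"] = welch_t(
            [s.travel_distance_km for s in by_basin[Basin.PACIFIC]],
            [s.travel_distance_km for s in by_basin[Basin.ATLANTIC]],
        )
        tests["travel_speed_welch"] = welch_t(
            [s.travel_speed_kmd for s in by_basin[Basin.PACIFIC]],
            [s.travel_speed_kmd for s in by_basin[Basin.ATLANTIC]],
        )
    return PipelineResult(results, wintering, log, tests)


def write_report_bundle(result: PipelineResult, outdir) -> None:
    """Write tracks, day states, phases, summaries, contours, and the log."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for b in result.birds:
        if b.track is not None:
            write_track(b.track, os.path.join(outdir, f"track_{b.bird_id}.csv"))
    result.day_state_frame().to_csv(os.path.join(outdir, "day_states.csv"), index=False)
    result.phase_frame().to_csv(os.path.join(outdir, "phases.csv"), index=False)
    result.summary_frame.to_csv(os.path.join(outdir, "migration_summary.csv"), index=False)
    for basin, area in result.wintering_areas.items():
        if area is None:
            continue
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {
                        "basin": basin.value,
                        "level_percent": area.level,
                        "captured_fraction": round(area.captured_fraction, 6),
                        "n_positions": area.n_positions,
                    },
                    "geometry": area.polygon_geographic.__geo_interface__,
                }
            ],
        }
        write_geojson(fc, os.path.join(outdir, f"wintering_{basin.value.lower()}.geojson"))
    write_stage_log(result.stage_log, os.path.join(outdir, "stage_log.jsonl"))
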