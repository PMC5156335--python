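"""Stopover/travel state machine, burst adjustment, phases."""
import datetime as dt
import itertools

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Polygon

from xema import (
    Basin,
    DayState,
    Phase,
    PipelineConfig,
    PositionEstimate,
    Source,
    State,
    Track,
    adjust_bursts,
    classify_days,
    define_wintering_area,
    infer_basin,
    split_phases,
)
from xema.segmentation import WinteringArea
from xema.spaceuse import SOUTH_AMERICA_ALBERS

D0 = dt.date(2010, 9, 1)
S, T = State.STOPOVER, State.TRAVEL


def reference_state_machine(exceeds, window=5, count=3):
    """Independent, deliberately naive transcription of the rule.

    ``exceeds[i]`` is True when day i moves more than the threshold. Start
    in stopover; while in stopover, look at the next ``window`` days from
    the current day: if at least ``count`` exceed, travel begins at the
    first exceeding day among them. Symmetric for the return transition.
    """
    n = len(exceeds)
    out = [None] * n
    state = "S"
    i = 0
    while i < n:
        win = list(range(i, min(i + window, n)))
        if state == "S":
            hits = [j for j in win if exceeds[j]]
        else:
            hits = [j for j in win if not exceeds[j]]
        if len(hits) >= count:
            first = hits[0]
            for k in range(i, first):
                out[k] = state
            state = "T" if state == "S" else "S"
            out[first] = state
            i = first + 1
        else:
            out[i] = state
            i += 1
    return out


def test_all_slow_days_stay_stopover():
    assert classify_days([50.0] * 10) == [S] * 10


def test_documented_example_sequence():
    series = [50, 150, 150, 150, 50, 50, 50, 50]
    assert classify_days(series) == [S, T, T, T, S, S, S, S]


def test_matches_reference_machine_on_all_length_12_sequences():
    """Exhaustive equivalence with the naive reference on all 4,096
    binary exceedance patterns."""
    for bits in itertools.product([False, True], repeat=12):
        series = [150.0 if b else 50.0 for b in bits]
        got = ["T" if s is T else "S" for s in classify_days(series)]
        assert got == reference_state_machine(list(bits)), bits


def test_window_start_effect_option():
    series = [50, 50, 150, 150, 150, 50, 50, 50]
    got = classify_days(series, effect="window_start")
    # the triggering window is anchored at day 0, so travel starts there
    assert got[0] is T


class TestBursts:
    def _states(self, pattern):
        return [S if c == "S" else T for c in pattern]

    def test_noisy_day_without_relocation_unchanged(self):
        states = self._states("SSSSSSS")
        dkm = [0, 10, 10, 120, 10, 10, 10]
        lats = [10.0] * 7
        lons = [-30.0] * 7
        out, adj = adjust_bursts(states, dkm, lats, lons)
        assert out == states and not any(adj)

    def test_burst_between_distant_stopovers_relabelled(self):
        states = self._states("SSSSSSS")
        dkm = [0, 10, 10, 400, 10, 10, 10]
        lats = [10.0] * 3 + [12.0] + [13.6] * 3  # ~400 km relocation
        lons = [-30.0] * 7
        out, adj = adjust_bursts(states, dkm, lats, lons)
        assert out[3] is T and adj[3]
        assert out[:3] == [S, S, S] and out[4:] == [S, S, S]

    def test_three_fast_days_out_of_scope(self):
        states = self._states("SSSSSSSS")
        dkm = [0, 10, 150, 150, 150, 10, 10, 10]
        lats = [10.0, 10.0, 10.0, 11.3, 12.6, 14.0, 14.0, 14.0]
        lons = [-30.0] * 8
        out, adj = adjust_bursts(states, dkm, lats, lons)
        assert out == states and not any(adj)  # run of 3 exceeds the 1-2 d rule


def square_area(lat0, lon0, half_deg):
    poly = MultiPolygon(
        [
            Polygon(
                [
                    (lon0 - half_deg, lat0 - half_deg),
                    (lon0 + half_deg, lat0 - half_deg),
                    (lon0 + half_deg, lat0 + half_deg),
                    (lon0 - half_deg, lat0 + half_deg),
                ]
            )
        ]
    )
    return WinteringArea(
        basin=Basin.PACIFIC,
        polygon_geographic=poly,
        polygon_projected=poly,
        projection=SOUTH_AMERICA_ALBERS,
        level=50.0,
        captured_fraction=0.5,
        n_positions=100,
    )


def day_states(states, start=D0):
    return [
        DayState(date=start + dt.timedelta(days=i), daily_km=0.0, state=s)
        for i, s in enumerate(states)
    ]


def track_from(lats_lons, colony=(75.8, -96.3)):
    positions = [
        PositionEstimate(
            "b",
            D0 + dt.timedelta(days=i),
            lat,
            lon,
            Source.FIXED_COLONY if i == 0 else Source.THRESHOLD,
        )
        for i, (lat, lon) in enumerate(lats_lons)
    ]
    return Track("b", None, None, colony[0], colony[1], positions)


class TestSplitPhases:
    def test_exact_departure_and_arrival(self):
        pts = [(75.8, -96.3), (75.8, -96.0), (70.0, -100.0), (40.0, -110.0), (-10.0, -85.0), (-10.1, -85.1)]
        track = track_from(pts)
        states = day_states([S, S, T, T, T, S])
        area = square_area(-10.0, -85.0, 2.0)
        split = split_phases(track, states, area)
        assert split.departure == D0 + dt.timedelta(days=2)
        assert split.arrival == D0 + dt.timedelta(days=5)
        assert split.phases == [
            Phase.BREEDING,
            Phase.BREEDING,
            Phase.FALL_MIGRATION,
            Phase.FALL_MIGRATION,
            Phase.FALL_MIGRATION,
            Phase.WINTER,
        ]

    def test_phase_partition_is_ordered(self):
        pts = [(75.8, -96.3), (70.0, -100.0), (-10.0, -85.0), (-10.1, -85.0), (0.0, -90.0), (-10.0, -85.0)]
        track = track_from(pts)
        states = day_states([S, T, S, S, T, S])
        split = split_phases(track, states, square_area(-10.0, -85.0, 2.0))
        order = [Phase.BREEDING, Phase.FALL_MIGRATION, Phase.WINTER]
        idx = [order.index(p) for p in split.phases]
        assert idx == sorted(idx)

    def test_no_travel_day_flags_no_migration(self):
        pts = [(75.8, -96.3), (75.8, -96.2), (75.8, -96.3)]
        split = split_phases(track_from(pts), day_states([S, S, S]), None)
        assert split.no_migration and split.departure is None

    def test_never_entering_polygon_is_direction_only(self):
        pts = [(75.8, -96.3), (70.0, -110.0), (50.0, -130.0), (49.0, -131.0)]
        track = track_from(pts)
        states = day_states([S, T, T, S])
        split = split_phases(track, states, square_area(-10.0, -85.0, 2.0))
        assert split.departure is not None
        assert split.arrival is None
        assert split.basin is Basin.PACIFIC  # from final longitude


def test_basin_inference_convention():
    assert infer_basin(-85.0) is Basin.PACIFIC
    assert infer_basin(10.0) is Basin.ATLANTIC
    assert infer_basin(-40.0) is Basin.ATLANTIC


class TestWinteringArea:
    def test_polygon_contains_cluster_centroid(self):
        rng = np.random.default_rng(0)
        lats = -10.0 + rng.normal(0, 1.0, 300)
        lons = -85.0 + rng.normal(0, 1.0, 300)
        area = define_wintering_area(lats, lons, Basin.PACIFIC)
        assert area.contains(-10.0, -85.0)
        assert area.level == 50.0

    def test_too_few_positions_error_names_basin(self):
        with pytest.raises(ValueError, match="ATLANTIC"):
            define_wintering_area([-25.0] * 10, [10.0] * 10, Basin.ATLANTIC)

    def test_small_two_bird_pool_still_produces_polygon(self):
        # mirrors the two-bird wintering contour: few birds, enough days
        rng = np.random.default_rng(1)
        lats = np.concatenate([-24.0 + rng.normal(0, 0.7, 30), -25.5 + rng.normal(0, 0.7, 30)])
        lons = np.concatenate([9.0 + rng.normal(0, 0.7, 30), 11.0 + rng.normal(0, 0.7, 30)])
        area = define_wintering_area(lats, lons, Basin.ATLANTIC)
        assert area.n_positions == 60
        assert not area.polygon_geographic.is_empty
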