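"""Sustained-speed filter and 1:2:1 smoothing."""
import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xema import (
    PipelineConfig,
    PositionEstimate,
    Source,
    Track,
    haversine_km,
    implied_speeds,
    smooth_track,
    speed_filter,
)

D0 = dt.date(2010, 9, 1)


def make_track(points, colony=None):
    """Build a daily track from (lat, lon) pairs, anchored at the first point."""
    colony = colony or points[0]
    positions = []
    for i, (lat, lon) in enumerate(points):
        src = Source.FIXED_COLONY if i == 0 else Source.THRESHOLD
        positions.append(PositionEstimate("b", D0 + dt.timedelta(days=i), lat, lon, src))
    return Track("b", None, None, colony[0], colony[1], positions)


class TestImpliedSpeeds:
    def test_identical_positions_give_zero(self):
        t = make_track([(10.0, 10.0), (10.0, 10.0 + 1e-12), (10.0, 10.0)])
        assert implied_speeds(t).pair_speeds_ms == pytest.approx([0.0, 0.0], abs=1e-6)

    def test_two_thousand_km_in_one_day(self):
        # 2,000,000 m / 86,400 s = 23.15 m/s
        lat2 = 2000.0 / 111.195
        t = make_track([(0.0, 0.0), (lat2, 0.0)])
        assert implied_speeds(t).pair_speeds_ms[0] == pytest.approx(23.148, abs=0.05)

    def test_boundary_speed_does_not_exceed_threshold(self):
        lat2 = 1200.0 / 111.195
        t = make_track([(0.0, 0.0), (lat2, 0.0)])
        s = implied_speeds(t).pair_speeds_ms[0]
        assert s == pytest.approx(13.889, abs=0.02)
        assert s < 13.9

    def test_duplicate_dates_rejected(self):
        p = [
            PositionEstimate("b", D0, 0.0, 0.0, Source.FIXED_COLONY),
            PositionEstimate("b", D0 + dt.timedelta(days=1), 1.0, 0.0, Source.THRESHOLD),
        ]
        t = Track("b", None, None, 0.0, 0.0, p)
        t.positions[1] = PositionEstimate("b", D0, 1.0, 0.0, Source.THRESHOLD)
        with pytest.raises(ValueError):
            implied_speeds(t)


def stationary_with_spike(n=12, spike_at=6, spike_km=2000.0):
    pts = [(10.0, -30.0)] * n
    pts[spike_at] = (10.0 + spike_km / 111.195, -30.0)
    return make_track(pts)


class TestSpeedFilter:
    def test_clean_track_untouched(self):
        # 350 km/d = 4 m/s, far under the ceiling
        pts = [(i * 350.0 / 111.195, 0.0) for i in range(10)]
        kept, removed = speed_filter(make_track(pts))
        assert removed == []
        assert len(kept) == 10

    def test_single_spike_removed_exactly(self):
        t = stationary_with_spike()
        kept, removed = speed_filter(t)
        assert [p.date for p in removed] == [D0 + dt.timedelta(days=6)]
        assert all(p.speed_rejected for p in removed)
        # oracle: of all single removals, only dropping the spike leaves a
        # violation-free track
        def violations(track):
            a = implied_speeds(track)
            return int(np.sum(a.windowed_rms_ms > 13.9))
        fixes = [
            i
            for i in range(1, len(t))
            if violations(t.replace_positions(t.positions[:i] + t.positions[i + 1 :])) == 0
        ]
        assert fixes == [6]

    def test_postcondition_no_sustained_violation(self, small_cohort, config):
        # noisy simulated tracks: after filtering, no retained windowed RMS
        # speed exceeds the ceiling
        from xema.pipeline import BirdInput, geolocate_bird

        b = small_cohort.birds[0]
        log = []
        pos = geolocate_bird(
            BirdInput(b.itinerary.bird_id, b.twilights, b.sst_samples), small_cohort.grids, config, log
        )
        track = Track("b", None, None, config.colony_lat, config.colony_lon, pos)
        kept, _ = speed_filter(track, config.v_max_ms, config.sustain_window_h)
        assert np.all(implied_speeds(kept, config.sustain_window_h).windowed_rms_ms <= config.v_max_ms)

    def test_idempotent(self):
        kept, _ = speed_filter(stationary_with_spike())
        kept2, removed2 = speed_filter(kept)
        assert removed2 == []
        assert [p.date for p in kept2.positions] == [p.date for p in kept.positions]

    def test_fixed_colony_never_removed(self):
        # a fixed start far from a stationary cluster implies huge speeds,
        # but the colony anchor must survive
        pts = [(75.8, -96.3)] + [(10.0, -30.0)] * 6
        t = make_track(pts, colony=(75.8, -96.3))
        kept, removed = speed_filter(t)
        assert kept.positions[0].source is Source.FIXED_COLONY


class TestSmoothing:
    def test_collinear_positions_are_fixed_point(self):
        t = make_track([(0.0, 0.0), (0.0, 1.0), (0.0, 2.0)])
        out = smooth_track(t)
        assert out.positions[1].lat == pytest.approx(0.0)
        assert out.positions[1].lon == pytest.approx(1.0)
        assert out.positions[1].source is Source.SMOOTHED

    def test_weighted_mean_arithmetic(self):
        # (0 + 2*2 + 0) / 4 = 1
        t = make_track([(0.0, 0.0), (2.0, 0.0), (0.0, 0.0)])
        out = smooth_track(t)
        assert out.positions[1].lat == pytest.approx(1.0)

    def test_large_daily_movement_not_smoothed(self):
        t = make_track([(0.0, 0.0), (0.0, 5.0), (0.0, 10.0)])
        out = smooth_track(t)
        mid = out.positions[1]
        assert mid.unsmoothed_jump
        assert (mid.lat, mid.lon) == (0.0, 5.0)
        assert mid.source is Source.THRESHOLD

    def test_six_degree_latitude_rule(self):
        t = make_track([(0.0, 0.0), (6.5, 0.0), (5.0, 0.0)])
        assert smooth_track(t).positions[1].unsmoothed_jump

    def test_antimeridian_unwrap(self):
        t = make_track([(0.0, 178.0), (0.0, 179.5), (0.0, -179.0)])
        out = smooth_track(t)
        mid = out.positions[1].lon
        assert abs(mid) > 170.0  # smooths to near +/-180, never near 0

    def test_short_track_unchanged(self):
        t = make_track([(0.0, 0.0), (1.0, 1.0)])
        assert smooth_track(t).positions == t.positions

    def test_ends_and_fixed_positions_pass_through(self):
        pts = [(75.8, -96.3), (74.0, -96.0), (73.5, -95.5), (73.0, -95.0)]
        t = make_track(pts, colony=(75.8, -96.3))
        out = smooth_track(t)
        assert out.positions[0] == t.positions[0]
        assert out.positions[-1] == t.positions[-1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_smoothing_reduces_day_over_day_variance(self, seed):
        """Mean squared displacement never grows under 1:2:1 smoothing on
        jump-free tracks."""
        rng = np.random.default_rng(seed)
        lat = np.cumsum(rng.normal(0.0, 0.4, size=12)) + 20.0
        lon = np.cumsum(rng.normal(0.0, 0.4, size=12)) - 60.0
        t = make_track(list(zip(lat, lon)))
        out = smooth_track(t)

        def msd(track):
            d = [
                haversine_km((track.lats[i], track.lons[i]), (track.lats[i + 1], track.lons[i + 1]))
                for i in range(len(track) - 1)
            ]
            return float(np.mean(np.square(d)))

        assert msd(out) <= msd(t) + 1e-9
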