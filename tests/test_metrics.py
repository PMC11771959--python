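"""Behavioral-metric unit tests and invariance properties."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroforage.config import MetricsConfig, SiteConfig
from aeroforage.metrics import (
    colony_distance_stats,
    compute_daily_metrics,
    daily_route,
    detect_visits,
    foraging_durations,
    interindividual_distance,
    mean_flight_speed,
    roost_times,
    visit_frequency,
)
from aeroforage.solar import sun_times

from conftest import make_track

UTC = dt.timezone.utc


class TestColonyDistance:
    def test_all_fixes_at_colony(self, site):
        track = make_track([0, 8], [0, 0], [0, 0])
        assert colony_distance_stats(track, site) == (0.0, 0.0)

    def test_mean_and_max_arithmetic(self, site):
        track = make_track([0, 8], [100, 300], [0, 0])
        mean_d, max_d = colony_distance_stats(track, site)
        assert (mean_d, max_d) == (200.0, 300.0)


class TestVisits:
    def test_gap_with_near_colony_endpoints_is_one_visit(self, site):
        track = make_track([0, 8, 78, 86], [20, 20, 20, 20], [0, 0, 0, 0])
        visits = detect_visits(track, site)
        assert len(visits) == 1
        assert visits[0].duration_s == pytest.approx(70.0)

    def test_distant_gap_is_not_a_visit(self, site):
        track = make_track([0, 300], [2000, 2000], [0, 0])
        assert detect_visits(track, site) == []

    def test_gap_of_exactly_sixty_seconds_counts(self, site):
        track = make_track([0, 60], [10, 10], [0, 0])
        assert len(detect_visits(track, site)) == 1

    def test_gap_just_below_threshold_does_not_count(self, site):
        track = make_track([0, 59], [10, 10], [0, 0])
        assert detect_visits(track, site) == []


class TestRoute:
    def test_out_and_back_one_km(self):
        cfg = MetricsConfig(route_min_hours=0.0)
        # out to 960 m and back in 80 m steps
        dist = 80.0 * np.concatenate([np.arange(13), np.arange(12, -1, -1)])
        track = make_track(np.arange(len(dist)) * 10.0, dist, np.zeros(len(dist)))
        # apogee 960 m -> route 1920 m
        assert daily_route(track, [], cfg) == pytest.approx(2 * 960.0)

    def test_square_loop(self):
        cfg = MetricsConfig(route_min_hours=0.0)
        xs = [0, 500, 500, 0, 0]
        ys = [0, 0, 500, 500, 0]
        track = make_track(np.arange(5) * 60.0, xs, ys)
        assert daily_route(track, [], cfg) == pytest.approx(2000.0)

    def test_short_activity_span_yields_nan(self):
        track = make_track([0, 8 * 3600], [0, 100], [0, 0])
        assert math.isnan(daily_route(track, [], MetricsConfig()))

    def test_long_non_visit_gap_yields_nan(self):
        offsets = [0, 1000, 11 * 3600]
        track = make_track(offsets, [0, 100, 200], [0, 0, 0])
        assert math.isnan(daily_route(track, [], MetricsConfig()))


class TestVisitFrequency:
    def test_no_visits(self):
        assert visit_frequency({}, {"a": 10.0}) == 0.0

    def test_single_tag_rate(self):
        assert visit_frequency({"a": 5}, {"a": 10.0}) == pytest.approx(0.5)

    def test_average_over_tags(self):
        rate = visit_frequency({"a": 5, "b": 10}, {"a": 10.0, "b": 10.0})
        assert rate == pytest.approx(0.75)


class TestForagingDurations:
    def test_identity_net_equals_day_length_minus_foraging(self, site):
        date = dt.date(2019, 4, 15)
        sun = sun_times(site.latitude, site.longitude, date)
        t0 = sun.sunrise_utc + dt.timedelta(minutes=10)
        span_s = 11.5 * 3600
        track = make_track([0, span_s], [500, 500], [0, 0], t0=t0)
        foraging, net = foraging_durations(track, [], sun, MetricsConfig())
        assert foraging == pytest.approx(11.5)
        assert net == pytest.approx(sun.day_length_hours - 11.5)

    def test_bird_inside_all_day(self, site):
        date = dt.date(2019, 4, 15)
        sun = sun_times(site.latitude, site.longitude, date)
        t0 = sun.sunrise_utc + dt.timedelta(minutes=30)
        track = make_track([0, 10 * 3600], [10, 10], [0, 0], t0=t0)
        visits = detect_visits(track, site)
        foraging, net = foraging_durations(track, visits, sun, MetricsConfig())
        assert foraging == pytest.approx(0.0)
        assert net == pytest.approx(sun.day_length_hours)


class TestRoost:
    def _sun(self, site, date=dt.date(2019, 4, 15)):
        return sun_times(site.latitude, site.longitude, date)

    def test_entry_exactly_at_sunset_offset_zero(self, site):
        sun = self._sun(site)
        track = make_track([0, 100], [3000, 0], [0, 0],
                           t0=sun.sunset_utc - dt.timedelta(seconds=100))
        arr, dep, arr_s, dep_s = roost_times(track, sun, site, MetricsConfig())
        assert arr == pytest.approx(0.0)
        assert arr_s is not None

    def test_entry_ninety_minutes_after_sunset_is_missing(self, site):
        sun = self._sun(site)
        track = make_track([0, 100], [3000, 0], [0, 0],
                           t0=sun.sunset_utc + dt.timedelta(minutes=90))
        arr, _, arr_s, _ = roost_times(track, sun, site, MetricsConfig())
        assert math.isnan(arr) and arr_s is None

    def test_roost_duration_is_exit_minus_entry(self, site):
        """Entry 19:00, exit 05:30 the next morning gives 10.5 hr."""
        sun1 = self._sun(site)
        sun2 = self._sun(site, dt.date(2019, 4, 16))
        entry = sun1.sunset_utc - dt.timedelta(minutes=10)
        exit_ = entry + dt.timedelta(hours=10.5)
        evening = make_track([0], [0], [0], t0=entry)
        morning = make_track([0, 60], [0, 400], [0, 0], t0=exit_)
        arr, _, arr_s, _ = roost_times(evening, sun1, site, MetricsConfig())
        _, dep, _, dep_s = roost_times(morning, sun2, site, MetricsConfig())
        assert arr_s is not None and dep_s is not None
        assert (dep_s - arr_s) / 3600.0 == pytest.approx(10.5)


class TestFlightSpeed:
    def test_stationary_is_zero(self):
        track = make_track([0, 8, 16], [5, 5, 5], [0, 0, 0])
        assert mean_flight_speed(track, []) == pytest.approx(0.0)

    def test_constant_speed_recovered(self):
        track = make_track(np.arange(5) * 10.0, np.arange(5) * 100.0, np.zeros(5))
        assert mean_flight_speed(track, []) == pytest.approx(10.0)


class TestInterindividualDistance:
    def _day(self, positions, site, n_fix=3):
        t0 = dt.datetime(2019, 4, 15, 8, 0, tzinfo=UTC)
        frames = [
            make_track(np.arange(n_fix) * 8.0, [x] * n_fix, [y] * n_fix,
                       tag_id=f"t{i}", t0=t0)
            for i, (x, y) in enumerate(positions)
        ]
        return pd.concat(frames, ignore_index=True)

    def test_identical_positions_give_zero(self, site):
        day = self._day([(100, 100)] * 4, site)
        assert interindividual_distance(day, site, MetricsConfig()) == pytest.approx(0.0)

    def test_unit_square_hand_computed(self, site):
        day = self._day([(0, 0), (100, 0), (100, 100), (0, 100)], site)
        expected = (4 * 100 + 2 * 100 * math.sqrt(2)) / 6
        assert interindividual_distance(day, site, MetricsConfig()) == pytest.approx(
            expected, abs=1e-6
        )
        assert expected == pytest.approx(113.807, abs=1e-3)

    def test_fewer_than_four_birds_is_missing(self, site):
        day = self._day([(0, 0), (100, 0), (50, 50)], site)
        assert math.isnan(interindividual_distance(day, site, MetricsConfig()))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        shift_x=st.floats(min_value=-1e4, max_value=1e4),
        shift_y=st.floats(min_value=-1e4, max_value=1e4),
        perm=st.permutations(range(4)),
    )
    def test_translation_and_label_invariance(self, shift_x, shift_y, perm):
        site = SiteConfig()
        pos = [(0, 0), (120, 40), (300, 250), (80, 400)]
        base = self._day(pos, site)
        moved = self._day(
            [(pos[i][0] + shift_x, pos[i][1] + shift_y) for i in perm], site
        )
        site_shifted = SiteConfig(colony_x_m=shift_x, colony_y_m=shift_y)
        a = interindividual_distance(base, site, MetricsConfig())
        b = interindividual_distance(moved, site_shifted, MetricsConfig())
        assert a == pytest.approx(b, rel=1e-9)


def test_route_at_least_twice_max_distance_on_out_and_back(clean_truth_cfg, site):
    """Triangle-inequality corollary on zero-noise central-place tracks."""
    from aeroforage.synthetic import generate_motr_days, generate_tracks

    motr = generate_motr_days(clean_truth_cfg)
    fixes, _ = generate_tracks(clean_truth_cfg, motr, site=site)
    metrics, _ = compute_daily_metrics(fixes, site)
    valid = metrics.dropna(subset=["daily_route_m"])
    assert len(valid) > 0
    assert (
        valid["daily_route_m"] >= 2 * valid["max_colony_distance_m"] - 1e-6
    ).all()
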