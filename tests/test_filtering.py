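"""Filter-chain unit and property tests, including the brute-force oracle."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroforage.config import FilterConfig, SiteConfig, TruthConfig
from aeroforage.filtering import (
    DuplicateTimestampError,
    _iterative_later_drop,
    filter_jump,
    filter_min_tags,
    filter_nbs,
    filter_speed,
    filter_stdloc,
    restrict_daylight,
    run_filter_chain,
    stdloc_fence,
    step_kinematics,
)
from aeroforage.solar import sun_times
from aeroforage.synthetic import generate_motr_days, generate_tracks

from conftest import make_track, naive_later_drop

UTC = dt.timezone.utc


class TestStepKinematics:
    def test_speed_arithmetic(self):
        track = make_track([0, 10], [0, 300], [0, 0])
        kin = step_kinematics(track)
        assert kin["speed_ms"].iloc[0] == pytest.approx(30.0)

    def test_single_fix_yields_no_steps(self):
        assert len(step_kinematics(make_track([0], [0], [0]))) == 0

    def test_consecutive_pair_definition_on_right_triangle(self):
        track = make_track([0, 10, 20], [0, 3, 3], [0, 0, 4])
        kin = step_kinematics(track)
        assert list(kin["distance_m"]) == pytest.approx([3.0, 4.0])

    def test_duplicate_timestamp_raises_with_tag_name(self):
        track = make_track([0, 0], [0, 10], [0, 0], tag_id="tagX")
        with pytest.raises(DuplicateTimestampError, match="tagX"):
            step_kinematics(track)


class TestSpeedFilter:
    def test_isolated_displaced_fix_removed(self):
        offsets = np.arange(0, 80, 8)
        xs = np.arange(0, 800, 80).astype(float)
        ys = np.zeros(10)
        xs[4] += 700.0  # ~90 m/s on the incoming step
        track = make_track(offsets, xs, ys)
        kept, removed = filter_speed(track, FilterConfig())
        assert list(removed) == [4]
        assert len(kept) == 9

    def test_exact_threshold_speed_retained(self):
        track = make_track([0, 10], [0, 300], [0, 0])
        _, removed = filter_speed(track, FilterConfig())
        assert len(removed) == 0


class TestStdlocFence:
    def test_constant_values_fence_equals_constant(self):
        assert stdloc_fence(np.full(8, 3.3)) == pytest.approx(3.3)

    def test_interpolated_quantiles_worked_example(self):
        assert stdloc_fence(np.arange(1.0, 9.0)) == pytest.approx(11.5)

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            stdloc_fence(np.array([1.0, 2.0, 3.0]))

    def test_filter_stdloc_partitions(self):
        track = make_track([0, 8, 16, 24], [0] * 4, [0] * 4,
                           stdloc=[2.0, 9.0, 4.0, 12.0])
        kept, removed = filter_stdloc(track, 8.0)
        assert list(kept["stdloc_m"]) == [2.0, 4.0]
        assert len(removed) == 2


class TestNbsFilter:
    def test_threshold_inclusive(self):
        track = make_track([0, 8, 16], [0] * 3, [0] * 3, nbs=[3, 4, 5])
        kept, removed = filter_nbs(track, FilterConfig())
        assert list(kept["nbs"]) == [4, 5]
        assert len(removed) == 1


class TestJumpFilter:
    def test_teleport_fix_removed(self):
        offsets = [0, 60, 120, 180, 240]
        xs = [0.0, 10.0, 620.0, 20.0, 30.0]
        track = make_track(offsets, xs, [0.0] * 5)
        kept, removed = filter_jump(track, FilterConfig())
        assert list(removed) == [2]

    def test_exact_500_m_step_retained(self):
        track = make_track([0, 60], [0, 500], [0, 0])
        _, removed = filter_jump(track, FilterConfig())
        assert len(removed) == 0

    def test_segment_mode_drops_whole_tag_day(self):
        offsets = [0, 60, 120]
        track = make_track(offsets, [0.0, 700.0, 710.0], [0.0] * 3)
        kept, removed = filter_jump(track, FilterConfig(jump_mode="segment"))
        assert len(kept) == 0 and len(removed) == 3


class TestDaylight:
    def test_noon_kept_pre_dawn_dropped_sunset_kept(self, site):
        date = dt.date(2019, 4, 15)
        stimes = sun_times(site.latitude, site.longitude, date)
        fixes = pd.concat(
            [
                make_track([0], [0], [0], t0=stimes.noon_utc),
                make_track([0], [0], [0], t0=stimes.sunrise_utc - dt.timedelta(hours=1)),
                make_track([0], [0], [0], t0=stimes.sunset_utc),
            ],
            ignore_index=True,
        )
        kept, removed = restrict_daylight(fixes, site)
        assert len(kept) == 2 and len(removed) == 1


class TestMinTags:
    def _day(self, n_tags, date=dt.date(2019, 4, 15)):
        t0 = dt.datetime(date.year, date.month, date.day, 8, 0, tzinfo=UTC)
        return pd.concat(
            [make_track([0, 8], [0, 10], [0, 0], tag_id=f"t{i}", t0=t0)
             for i in range(n_tags)],
            ignore_index=True,
        )

    def test_day_with_three_tags_dropped(self, site):
        kept, _, days = filter_min_tags(self._day(3), site, FilterConfig())
        assert len(kept) == 0 and len(days) == 1

    def test_day_with_four_tags_kept(self, site):
        kept, _, days = filter_min_tags(self._day(4), site, FilterConfig())
        assert len(kept) == 8 and days == []

    def test_empty_dataset(self, site):
        empty = self._day(1).iloc[:0]
        kept, _, days = filter_min_tags(empty, site, FilterConfig())
        assert len(kept) == 0 and days == []


@pytest.fixture(scope="module")
def noisy_world():
    cfg = TruthConfig(n_days=2, tags_per_day=5, seed=31, outlier_rate=0.05)
    motr = generate_motr_days(cfg)
    fixes, _ = generate_tracks(cfg, motr)
    return fixes


class TestChainProperties:
    def test_idempotence_with_frozen_fence(self, noisy_world):
        """Re-running the chain on its own output removes nothing.

        The StdLoc fence must be held at its first-pass value: a Tukey fence
        recomputed on already-fenced data always tightens, so only the fence
        is carried over; every other stage is intrinsically idempotent.
        """
        once, rep1 = run_filter_chain(noisy_world)
        twice, rep2 = run_filter_chain(once, stdloc_fence_m=rep1.stdloc_fence_m)
        assert len(twice) == len(once)
        assert sum(rep2.stage_removed.values()) == 0

    def test_monotonicity_in_thresholds(self, noisy_world):
        tight, _ = run_filter_chain(noisy_world, FilterConfig())
        loose, _ = run_filter_chain(
            noisy_world, FilterConfig(vmax_ms=60.0, max_step_m=1500.0)
        )
        assert len(loose) >= len(tight)

    def test_stage_counts_sum_to_total(self, noisy_world):
        retained, rep = run_filter_chain(noisy_world)
        assert rep.n_raw - sum(rep.stage_removed.values()) == len(retained)
        fracs = rep.stage_fractions
        assert sum(fracs.values()) + len(retained) / rep.n_raw == pytest.approx(1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n=st.integers(min_value=2, max_value=10),
    mode=st.sampled_from(["speed", "distance"]),
)
def test_iterative_later_drop_matches_bruteforce_oracle(data, n, mode):
    """Heap-based worst-pair removal equals the naive reference on short tracks."""
    xs = data.draw(st.lists(
        st.floats(min_value=-2000, max_value=2000), min_size=n, max_size=n))
    ys = data.draw(st.lists(
        st.floats(min_value=-2000, max_value=2000), min_size=n, max_size=n))
    t = np.arange(n, dtype=float) * 8.0
    limit = 30.0 if mode == "speed" else 500.0
    fast = _iterative_later_drop(t, np.array(xs), np.array(ys), limit, mode)
    slow = naive_later_drop(t, xs, ys, limit, mode)
    assert list(fast) == slow
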