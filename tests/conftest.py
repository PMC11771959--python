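"""Shared fixtures: a hand-built quality-defect track and small configs."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from aeroforage.config import FilterConfig, MetricsConfig, SiteConfig, TruthConfig

UTC = dt.timezone.utc


@pytest.fixture(scope="session")
def site() -> SiteConfig:
    return SiteConfig()


def make_track(
    offsets_s,
    xs,
    ys,
    stdloc=None,
    nbs=None,
    tag_id: str = "tagA",
    t0: dt.datetime = dt.datetime(2019, 4, 15, 7, 0, 0, tzinfo=UTC),
) -> pd.DataFrame:
    """Build a fix table from second offsets and planar coordinates."""
    n = len(offsets_s)
    return pd.DataFrame(
        {
            "tag_id": tag_id,
            "timestamp_utc": [t0 + dt.timedelta(seconds=float(s)) for s in offsets_s],
            "x_m": np.asarray(xs, dtype=float),
            "y_m": np.asarray(ys, dtype=float),
            "stdloc_m": np.asarray(stdloc if stdloc is not None else [5.0] * n, float),
            "nbs": np.asarray(nbs if nbs is not None else [7] * n, int),
        }
    )


@pytest.fixture()
def defect_track() -> tuple[pd.DataFrame, dict]:
    """Twelve fixes containing exactly one violation of each filter rule.

    index 3  -- displaced 400 m sideways between 10 s neighbors (speed rule)
    index 5  -- StdLoc 50 m against a ~5 m background (StdLoc fence)
    index 9  -- NBS 3 (base-station rule)
    index 8  -- displaced 660 m between 120 s gaps (jump rule, too slow for
                the speed rule)
    Boundary cases that must survive: step of exactly 30.0 m/s (fixes 0-1),
    step of exactly 500 m (fixes 6-7), NBS exactly 4 (fixes 6 and 10).
    """
    offsets = [0, 10, 20, 30, 40, 50, 60, 80, 200, 320, 330, 340]
    xs = [0, 300, 350, 410, 450, 500, 550, 550, 1210, 600, 650, 700]
    ys = [0, 0, 0, 400, 0, 0, 0, 500, 500, 500, 500, 500]
    stdloc = [5.0, 4.5, 5.2, 4.8, 5.5, 50.0, 4.2, 5.8, 5.1, 4.9, 5.3, 4.6]
    nbs = [7, 8, 6, 9, 5, 6, 4, 7, 6, 3, 4, 6]
    track = make_track(offsets, xs, ys, stdloc, nbs)
    expected = {"speed": [3], "stdloc": [5], "nbs": [9], "jump": [8]}
    return track, expected


@pytest.fixture(scope="session")
def clean_truth_cfg() -> TruthConfig:
    """Measurement-noise-free generator settings for exact recovery checks."""
    return TruthConfig(
        n_days=3,
        tags_per_day=4,
        seed=7,
        noise_sd_m=0.0,
        outlier_rate=0.0,
        stdloc_outlier_rate=0.0,
        stdloc_log_sd=0.0,
        nbs_low_rate=0.0,
    )


def naive_later_drop(t, x, y, limit, mode):
    """Reference implementation: repeatedly find the single worst offending
    consecutive pair and drop its later fix until the track is clean."""
    idx = list(range(len(t)))
    removed = []
    while True:
        worst, worst_v = None, limit
        for a, b in zip(idx, idx[1:]):
            d = math.hypot(x[b] - x[a], y[b] - y[a])
            v = d / (t[b] - t[a]) if mode == "speed" else d
            if v > worst_v:
                worst, worst_v = b, v
        if worst is None:
            return sorted(removed)
        idx.remove(worst)
        removed.append(worst)
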