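"""Fix-level quality filters for reverse-GPS tracking data.

The chain mirrors the study protocol: restrict to daylight, then remove
(1) steps implying flight speeds above a biological maximum, (2) fixes whose
localization standard error (StdLoc) lies above a Tukey fence pooled over the
whole dataset, (3) fixes received by too few base stations (NBS), (4) steps
with implausibly long displacements, and finally (5) whole days with too few
active tags.  Every stage's removals are accounted against the raw (daylight)
fix count, matching the attrition bookkeeping style of ATLAS studies.

Over-speed and over-jump removal is iterative: the *later* fix of the worst
offending consecutive pair is dropped and kinematics are recomputed until no
pair violates the threshold.  Gross localization errors appear as isolated
displaced fixes, for which this rule removes exactly the bad fix.
"""

from __future__ import annotations

import datetime as _dt
import heapq
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import FilterConfig, SiteConfig
from .solar import sun_times


class DuplicateTimestampError(ValueError):
    """Two fixes of one tag share a timestamp."""


def _seconds(ts: pd.Series) -> np.ndarray:
    return pd.to_datetime(ts, utc=True).astype("int64").to_numpy() / 1e9


def _check_ordered(tag: str, t: np.ndarray) -> None:
    if len(t) > 1:
        dup = np.flatnonzero(np.diff(t) == 0)
        if dup.size:
            when = _dt.datetime.fromtimestamp(t[dup[0]], _dt.timezone.utc)
            raise DuplicateTimestampError(
                f"tag {tag!r} has duplicate timestamp at {when.isoformat()}"
            )


def step_kinematics(track: pd.DataFrame) -> pd.DataFrame:
    """Per-step Euclidean distance (m), time delta (s) and speed (m/s).

    ``track`` holds the time-ordered fixes of a single tag; the result has
    one row per consecutive pair (n-1 rows).
    """
    t = _seconds(track["timestamp_utc"])
    tag = str(track["tag_id"].iloc[0]) if len(track) else ""
    _check_ordered(tag, t)
    if len(track) < 2:
        return pd.DataFrame(columns=["distance_m", "dt_s", "speed_ms"])
    dx = np.diff(track["x_m"].to_numpy())
    dy = np.diff(track["y_m"].to_numpy())
    dt = np.diff(t)
    dist = np.hypot(dx, dy)
    return pd.DataFrame({"distance_m": dist, "dt_s": dt, "speed_ms": dist / dt})


def _iterative_later_drop(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, limit: float, mode: str
) -> np.ndarray:
    """Indices removed by worst-pair-first later-fix dropping.

    mode 'speed' compares step speed (m/s), 'distance' compares step length
    (m) against ``limit`` (strict '>').  Implemented as a lazy max-heap over
    violating pairs with a doubly linked list of surviving fixes.
    """
    n = len(t)
    if n < 2:
        return np.empty(0, dtype=int)

    def value(i: int, j: int) -> float:
        d = float(np.hypot(x[j] - x[i], y[j] - y[i]))
        return d / (t[j] - t[i]) if mode == "speed" else d

    nxt = np.arange(1, n + 1)
    prv = np.arange(-1, n - 1)
    alive = np.ones(n, dtype=bool)
    heap: List[Tuple[float, int, int]] = []
    for i in range(n - 1):
        v = value(i, i + 1)
        if v > limit:
            heap.append((-v, i, i + 1))
    heapq.heapify(heap)

    removed: List[int] = []
    while heap:
        neg_v, i, j = heapq.heappop(heap)
        if not (alive[i] and alive[j] and nxt[i] == j):
            continue  # stale entry
        if -neg_v <= limit:
            continue
        alive[j] = False
        removed.append(j)
        k = nxt[j]
        nxt[i] = k
        if k < n:
            prv[k] = i
            v = value(i, k)
            if v > limit:
                heapq.heappush(heap, (-v, i, k))
    return np.array(sorted(removed), dtype=int)


def _per_tag_pair_filter(
    fixes: pd.DataFrame, limit: float, mode: str
) -> Tuple[pd.DataFrame, pd.Index]:
    removed_labels: List = []
    for tag, grp in fixes.groupby("tag_id", sort=False):
        t = _seconds(grp["timestamp_utc"])
        _check_ordered(str(tag), t)
        rem = _iterative_later_drop(
            t, grp["x_m"].to_numpy(), grp["y_m"].to_numpy(), limit, mode
        )
        removed_labels.extend(grp.index[rem])
    idx = pd.Index(removed_labels)
    return fixes.drop(index=idx), idx


def filter_speed(fixes: pd.DataFrame, cfg: FilterConfig) -> Tuple[pd.DataFrame, pd.Index]:
    """Remove fixes until no consecutive pair exceeds ``vmax_ms`` (strict >)."""
    return _per_tag_pair_filter(fixes, cfg.vmax_ms, "speed")


def stdloc_fence(stdloc: np.ndarray | pd.Series, iqr_k: float = 1.5,
                 method: str = "linear") -> float:
    """Upper Tukey fence Q3 + k*(Q3-Q1) of pooled StdLoc values."""
    vals = np.asarray(stdloc, dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 StdLoc values to compute a fence")
    q1, q3 = np.quantile(vals, [0.25, 0.75], method=method)
    return float(q3 + iqr_k * (q3 - q1))


def filter_stdloc(fixes: pd.DataFrame, fence: float) -> Tuple[pd.DataFrame, pd.Index]:
    """Keep fixes with StdLoc <= fence."""
    bad = fixes.index[fixes["stdloc_m"] > fence]
    return fixes.drop(index=bad), bad


def filter_nbs(fixes: pd.DataFrame, cfg: FilterConfig) -> Tuple[pd.DataFrame, pd.Index]:
    """Keep fixes received by at least ``min_nbs`` base stations (>=, inclusive)."""
    bad = fixes.index[fixes["nbs"] < cfg.min_nbs]
    return fixes.drop(index=bad), bad


def filter_jump(fixes: pd.DataFrame, cfg: FilterConfig) -> Tuple[pd.DataFrame, pd.Index]:
    """Remove fixes involved in consecutive displacements > ``max_step_m``.

    jump_mode 'fix' iteratively drops the later fix of the worst pair;
    'segment' drops every fix of any tag-day containing a violation (the
    literal whole-track reading).
    """
    if cfg.jump_mode == "fix":
        return _per_tag_pair_filter(fixes, cfg.max_step_m, "distance")
    removed: List = []
    t_all = _seconds(fixes["timestamp_utc"])
    day = pd.to_datetime(fixes["timestamp_utc"], utc=True).dt.date
    for (tag, d), grp in fixes.groupby(["tag_id", day], sort=False):
        kin = step_kinematics(grp)
        if len(kin) and (kin["distance_m"] > cfg.max_step_m).any():
            removed.extend(grp.index)
    idx = pd.Index(removed)
    return fixes.drop(index=idx), idx


def restrict_daylight(
    fixes: pd.DataFrame, site: SiteConfig
) -> Tuple[pd.DataFrame, pd.Index]:
    """Keep fixes with sunrise <= t <= sunset on the fix's local day (closed)."""
    ts = pd.to_datetime(fixes["timestamp_utc"], utc=True)
    local_date = (ts + pd.Timedelta(hours=site.utc_offset_hours)).dt.date
    keep = np.zeros(len(fixes), dtype=bool)
    for d in pd.unique(local_date):
        st = sun_times(site.latitude, site.longitude, d)
        m = (local_date == d).to_numpy()
        keep[m] = (ts[m] >= st.sunrise_utc) & (ts[m] <= st.sunset_utc)
    bad = fixes.index[~keep]
    return fixes.drop(index=bad), bad


def local_dates(fixes: pd.DataFrame, site: SiteConfig) -> pd.Series:
    ts = pd.to_datetime(fixes["timestamp_utc"], utc=True)
    return (ts + pd.Timedelta(hours=site.utc_offset_hours)).dt.date


def filter_min_tags(
    fixes: pd.DataFrame, site: SiteConfig, cfg: FilterConfig
) -> Tuple[pd.DataFrame, pd.Index, List[_dt.date]]:
    """Drop whole days with fewer than ``min_tags_per_day`` active tags.

    A tag is active on a day when it has at least one retained fix that day.
    """
    if len(fixes) == 0:
        return fixes, pd.Index([]), []
    dates = local_dates(fixes, site)
    tags_per_day = fixes.groupby(dates)["tag_id"].nunique()
    dropped_days = sorted(tags_per_day.index[tags_per_day < cfg.min_tags_per_day])
    bad = fixes.index[dates.isin(dropped_days)]
    return fixes.drop(index=bad), bad, list(dropped_days)


@dataclass
class AttritionReport:
    """Per-stage removal accounting, as fractions of the raw daylight count."""

    n_raw: int
    daylight_removed: int
    stage_removed: Dict[str, int] = field(default_factory=dict)
    dropped_days: List[_dt.date] = field(default_factory=list)
    stdloc_fence_m: float = float("nan")
    retained_per_tag_day: Optional[pd.DataFrame] = None

    @property
    def stage_fractions(self) -> Dict[str, float]:
        if self.n_raw == 0:
            return {k: 0.0 for k in self.stage_removed}
        return {k: v / self.n_raw for k, v in self.stage_removed.items()}

    @property
    def filter_total_fraction(self) -> float:
        """Fraction removed by the four fix-quality filters (not the day rule)."""
        keys = ("speed", "stdloc", "nbs", "jump")
        return sum(self.stage_fractions.get(k, 0.0) for k in keys)

    @property
    def total_removed_fraction(self) -> float:
        return sum(self.stage_fractions.values())

    @property
    def n_retained(self) -> int:
        return self.n_raw - sum(self.stage_removed.values())

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "daylight_removed": self.daylight_removed,
            "stage_removed": dict(self.stage_removed),
            "stage_fractions": self.stage_fractions,
            "filter_total_fraction": self.filter_total_fraction,
            "total_removed_fraction": self.total_removed_fraction,
            "n_retained": self.n_retained,
            "stdloc_fence_m": self.stdloc_fence_m,
            "dropped_days": [d.isoformat() for d in self.dropped_days],
        }


def run_filter_chain(
    fixes: pd.DataFrame,
    cfg: Optional[FilterConfig] = None,
    site: Optional[SiteConfig] = None,
    stdloc_fence_m: Optional[float] = None,
) -> Tuple[pd.DataFrame, AttritionReport]:
    """Daylight restriction followed by speed, StdLoc, NBS, jump and day rules.

    Stage fractions are reported against the raw count *after* the daylight
    restriction, which defines the analyzable dataset.  The StdLoc fence is
    computed once, pooled over all post-speed-filter fixes; pass
    ``stdloc_fence_m`` to reuse a previously computed fence (a fence
    recomputed on already-fenced data always tightens, so reruns on a chain's
    own output are only no-ops with the fence held fixed).
    """
    cfg = cfg or FilterConfig()
    site = site or SiteConfig()
    fixes = fixes.sort_values(["tag_id", "timestamp_utc"], kind="stable")

    day_fixes, dropped_night = restrict_daylight(fixes, site)
    n_raw = len(day_fixes)
    report = AttritionReport(n_raw=n_raw, daylight_removed=len(dropped_night))

    after_speed, rem_speed = filter_speed(day_fixes, cfg)
    report.stage_removed["speed"] = len(rem_speed)

    if stdloc_fence_m is not None:
        fence = stdloc_fence_m
    elif len(after_speed) >= 4:
        fence = stdloc_fence(after_speed["stdloc_m"], cfg.iqr_k, cfg.quantile_method)
    else:
        fence = float("inf")
    report.stdloc_fence_m = fence
    after_stdloc, rem_stdloc = filter_stdloc(after_speed, fence)
    report.stage_removed["stdloc"] = len(rem_stdloc)

    after_nbs, rem_nbs = filter_nbs(after_stdloc, cfg)
    report.stage_removed["nbs"] = len(rem_nbs)

    after_jump, rem_jump = filter_jump(after_nbs, cfg)
    report.stage_removed["jump"] = len(rem_jump)

    retained, rem_days, dropped_days = filter_min_tags(after_jump, site, cfg)
    report.stage_removed["min_tags"] = len(rem_days)
    report.dropped_days = dropped_days

    if len(retained):
        dates_series = local_dates(retained, site).rename("date")
        counts = retained.groupby([dates_series, "tag_id"]).size()
        report.retained_per_tag_day = counts.rename("n_fixes").reset_index()
    return retained, report
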