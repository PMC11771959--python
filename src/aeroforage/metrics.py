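"""Per-day behavioral metrics of central-place foraging from filtered fixes.

The colony building blocks tag reception, so a colony *visit* is observed as
a reception gap bounded on both sides by fixes close to the colony.  All
other quantities (distances, route, durations, timings, inter-individual
distance) derive from the filtered fix table plus sunrise/sunset times.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .config import MetricsConfig, SiteConfig
from .solar import SunTimes, sun_times

_EPOCH = _dt.datetime(1970, 1, 1, tzinfo=_dt.timezone.utc)


@dataclass(frozen=True)
class VisitEvent:
    """One colony visit: a reception gap with near-colony bounding fixes."""

    tag_id: str
    entry: _dt.datetime   # last fix before the gap
    exit: _dt.datetime    # first fix after the gap

    @property
    def duration_s(self) -> float:
        return (self.exit - self.entry).total_seconds()


def _to_seconds(ts) -> np.ndarray:
    if isinstance(ts, pd.Series) and pd.api.types.is_datetime64_any_dtype(ts):
        return ts.astype("int64").to_numpy() / 1e9
    return pd.to_datetime(ts, utc=True).astype("int64").to_numpy() / 1e9


def colony_distances(x: np.ndarray, y: np.ndarray, site: SiteConfig) -> np.ndarray:
    return np.hypot(x - site.colony_x_m, y - site.colony_y_m)


def colony_distance_stats(
    day_fixes: pd.DataFrame, site: SiteConfig
) -> Tuple[float, float]:
    """(mean, max) distance to the colony over all fixes of all tags that day."""
    d = colony_distances(day_fixes["x_m"].to_numpy(), day_fixes["y_m"].to_numpy(), site)
    if d.size == 0:
        return float("nan"), float("nan")
    return float(d.mean()), float(d.max())


def detect_visits(
    track: pd.DataFrame,
    site: SiteConfig,
    colony_radius_m: float = 100.0,
    visit_min_s: float = 60.0,
) -> List[VisitEvent]:
    """Visits of one tag: reception gaps >= ``visit_min_s`` (inclusive) whose
    bounding fixes both lie within ``colony_radius_m`` of the colony."""
    if len(track) < 2:
        return []
    t = _to_seconds(track["timestamp_utc"])
    d = colony_distances(track["x_m"].to_numpy(), track["y_m"].to_numpy(), site)
    gaps = np.diff(t)
    tag = str(track["tag_id"].iloc[0])
    idx = np.flatnonzero(
        (gaps >= visit_min_s) & (d[:-1] <= colony_radius_m) & (d[1:] <= colony_radius_m)
    )
    return [
        VisitEvent(
            tag_id=tag,
            entry=_EPOCH + _dt.timedelta(seconds=float(t[i])),
            exit=_EPOCH + _dt.timedelta(seconds=float(t[i + 1])),
        )
        for i in idx
    ]


def _visit_step_mask(t: np.ndarray, visits: List[VisitEvent]) -> np.ndarray:
    """Boolean mask over steps (len n-1): True where the step is a visit gap."""
    mask = np.zeros(len(t) - 1, dtype=bool)
    entries = {round((v.entry - _EPOCH).total_seconds(), 6) for v in visits}
    for i in range(len(t) - 1):
        if round(float(t[i]), 6) in entries:
            mask[i] = True
    return mask


def daily_route(
    track: pd.DataFrame,
    visits: List[VisitEvent],
    cfg: MetricsConfig,
) -> float:
    """Total path length (m) of one tag-day, or NaN when coverage is too poor.

    Coverage requires a fix span of at least ``route_min_hours`` with no
    non-visit reception gap longer than ``gap_tolerance_s``.
    """
    if len(track) < 2:
        return float("nan")
    t = _to_seconds(track["timestamp_utc"])
    span_hr = (t[-1] - t[0]) / 3600.0
    gaps = np.diff(t)
    vmask = _visit_step_mask(t, visits)
    if span_hr < cfg.route_min_hours or np.any(gaps[~vmask] > cfg.gap_tolerance_s):
        return float("nan")
    dx = np.diff(track["x_m"].to_numpy())
    dy = np.diff(track["y_m"].to_numpy())
    step = np.hypot(dx, dy)
    return float(step[~vmask].sum())


def mean_flight_speed(track: pd.DataFrame, visits: List[VisitEvent]) -> float:
    """Mean step speed (m/s) of one tag-day over non-visit steps."""
    if len(track) < 2:
        return float("nan")
    t = _to_seconds(track["timestamp_utc"])
    dx = np.diff(track["x_m"].to_numpy())
    dy = np.diff(track["y_m"].to_numpy())
    speed = np.hypot(dx, dy) / np.diff(t)
    keep = ~_visit_step_mask(t, visits)
    if not keep.any():
        return float("nan")
    return float(speed[keep].mean())


def foraging_durations(
    track: pd.DataFrame,
    visits: List[VisitEvent],
    sun: SunTimes,
    cfg: MetricsConfig,
) -> Tuple[float, float]:
    """(foraging_hr, net_foraging_hr) of one tag-day.

    Foraging duration is the activity span (first to last fix) minus time
    spent inside the colony; net foraging duration is day length minus
    foraging duration (the day-length-standardized identity).
    """
    if len(track) == 0:
        return float("nan"), float("nan")
    t = _to_seconds(track["timestamp_utc"])
    span_hr = (t[-1] - t[0]) / 3600.0
    visit_hr = sum(v.duration_s for v in visits) / 3600.0
    foraging = span_hr - visit_hr if cfg.exclude_visit_time else span_hr
    return foraging, sun.day_length_hours - foraging


def visit_frequency(
    per_tag_counts: Dict[str, int], per_tag_span_hr: Dict[str, float]
) -> float:
    """Visits per tag per hour: per-tag rate averaged over active tags."""
    rates = [
        per_tag_counts.get(tag, 0) / span
        for tag, span in per_tag_span_hr.items()
        if span > 0
    ]
    return float(np.mean(rates)) if rates else float("nan")


def roost_times(
    track: pd.DataFrame,
    sun: SunTimes,
    site: SiteConfig,
    cfg: MetricsConfig,
) -> Tuple[float, float, Optional[float], Optional[float]]:
    """(arrival_offset_min, departure_offset_min, arrival_s, departure_s).

    Evening arrival is the last fix of the tag-day when it lies within the
    colony radius and within the window around sunset; morning departure is
    the first fix, within the colony radius and window around sunrise.
    Non-qualifying events yield NaN offsets (omitted, not errors).
    """
    if len(track) == 0:
        return float("nan"), float("nan"), None, None
    t = _to_seconds(track["timestamp_utc"])
    d = colony_distances(track["x_m"].to_numpy(), track["y_m"].to_numpy(), site)
    sr = (sun.sunrise_utc - _EPOCH).total_seconds()
    ss = (sun.sunset_utc - _EPOCH).total_seconds()
    win = cfg.roost_window_min * 60.0

    arrival = float("nan")
    arrival_s: Optional[float] = None
    if d[-1] <= cfg.colony_radius_m and abs(t[-1] - ss) <= win:
        arrival = (t[-1] - ss) / 60.0
        arrival_s = float(t[-1])
    departure = float("nan")
    departure_s: Optional[float] = None
    if d[0] <= cfg.colony_radius_m and abs(t[0] - sr) <= win:
        departure = (t[0] - sr) / 60.0
        departure_s = float(t[0])
    return arrival, departure, arrival_s, departure_s


def interindividual_distance(
    day_fixes: pd.DataFrame,
    site: SiteConfig,
    cfg: MetricsConfig,
) -> float:
    """Daily mean pairwise distance (m) between simultaneously tracked birds.

    Positions are averaged per bird in clock-aligned bins (default 5 min,
    local time); bins with fewer than ``min_birds_per_bin`` birds are
    dropped; the daily value is the mean over retained bins of the mean
    pairwise Euclidean distance.  NaN when no bin qualifies.
    """
    if len(day_fixes) == 0:
        return float("nan")
    t = _to_seconds(day_fixes["timestamp_utc"]) + site.utc_offset_hours * 3600.0
    bins = np.floor(t / cfg.bin_s).astype(np.int64)
    df = pd.DataFrame(
        {
            "bin": bins,
            "tag": day_fixes["tag_id"].to_numpy(),
            "x": day_fixes["x_m"].to_numpy(),
            "y": day_fixes["y_m"].to_numpy(),
        }
    )
    mean_pos = df.groupby(["bin", "tag"], sort=True)[["x", "y"]].mean()
    bin_ids = mean_pos.index.get_level_values("bin").to_numpy()
    xy = mean_pos.to_numpy()
    _, starts, counts = np.unique(bin_ids, return_index=True, return_counts=True)
    per_bin: List[float] = []
    for s, c in zip(starts, counts):
        if c < cfg.min_birds_per_bin:
            continue
        per_bin.append(float(pdist(xy[s: s + c]).mean()))
    return float(np.mean(per_bin)) if per_bin else float("nan")


def compute_daily_metrics(
    fixes: pd.DataFrame,
    site: Optional[SiteConfig] = None,
    cfg: Optional[MetricsConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """All per-day metrics plus the per-visit table.

    Returns (metrics, visits): one metrics row per local day, one visits row
    per detected colony visit.  Day-level values are unweighted means over
    the qualifying tags of that day.  Roost duration on day *d* pairs the
    evening arrival of day *d* with the morning departure of day *d+1*.
    """
    site = site or SiteConfig()
    cfg = cfg or MetricsConfig()
    fixes = fixes.sort_values(["tag_id", "timestamp_utc"], kind="stable")
    ts = pd.to_datetime(fixes["timestamp_utc"], utc=True)
    dates = (ts + pd.Timedelta(hours=site.utc_offset_hours)).dt.date

    sun_cache: Dict[_dt.date, SunTimes] = {}
    visit_rows: List[dict] = []
    rows: List[dict] = []
    arrival_epochs: Dict[Tuple[_dt.date, str], float] = {}
    departure_epochs: Dict[Tuple[_dt.date, str], float] = {}
    day_tag_values: Dict[_dt.date, dict] = {}

    for date, day_fixes in fixes.groupby(dates, sort=True):
        sun = sun_cache.setdefault(date, sun_times(site.latitude, site.longitude, date))
        mean_d, max_d = colony_distance_stats(day_fixes, site)
        per_tag = {
            "routes": [], "speeds": [], "foraging": [], "net": [],
            "arrivals": [], "departures": [],
            "visit_counts": {}, "spans": {},
        }
        for tag, track in day_fixes.groupby("tag_id", sort=True):
            visits = detect_visits(track, site, cfg.colony_radius_m, cfg.visit_min_s)
            for v in visits:
                visit_rows.append(
                    {
                        "date": date, "tag_id": v.tag_id,
                        "entry_utc": v.entry, "exit_utc": v.exit,
                        "duration_s": v.duration_s,
                    }
                )
            t = _to_seconds(track["timestamp_utc"])
            if len(t) >= 2:
                per_tag["spans"][tag] = (t[-1] - t[0]) / 3600.0
                per_tag["visit_counts"][tag] = len(visits)
            per_tag["routes"].append(daily_route(track, visits, cfg))
            per_tag["speeds"].append(mean_flight_speed(track, visits))
            for_hr, net_hr = foraging_durations(track, visits, sun, cfg)
            per_tag["foraging"].append(for_hr)
            per_tag["net"].append(net_hr)
            arr, dep, arr_s, dep_s = roost_times(track, sun, site, cfg)
            per_tag["arrivals"].append(arr)
            per_tag["departures"].append(dep)
            if arr_s is not None:
                arrival_epochs[(date, tag)] = arr_s
            if dep_s is not None:
                departure_epochs[(date, tag)] = dep_s
        day_tag_values[date] = per_tag

        def _nanmean(vals: List[float]) -> float:
            arr = np.asarray(vals, dtype=float)
            return float(np.nanmean(arr)) if np.isfinite(arr).any() else float("nan")

        rows.append(
            {
                "date": date,
                "n_active_tags": day_fixes["tag_id"].nunique(),
                "mean_colony_distance_m": mean_d,
                "max_colony_distance_m": max_d,
                "daily_route_m": _nanmean(per_tag["routes"]),
                "foraging_hr": _nanmean(per_tag["foraging"]),
                "net_foraging_hr": _nanmean(per_tag["net"]),
                "visit_freq_per_tag_hr": visit_frequency(
                    per_tag["visit_counts"], per_tag["spans"]
                ),
                "mean_flight_speed_ms": _nanmean(per_tag["speeds"]),
                "arrival_offset_min": _nanmean(per_tag["arrivals"]),
                "departure_offset_min": _nanmean(per_tag["departures"]),
                "interindividual_distance_m": interindividual_distance(
                    day_fixes, site, cfg
                ),
                "day_length_hr": sun.day_length_hours,
            }
        )

    metrics = pd.DataFrame(rows)
    # roost duration: evening arrival on day d to morning departure on day d+1
    roost_col = []
    for row in rows:
        d = row["date"]
        nxt = d + _dt.timedelta(days=1)
        durs = [
            (departure_epochs[(nxt, tag)] - arr_s) / 3600.0
            for (dd, tag), arr_s in arrival_epochs.items()
            if dd == d and (nxt, tag) in departure_epochs
        ]
        roost_col.append(float(np.mean(durs)) if durs else float("nan"))
    metrics["roost_duration_hr"] = roost_col

    visits_df = pd.DataFrame(
        visit_rows,
        columns=["date", "tag_id", "entry_utc", "exit_utc", "duration_s"],
    )
    return metrics, visits_df
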