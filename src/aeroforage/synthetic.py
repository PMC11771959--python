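"""Synthetic reverse-GPS tracks and radar echo streams with known ground truth.

The generator produces the three inputs the analysis consumes — a fix table,
an echo table and a truth record — with the statistical structure the study
design assumes:

* daily insect movement traffic rate (MoTR) drawn from a gamma distribution
  truncated to the observed range and moment-calibrated so the *emitted*
  values have the configured mean/SD;
* per tag and day, an out-and-back central-place foraging schedule whose trip
  apogee (log scale), colony-visit rate, heading concentration and evening
  arrival offset are linear in MoTR with configurable coefficients;
* colony visits represented as reception gaps (no fixes emitted while the
  bird is inside the building), bounded by at-colony fixes;
* Gaussian localization noise, gross outlier fixes displaced by hundreds of
  meters, heavy-tailed localization standard errors and base-station counts
  with a configurable sub-threshold fraction;
* a Poisson echo stream in a vertical conical beam whose expected hourly MoTR
  (under the transect normalization of :mod:`aeroforage.radar`) equals the
  day's true MoTR.

Everything is driven by a single :class:`~aeroforage.config.TruthConfig` and
a seed; identical configurations give byte-identical tables.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import BeamConfig, ConfigurationError, SiteConfig, TruthConfig
from .radar import mean_inverse_width
from .solar import sun_times

FIX_COLUMNS = ["tag_id", "timestamp_utc", "x_m", "y_m", "stdloc_m", "nbs"]
ECHO_COLUMNS = ["timestamp_utc", "altitude_m", "rcs_mm2", "class"]


# ---------------------------------------------------------------------------
# ground truth record
# ---------------------------------------------------------------------------

@dataclass
class TagDayTruth:
    """True schedule of one tag on one day (all times UTC)."""

    apogees_m: List[float]
    visits: List[Tuple[_dt.datetime, _dt.datetime]]
    departure_offset_min: float     # first fix minus sunrise
    arrival_offset_min: float       # last fix minus sunset (negative = before)
    route_m: float                  # 2 * sum(apogees)
    foraging_hr: float              # activity span minus time inside colony
    n_fixes: int

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class TruthRecord:
    """Everything the generator knows and the pipeline should recover."""

    motr: Dict[_dt.date, float] = field(default_factory=dict)
    tags: Dict[Tuple[_dt.date, str], TagDayTruth] = field(default_factory=dict)
    outlier_rows: List[int] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "motr": {d.isoformat(): v for d, v in self.motr.items()},
            "tags": {
                f"{d.isoformat()}|{tag}": {
                    "apogees_m": t.apogees_m,
                    "visits": [[a.isoformat(), b.isoformat()] for a, b in t.visits],
                    "departure_offset_min": t.departure_offset_min,
                    "arrival_offset_min": t.arrival_offset_min,
                    "route_m": t.route_m,
                    "foraging_hr": t.foraging_hr,
                    "n_fixes": t.n_fixes,
                }
                for (d, tag), t in self.tags.items()
            },
            "outlier_rows": self.outlier_rows,
        }


# ---------------------------------------------------------------------------
# daily MoTR
# ---------------------------------------------------------------------------

def _truncated_gamma_base(mean: float, sd: float, lo: float, hi: float) -> Tuple[float, float]:
    """Base gamma (shape, scale) whose [lo, hi]-truncation has the given mean/SD.

    Uses the closed-form truncated gamma moments
    E[X^m | lo<X<hi] proportional to F_{shape+m}(hi/scale) - F_{shape+m}(lo/scale)
    and solves the two-moment system.
    """

    def trunc_mean_sd(log_params: np.ndarray) -> np.ndarray:
        m0, s0 = np.exp(log_params)
        shape = (m0 / s0) ** 2
        scale = s0 * s0 / m0
        cdf = stats.gamma.cdf
        z = cdf(hi / scale, shape) - cdf(lo / scale, shape)
        if z <= 0:
            return np.array([np.inf, np.inf])
        m1 = shape * scale * (cdf(hi / scale, shape + 1) - cdf(lo / scale, shape + 1)) / z
        m2 = (
            scale**2 * shape * (shape + 1)
            * (cdf(hi / scale, shape + 2) - cdf(lo / scale, shape + 2)) / z
        )
        return np.array([m1, math.sqrt(max(m2 - m1 * m1, 1e-12))])

    target = np.array([mean, sd])
    sol = optimize.root(
        lambda p: trunc_mean_sd(p) - target, x0=np.log(target), method="hybr"
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise ConfigurationError(
            f"cannot calibrate truncated gamma for mean={mean}, sd={sd}, range=({lo}, {hi})"
        )
    m0, s0 = np.exp(sol.x)
    return (m0 / s0) ** 2, s0 * s0 / m0


def generate_motr_days(cfg: TruthConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw one true daily MoTR value per day.

    Values come from a gamma distribution rejection-truncated to
    ``cfg.motr_range``; the base parameters are calibrated so the truncated
    draws have mean ``cfg.motr_mean`` and SD ``cfg.motr_sd``.
    """
    lo, hi = cfg.motr_range
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.motr_sd == 0.0:
        return np.full(cfg.n_days, float(cfg.motr_mean))
    shape, scale = _truncated_gamma_base(cfg.motr_mean, cfg.motr_sd, lo, hi)
    out = np.empty(0)
    while out.size < cfg.n_days:
        draw = rng.gamma(shape, scale, size=max(4 * cfg.n_days, 64))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[: cfg.n_days]


# ---------------------------------------------------------------------------
# tag-day trajectory
# ---------------------------------------------------------------------------

def _simulate_tag_day(
    rng: np.random.Generator,
    cfg: TruthConfig,
    motr: float,
    sunrise_s: float,
    sunset_s: float,
    day_heading: float,
    day_log_effect: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """One tag-day: fix times (s, UTC epoch), noise-free x/y, and truth info.

    The day is a sequence of straight out-and-back foraging trips at constant
    cruise speed, interleaved with colony visits that emit no fixes.  All
    event times fall on the fix-interval grid so that zero-noise runs are
    exactly recoverable.
    """
    dt = cfg.fix_interval_s
    v = cfg.flight_speed_ms

    dep_min = float(np.clip(rng.normal(cfg.departure_mean_min, cfg.departure_sd_min), 0.0, 55.0))
    arr_min = float(
        np.clip(
            cfg.arrival_center_min
            + cfg.beta_arrival * (motr - cfg.motr_mean)
            + rng.normal(0.0, cfg.arrival_sd_min),
            -55.0,
            -2.0,
        )
    )
    t0 = round(sunrise_s + dep_min * 60.0)  # whole-second grid origin
    t_end = sunset_s + arr_min * 60.0
    total = t_end - t0
    if total < 3600.0:  # degenerate dusk/dawn geometry; should not happen at 33N
        total = 3600.0

    # colony visits: count and grid-aligned durations
    rate_hr = max(cfg.visit_rate_floor_hr, cfg.visit_rate_base_hr + cfg.beta_visits * motr)
    k = int(rng.poisson(rate_hr * total / 3600.0))
    durs = dt * np.ceil(rng.uniform(cfg.visit_min_s, cfg.visit_max_s, size=k) / dt)
    durs = np.maximum(durs, dt * math.ceil(max(cfg.visit_min_s, 60.0) / dt))
    if k and durs.sum() > 0.5 * total:
        k = int(0.5 * total // durs.mean())
        durs = durs[:k]
    flight_budget = total - durs.sum()

    # trips: apogee log-median linear in MoTR; durations quantized to the grid
    heading_sd = max(cfg.heading_sd_min, cfg.heading_sd_base + cfg.beta_heading_sd * motr)
    log_med = math.log(cfg.apogee_median_m) + cfg.beta_distance * motr + day_log_effect
    n_out: List[int] = []
    used = 0.0
    while True:
        d = math.exp(rng.normal(log_med, cfg.apogee_log_sd))
        steps = max(1, round(d / (v * dt)))
        trip_t = 2 * steps * dt
        if used + trip_t > flight_budget:
            break
        n_out.append(steps)
        used += trip_t
    filler = int((flight_budget - used) // (2 * dt))
    if filler >= 1:
        n_out.append(filler)
    if not n_out:
        n_out = [max(1, int(flight_budget // (2 * dt)))]
    m = len(n_out)

    # place the k visits at distinct trip boundaries (m trips -> m-1 slots)
    k = min(k, m - 1)
    durs = durs[:k]
    slots = rng.choice(m - 1, size=k, replace=False) if k else np.array([], dtype=int)
    gap_after = np.zeros(m, dtype=float)
    gap_after[np.sort(slots)] = durs  # visit follows these trips

    times: List[np.ndarray] = []
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    visits: List[Tuple[float, float]] = []
    apogees: List[float] = []
    t_cursor = t0
    contiguous = False  # previous segment ended with a fix at t_cursor
    for j, steps in enumerate(n_out):
        theta = day_heading + rng.normal(0.0, heading_sd)
        i = np.arange(0, 2 * steps + 1)
        r = v * dt * np.minimum(i, 2 * steps - i)
        tt = t_cursor + i * dt
        if contiguous:
            # drop duplicate colony fix shared with the previous trip's end;
            # after a visit gap the start fix is the visit's exit fix and stays
            i, r, tt = i[1:], r[1:], tt[1:]
        times.append(tt)
        xs.append(r * math.cos(theta))
        ys.append(r * math.sin(theta))
        apogees.append(v * dt * steps)
        t_cursor += 2 * steps * dt
        contiguous = True
        if gap_after[j] > 0:
            visits.append((t_cursor, t_cursor + gap_after[j]))
            t_cursor += gap_after[j]
            contiguous = False

    t_arr = np.concatenate(times)
    x_arr = np.concatenate(xs)
    y_arr = np.concatenate(ys)

    truth = {
        "apogees": apogees,
        "visits": visits,
        "departure_offset_min": (t_arr[0] - sunrise_s) / 60.0,
        "arrival_offset_min": (t_arr[-1] - sunset_s) / 60.0,
        "route_m": 2.0 * float(np.sum(apogees)),
        "foraging_hr": ((t_arr[-1] - t_arr[0]) - float(np.sum(durs))) / 3600.0,
    }
    return t_arr, x_arr, y_arr, truth


def _pick_isolated(
    rng: np.random.Generator,
    eligible: np.ndarray,
    count: int,
    taken: np.ndarray,
    halfwidth: int,
) -> np.ndarray:
    """Greedily pick ``count`` indices from ``eligible`` such that no pick has
    another marked index within ``halfwidth``; marks picks in ``taken``."""
    chosen: List[int] = []
    if count <= 0 or eligible.size == 0:
        return np.empty(0, dtype=int)
    n = len(taken)
    for idx in rng.permutation(eligible):
        lo, hi = max(idx - halfwidth, 0), min(idx + halfwidth + 1, n)
        if taken[lo:hi].any():
            continue
        chosen.append(int(idx))
        taken[idx] = True
        if len(chosen) >= count:
            break
    return np.array(sorted(chosen), dtype=int)


def _inject_outliers(
    rng: np.random.Generator,
    cfg: TruthConfig,
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    taken: np.ndarray,
) -> np.ndarray:
    """Displace isolated interior fixes; returns local indices of outliers.

    Each outlier is displaced by 0.7-2.5 km in a direction within 60 degrees
    of the local track direction, which guarantees (i) the step *into* the
    outlier is longer than the step out of it, so iterative later-fix removal
    drops exactly the outlier, and (ii) both the speed and jump rules fire on
    the incoming step.
    """
    n = len(t)
    if n < 5 or cfg.outlier_rate == 0.0:
        return np.empty(0, dtype=int)
    dt = cfg.fix_interval_s
    interior = np.arange(2, n - 2)
    on_grid = (
        np.isclose(t[interior] - t[interior - 1], dt)
        & np.isclose(t[interior + 1] - t[interior], dt)
    )
    eligible = interior[on_grid]
    chosen_a = _pick_isolated(rng, eligible, round(cfg.outlier_rate * n), taken, 2)
    if chosen_a.size == 0:
        return chosen_a
    disp = rng.uniform(*cfg.outlier_disp_range_m, size=chosen_a.size)
    track_dir = np.arctan2(y[chosen_a + 1] - y[chosen_a - 1], x[chosen_a + 1] - x[chosen_a - 1])
    ang = track_dir + rng.uniform(-math.pi / 3, math.pi / 3, size=chosen_a.size)
    x[chosen_a] = x[chosen_a - 1] + disp * np.cos(ang)
    y[chosen_a] = y[chosen_a - 1] + disp * np.sin(ang)
    return chosen_a


def generate_tracks(
    cfg: TruthConfig,
    motr_days: np.ndarray,
    site: Optional[SiteConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """Generate the multi-day multi-tag fix table and its truth record."""
    site = site or SiteConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if len(motr_days) != cfg.n_days:
        raise ConfigurationError("motr_days length must equal cfg.n_days")

    frames: List[pd.DataFrame] = []
    truth = TruthRecord()
    row_offset = 0
    epoch = _dt.datetime(1970, 1, 1, tzinfo=_dt.timezone.utc)

    for d in range(cfg.n_days):
        date = cfg.start_date + _dt.timedelta(days=d)
        st = sun_times(site.latitude, site.longitude, date)
        sr = (st.sunrise_utc - epoch).total_seconds()
        ss = (st.sunset_utc - epoch).total_seconds()
        motr = float(motr_days[d])
        truth.motr[date] = motr
        day_heading = rng.uniform(0.0, 2.0 * math.pi)
        day_log_effect = rng.normal(0.0, cfg.apogee_day_log_sd)
        for tag_i in range(cfg.tags_per_day):
            tag = f"tag{tag_i:02d}"
            t, x, y, info = _simulate_tag_day(
                rng, cfg, motr, sr, ss, day_heading, day_log_effect
            )
            n = len(t)
            # all injected defects are isolated single-fix dropouts, so the
            # removal of one never opens a > max_step hole for the jump rule
            taken = np.zeros(n, dtype=bool)
            out_idx = _inject_outliers(rng, cfg, t, x, y, taken)
            every = np.arange(n)
            bad_std = _pick_isolated(
                rng, every, round(cfg.stdloc_outlier_rate * n), taken, 1
            )
            bad_nbs = _pick_isolated(
                rng, every, round(cfg.nbs_low_rate * n), taken, 1
            )
            if cfg.noise_sd_m > 0:
                x = x + rng.normal(0.0, cfg.noise_sd_m, size=len(x))
                y = y + rng.normal(0.0, cfg.noise_sd_m, size=len(y))
            stdloc = np.exp(rng.normal(math.log(cfg.stdloc_median_m), cfg.stdloc_log_sd, size=n))
            stdloc[bad_std] = rng.uniform(*cfg.stdloc_outlier_range_m, size=bad_std.size)
            nbs = 4 + rng.binomial(10, 0.26, size=n)
            nbs[bad_nbs] = 3
            frames.append(
                pd.DataFrame(
                    {
                        "tag_id": tag,
                        "timestamp_utc": pd.to_datetime(t, unit="s", utc=True),
                        "x_m": x + site.colony_x_m,
                        "y_m": y + site.colony_y_m,
                        "stdloc_m": stdloc,
                        "nbs": nbs,
                    }
                )
            )
            truth.tags[(date, tag)] = TagDayTruth(
                apogees_m=[float(a) for a in info["apogees"]],
                visits=[
                    (
                        epoch + _dt.timedelta(seconds=float(a)),
                        epoch + _dt.timedelta(seconds=float(b)),
                    )
                    for a, b in info["visits"]
                ],
                departure_offset_min=float(info["departure_offset_min"]),
                arrival_offset_min=float(info["arrival_offset_min"]),
                route_m=float(info["route_m"]),
                foraging_hr=float(info["foraging_hr"]),
                n_fixes=n,
            )
            truth.outlier_rows.extend((out_idx + row_offset).tolist())
            row_offset += n

    fixes = pd.concat(frames, ignore_index=True)
    return fixes, truth


# ---------------------------------------------------------------------------
# radar echoes
# ---------------------------------------------------------------------------

def generate_echoes(
    date: _dt.date,
    true_motr: float,
    beam: Optional[BeamConfig] = None,
    rng: Optional[np.random.Generator] = None,
    utc_offset_hours: float = 3.0,
    rcs_subthreshold_frac: float = 0.10,
    noninsect_rate_hr: float = 20.0,
) -> pd.DataFrame:
    """Poisson echo stream for one day whose expected daily MoTR is ``true_motr``.

    Echo altitudes are uniform in the beam's altitude band; the hourly Poisson
    intensity is ``true_motr`` divided by the expected per-echo transect
    weight, so the transect-normalized hourly count is unbiased for the true
    rate.  Sub-threshold-RCS insects and non-insect targets are added on top
    to exercise the detectability and class filters.
    """
    beam = beam or BeamConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    if true_motr < 0:
        raise ConfigurationError("true_motr must be >= 0")
    if true_motr == 0 and noninsect_rate_hr == 0:
        return pd.DataFrame({k: [] for k in ECHO_COLUMNS})

    c = mean_inverse_width(beam)  # E[1000 / w(alt)] under uniform altitude
    lam = true_motr / c
    midnight_s = (
        _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc)
        - _dt.datetime(1970, 1, 1, tzinfo=_dt.timezone.utc)
    ).total_seconds()

    secs: List[np.ndarray] = []
    rcs_parts: List[np.ndarray] = []
    cls_parts: List[np.ndarray] = []

    def _append(n: int, hour_local: int, rcs: np.ndarray, cls: str) -> None:
        start_s = (hour_local - utc_offset_hours) * 3600.0
        secs.append(start_s + np.round(rng.uniform(0.0, 3600.0, size=n), 3))
        rcs_parts.append(rcs)
        cls_parts.append(np.full(n, cls, dtype=object))

    for hour in range(beam.window_start_hour, beam.window_end_hour):
        if true_motr > 0:
            n_main = rng.poisson(lam)
            rcs_main = beam.rcs_min_mm2 + rng.gamma(2.0, 3.0, size=n_main)
            _append(n_main, hour, rcs_main, "insect")
            if rcs_subthreshold_frac > 0:
                n_small = rng.poisson(lam * rcs_subthreshold_frac / (1 - rcs_subthreshold_frac))
                rcs_small = rng.uniform(0.3, beam.rcs_min_mm2 * 0.95, size=n_small)
                _append(n_small, hour, rcs_small, "insect")
        if noninsect_rate_hr > 0:
            n_bird = rng.poisson(noninsect_rate_hr)
            _append(n_bird, hour, rng.gamma(3.0, 400.0, size=n_bird), "bird")

    sec = np.concatenate(secs) if secs else np.empty(0)
    n_tot = len(sec)
    ms = np.round((midnight_s + sec) * 1e3).astype(np.int64)  # exact-ms stamps
    df = pd.DataFrame(
        {
            "timestamp_utc": pd.to_datetime(ms, unit="ms", utc=True),
            "altitude_m": rng.uniform(beam.alt_min_m, beam.alt_max_m, size=n_tot),
            "rcs_mm2": np.concatenate(rcs_parts) if rcs_parts else np.empty(0),
            "class": np.concatenate(cls_parts) if cls_parts else np.empty(0, dtype=object),
        }
    )
    return df.sort_values("timestamp_utc", ignore_index=True)


def generate_echo_table(
    cfg: TruthConfig,
    motr_days: np.ndarray,
    beam: Optional[BeamConfig] = None,
    site: Optional[SiteConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Echo table for the whole simulated period."""
    site = site or SiteConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    parts = []
    for d in range(cfg.n_days):
        date = cfg.start_date + _dt.timedelta(days=d)
        parts.append(
            generate_echoes(
                date,
                float(motr_days[d]),
                beam=beam,
                rng=rng,
                utc_offset_hours=site.utc_offset_hours,
                rcs_subthreshold_frac=cfg.rcs_subthreshold_frac,
                noninsect_rate_hr=cfg.noninsect_rate_hr,
            )
        )
    return pd.concat(parts, ignore_index=True)


def simulate_dataset(
    cfg: TruthConfig,
    site: Optional[SiteConfig] = None,
    beam: Optional[BeamConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Full synthetic dataset: (fix table, echo table, truth record)."""
    site = site or SiteConfig()
    motr = generate_motr_days(cfg)
    fixes, truth = generate_tracks(cfg, motr, site=site)
    echoes = generate_echo_table(cfg, motr, beam=beam, site=site)
    return fixes, echoes, truth
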