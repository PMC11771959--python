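"""Movement traffic rate (MoTR) from vertical-beam radar echoes.

A vertically pointing conical radar beam samples a transect whose width grows
linearly with altitude, w(a) = 2 a tan(theta/2).  Each retained echo is
weighted by the ratio of a 1 km reference transect to the beam width at its
altitude, so the hourly MoTR is the number of targets that would have crossed
a 1 km cross-section per hour.  The daily MoTR is the arithmetic mean of the
hourly values inside the local-time observation window.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import BeamConfig

REFERENCE_TRANSECT_M = 1000.0


def transect_width(altitude_m, beam: BeamConfig) -> np.ndarray | float:
    """Width (m) of the conical beam's horizontal cross-section at altitude."""
    half = math.radians(beam.opening_angle_deg / 2.0)
    return 2.0 * np.asarray(altitude_m, dtype=float) * math.tan(half)


def mean_inverse_width(beam: BeamConfig) -> float:
    """E[1000 / w(A)] for altitude A uniform on the beam's altitude band.

    This is the expected per-echo contribution to the hourly MoTR and the
    constant the synthetic echo generator inverts to stay unbiased.
    """
    half = math.radians(beam.opening_angle_deg / 2.0)
    lo, hi = beam.alt_min_m, beam.alt_max_m
    return REFERENCE_TRANSECT_M / (2.0 * math.tan(half)) * math.log(hi / lo) / (hi - lo)


def select_insect_echoes(echoes: pd.DataFrame, beam: BeamConfig) -> pd.DataFrame:
    """Echoes classified as insects, above the RCS floor, inside the altitude band."""
    mask = (
        (echoes["class"] == "insect")
        & (echoes["rcs_mm2"] >= beam.rcs_min_mm2)
        & (echoes["altitude_m"] >= beam.alt_min_m)
        & (echoes["altitude_m"] <= beam.alt_max_m)
    )
    return echoes.loc[mask]


def hourly_mtr(echoes: pd.DataFrame, beam: BeamConfig) -> float:
    """Transect-normalized traffic rate for the echoes of a single hour.

    Sum over retained echoes of 1000 m / w(altitude); assumes ``echoes`` has
    already been restricted to one clock hour.
    """
    if len(echoes) == 0:
        return 0.0
    w = transect_width(echoes["altitude_m"].to_numpy(), beam)
    return float(np.sum(REFERENCE_TRANSECT_M / w))


def daily_motr_from_hourly(hourly: pd.DataFrame) -> pd.DataFrame:
    """Daily MoTR = arithmetic mean of the window's hourly values per date.

    ``hourly`` must carry only operational window hours (zero-echo hours as
    explicit 0 rows); excluded hours are simply absent.
    """
    return (
        hourly.groupby("date", as_index=False)["hourly_mtr"]
        .mean()
        .rename(columns={"hourly_mtr": "daily_motr"})
    )


def motr_series(
    echoes: pd.DataFrame,
    beam: Optional[BeamConfig] = None,
    utc_offset_hours: float = 3.0,
    operational_hours: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly and daily MoTR from a raw echo table.

    Parameters
    ----------
    echoes : DataFrame with columns timestamp_utc, altitude_m, rcs_mm2, class.
    utc_offset_hours : fixed local-time offset used for the daily window.
    operational_hours : optional DataFrame (date, hour) flagging hours the
        radar was running.  By default every window hour of every date spanned
        by the data counts; window hours without retained echoes score 0,
        matching the convention that absence of insects is a measurement of
        zero, not a gap.

    Returns
    -------
    (hourly, daily) : hourly has columns date, hour, hourly_mtr; daily has
        columns date, daily_motr (insects km^-1 hr^-1).
    """
    beam = beam or BeamConfig()
    if len(echoes) == 0:
        empty_h = pd.DataFrame(columns=["date", "hour", "hourly_mtr"])
        empty_d = pd.DataFrame(columns=["date", "daily_motr"])
        return empty_h, empty_d

    ts = pd.to_datetime(echoes["timestamp_utc"], utc=True)
    local = ts + pd.Timedelta(hours=utc_offset_hours)
    sel = select_insect_echoes(
        echoes.assign(_date=local.dt.date, _hour=local.dt.hour), beam
    )

    all_dates = sorted(pd.unique(local.dt.date))
    window = range(beam.window_start_hour, beam.window_end_hour)
    if operational_hours is not None:
        op = {(r.date, int(r.hour)) for r in operational_hours.itertuples(index=False)}
    else:
        op = {(d, h) for d in all_dates for h in window}

    w_all = transect_width(sel["altitude_m"].to_numpy(), beam)
    contrib = pd.DataFrame(
        {"date": sel["_date"], "hour": sel["_hour"], "c": REFERENCE_TRANSECT_M / w_all}
    )
    sums = contrib.groupby(["date", "hour"])["c"].sum()

    rows = []
    for d in all_dates:
        for h in window:
            if (d, h) not in op:
                continue
            rows.append({"date": d, "hour": h, "hourly_mtr": float(sums.get((d, h), 0.0))})
    hourly = pd.DataFrame(rows)
    daily = (
        hourly.groupby("date", as_index=False)["hourly_mtr"]
        .mean()
        .rename(columns={"hourly_mtr": "daily_motr"})
    )
    return hourly, daily
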