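"""Sunrise, sunset and day length from standard NOAA solar geometry.

All timing metrics of the analysis are anchored to sunrise and sunset at the
colony, so these are computed from first principles (NOAA solar-calculator
equations, Meeus-style series) rather than from a timezone database.  The
-0.833 degree zenith offset accounts for atmospheric refraction and the solar
disc radius.  Accuracy is well within a minute at mid-latitudes, far below
the behavioral resolution of the data.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

_ZENITH_DEG = 90.833  # official sunrise/sunset zenith


class PolarDayError(ValueError):
    """The sun does not rise or set on this date at this latitude."""


@dataclass(frozen=True)
class SunTimes:
    """Solar event times for one site and calendar date (UTC)."""

    date: _dt.date
    sunrise_utc: _dt.datetime
    sunset_utc: _dt.datetime
    noon_utc: _dt.datetime

    @property
    def day_length_hours(self) -> float:
        return (self.sunset_utc - self.sunrise_utc).total_seconds() / 3600.0


def _julian_day(date: _dt.date) -> float:
    """Julian day number at 00:00 UT of ``date``."""
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def _sun_position(jc: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (min) at Julian century jc."""
    rad = math.radians
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_ctr = (
        math.sin(rad(anom)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(rad(2 * anom)) * (0.019993 - 0.000101 * jc)
        + math.sin(rad(3 * anom)) * 0.000289
    )
    true_long = l0 + eq_ctr
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(rad(omega))
    obliq0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = obliq0 + 0.00256 * math.cos(rad(omega))
    decl = math.degrees(math.asin(math.sin(rad(obliq)) * math.sin(rad(app_long))))
    var_y = math.tan(rad(obliq / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        var_y * math.sin(2 * rad(l0))
        - 2.0 * ecc * math.sin(rad(anom))
        + 4.0 * ecc * var_y * math.sin(rad(anom)) * math.cos(2 * rad(l0))
        - 0.5 * var_y**2 * math.sin(4 * rad(l0))
        - 1.25 * ecc**2 * math.sin(2 * rad(anom))
    )
    return decl, eot


def sun_times(latitude: float, longitude: float, date: _dt.date) -> SunTimes:
    """Sunrise/sunset/solar noon (UTC) for a site and date.

    Longitude is positive east.  Raises :class:`PolarDayError` when the sun
    never crosses the sunrise zenith (impossible at the study latitude).
    """
    jd0 = _julian_day(date)
    # evaluate declination / equation of time at local solar noon
    noon_guess_min = 720.0 - 4.0 * longitude
    jc = (jd0 + noon_guess_min / 1440.0 - 2451545.0) / 36525.0
    decl, eot = _sun_position(jc)
    noon_min = 720.0 - 4.0 * longitude - eot

    lat_r = math.radians(latitude)
    dec_r = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat_r) * math.cos(dec_r))
        - math.tan(lat_r) * math.tan(dec_r)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise PolarDayError(
            f"no sunrise/sunset at latitude {latitude} on {date.isoformat()}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise_min = noon_min - 4.0 * ha_deg
    sunset_min = noon_min + 4.0 * ha_deg

    midnight = _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc)
    return SunTimes(
        date=date,
        sunrise_utc=midnight + _dt.timedelta(minutes=sunrise_min),
        sunset_utc=midnight + _dt.timedelta(minutes=sunset_min),
        noon_utc=midnight + _dt.timedelta(minutes=noon_min),
    )


def sun_times_for_site(site, date: _dt.date) -> SunTimes:
    """Convenience wrapper taking a :class:`~aeroforage.config.SiteConfig`."""
    return sun_times(site.latitude, site.longitude, date)


def day_length_hours(latitude: float, longitude: float, date: _dt.date) -> float:
    return sun_times(latitude, longitude, date).day_length_hours
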