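"""Configuration models for the tracking + radar foraging pipeline.

All tunable thresholds live here as pydantic models so that YAML configs,
CLI flags and library calls share one validated schema.  Defaults encode the
study conditions: an ATLAS reverse-GPS array tracking Little Swifts around a
breeding colony in the Hula Valley, and a vertical-beam radar measuring the
insect movement traffic rate (MoTR) nearby.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


class SiteConfig(BaseModel):
    """Colony site: geographic position for solar times, planar colony origin.

    Coordinates of fixes are in a local east/north meter frame; the colony
    position is given in that same frame (default: the origin).
    """

    latitude: float = 33.05
    longitude: float = 35.59
    utc_offset_hours: float = 3.0
    colony_x_m: float = 0.0
    colony_y_m: float = 0.0

    @field_validator("latitude")
    @classmethod
    def _lat_range(cls, v: float) -> float:
        if not -90.0 <= v <= 90.0:
            raise ValueError("latitude must be in [-90, 90]")
        return v

    @field_validator("longitude")
    @classmethod
    def _lon_range(cls, v: float) -> float:
        if not -180.0 <= v <= 180.0:
            raise ValueError("longitude must be in [-180, 180]")
        return v


class FilterConfig(BaseModel):
    """Thresholds of the fix-level filter chain.

    vmax_ms        -- maximum plausible flight speed; faster steps are errors.
    iqr_k          -- multiplier of the interquartile range for the StdLoc fence.
    min_nbs        -- minimum number of receiving base stations per fix.
    max_step_m     -- maximum plausible displacement between consecutive fixes.
    min_tags_per_day -- days with fewer active tags are dropped entirely.
    jump_mode      -- 'fix' removes single offending fixes; 'segment' drops the
                      whole tag-day track containing an over-long step.
    """

    vmax_ms: float = 30.0
    iqr_k: float = 1.5
    min_nbs: int = 4
    max_step_m: float = 500.0
    min_tags_per_day: int = 4
    jump_mode: Literal["fix", "segment"] = "fix"
    quantile_method: str = "linear"

    @model_validator(mode="after")
    def _positive(self) -> "FilterConfig":
        for name in ("vmax_ms", "iqr_k", "max_step_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_nbs < 1 or self.min_tags_per_day < 1:
            raise ValueError("min_nbs and min_tags_per_day must be >= 1")
        return self


class BeamConfig(BaseModel):
    """Vertical radar beam geometry and the echo-selection window.

    The radar points straight up with a conical beam; insects are counted
    between ``alt_min_m`` and ``alt_max_m`` during local hours
    [window_start_hour, window_end_hour).
    """

    opening_angle_deg: float = 105.0  # midpoint of the 90-120 degree cone
    alt_min_m: float = 50.0
    alt_max_m: float = 700.0
    rcs_min_mm2: float = 3.0
    window_start_hour: int = 5
    window_end_hour: int = 20

    @model_validator(mode="after")
    def _geometry(self) -> "BeamConfig":
        if not 0.0 < self.opening_angle_deg < 180.0:
            raise ValueError("opening_angle_deg must be in (0, 180)")
        if not 0.0 < self.alt_min_m < self.alt_max_m:
            raise ValueError("require 0 < alt_min_m < alt_max_m")
        if not 0 <= self.window_start_hour < self.window_end_hour <= 24:
            raise ValueError("invalid local-hour window")
        return self


class MetricsConfig(BaseModel):
    """Parameters of the behavioral metric extraction."""

    colony_radius_m: float = 100.0     # fixes this close to the colony bound visits
    visit_min_s: float = 60.0          # minimum reception gap that counts as a visit
    route_min_hours: float = 10.0      # coverage needed before a daily route is reported
    gap_tolerance_s: float = 900.0     # longest tolerated non-visit reception gap
    bin_s: float = 300.0               # inter-individual distance bin width
    min_birds_per_bin: int = 4
    roost_window_min: float = 60.0     # arrival/departure window around sunset/sunrise
    exclude_visit_time: bool = True    # subtract visit time from foraging duration


class TruthConfig(BaseModel):
    """Parameters of the synthetic-data generator.

    The generator emulates the study conditions: daily insect MoTR drawn from
    a truncated gamma matching the observed mean/SD/range, multi-tag foraging
    days whose trip distances, colony-visit rates, heading concentration and
    evening arrival depend linearly (on the appropriate scale) on MoTR, ~10 m
    localization noise, gross outliers, and base-station counts.
    """

    n_days: int = 31
    tags_per_day: int = 6
    start_date: _dt.date = _dt.date(2019, 4, 1)

    # daily insect traffic rate (insects km^-1 hr^-1)
    motr_mean: float = 1207.7
    motr_sd: float = 566.7
    motr_range: Tuple[float, float] = (164.4, 2518.9)

    # behavioral couplings to MoTR
    beta_distance: float = -5e-4       # per-MoTR effect on log median trip apogee
    beta_visits: float = 4e-4          # per-MoTR effect on visit rate (hr^-1)
    beta_arrival: float = -0.01        # minutes of arrival shift per MoTR unit
    beta_heading_sd: float = -8e-4     # per-MoTR change of heading spread (rad)

    # trip / schedule shape
    flight_speed_ms: float = 8.0       # cruise speed, well below the 30 m/s cap
    apogee_median_m: float = 6000.0    # trip apogee median at MoTR = 0
    apogee_log_sd: float = 0.35        # trip-to-trip spread
    apogee_day_log_sd: float = 0.3     # shared day-level spread (weather, patches)
    visit_rate_base_hr: float = 0.5    # visit rate at MoTR = 0
    visit_rate_floor_hr: float = 0.05
    visit_min_s: float = 90.0
    visit_max_s: float = 600.0
    arrival_center_min: float = -28.0  # mean arrival offset before sunset
    arrival_sd_min: float = 8.0
    departure_mean_min: float = 10.0
    departure_sd_min: float = 5.0
    heading_sd_base: float = 2.5
    heading_sd_min: float = 0.3

    # measurement model
    noise_sd_m: float = 10.0
    outlier_rate: float = 0.10
    outlier_disp_range_m: Tuple[float, float] = (700.0, 2500.0)
    stdloc_median_m: float = 8.0
    stdloc_log_sd: float = 0.3
    stdloc_outlier_rate: float = 0.10
    stdloc_outlier_range_m: Tuple[float, float] = (30.0, 100.0)
    nbs_low_rate: float = 0.04
    fix_interval_s: float = 8.0

    # radar echo stream
    rcs_subthreshold_frac: float = 0.10
    noninsect_rate_hr: float = 20.0

    seed: int = 0

    @model_validator(mode="after")
    def _invariants(self) -> "TruthConfig":
        lo, hi = self.motr_range
        if lo <= 0 or hi <= lo:
            raise ConfigurationError("motr_range must satisfy 0 < lo < hi")
        if not lo <= self.motr_mean <= hi:
            raise ConfigurationError("motr_mean must lie inside motr_range")
        for name in ("outlier_rate", "nbs_low_rate", "stdloc_outlier_rate",
                     "rcs_subthreshold_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.fix_interval_s <= 0:
            raise ConfigurationError("fix_interval_s must be > 0")
        if self.motr_sd < 0 or self.n_days < 1 or self.tags_per_day < 1:
            raise ConfigurationError("n_days, tags_per_day >= 1 and motr_sd >= 0")
        return self


class RunConfig(BaseModel):
    """Top-level configuration of a full pipeline run."""

    site: SiteConfig = Field(default_factory=SiteConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    beam: BeamConfig = Field(default_factory=BeamConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    truth: TruthConfig = Field(default_factory=TruthConfig)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
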