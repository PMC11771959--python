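"""End-to-end orchestration: simulate -> filter -> metrics -> MoTR -> fit.

Each stage reads/writes plain CSV + JSON inside a run directory; every
artifact carries the seed and a hash of the configuration.  Stage failures
propagate as :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import io
from .config import RunConfig
from .filtering import run_filter_chain
from .inference import build_day_table, report_to_json, run_paper_models
from .metrics import compute_daily_metrics
from .radar import motr_series
from .synthetic import simulate_dataset

logger = logging.getLogger("aeroforage")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def run_all(cfg: RunConfig, out_dir) -> Path:
    """Execute the full chain on simulated data; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    meta = {"seed": cfg.seed, "config_sha": cfg.config_hash()}

    truth_cfg = cfg.truth.model_copy(update={"seed": cfg.seed})
    fixes, echoes, truth = _stage("simulate")(simulate_dataset)(
        truth_cfg, site=cfg.site, beam=cfg.beam
    )
    io.write_fixes_csv(fixes, out / "fixes.csv", meta)
    io.write_echoes_csv(echoes, out / "echoes.csv", meta)
    io.write_json(truth.to_json_dict(), out / "truth.json", meta)
    logger.info("simulated %d fixes, %d echoes", len(fixes), len(echoes))

    filtered, report = _stage("filter")(run_filter_chain)(fixes, cfg.filters, cfg.site)
    io.write_fixes_csv(filtered, out / "fixes_filtered.csv", meta)
    io.write_json(report.to_dict(), out / "attrition.json", meta)
    logger.info("filtering removed %.1f%% of daylight fixes",
                100 * report.total_removed_fraction)

    metrics, visits = _stage("metrics")(compute_daily_metrics)(
        filtered, cfg.site, cfg.metrics
    )
    io.write_table_csv(metrics, out / "metrics.csv", meta)
    io.write_table_csv(visits, out / "visits.csv", meta)

    hourly, daily = _stage("motr")(motr_series)(
        echoes, cfg.beam, cfg.site.utc_offset_hours
    )
    io.write_table_csv(hourly, out / "motr_hourly.csv", meta)
    io.write_table_csv(daily, out / "motr_daily.csv", meta)

    day_table = _stage("join")(build_day_table)(metrics, daily)
    io.write_table_csv(day_table, out / "day_table.csv", meta)

    report_models = _stage("fit")(run_paper_models)(day_table)
    io.write_json(report_to_json(report_models), out / "model_report.json", meta)
    io.write_json(
        {"seed": cfg.seed, "config_sha": meta["config_sha"],
         "config": cfg.model_dump(mode="json")},
        out / "run_manifest.json",
    )
    return out


def simulate_world_day_table(
    cfg: RunConfig,
    run_filters: bool = True,
) -> tuple[pd.DataFrame, "object"]:
    """In-memory pipeline up to the joined day table (no file I/O).

    Used by simulation studies (parameter recovery, sign-pattern replication)
    that need many replicate worlds.
    """
    truth_cfg = cfg.truth.model_copy(update={"seed": cfg.seed})
    fixes, echoes, truth = simulate_dataset(truth_cfg, site=cfg.site, beam=cfg.beam)
    if run_filters:
        fixes, _ = run_filter_chain(fixes, cfg.filters, cfg.site)
    metrics, _ = compute_daily_metrics(fixes, cfg.site, cfg.metrics)
    _, daily = motr_series(echoes, cfg.beam, cfg.site.utc_offset_hours)
    return build_day_table(metrics, daily), truth
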