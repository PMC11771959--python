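"""CSV/JSON readers and writers for the pipeline's artifacts.

All tables are plain CSV with ISO-8601 UTC timestamps.  Files written by the
pipeline start with ``#``-prefixed metadata lines (seed, config hash) that
the readers skip, so every artifact records its provenance without breaking
round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f%z"


def _write_csv(df: pd.DataFrame, path: Path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, date_format=_TS_FORMAT)


def write_fixes_csv(fixes: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    cols = ["tag_id", "timestamp_utc", "x_m", "y_m", "stdloc_m", "nbs"]
    _write_csv(fixes[cols], Path(path), meta)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"tag_id", "timestamp_utc", "x_m", "y_m", "stdloc_m", "nbs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV {path} lacks columns: {sorted(missing)}")
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], utc=True, format="ISO8601")
    return df


def write_echoes_csv(echoes: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    cols = ["timestamp_utc", "altitude_m", "rcs_mm2", "class"]
    _write_csv(echoes[cols], Path(path), meta)


def read_echoes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"timestamp_utc", "altitude_m", "rcs_mm2", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"echo CSV {path} lacks columns: {sorted(missing)}")
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"], utc=True, format="ISO8601")
    return df


def write_table_csv(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    _write_csv(df, Path(path), meta)


def read_table_csv(path, date_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in date_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


def write_json(obj, path, meta: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"meta": meta or {}, **({"data": obj} if not isinstance(obj, dict) else obj)}
    if isinstance(obj, dict) and meta:
        payload = {"meta": meta, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
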