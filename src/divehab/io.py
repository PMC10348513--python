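"""File I/O: CSV tables of fixes, depth traces and dive events, plus
ASCII-grid rasters and GeoJSON isopleths.

Schemas match what the simulator writes: GPS fixes as
``bird_id,timestamp,lon,lat[,trip_id]``, depth traces as
``bird_id,timestamp,depth_m``, timestamps ISO-8601 UTC.  Malformed rows
are rejected with line numbers; out-of-order timestamps name the bird.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .grids import EnvStack, read_ascii_grid, write_ascii_grid

__all__ = [
    "read_fixes", "read_traces", "read_events", "write_fixes", "write_traces",
    "write_events", "write_env", "read_env", "write_json", "read_json",
]

FIX_COLUMNS = ["bird_id", "timestamp", "lon", "lat"]
TRACE_COLUMNS = ["bird_id", "timestamp", "depth_m"]


class SchemaError(ValueError):
    pass


def _read_csv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna()
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna()
        df[col] = vals
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise SchemaError(f"{path}: malformed value(s) at line(s) {lines}")
    df["timestamp"] = ts
    return df


def _check_monotone(df: pd.DataFrame, path) -> None:
    bad = [str(b) for b, g in df.groupby("bird_id")
           if not g["timestamp"].is_monotonic_increasing]
    if bad:
        raise SchemaError(f"{path}: out-of-order timestamps for bird(s) {bad}")


def read_fixes(path) -> pd.DataFrame:
    df = _read_csv(path, FIX_COLUMNS, ["lon", "lat"])
    _check_monotone(df, path)
    return df


def read_traces(path) -> pd.DataFrame:
    df = _read_csv(path, TRACE_COLUMNS, ["depth_m"])
    _check_monotone(df, path)
    return df


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("start_time", "end_time"):
        if col in df:
            df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601")
    return df


def _write_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.DatetimeTZDtype):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def write_fixes(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def write_traces(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def write_events(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def write_env(env: EnvStack, directory) -> None:
    """One .asc file per static layer and per SST day."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(directory / "bathy.asc", env.bathy)
    write_ascii_grid(directory / "slope.asc", env.slope)
    write_ascii_grid(directory / "sea.asc", env.sea)
    for date, layer in env.sst.items():
        write_ascii_grid(directory / f"sst_{date.isoformat()}.asc", layer)


def read_env(directory) -> EnvStack:
    directory = Path(directory)
    sst = {}
    for f in sorted(directory.glob("sst_*.asc")):
        date = pd.Timestamp(f.stem.removeprefix("sst_")).date()
        sst[date] = read_ascii_grid(f)
    return EnvStack(
        bathy=read_ascii_grid(directory / "bathy.asc"),
        slope=read_ascii_grid(directory / "slope.asc"),
        sea=read_ascii_grid(directory / "sea.asc"),
        sst=sst,
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
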