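"""GPS telemetry tables: IO, daily subsampling and foraging-time filters.

A telemetry table is a pandas DataFrame with columns
``animal_id`` (str), ``timestamp`` (datetime64, local clock), ``x``, ``y``
(metres), sorted by animal and time.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_telemetry",
    "write_telemetry",
    "validate_telemetry",
    "subsample_daily",
    "filter_foraging_locations",
]

COLUMNS = ["animal_id", "timestamp", "x", "y"]


def read_telemetry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return validate_telemetry(df)


def write_telemetry(df: pd.DataFrame, path: str | Path) -> None:
    out = df[COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def validate_telemetry(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry table missing columns: {missing}")
    df = df[COLUMNS].copy()
    df["animal_id"] = df["animal_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("telemetry coordinates must be finite")
    df = df.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)
    dup = df.groupby("animal_id")["timestamp"].apply(lambda s: s.duplicated().any())
    if dup.any():
        bad = dup[dup].index.tolist()
        raise ValueError(f"non-increasing timestamps within animal(s): {bad}")
    return df


def subsample_daily(locations: pd.DataFrame) -> pd.DataFrame:
    """Keep one fix per animal per calendar day (the earliest of that day).

    Home ranges are built from daily fixes so that animals with 30-min
    collars do not dominate the kernel relative to 2-h collars.
    """
    df = validate_telemetry(locations)
    if df.empty:
        return df
    day = df["timestamp"].dt.normalize()
    # sorted by time within animal, so first() is the earliest fix of the day
    out = df.groupby(["animal_id", day], sort=True, as_index=False).first()
    return out[COLUMNS].sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def filter_foraging_locations(
    locations: pd.DataFrame,
    season: tuple[tuple[int, int], tuple[int, int]] = ((7, 1), (8, 31)),
    rest_window: tuple[dt.time, dt.time] = (dt.time(11, 0), dt.time(18, 0)),
) -> pd.DataFrame:
    """Restrict fixes to the summer foraging season and active hours.

    Keeps rows whose date falls in ``season`` (month/day bounds, inclusive)
    and whose local time is NOT in the midday rest window.  The window is
    half-open: a fix at exactly 11:00 is dropped, a fix at exactly 18:00 is
    kept.
    """
    df = validate_telemetry(locations)
    if df.empty:
        return df
    ts = df["timestamp"]
    md = ts.dt.month * 100 + ts.dt.day
    (m0, d0), (m1, d1) = season
    in_season = (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)
    t = ts.dt.time
    lo, hi = rest_window
    resting = (t >= lo) & (t < hi)
    return df[in_season & ~resting].reset_index(drop=True)
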