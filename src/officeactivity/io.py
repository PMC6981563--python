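"""Readers and writers for the package's plain-text interchange formats.

Epoch CSV: ``participant_id, group, phase, timestamp, met`` (ISO 8601 local
timestamps; met = 0 encodes no signal). Entry/exit CSV: ``participant_id,
date, entry_time, exit_time`` (repeated rows per day allowed). Detection
logs: CSV or JSON Lines with ``day_index, timestamp, camera_id, x_m, y_m``.
Plans are GeoJSON FeatureCollections (see :class:`~officeactivity.spaces.OfficePlan`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .accelerometry import EpochSeries

__all__ = [
    "write_epoch_csv",
    "read_epoch_csv",
    "write_entry_exit_csv",
    "read_entry_exit_csv",
    "write_detection_log",
    "read_detection_log",
]


def write_epoch_csv(series: Iterable[EpochSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "phase": s.phase,
                "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "met": np.round(s.met, 4),
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epoch_csv(path: str | Path) -> list[EpochSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (pid, group, phase), grp in df.groupby(
        ["participant_id", "group", "phase"], sort=True
    ):
        grp = grp.sort_values("timestamp")
        out.append(
            EpochSeries(
                participant_id=str(pid),
                group=str(group),
                phase=str(phase),
                timestamps=pd.DatetimeIndex(grp["timestamp"]),
                met=grp["met"].to_numpy(dtype=float),
            )
        )
    return out


def write_entry_exit_csv(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False)


def read_entry_exit_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"participant_id": str, "entry_time": str, "exit_time": str}
    )


def write_detection_log(log: pd.DataFrame, path: str | Path) -> None:
    """Write a detection log as CSV or JSON Lines (by file suffix)."""
    df = log.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["x_m"] = np.round(df["x_m"].astype(float), 4)
    df["y_m"] = np.round(df["y_m"].astype(float), 4)
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)


def read_detection_log(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
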