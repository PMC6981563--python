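"""Office zone assignment and 15-min slot aggregation of person detections.

An office plan is a set of labelled polygons in floor meters, each with a
space category (aisle subtype or workstation subtype), an overlap-resolution
priority and an area. Person detections (timestamp + floor coordinate) are
assigned to zones by point-in-polygon containment (boundary inclusive) and
aggregated into per-zone per-day counts over half-open 15-min slots — 28
slots for the standard 10:00-17:00 recording window. "Space utilization" is
the detectable number of persons per zone per slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "Zone",
    "OfficePlan",
    "AISLE_CATEGORIES",
    "WORKSTATION_CATEGORIES",
    "assign_zone",
    "assign_zones",
    "aggregate_slot_counts",
    "summarize_space",
    "slot_profile",
]

AISLE_CATEGORIES = frozenset(
    {"main_aisle", "around_workstation_aisle", "multiple_usage_aisle"}
)
WORKSTATION_CATEGORIES = frozenset({"dedicated_workstation", "shared_workstation"})
CATEGORIES = AISLE_CATEGORIES | WORKSTATION_CATEGORIES

#: Default video recording window and slot length.
RECORD_START = time(10, 0)
RECORD_END = time(17, 0)
SLOT_MIN = 15


@dataclass
class Zone:
    """A labelled office space: polygon in floor meters plus metadata."""

    label: str
    category: str
    polygon: Polygon
    priority: int = 0
    area_m2: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown space category: {self.category!r}")
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(f"zone {self.label!r}: polygon must be simple with area > 0")
        if self.area_m2 is None:
            self.area_m2 = float(self.polygon.area)
        if self.area_m2 <= 0:
            raise ValueError(f"zone {self.label!r}: area must be positive")


@dataclass
class OfficePlan:
    """A collection of zones forming one office layout."""

    zones: list[Zone]
    name: str = "office"

    def __post_init__(self) -> None:
        labels = [z.label for z in self.zones]
        if len(set(labels)) != len(labels):
            raise ValueError("zone labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [z.label for z in self.zones]

    def zone(self, label: str) -> Zone:
        for z in self.zones:
            if z.label == label:
                return z
        raise KeyError(label)

    def ordered(self) -> list[Zone]:
        """Zones in assignment order: priority descending, then label."""
        return sorted(self.zones, key=lambda z: (-z.priority, z.label))

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(z.polygon),
                "properties": {
                    "label": z.label,
                    "category": z.category,
                    "priority": z.priority,
                    "area_m2": z.area_m2,
                },
            }
            for z in self.zones
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
        )

    @classmethod
    def from_geojson(cls, path: str | Path, name: str | None = None) -> "OfficePlan":
        data = json.loads(Path(path).read_text())
        zones = []
        for feat in data["features"]:
            props = feat["properties"]
            geom = shape(feat["geometry"])
            if not isinstance(geom, Polygon):
                raise ValueError(f"zone {props.get('label')}: geometry must be Polygon")
            zones.append(
                Zone(
                    label=props["label"],
                    category=props["category"],
                    polygon=geom,
                    priority=int(props.get("priority", 0)),
                    area_m2=props.get("area_m2"),
                )
            )
        return cls(zones=zones, name=name or Path(path).stem)


def assign_zone(location: tuple[float, float], plan: OfficePlan) -> str | None:
    """Label of the zone containing a point, or None.

    Containment includes the boundary; overlapping zones are resolved by
    highest priority, then lexicographically smallest label.
    """
    labels = assign_zones(np.array([location], dtype=float), plan)
    return labels[0]


def assign_zones(xy: np.ndarray, plan: OfficePlan) -> list[str | None]:
    """Vectorised zone assignment for an (n, 2) array of coordinates."""
    if not plan.zones:
        raise ValueError("plan has no zones")
    xy = np.asarray(xy, dtype=float)
    points = shapely.points(xy[:, 0], xy[:, 1])
    out: list[str | None] = [None] * len(points)
    unassigned = np.ones(len(points), dtype=bool)
    for zone in plan.ordered():
        if not unassigned.any():
            break
        idx = np.flatnonzero(unassigned)
        hit = shapely.covers(zone.polygon, points[idx])
        for i in idx[hit]:
            out[i] = zone.label
        unassigned[idx[hit]] = False
    return out


def _slot_of(timestamps: pd.Series, start: time, end: time, slot_min: int):
    """Half-open slot index of each timestamp; -1 outside [start, end)."""
    ts = pd.to_datetime(timestamps, format="mixed")
    sec = ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
    start_s = start.hour * 3600 + start.minute * 60
    end_s = end.hour * 3600 + end.minute * 60
    n_slots = (end_s - start_s) // (slot_min * 60)
    slot = (sec - start_s) // (slot_min * 60)
    slot = slot.where((sec >= start_s) & (sec < end_s), -1)
    return slot.astype(int), int(n_slots)


def aggregate_slot_counts(
    log: pd.DataFrame,
    plan: OfficePlan,
    start: time = RECORD_START,
    end: time = RECORD_END,
    slot_min: int = SLOT_MIN,
) -> pd.DataFrame:
    """Per-zone per-day per-slot detection counts.

    ``log`` needs columns ``day_index, timestamp, x_m, y_m``. Slots are
    half-open and partition ``[start, end)``; detections outside the window
    or in no zone are dropped (counts recorded in ``df.attrs``). Every
    (zone, day, slot) cell is present, zero-filled, so the table always has
    n_zones x n_days x n_slots rows.
    """
    start_s = start.hour * 60 + start.minute
    end_s = end.hour * 60 + end.minute
    if (end_s - start_s) % slot_min != 0:
        raise ValueError("recording window must be divisible by slot length")
    slot, n_slots = _slot_of(log["timestamp"], start, end, slot_min)
    labels = assign_zones(log[["x_m", "y_m"]].to_numpy(dtype=float), plan)
    df = pd.DataFrame(
        {
            "label": labels,
            "day_index": log["day_index"].to_numpy(),
            "slot_index": slot.to_numpy(),
        }
    )
    out_of_window = int((df["slot_index"] < 0).sum())
    unassigned = int(df["label"].isna().sum())
    kept = df[(df["slot_index"] >= 0) & df["label"].notna()]
    counts = (
        kept.groupby(["label", "day_index", "slot_index"]).size().rename("count")
    )
    days = sorted(pd.unique(log["day_index"])) or [1]
    grid = pd.MultiIndex.from_product(
        [plan.labels, days, range(n_slots)], names=["label", "day_index", "slot_index"]
    )
    table = counts.reindex(grid, fill_value=0).reset_index()
    cat = {z.label: z.category for z in plan.zones}
    table.insert(1, "category", table["label"].map(cat))
    table.attrs["dropped_out_of_window"] = out_of_window
    table.attrs["dropped_unassigned"] = unassigned
    table.attrs["n_slots"] = n_slots
    return table


def summarize_space(
    slot_counts: pd.DataFrame,
    level: str = "zone",
    dispersion: str = "cells",
) -> pd.DataFrame:
    """Mean and standard error of per-15-min counts per space.

    ``level='zone'`` summarises per zone label, ``'category'`` pools zones of
    one category (counts summed per day x slot cell first). The SE is
    computed across day x slot cells by default (``dispersion='cells'``);
    ``'days'`` first averages slots within a day and takes the SE across
    days, ``'slots'`` the converse. Spaces with no cells are excluded with a
    warning.
    """
    if level not in ("zone", "category"):
        raise ValueError("level must be 'zone' or 'category'")
    if dispersion not in ("cells", "days", "slots"):
        raise ValueError("dispersion must be 'cells', 'days' or 'slots'")
    key = "label" if level == "zone" else "category"
    pooled = (
        slot_counts.groupby([key, "day_index", "slot_index"])["count"]
        .sum()
        .reset_index()
    )
    rows = []
    for space, grp in pooled.groupby(key):
        if dispersion == "cells":
            vals = grp["count"].to_numpy(dtype=float)
        elif dispersion == "days":
            vals = grp.groupby("day_index")["count"].mean().to_numpy()
        else:
            vals = grp.groupby("slot_index")["count"].mean().to_numpy()
        if len(vals) == 0:
            import warnings

            warnings.warn(f"space {space!r} has no cells; excluded", stacklevel=2)
            continue
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            dict(space=space, mean=float(np.mean(vals)), se=se, n=len(vals))
        )
    out = pd.DataFrame(rows, columns=["space", "mean", "se", "n"])
    if level == "zone":
        cat = slot_counts.drop_duplicates("label").set_index("label")["category"]
        out.insert(1, "category", out["space"].map(cat))
        aisle_first = out["category"].isin(AISLE_CATEGORIES)
        out = (
            out.assign(_aisle=~aisle_first)
            .sort_values(["_aisle", "space"])
            .drop(columns="_aisle")
            .reset_index(drop=True)
        )
    return out


def slot_profile(
    slot_counts: pd.DataFrame, labels: list[str] | None = None
) -> pd.DataFrame:
    """Per-slot count series per zone: one column per (label, day) plus an
    across-day ``(label, 'mean')`` column; rows indexed by slot."""
    df = slot_counts
    if labels is not None:
        missing = set(labels) - set(df["label"].unique())
        if missing:
            raise KeyError(f"unknown zone label(s): {sorted(missing)}")
        df = df[df["label"].isin(labels)]
    wide = df.pivot_table(
        index="slot_index", columns=["label", "day_index"], values="count",
        aggfunc="sum",
    )
    means = wide.T.groupby(level="label").mean().T
    means.columns = pd.MultiIndex.from_product([means.columns, ["mean"]])
    out = pd.concat([wide, means], axis=1).sort_index(axis=1)
    out.columns.names = ["label", "day_index"]
    return out
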