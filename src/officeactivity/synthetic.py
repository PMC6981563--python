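"""Synthetic study-data generators.

The raw data of the office-renovation study (accelerometer epoch files,
entry/exit sheets, floor drawings and camera person-detection logs) were
never deposited, so this module emulates their statistical structure:

* weekday 60-s MET epoch series with a 07:00-22:00 wear day, occasional
  non-wear gaps, and working-hours SB/LPA/MVPA composition set per
  group x phase cell (the renovation-post cell shifts minutes from SB to
  LPA);
* daily office entry/exit logs;
* labelled floor plans for the pre- and post-renovation layouts (synthetic
  rectangle layouts — the study's drawings were not published — with the
  published category structure: the post layout adds two multiple-usage
  aisles and four shared workstations);
* Poisson person-detection logs over the 10:00-17:00 recording window.

Within-day activity is laid out as an alternating-renewal (run-length)
process: each day's category minute targets are drawn first, then written
into the wear epochs as geometric-length bouts. Category minutes therefore
hit their daily targets exactly (up to epoch rounding), so cohort-level
calibration error comes only from the configured between- and within-person
SDs, while realistic bouts make prolonged-SB detection non-vacuous.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .accelerometry import EpochSeries, WorkingWindow
from .spaces import OfficePlan, Zone, assign_zones

__all__ = [
    "AccelSimConfig",
    "VideoSimConfig",
    "GROUPS",
    "PHASES",
    "GROUP_BASELINE_MEANS",
    "generate_epoch_series",
    "generate_entry_exit_log",
    "generate_office_plan",
    "default_zone_intensities",
    "generate_detection_log",
]

GROUPS = ("control", "renovation")
PHASES = ("pre", "post")

#: Published working-hours baseline cell means (SB, LPA, MVPA) in
#: min/working-hours; each triple partitions the 520-min workday exactly.
GROUP_BASELINE_MEANS: dict[str, tuple[float, float, float]] = {
    "control": (365.0, 122.3, 32.7),
    "renovation": (346.8, 130.4, 42.8),
}

#: Monday starts of the two measurement periods.
PHASE_START = {"pre": date(2017, 11, 6), "post": date(2018, 7, 23)}

_GCODE = {"control": 11, "renovation": 12}
_PCODE = {"pre": 21, "post": 22}


@dataclass
class AccelSimConfig:
    """Configuration of the accelerometer cohort simulator.

    ``working_*_min`` are the expected SB/LPA/MVPA minutes within the
    520-min working window for a group x phase cell; they must partition the
    window (the published cells do, by the normalisation identity). The
    renovation-post cell shifts ``effect_sb_change`` minutes from SB to LPA.
    ``sd_between`` is the SD of a stable per-participant SB<->LPA shift
    (shared across phases); ``sd_within`` the day-to-day SD of the same
    shift. Bout mean lengths (minutes) control run structure; adjacent
    same-category runs merge after interleaving, so the effective SB bouts
    are longer than ``sb_bout_mean`` — the default of 6 min puts ~27% of SB
    time into bouts >= 30 min, the share observed in office cohorts.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"control": 29, "renovation": 13}
    )
    n_weekdays: int = 10
    epoch_len: int = 60
    wear_start: time = time(7, 0)
    wear_end: time = time(22, 0)
    nonwear_gap_rate: float = 1.0
    nonwear_gap_len: int = 30
    working_sb_min: float = 346.8
    working_lpa_min: float = 130.4
    working_mvpa_min: float = 42.8
    sd_between: float = 25.0
    sd_within: float = 10.0
    effect_sb_change: float = 25.0
    sb_bout_mean: float = 6.0
    lpa_bout_mean: float = 4.0
    mvpa_bout_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        window = WorkingWindow()
        if self.epoch_len != 60:
            raise ValueError("epoch_len is fixed at 60 s")
        for name in ("working_sb_min", "working_lpa_min", "working_mvpa_min",
                     "nonwear_gap_rate", "nonwear_gap_len", "effect_sb_change"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.working_sb_min + self.working_lpa_min + self.working_mvpa_min
        if total > window.duration_min + 0.5:
            raise ValueError(
                f"configured working-hours durations ({total:.1f} min) exceed "
                f"the {window.duration_min}-min window"
            )
        if abs(total - window.duration_min) > 0.5:
            raise ValueError(
                "working-hours SB+LPA+MVPA must partition the 520-min window "
                f"(got {total:.1f})"
            )
        if self.wear_start > window.start or self.wear_end < window.end:
            raise ValueError("wear day must cover the working window")
        if not all(g in GROUPS for g in self.n_per_group):
            raise ValueError(f"groups must be subset of {GROUPS}")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("n_per_group entries must be positive")
        for name in ("sb_bout_mean", "lpa_bout_mean", "mvpa_bout_mean"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 minute")

    def with_means(self, sb: float, lpa: float, mvpa: float) -> "AccelSimConfig":
        return replace(
            self, working_sb_min=sb, working_lpa_min=lpa, working_mvpa_min=mvpa
        )


def _weekdays(start: date, n: int) -> list[date]:
    days, d = [], start
    while len(days) < n:
        if d.weekday() < 5:
            days.append(d)
        d += timedelta(days=1)
    return days


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` closest to ``proportions*total``."""
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _bout_sequence(
    counts: np.ndarray, bout_means: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Category codes (0=SB,1=LPA,2=MVPA) of length counts.sum(), laid out
    as shuffled geometric-length runs with exact per-category totals."""
    runs: list[tuple[int, int]] = []
    for cat, (n, mean) in enumerate(zip(counts, bout_means)):
        remaining = int(n)
        while remaining > 0:
            length = min(int(rng.geometric(1.0 / mean)), remaining)
            runs.append((cat, length))
            remaining -= length
    order = rng.permutation(len(runs))
    seq = np.empty(int(counts.sum()), dtype=np.int8)
    pos = 0
    for i in order:
        cat, length = runs[i]
        seq[pos : pos + length] = cat
        pos += length
    return seq


_MET_RANGES = ((0.9, 1.5), (1.6, 2.9), (3.0, 6.0))  # SB, LPA, MVPA


def _mets_for(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    met = np.empty(seq.shape, dtype=float)
    for cat, (lo, hi) in enumerate(_MET_RANGES):
        mask = seq == cat
        met[mask] = rng.uniform(lo, hi, mask.sum())
    return met


def _participant_shift(config: AccelSimConfig, group: str, i: int) -> tuple[float, float]:
    """Stable activity disposition of participant ``i`` (phase-independent
    stream): an SB<->LPA shift with SD ``sd_between`` and an MVPA<->LPA
    shift with half that SD (between-person MVPA variation is roughly half
    the SB variation in office cohorts)."""
    rng = np.random.default_rng([config.seed, _GCODE[group], 101, i])
    return (
        float(rng.normal(0.0, config.sd_between)),
        float(rng.normal(0.0, config.sd_between / 2.0)),
    )


def generate_epoch_series(
    config: AccelSimConfig, group: str, phase: str
) -> list[EpochSeries]:
    """Simulate one group x phase cell: one series per participant.

    Epochs run every 60 s from ``wear_start`` to ``wear_end`` on each
    weekday; non-wear gaps appear as contiguous MET = 0 runs. Within the
    working window the expected SB/LPA/MVPA minutes equal the configured
    cell means (renovation-post shifted by ``effect_sb_change`` from SB to
    LPA). Deterministic under the config seed.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group: {group!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase: {phase!r}")
    window = WorkingWindow()
    days = _weekdays(PHASE_START[phase], config.n_weekdays)
    n_day = (config.wear_end.hour * 60 + config.wear_end.minute) - (
        config.wear_start.hour * 60 + config.wear_start.minute
    )
    minute_of_day = (
        config.wear_start.hour * 60 + config.wear_start.minute + np.arange(n_day)
    )
    win_lo = window.start.hour * 60 + window.start.minute
    win_hi = window.end.hour * 60 + window.end.minute
    segments = [
        np.flatnonzero(minute_of_day < win_lo),
        np.flatnonzero((minute_of_day >= win_lo) & (minute_of_day < win_hi)),
        np.flatnonzero(minute_of_day >= win_hi),
    ]
    effect = config.effect_sb_change if (group, phase) == ("renovation", "post") else 0.0
    bout_means = np.array(
        [config.sb_bout_mean, config.lpa_bout_mean, config.mvpa_bout_mean]
    )
    out = []
    for i in range(config.n_per_group[group]):
        delta_i, gamma_i = _participant_shift(config, group, i)
        rng = np.random.default_rng([config.seed, _GCODE[group], _PCODE[phase], i])
        all_ts, all_met = [], []
        for day in days:
            met = np.zeros(n_day)
            worn = np.ones(n_day, dtype=bool)
            n_gaps = rng.poisson(config.nonwear_gap_rate)
            gap_len = min(config.nonwear_gap_len, n_day)
            for _ in range(n_gaps):
                s = int(rng.integers(0, n_day - gap_len + 1))
                worn[s : s + gap_len] = False
            shift = delta_i + rng.normal(0.0, config.sd_within)
            mvpa = (
                config.working_mvpa_min
                + gamma_i
                + rng.normal(0.0, config.sd_within / 3.0)
            )
            mvpa = float(np.clip(mvpa, 0.0, window.duration_min))
            sb = config.working_sb_min + shift - effect
            sb = float(np.clip(sb, 0.0, window.duration_min - mvpa))
            lpa = window.duration_min - sb - mvpa
            props = np.array([sb, lpa, mvpa]) / window.duration_min
            for seg in segments:
                wear_pos = seg[worn[seg]]
                if wear_pos.size == 0:
                    continue
                counts = _largest_remainder(props, wear_pos.size)
                seq = _bout_sequence(counts, bout_means, rng)
                met[wear_pos] = _mets_for(seq, rng)
            start_dt = datetime.combine(day, config.wear_start)
            all_ts.append(
                pd.date_range(start_dt, periods=n_day, freq="60s")
            )
            all_met.append(met)
        pid = f"{group}_{i:02d}"
        out.append(
            EpochSeries(
                participant_id=pid,
                group=group,
                phase=phase,
                timestamps=all_ts[0].append(all_ts[1:]),
                met=np.concatenate(all_met),
            )
        )
    return out


def generate_entry_exit_log(
    config: AccelSimConfig,
    mean_hours: float = 7.0,
    group: str = "renovation",
    phase: str = "pre",
) -> pd.DataFrame:
    """Daily office entry/exit pairs for each simulated participant.

    Daily total in-office hours are normal around ``mean_hours`` (SD 1 h,
    clipped to [2, 11]); about a quarter of days split into two pairs with a
    midday exit. Columns: participant_id, date, entry_time, exit_time.
    """
    if not 0 < mean_hours <= 24:
        raise ValueError("mean_hours must be in (0, 24]")
    days = _weekdays(PHASE_START[phase], config.n_weekdays)
    rows = []
    for i in range(config.n_per_group[group]):
        rng = np.random.default_rng(
            [config.seed, _GCODE[group], _PCODE[phase], 301, i]
        )
        pid = f"{group}_{i:02d}"
        for day in days:
            total = float(np.clip(rng.normal(mean_hours, 1.0), 2.0, 11.0))
            entry = 8.0 + 40.0 / 60.0 + float(rng.normal(0.0, 0.25))
            entry = float(np.clip(entry, 7.5, 10.0))
            if rng.random() < 0.25:
                first = total * float(rng.uniform(0.4, 0.6))
                gap = float(rng.uniform(0.5, 1.5))
                pairs = [
                    (entry, entry + first),
                    (entry + first + gap, entry + first + gap + (total - first)),
                ]
            else:
                pairs = [(entry, entry + total)]
            for t0, t1 in pairs:
                rows.append(
                    dict(
                        participant_id=pid,
                        date=day.isoformat(),
                        entry_time=_hhmm(t0),
                        exit_time=_hhmm(t1),
                    )
                )
    return pd.DataFrame(rows, columns=["participant_id", "date", "entry_time", "exit_time"])


def _hhmm(hours: float) -> str:
    total_min = int(round(hours * 60))
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


# ---------------------------------------------------------------------------
# Floor plans and detection logs
# ---------------------------------------------------------------------------

def generate_office_plan(layout: str) -> OfficePlan:
    """Synthetic rectangular floor plan (28 x 13 m, 364 m²) for one layout.

    The real office drawings were never published; these synthetic layouts
    reproduce the category structure: the pre layout has main and
    around-workstation aisles only, the post layout adds two multiple-usage
    aisles (the round-aisle renovation) and four shared workstations.
    Workstations carry higher priority than aisles for overlap resolution.
    """
    if layout == "pre":
        zones = [
            Zone("main_aisle", "main_aisle", box(0, 5.5, 28, 7.5), 1),
            Zone("around_workstation_aisle_1", "around_workstation_aisle",
                 box(0, 3.5, 28, 5.5), 1),
            Zone("around_workstation_aisle_2", "around_workstation_aisle",
                 box(0, 7.5, 28, 9.5), 1),
            Zone("dedicated_workstation_1", "dedicated_workstation",
                 box(0, 9.5, 28, 13), 2),
            Zone("dedicated_workstation_2", "dedicated_workstation",
                 box(0, 0, 20, 3.5), 2),
            Zone("shared_workstation_1", "shared_workstation",
                 box(20, 0, 28, 3.5), 2),
        ]
    elif layout == "post":
        zones = [
            Zone("main_aisle", "main_aisle", box(4, 5.5, 28, 7.5), 1),
            Zone("multiple_usage_aisle_1", "multiple_usage_aisle",
                 box(0, 0, 4, 13), 1),
            Zone("multiple_usage_aisle_2", "multiple_usage_aisle",
                 box(12, 0, 17, 5.5), 1),
            Zone("around_workstation_aisle", "around_workstation_aisle",
                 box(4, 7.5, 28, 9), 1),
            Zone("dedicated_workstation_1", "dedicated_workstation",
                 box(4, 9, 16, 13), 2),
            Zone("dedicated_workstation_2", "dedicated_workstation",
                 box(16, 9, 28, 13), 2),
            Zone("shared_workstation_1", "shared_workstation", box(4, 0, 12, 2.75), 2),
            Zone("shared_workstation_2", "shared_workstation", box(4, 2.75, 12, 5.5), 2),
            Zone("shared_workstation_3", "shared_workstation", box(17, 0, 28, 2.75), 2),
            Zone("shared_workstation_4", "shared_workstation", box(17, 2.75, 28, 5.5), 2),
        ]
    else:
        raise ValueError("layout must be 'pre' or 'post'")
    return OfficePlan(zones=zones, name=layout)


#: Published per-space detection means (persons / 15 min), split evenly
#: across a category's zones where the table reports the category total.
_TABLE_INTENSITIES = {
    "pre": {
        "main_aisle": 59.5,
        "around_workstation_aisle_1": 63.9 / 2,
        "around_workstation_aisle_2": 63.9 / 2,
        "dedicated_workstation_1": 1016.7 / 2,
        "dedicated_workstation_2": 1016.7 / 2,
        "shared_workstation_1": 241.1,
    },
    "post": {
        "main_aisle": 107.0,
        "multiple_usage_aisle_1": 27.6,
        "multiple_usage_aisle_2": 135.2,
        "around_workstation_aisle": 57.2,
        "dedicated_workstation_1": 1629.0 / 2,
        "dedicated_workstation_2": 1629.0 / 2,
        "shared_workstation_1": 442.3 / 4,
        "shared_workstation_2": 442.3 / 4,
        "shared_workstation_3": 442.3 / 4,
        "shared_workstation_4": 442.3 / 4,
    },
}


def default_zone_intensities(plan: OfficePlan) -> dict[str, float]:
    """Per-zone mean detections per 15-min slot matching the published
    per-space magnitudes for the pre/post layouts of
    :func:`generate_office_plan`."""
    try:
        return dict(_TABLE_INTENSITIES[plan.name])
    except KeyError:
        raise ValueError(
            f"no default intensities for plan {plan.name!r}; supply zone_intensities"
        ) from None


@dataclass
class VideoSimConfig:
    """Configuration of the person-detection log simulator.

    ``zone_intensities`` maps zone labels to the mean detections per slot —
    a scalar, or a per-slot sequence to plant time-of-day structure (e.g. a
    lunchtime peak). Counts are Poisson per (zone, day, slot).
    """

    zone_intensities: Mapping[str, float | Sequence[float]]
    n_days: int = 3
    slot_len: int = 15
    record_start: time = time(10, 0)
    record_end: time = time(17, 0)
    base_date: date = date(2018, 7, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.record_end <= self.record_start:
            raise ValueError("record_end must be after record_start")
        span = (self.record_end.hour * 60 + self.record_end.minute) - (
            self.record_start.hour * 60 + self.record_start.minute
        )
        if span % self.slot_len != 0:
            raise ValueError("recording window must be divisible by slot length")
        for label, lam in self.zone_intensities.items():
            if np.any(np.asarray(lam, dtype=float) < 0):
                raise ValueError(f"intensity for {label!r} must be non-negative")
        if self.n_days < 1:
            raise ValueError("n_days must be positive")

    @property
    def n_slots(self) -> int:
        span = (self.record_end.hour * 60 + self.record_end.minute) - (
            self.record_start.hour * 60 + self.record_start.minute
        )
        return span // self.slot_len


def _points_in(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points strictly inside a polygon via bounding-box rejection."""
    minx, miny, maxx, maxy = polygon.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(32, int(1.5 * (n - len(pts)) / max(polygon.area / ((maxx - minx) * (maxy - miny)), 1e-6)))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = shapely.contains_xy(polygon, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[inside]])
    return pts[:n]


def generate_detection_log(plan: OfficePlan, config: VideoSimConfig) -> pd.DataFrame:
    """Simulate a person-detection log over the recording window.

    Each record carries a timestamp within ``[record_start, record_end)`` on
    one of ``n_days`` simulated days and a coordinate strictly inside its
    source zone; per-zone per-slot counts are Poisson with the configured
    mean. Columns: day_index, timestamp, camera_id, x_m, y_m.
    """
    unknown = set(config.zone_intensities) - set(plan.labels)
    if unknown:
        raise ValueError(f"unknown zone label(s) in intensities: {sorted(unknown)}")
    n_slots = config.n_slots
    frames = []
    for z_idx, label in enumerate(plan.labels):
        if label not in config.zone_intensities:
            continue
        lam = np.broadcast_to(
            np.asarray(config.zone_intensities[label], dtype=float), (n_slots,)
        )
        rng = np.random.default_rng([config.seed, 401, z_idx])
        counts = rng.poisson(np.tile(lam, (config.n_days, 1)))
        total = int(counts.sum())
        if total == 0:
            continue
        pts = _points_in(plan.zone(label).polygon, total, rng)
        day_idx = np.repeat(
            np.arange(1, config.n_days + 1), counts.sum(axis=1)
        )
        slot_idx = np.concatenate(
            [np.repeat(np.arange(n_slots), counts[d]) for d in range(config.n_days)]
        )
        offset_s = rng.uniform(0, config.slot_len * 60, total).astype(int)
        start_s = config.record_start.hour * 3600 + config.record_start.minute * 60
        ts = (
            pd.to_datetime(config.base_date.isoformat())
            + pd.to_timedelta(day_idx - 1, unit="D")
            + pd.to_timedelta(start_s + slot_idx * config.slot_len * 60 + offset_s, unit="s")
        )
        frames.append(
            pd.DataFrame(
                {
                    "day_index": day_idx,
                    "timestamp": ts,
                    "camera_id": f"cam{z_idx + 1:02d}",
                    "x_m": pts[:, 0],
                    "y_m": pts[:, 1],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["day_index", "timestamp", "camera_id", "x_m", "y_m"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["day_index", "timestamp", "camera_id"], kind="stable").reset_index(
        drop=True
    )
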