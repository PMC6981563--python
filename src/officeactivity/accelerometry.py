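"""Accelerometer epoch processing: wear detection, intensity classification,
working-hours windowing, bout detection and per-day / per-phase summaries.

The device model is a hip-worn triaxial accelerometer reporting one MET value
per 60-s epoch. Intensity categories follow the standard occupational
cut-points: sedentary behaviour (SB) at <= 1.5 METs, light-intensity physical
activity (LPA) above 1.5 and below 3.0 METs, moderate-to-vigorous activity
(MVPA) at >= 3.0 METs. A MET of exactly 0 is the no-signal sentinel used by
the non-wear detector ("under the detectable intensity").

Durations measured on a workday are normalised to the standard working window
(8:40-17:20, 520 min = 8.67 h) as::

    min/working-hours = observed duration / wearing time * 520

so that, for any day, normalised SB + normalised total PA = 520 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityCategory",
    "WorkingWindow",
    "EpochSeries",
    "classify_epoch",
    "classify_mets",
    "find_runs",
    "detect_nonwear",
    "window_working_hours",
    "detect_prolonged_sb",
    "summarize_day",
    "summarize_days",
    "normalize_to_working_hours",
    "filter_valid_participants",
    "summarize_phase",
    "DAY_SUMMARY_METRICS",
]

#: MET cut-points (inclusive upper bound for SB, inclusive lower bound for MVPA).
SB_MAX_MET = 1.5
MVPA_MIN_MET = 3.0

#: Defaults of the processing rules.
NONWEAR_MIN_RUN = 20  # minutes below detectable intensity
PROLONGED_SB_MIN_RUN = 30  # minutes of uninterrupted SB
VALID_DAY_WEAR_MIN = 600  # >= 10 h all-day wear
MIN_VALID_DAYS = 4  # per working week


class IntensityCategory(IntEnum):
    """Per-epoch activity intensity category."""

    NONWEAR_CANDIDATE = 0
    SB = 1
    LPA = 2
    MVPA = 3


@dataclass(frozen=True)
class WorkingWindow:
    """Standard working hours, half-open ``[start, end)``.

    Defaults to the 8:40-17:20 company workday (520 min, 8.67 h).
    """

    start: time = time(8, 40)
    end: time = time(17, 20)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("working window start must precede end")

    @property
    def duration_min(self) -> int:
        start = self.start.hour * 60 + self.start.minute
        end = self.end.hour * 60 + self.end.minute
        return end - start

    @property
    def duration_h(self) -> float:
        return round(self.duration_min / 60.0, 2)


@dataclass
class EpochSeries:
    """One participant's 60-s MET epochs for one measurement phase.

    ``met == 0`` encodes "no signal" (below the device's detectable
    intensity); all other values are METs. Timestamps must be strictly
    increasing and 60 s apart within each calendar day.
    """

    participant_id: str
    group: str
    phase: str
    timestamps: pd.DatetimeIndex
    met: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.met = np.asarray(self.met, dtype=float)
        if len(self.timestamps) != len(self.met):
            raise ValueError("timestamps and met must have equal length")
        if np.any(self.met < 0):
            raise ValueError("MET values must be non-negative")
        if len(self.timestamps) > 1:
            same_day = self.timestamps[1:].normalize() == self.timestamps[:-1].normalize()
            deltas = np.diff(self.timestamps.asi8)
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.any(same_day & (deltas != 60_000_000_000)):
                raise ValueError("epochs within a day must be spaced 60 s apart")

    def __len__(self) -> int:
        return len(self.met)


def classify_epoch(met: float) -> IntensityCategory:
    """Classify a single epoch MET value.

    0 is the no-signal sentinel; (0, 1.5] is SB; (1.5, 3.0) is LPA
    (device output is continuous, so the nominal 1.6 lower bound is the
    open interval above the SB cut-point); >= 3.0 is MVPA.
    """
    if met < 0:
        raise ValueError(f"MET must be non-negative, got {met}")
    if met == 0:
        return IntensityCategory.NONWEAR_CANDIDATE
    if met <= SB_MAX_MET:
        return IntensityCategory.SB
    if met < MVPA_MIN_MET:
        return IntensityCategory.LPA
    return IntensityCategory.MVPA


def classify_mets(met: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_epoch`; returns ``IntensityCategory`` codes."""
    met = np.asarray(met, dtype=float)
    if np.any(met < 0):
        raise ValueError("MET values must be non-negative")
    out = np.full(met.shape, IntensityCategory.SB, dtype=np.int8)
    out[met == 0] = IntensityCategory.NONWEAR_CANDIDATE
    out[met > SB_MAX_MET] = IntensityCategory.LPA
    out[met >= MVPA_MIN_MET] = IntensityCategory.MVPA
    return out


def find_runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode an array: returns (start indices, lengths, values)."""
    values = np.asarray(values)
    if values.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int), values
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [values.size])))
    return starts, lengths, values[starts]


def detect_nonwear(
    series: EpochSeries, min_run: int = NONWEAR_MIN_RUN
) -> np.ndarray:
    """Per-epoch wear mask (True = worn).

    A maximal run of at least ``min_run`` consecutive no-signal (MET = 0)
    epochs is non-wear; shorter zero-runs remain wear. Runs never span a day
    boundary (days are the analysis unit).
    """
    wear = np.ones(len(series), dtype=bool)
    if len(series) == 0:
        return wear
    days = series.timestamps.normalize()
    zero = series.met == 0
    for day in pd.unique(days):
        idx = np.flatnonzero(days == day)
        starts, lengths, vals = find_runs(zero[idx])
        for s, l, v in zip(starts, lengths, vals):
            if v and l >= min_run:
                wear[idx[s : s + l]] = False
    return wear


def window_working_hours(
    series: EpochSeries, window: WorkingWindow | None = None
) -> EpochSeries:
    """Restrict a series to the working window by epoch start time, half-open."""
    window = window or WorkingWindow()
    mask = _window_mask(series.timestamps, window)
    return EpochSeries(
        participant_id=series.participant_id,
        group=series.group,
        phase=series.phase,
        timestamps=series.timestamps[mask],
        met=series.met[mask],
    )


def _window_mask(timestamps: pd.DatetimeIndex, window: WorkingWindow) -> np.ndarray:
    tod = timestamps.hour * 60 + timestamps.minute
    start = window.start.hour * 60 + window.start.minute
    end = window.end.hour * 60 + window.end.minute
    return np.asarray((tod >= start) & (tod < end))


@dataclass
class ProlongedSB:
    """Prolonged sedentary bouts: total minutes and (start, length) runs."""

    minutes: int
    bouts: list[tuple[int, int]] = field(default_factory=list)


def detect_prolonged_sb(
    categories: Sequence[int] | np.ndarray, min_run: int = PROLONGED_SB_MIN_RUN
) -> ProlongedSB:
    """Sum maximal SB runs of at least ``min_run`` epochs.

    ``categories`` is a per-epoch sequence aligned to one day (or one window
    of a day) in time order; any non-SB epoch — LPA, MVPA or non-wear — breaks
    a run.
    """
    cats = np.asarray(categories)
    is_sb = cats == IntensityCategory.SB
    starts, lengths, vals = find_runs(is_sb)
    bouts = [
        (int(s), int(l)) for s, l, v in zip(starts, lengths, vals) if v and l >= min_run
    ]
    return ProlongedSB(minutes=sum(l for _, l in bouts), bouts=bouts)


def _day_categories(met: np.ndarray, wear: np.ndarray) -> np.ndarray:
    """Categories used for summaries: worn zero-MET epochs count as SB.

    A zero-run shorter than the non-wear threshold is worn time below the
    detectable intensity, i.e. <= 1.5 METs, hence SB; this keeps
    SB + LPA + MVPA = wear minutes an exact identity.
    """
    cats = np.full(met.shape, IntensityCategory.NONWEAR_CANDIDATE, dtype=np.int8)
    cats[wear & (met <= SB_MAX_MET)] = IntensityCategory.SB
    cats[wear & (met > SB_MAX_MET) & (met < MVPA_MIN_MET)] = IntensityCategory.LPA
    cats[wear & (met >= MVPA_MIN_MET)] = IntensityCategory.MVPA
    return cats


DAY_SUMMARY_METRICS = (
    "wear_min",
    "sb_min",
    "lpa_min",
    "mvpa_min",
    "total_pa_min",
    "prolonged_sb_min",
)


def _window_metrics(cats: np.ndarray, prolonged_min_run: int) -> dict[str, int]:
    sb = int(np.sum(cats == IntensityCategory.SB))
    lpa = int(np.sum(cats == IntensityCategory.LPA))
    mvpa = int(np.sum(cats == IntensityCategory.MVPA))
    prolonged = detect_prolonged_sb(cats, min_run=prolonged_min_run).minutes
    return {
        "wear_min": sb + lpa + mvpa,
        "sb_min": sb,
        "lpa_min": lpa,
        "mvpa_min": mvpa,
        "total_pa_min": lpa + mvpa,
        "prolonged_sb_min": prolonged,
    }


def summarize_day(
    series: EpochSeries,
    window: WorkingWindow | None = None,
    nonwear_min: int = NONWEAR_MIN_RUN,
    prolonged_min: int = PROLONGED_SB_MIN_RUN,
    valid_day_min: int = VALID_DAY_WEAR_MIN,
) -> pd.DataFrame:
    """Per-calendar-day summary of one series.

    Returns one row per day with all-day and working-hours wear/SB/LPA/MVPA/
    total-PA/prolonged-SB minutes, a weekday flag, and the valid-day flag
    (all-day wear >= ``valid_day_min`` minutes, default 10 h).
    """
    window = window or WorkingWindow()
    wear = detect_nonwear(series, min_run=nonwear_min)
    days = series.timestamps.normalize()
    in_window = _window_mask(series.timestamps, window)
    rows = []
    for day in pd.unique(days):
        idx = np.flatnonzero(days == day)
        cats = _day_categories(series.met[idx], wear[idx])
        allday = _window_metrics(cats, prolonged_min)
        working = _window_metrics(cats[in_window[idx]], prolonged_min)
        date = pd.Timestamp(day)
        row = {
            "participant_id": series.participant_id,
            "group": series.group,
            "phase": series.phase,
            "date": date.date(),
            "weekday": date.weekday() < 5,
            "valid_day": allday["wear_min"] >= valid_day_min,
        }
        row.update({f"{k}_allday": v for k, v in allday.items()})
        row.update({f"{k}_working": v for k, v in working.items()})
        rows.append(row)
    columns = (
        ["participant_id", "group", "phase", "date", "weekday", "valid_day"]
        + [f"{m}_allday" for m in DAY_SUMMARY_METRICS]
        + [f"{m}_working" for m in DAY_SUMMARY_METRICS]
    )
    return pd.DataFrame(rows, columns=columns)


def summarize_days(
    series_collection: Iterable[EpochSeries],
    window: WorkingWindow | None = None,
    nonwear_min: int = NONWEAR_MIN_RUN,
    prolonged_min: int = PROLONGED_SB_MIN_RUN,
    valid_day_min: int = VALID_DAY_WEAR_MIN,
) -> pd.DataFrame:
    """Concatenate :func:`summarize_day` over a collection of series."""
    frames = [
        summarize_day(s, window, nonwear_min, prolonged_min, valid_day_min)
        for s in series_collection
    ]
    if not frames:
        return summarize_day(
            EpochSeries("", "", "", pd.DatetimeIndex([]), np.array([])), window
        )
    return pd.concat(frames, ignore_index=True)


def normalize_to_working_hours(
    observed_min: float, wearing_min: float, window: WorkingWindow | None = None
) -> float:
    """Rescale an observed duration to min/working-hours.

    ``observed / wearing * 520`` for the default window. Raises if the day
    has no wear time (such a day is already invalid upstream).
    """
    window = window or WorkingWindow()
    if wearing_min <= 0:
        raise ValueError("normalization undefined for zero wearing time")
    if observed_min < 0 or observed_min > wearing_min:
        raise ValueError("observed duration must lie in [0, wearing time]")
    return observed_min / wearing_min * window.duration_min


def filter_valid_participants(
    day_df: pd.DataFrame,
    min_valid_days: int = MIN_VALID_DAYS,
    rule: str = "per-week",
) -> set[tuple[str, str]]:
    """Retained (participant, phase) pairs under the valid-data rule.

    ``rule='per-week'`` (default): every covered Monday-Friday week must
    contain at least ``min_valid_days`` valid weekdays. ``rule='overall'``:
    at least ``min_valid_days`` valid weekdays over the whole wear period.
    Weekend days never count.
    """
    if rule not in ("per-week", "overall"):
        raise ValueError(f"unknown week rule: {rule!r}")
    retained: set[tuple[str, str]] = set()
    weekdays = day_df[day_df["weekday"]]
    for (pid, phase), grp in weekdays.groupby(["participant_id", "phase"]):
        if rule == "overall":
            if int(grp["valid_day"].sum()) >= min_valid_days:
                retained.add((pid, phase))
            continue
        weeks = pd.to_datetime(grp["date"]).dt.isocalendar()
        key = weeks["year"].astype(str) + "-W" + weeks["week"].astype(str)
        counts = grp.groupby(key.to_numpy())["valid_day"].sum()
        if len(counts) and (counts >= min_valid_days).all():
            retained.add((pid, phase))
    return retained


def _time_in_office_hours(entry_exit: pd.DataFrame) -> pd.Series:
    """Mean daily in-office hours per participant from an entry/exit log."""
    df = entry_exit.copy()
    entry = pd.to_datetime(df["entry_time"], format="mixed")
    exit_ = pd.to_datetime(df["exit_time"], format="mixed")
    if (exit_ <= entry).any():
        raise ValueError("exit time must be after entry time")
    df["hours"] = (exit_ - entry).dt.total_seconds() / 3600.0
    daily = df.groupby(["participant_id", "date"])["hours"].sum()
    return daily.groupby("participant_id").mean()


def summarize_phase(
    day_df: pd.DataFrame,
    entry_exit: pd.DataFrame | None = None,
    window: WorkingWindow | None = None,
    min_valid_days: int = MIN_VALID_DAYS,
    rule: str = "per-week",
) -> pd.DataFrame:
    """Per-participant per-phase summary over valid weekdays.

    All-day metrics are raw means (so SB + total PA = all-day wear time);
    working-hours metrics are normalised per day to min/working-hours and
    then averaged. Participants failing the valid-data rule are dropped.
    Adds ``time_in_office_h`` when an entry/exit log is supplied.
    """
    window = window or WorkingWindow()
    retained = filter_valid_participants(day_df, min_valid_days, rule)
    valid = day_df[day_df["weekday"] & day_df["valid_day"]]
    rows = []
    for (pid, group, phase), grp in valid.groupby(["participant_id", "group", "phase"]):
        if (pid, phase) not in retained:
            continue
        row: dict[str, object] = {
            "participant_id": pid,
            "group": group,
            "phase": phase,
            "n_valid_days": len(grp),
        }
        for m in DAY_SUMMARY_METRICS:
            row[f"{m}_allday"] = grp[f"{m}_allday"].mean()
            row[f"{m}_working"] = grp[f"{m}_working"].mean()
        norm_days = grp[grp["wear_min_working"] > 0]
        row["n_norm_days"] = len(norm_days)
        for m in DAY_SUMMARY_METRICS:
            if m == "wear_min":
                continue
            normed = [
                normalize_to_working_hours(o, w, window)
                for o, w in zip(norm_days[f"{m}_working"], norm_days["wear_min_working"])
            ]
            row[f"{m}_norm"] = float(np.mean(normed)) if normed else np.nan
        rows.append(row)
    if not rows:
        raise ValueError("no retained participants with valid days")
    out = pd.DataFrame(rows)
    if entry_exit is not None and len(entry_exit):
        hours = _time_in_office_hours(entry_exit).rename("time_in_office_h")
        out = out.merge(hours, left_on="participant_id", right_index=True, how="left")
    return out
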