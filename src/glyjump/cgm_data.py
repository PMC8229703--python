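"""Ingestion and day-level segmentation of continuous glucose monitoring traces.

CGM devices report interstitial glucose (mg/dL) every few minutes and
disconnect fairly often.  Everything downstream of this module works on a
uniform 1-minute grid: raw exports are linearly interpolated across short
gaps, long gaps are flagged as missing, and only calendar days with all
1440 minutes present are retained.  Maximal runs of consecutive complete
days form stand-alone groups that later stages treat independently, so no
input window or forecast target ever spans a sensor disconnection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

#: default CSV column names for CGM exports
DEFAULT_CGM_DIALECT: Mapping[str, str] = {
    "timestamp": "timestamp",
    "glucose": "glucose_mg_dl",
}

#: default CSV column names for physical-activity annotations
DEFAULT_ACTIVITY_DIALECT: Mapping[str, str] = {
    "start": "start",
    "end": "end",
    "type": "type",
}

PA_TYPES = ("aerobic", "anaerobic")


class CgmFormatError(ValueError):
    """A CGM or activity table could not be parsed."""


class InsufficientDataError(ValueError):
    """Too few records to carry out the requested operation."""


@dataclass(frozen=True)
class CgmSeries:
    """A glucose trace on a uniform 1-minute grid.

    ``values[i]`` is the glucose in mg/dL at ``start_time + i`` minutes;
    minutes with no reading carry ``missing_mask[i] = True`` (their value
    is NaN and never consumed downstream).
    """

    patient_id: str
    start_time: pd.Timestamp
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if values.ndim != 1 or mask.shape != values.shape:
            raise ValueError("values and missing_mask must be 1-D and equal length")
        start = pd.Timestamp(self.start_time)
        if start.second or start.microsecond or start.nanosecond:
            raise ValueError("start_time must have minute resolution")
        present = values[~mask]
        if present.size and (not np.all(np.isfinite(present)) or np.any(present <= 0)):
            raise ValueError("non-missing glucose values must be finite and > 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)
        object.__setattr__(self, "start_time", start)

    def __len__(self) -> int:
        return self.values.size

    def time_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="min")

    @property
    def end_time(self) -> pd.Timestamp:
        """Timestamp of the last grid minute."""
        return self.start_time + pd.Timedelta(minutes=len(self) - 1)

    def slice(self, start_idx: int, stop_idx: int) -> "CgmSeries":
        """Sub-series over grid positions ``[start_idx, stop_idx)``."""
        return replace(
            self,
            start_time=self.start_time + pd.Timedelta(minutes=start_idx),
            values=self.values[start_idx:stop_idx].copy(),
            missing_mask=self.missing_mask[start_idx:stop_idx].copy(),
        )


@dataclass(frozen=True)
class ActivityEvent:
    """A labelled exercise interval on the patient's timeline.

    The interval is closed: both ``start`` and ``end`` minutes count as
    physical activity.
    """

    start: pd.Timestamp
    end: pd.Timestamp
    pa_type: str

    def __post_init__(self) -> None:
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if not start < end:
            raise ValueError(f"activity start {start} must precede end {end}")
        if self.pa_type not in PA_TYPES:
            raise ValueError(f"pa_type must be one of {PA_TYPES}, got {self.pa_type!r}")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)


@dataclass(frozen=True)
class ContinuousDayGroup:
    """A maximal run of consecutive gap-free calendar days for one patient."""

    patient_id: str
    day_start_times: tuple
    series: CgmSeries

    def __post_init__(self) -> None:
        if self.series.missing_mask.any():
            raise ValueError("a continuous-day group must contain no missing samples")
        if len(self.series) % MINUTES_PER_DAY != 0 or len(self.series) == 0:
            raise ValueError("group length must be a positive multiple of 1440 minutes")
        days = tuple(pd.Timestamp(d) for d in self.day_start_times)
        if len(days) != len(self.series) // MINUTES_PER_DAY:
            raise ValueError("day_start_times inconsistent with series length")
        for a, b in zip(days, days[1:]):
            if b - a != pd.Timedelta(days=1):
                raise ValueError("days within a group must be consecutive")
        object.__setattr__(self, "day_start_times", days)

    @property
    def n_days(self) -> int:
        return len(self.day_start_times)

    @property
    def n_minutes(self) -> int:
        return len(self.series)


def read_cgm_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a CGM export into a time-sorted ``DataFrame`` (``time``, ``glucose``).

    Duplicate timestamps are collapsed to their mean, which makes the result
    independent of row order in the file.
    """
    dialect = dict(DEFAULT_CGM_DIALECT, **(dialect or {}))
    df = pd.read_csv(path)
    for key in ("timestamp", "glucose"):
        if dialect[key] not in df.columns:
            raise CgmFormatError(
                f"{path}: missing required column {dialect[key]!r} "
                f"(have {list(df.columns)})"
            )
    times = pd.to_datetime(df[dialect["timestamp"]], errors="coerce", format="mixed")
    if times.isna().any():
        row = int(times.index[times.isna()][0])
        raise CgmFormatError(f"{path}: unparseable timestamp in data row {row}")
    glucose = pd.to_numeric(df[dialect["glucose"]], errors="coerce")
    if glucose.isna().any():
        row = int(glucose.index[glucose.isna()][0])
        raise CgmFormatError(f"{path}: non-numeric glucose in data row {row}")
    out = (
        pd.DataFrame({"time": times, "glucose": glucose.astype(float)})
        .groupby("time", as_index=False)["glucose"]
        .mean()
        .sort_values("time", ignore_index=True)
    )
    return out


def read_activity_table(path, dialect: Mapping[str, str] | None = None) -> list[ActivityEvent]:
    """Read physical-activity annotations (start, end, aerobic/anaerobic)."""
    dialect = dict(DEFAULT_ACTIVITY_DIALECT, **(dialect or {}))
    df = pd.read_csv(path)
    for key in ("start", "end", "type"):
        if dialect[key] not in df.columns:
            raise CgmFormatError(f"{path}: missing required column {dialect[key]!r}")
    events = []
    for row, rec in df.iterrows():
        start = pd.to_datetime(rec[dialect["start"]], errors="coerce")
        end = pd.to_datetime(rec[dialect["end"]], errors="coerce")
        if pd.isna(start) or pd.isna(end):
            raise CgmFormatError(f"{path}: unparseable activity interval in data row {row}")
        events.append(ActivityEvent(start=start, end=end, pa_type=str(rec[dialect["type"]])))
    return events


def resample_to_minute_grid(
    records: pd.DataFrame,
    max_gap_minutes: int = 10,
    patient_id: str = "unknown",
) -> CgmSeries:
    """Put raw readings on a 1-minute grid by linear interpolation.

    Consecutive readings at most ``max_gap_minutes`` apart are bridged
    linearly (a single missed 5-minute sample is recoverable); longer
    intervals are treated as sensor disconnections and their interior
    minutes are marked missing.  Values at original reading minutes are
    preserved exactly.
    """
    if len(records) < 2:
        raise InsufficientDataError(
            f"patient {patient_id}: need at least 2 CGM records, got {len(records)}"
        )
    times = pd.to_datetime(records["time"]).dt.round("min")
    df = (
        pd.DataFrame({"time": times, "glucose": records["glucose"].astype(float)})
        .groupby("time", as_index=False)["glucose"]
        .mean()
        .sort_values("time", ignore_index=True)
    )
    t0 = df["time"].iloc[0]
    pos = ((df["time"] - t0).dt.total_seconds() // 60).astype(int).to_numpy()
    vals = df["glucose"].to_numpy()
    n = int(pos[-1]) + 1
    grid = np.arange(n)
    values = np.interp(grid, pos, vals)
    missing = np.zeros(n, dtype=bool)
    gaps = np.diff(pos)
    for i in np.nonzero(gaps > max_gap_minutes)[0]:
        missing[pos[i] + 1 : pos[i + 1]] = True
    values = values.copy()
    values[missing] = np.nan
    return CgmSeries(
        patient_id=patient_id, start_time=t0, values=values, missing_mask=missing
    )


def find_continuous_day_groups(series: CgmSeries) -> list[ContinuousDayGroup]:
    """Apply the continuous-24-h inclusion rule and group surviving days.

    A calendar day (midnight to midnight) is complete iff every one of its
    1440 minutes lies inside the series and carries a reading.  Maximal
    runs of consecutive complete days become one stand-alone group;
    incomplete days are discarded entirely.
    """
    if len(series) == 0:
        return []
    t0 = series.start_time
    first_midnight = t0.normalize()
    if first_midnight < t0:
        first_midnight += pd.Timedelta(days=1)
    complete_days: list[pd.Timestamp] = []
    day = first_midnight
    while True:
        start_idx = int((day - t0) / pd.Timedelta(minutes=1))
        stop_idx = start_idx + MINUTES_PER_DAY
        if stop_idx > len(series):
            break
        if not series.missing_mask[start_idx:stop_idx].any():
            complete_days.append(day)
        day += pd.Timedelta(days=1)

    groups: list[ContinuousDayGroup] = []
    run: list[pd.Timestamp] = []
    for d in complete_days:
        if run and d - run[-1] != pd.Timedelta(days=1):
            groups.append(_make_group(series, run))
            run = []
        run.append(d)
    if run:
        groups.append(_make_group(series, run))
    return groups


def _make_group(series: CgmSeries, days: Sequence[pd.Timestamp]) -> ContinuousDayGroup:
    start_idx = int((days[0] - series.start_time) / pd.Timedelta(minutes=1))
    stop_idx = start_idx + MINUTES_PER_DAY * len(days)
    return ContinuousDayGroup(
        patient_id=series.patient_id,
        day_start_times=tuple(days),
        series=series.slice(start_idx, stop_idx),
    )


def pa_mask(group: ContinuousDayGroup, events: Iterable[ActivityEvent]) -> np.ndarray:
    """Per-minute boolean mask: True where some activity interval covers the minute.

    Intervals are closed on both ends; overlapping events are unioned.
    Events entirely outside the group's timeline are ignored with a warning.
    """
    times = group.series.time_index()
    mask = np.zeros(len(times), dtype=bool)
    for ev in events:
        if ev.end < times[0] or ev.start > times[-1]:
            logger.warning(
                "activity event %s..%s (%s) lies outside group %s..%s; ignored",
                ev.start, ev.end, ev.pa_type, times[0], times[-1],
            )
            continue
        mask |= (times >= ev.start) & (times <= ev.end)
    return mask


def group_index(groups: Iterable[ContinuousDayGroup]) -> dict:
    """JSON-serializable index of surviving days per patient."""
    index: dict[str, list[list[str]]] = {}
    for g in groups:
        index.setdefault(g.patient_id, []).append(
            [d.strftime("%Y-%m-%d") for d in g.day_start_times]
        )
    return index


def write_group_index(groups: Iterable[ContinuousDayGroup], path) -> None:
    Path(path).write_text(json.dumps(group_index(groups), indent=2))
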