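"""Supervised pair construction and the chronological first-day split.

Within a gap-free group of ``N`` minutes, each minute ``t`` that has a full
``M``-minute history and a realized target at ``t + PH`` yields one training
pair: the input is the window ``[t - M + 1, t]`` (oldest first, current
value last) and the label is the glucose at ``t + PH``.  Offline training
uses only pairs whose target falls inside the first 24 h of the first
group, split chronologically 80/20 into train and validation — no
shuffling, so no future sample ever informs an earlier prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .cgm_data import ContinuousDayGroup, InsufficientDataError


class EmptyDatasetError(ValueError):
    """A group is too short to yield a single supervised pair."""


@dataclass(frozen=True)
class WindowedDataset:
    """Supervised (input window, future target) pairs from one gap-free group."""

    inputs: np.ndarray        # (n, M), row = [y(t-M+1) .. y(t)]
    targets: np.ndarray       # (n,), y(t + PH)
    anchor_times: pd.DatetimeIndex   # the t of each pair
    target_times: pd.DatetimeIndex   # t + PH
    series_start: pd.Timestamp       # first minute of the source group

    def __post_init__(self) -> None:
        n = self.inputs.shape[0]
        if self.targets.shape != (n,) or len(self.anchor_times) != n or len(self.target_times) != n:
            raise ValueError("inconsistent pair array lengths")
        if n > 1 and not (np.diff(self.anchor_times.asi8) > 0).all():
            raise ValueError("anchor times must be strictly increasing")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def M(self) -> int:
        return self.inputs.shape[1]

    def subset(self, idx) -> "WindowedDataset":
        return replace(
            self,
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            anchor_times=self.anchor_times[idx],
            target_times=self.target_times[idx],
        )


def build_supervised_windows(group, M: int = 10, PH: int = 30) -> WindowedDataset:
    """All valid (window, target) pairs of one group: ``N - PH - M + 1`` of them.

    Anchors run over ``t in [M, N - PH]`` (1-based): the window must not
    reach before the group start and the target must not reach past its end.
    ``group`` may be a :class:`ContinuousDayGroup` or any gap-free
    :class:`~glyjump.cgm_data.CgmSeries`.
    """
    if M < 1 or PH < 1:
        raise ValueError("M and PH must be >= 1")
    series = group.series if isinstance(group, ContinuousDayGroup) else group
    if series.missing_mask.any():
        raise ValueError("supervised windows require a gap-free series")
    values = series.values
    N = values.size
    if N < M + PH:
        raise EmptyDatasetError(
            f"group {series.patient_id} starting {series.start_time} "
            f"has {N} minutes; need at least M + PH = {M + PH}"
        )
    n_pairs = N - PH - M + 1
    windows = sliding_window_view(values, M)          # row k anchored at index k + M - 1
    anchors = np.arange(M - 1, N - PH)                # 0-based anchor indices
    times = series.time_index()
    return WindowedDataset(
        inputs=windows[:n_pairs].copy(),
        targets=values[anchors + PH].copy(),
        anchor_times=times[anchors],
        target_times=times[anchors + PH],
        series_start=times[0],
    )


def chronological_split(
    ds: WindowedDataset,
    first_day_minutes: int = 1440,
    train_fraction: float = 0.8,
) -> tuple[WindowedDataset, WindowedDataset]:
    """First-day pairs split chronologically into train and validation.

    Membership is keyed on the *target* time falling within the first
    ``first_day_minutes`` of the group, so no label leaks past the stated
    training day.  The earliest ``floor(train_fraction * count)`` pairs go
    to train, the remainder to validation.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie strictly in (0, 1), got {train_fraction}")
    offsets = (ds.target_times - ds.series_start) // pd.Timedelta(minutes=1)
    first_day = np.nonzero(np.asarray(offsets) < first_day_minutes)[0]
    if first_day.size < 2:
        raise InsufficientDataError(
            f"only {first_day.size} pairs target the first {first_day_minutes} minutes; need >= 2"
        )
    n_train = math.floor(train_fraction * first_day.size)
    if n_train == 0 or n_train == first_day.size:
        raise InsufficientDataError(
            f"split of {first_day.size} pairs at fraction {train_fraction} leaves an empty side"
        )
    return ds.subset(first_day[:n_train]), ds.subset(first_day[n_train:])
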