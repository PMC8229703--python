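"""The three training protocols: offline, online, and online with penalty.

Every protocol starts the same way: the network is trained once on the
first 24 h of the first continuous-day group (chronological 80/20
train/validation split, MSE loss, early stopping).  The protocols then
diverge over the remaining data:

* offline — weights are frozen; every later eligible timestamp is
  forecast with the one trained model.
* online — starting from the offline weights, the model forecasts each
  timestamp and, every ``update_cadence`` timestamps, takes a small
  clipped gradient step on the pairs drawn from the trailing 24 h of CGM
  (both window and target inside that span, so updates stay causal).
* online with penalty — identical, but the update loss weights each
  squared error by the piecewise penalty of its magnitude.

Training operates in standardized units: windows and targets are z-scored
with the mean and standard deviation of the first-day training split, and
predictions are mapped back to mg/dL.  On raw mg/dL inputs the squared
loss is so ill-conditioned (curvature ~ mean glucose squared) that a
first-order method at the stated learning rates cannot leave its clipping
limit cycle; standardization is the usual remedy and leaves the network
equation untouched.  Penalty weights are always computed on mg/dL errors.

Groups of continuous days are stand-alone: no window, target, or update
batch ever crosses a sensor gap.  Weights persist across groups.  The
first 24 h (the training day) is excluded from all test metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import jumpnet, losses
from .cgm_data import ActivityEvent, ContinuousDayGroup, pa_mask
from .jumpnet import JumpNetParams, TrainingHyperparams
from .supervision import WindowedDataset, build_supervised_windows, chronological_split

logger = logging.getLogger(__name__)

CONFIG_LABELS = ("offline", "online", "online-penalty")


class ProtocolError(RuntimeError):
    """The available data cannot support the requested protocol."""


@dataclass
class ProtocolConfig:
    """All knobs of the forecasting protocols (defaults are the study settings)."""

    PH: int = 30                     # prediction horizon, minutes
    M: int = 10                      # input window, minutes
    L: int = 4                       # hidden-layer width
    first_day_minutes: int = 1440
    train_fraction: float = 0.8
    online_window_minutes: int = 1440
    update_cadence: int = 5          # timestamps between online updates
    lr_offline: float = 0.1
    lr_online: float = 0.01
    clip_value: float | None = 0.3
    max_epochs: int = 500
    validation_check_every: int = 4
    patience_checks: int = 10
    online_epochs_per_update: int = 1
    penalty_enabled: bool = False
    biases_enabled: bool = False
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.PH, self.M, self.update_cadence) < 1:
            raise ValueError("PH, M and update_cadence must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    def offline_hyperparams(self) -> TrainingHyperparams:
        return TrainingHyperparams(
            learning_rate=self.lr_offline,
            max_epochs=self.max_epochs,
            clip_value=self.clip_value,
            validation_check_every=self.validation_check_every,
            patience_checks=self.patience_checks,
            seed=self.seed,
        )


@dataclass
class RunResult:
    """Per-timestamp forecasts of one patient under one protocol.

    ``times`` are the target timestamps (when each truth realizes);
    ``pa_flags`` mark forecasts whose target lies inside an activity
    interval.  ``params_init`` is the post-offline-training warm start and
    ``params_final`` the weights after the test sweep — identical for the
    frozen offline protocol.
    """

    patient_id: str
    label: str
    times: pd.DatetimeIndex
    anchor_times: pd.DatetimeIndex
    truths: np.ndarray
    predictions: np.ndarray
    pa_flags: np.ndarray
    group_ids: np.ndarray
    params_init: JumpNetParams
    params_final: JumpNetParams
    update_count: int = 0
    update_times: list = field(default_factory=list)
    update_max_target_times: list = field(default_factory=list)

    def __len__(self) -> int:
        return self.truths.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "truth_mg_dl": self.truths,
                "prediction_mg_dl": self.predictions,
                "pa_flag": self.pa_flags,
                "group_id": self.group_ids,
            }
        )


@dataclass(frozen=True)
class StandardScaler:
    """Shared z-scoring of windows and targets (identity when sd == 1, mu == 0)."""

    mu: float = 0.0
    sd: float = 1.0

    def transform(self, a):
        return (np.asarray(a, dtype=float) - self.mu) / self.sd

    def inverse(self, a):
        return self.mu + self.sd * np.asarray(a, dtype=float)

    def scale_dataset(self, ds: WindowedDataset) -> WindowedDataset:
        from dataclasses import replace
        return replace(ds, inputs=self.transform(ds.inputs), targets=self.transform(ds.targets))


@dataclass(frozen=True)
class WarmStart:
    """Offline-trained weights plus the scaler they were trained under."""

    params: JumpNetParams
    scaler: StandardScaler
    history: dict


def train_warm_start(
    groups: Sequence[ContinuousDayGroup], cfg: ProtocolConfig
) -> WarmStart:
    """Offline training on the first 24 h of the first group (shared by all protocols)."""
    if not groups:
        raise ProtocolError("no continuous-day groups available")
    first = groups[0]
    if first.n_minutes < cfg.first_day_minutes:
        raise ProtocolError(
            f"first group has {first.n_minutes} minutes; "
            f"the protocols need a full first day ({cfg.first_day_minutes})"
        )
    params0 = jumpnet.init_params(M=cfg.M, L=cfg.L, seed=cfg.seed)
    params0.biases_enabled = cfg.biases_enabled
    ds = build_supervised_windows(first, M=cfg.M, PH=cfg.PH)
    train, val = chronological_split(ds, cfg.first_day_minutes, cfg.train_fraction)
    if cfg.standardize:
        sd = float(train.inputs.std())
        scaler = StandardScaler(mu=float(train.inputs.mean()), sd=sd if sd > 0 else 1.0)
    else:
        scaler = StandardScaler()
    trained, history = jumpnet.train_offline(
        params0,
        scaler.scale_dataset(train),
        scaler.scale_dataset(val),
        cfg.offline_hyperparams(),
        loss="mse",
    )
    logger.info(
        "offline warm start: %d train / %d val pairs, stopped at epoch %s (best %s)",
        len(train), len(val), history.get("stopped_epoch"), history.get("best_epoch"),
    )
    return WarmStart(params=trained, scaler=scaler, history=history)


def _group_test_rows(group_index: int, ds: WindowedDataset, cfg: ProtocolConfig) -> np.ndarray:
    """Row indices of test pairs: in the first group, anchors past the training day."""
    if group_index == 0:
        # row r is anchored at in-group minute index r + M - 1 (0-based)
        first_row = cfg.first_day_minutes - (cfg.M - 1)
        return np.arange(max(0, first_row), len(ds))
    return np.arange(len(ds))


def _iter_group_data(
    groups: Sequence[ContinuousDayGroup],
    events: Iterable[ActivityEvent],
    cfg: ProtocolConfig,
):
    events = list(events)
    for gi, group in enumerate(groups):
        if len(group.series) < cfg.M + cfg.PH:
            logger.warning(
                "group %d of patient %s too short for any forecast; skipped",
                gi, group.patient_id,
            )
            continue
        ds = build_supervised_windows(group, M=cfg.M, PH=cfg.PH)
        rows = _group_test_rows(gi, ds, cfg)
        if rows.size == 0:
            continue
        mask = pa_mask(group, events)
        target_idx = rows + (cfg.M - 1) + cfg.PH
        yield gi, ds, rows, mask[target_idx]


def _collect(patient_id, label, pieces, params_init, params_final, updates=None) -> RunResult:
    times = pd.DatetimeIndex(np.concatenate([np.asarray(p["times"]) for p in pieces]))
    anchors = pd.DatetimeIndex(np.concatenate([np.asarray(p["anchors"]) for p in pieces]))
    updates = updates or {"count": 0, "times": [], "max_targets": []}
    return RunResult(
        patient_id=patient_id,
        label=label,
        times=times,
        anchor_times=anchors,
        truths=np.concatenate([p["truths"] for p in pieces]),
        predictions=np.concatenate([p["preds"] for p in pieces]),
        pa_flags=np.concatenate([p["pa"] for p in pieces]),
        group_ids=np.concatenate([np.full(p["truths"].size, p["gi"]) for p in pieces]),
        params_init=params_init,
        params_final=params_final,
        update_count=updates["count"],
        update_times=updates["times"],
        update_max_target_times=updates["max_targets"],
    )


def run_offline(
    groups: Sequence[ContinuousDayGroup],
    events: Iterable[ActivityEvent],
    cfg: ProtocolConfig,
    warm_start: WarmStart | None = None,
) -> RunResult:
    """Frozen-weights protocol: train once, forecast everything after day 1."""
    warm = warm_start if warm_start is not None else train_warm_start(groups, cfg)
    params, scaler = warm.params.copy(), warm.scaler
    pieces = []
    for gi, ds, rows, pa in _iter_group_data(groups, events, cfg):
        preds = scaler.inverse(jumpnet.forward(params, scaler.transform(ds.inputs[rows])))
        pieces.append(
            dict(gi=gi, times=ds.target_times[rows], anchors=ds.anchor_times[rows],
                 truths=ds.targets[rows], preds=np.atleast_1d(preds), pa=pa)
        )
    if not pieces:
        raise ProtocolError("no test timestamps beyond the training day")
    return _collect(groups[0].patient_id, "offline", pieces, params.copy(), params.copy())


def run_online(
    groups: Sequence[ContinuousDayGroup],
    events: Iterable[ActivityEvent],
    cfg: ProtocolConfig,
    penalty_enabled: bool | None = None,
    warm_start: WarmStart | None = None,
) -> RunResult:
    """Sliding-window protocol: forecast each timestamp, retrain every few.

    Every ``update_cadence``-th test timestamp t triggers
    ``online_epochs_per_update`` clipped gradient passes (learning rate
    ``lr_online``) over the pairs whose window and target both lie in the
    trailing ``online_window_minutes`` of CGM ending at t.  After a sensor
    gap, forecasting resumes as soon as an M-history exists but updates
    wait until the trailing window has refilled inside the new group.
    """
    if penalty_enabled is None:
        penalty_enabled = cfg.penalty_enabled
    warm = warm_start if warm_start is not None else train_warm_start(groups, cfg)
    params, scaler = warm.params.copy(), warm.scaler
    params_init = params.copy()

    W, PH, M = cfg.online_window_minutes, cfg.PH, cfg.M
    counter = 0
    updates = {"count": 0, "times": [], "max_targets": []}
    pieces = []
    for gi, ds, rows, pa in _iter_group_data(groups, events, cfg):
        zds = scaler.scale_dataset(ds)
        preds = np.empty(rows.size)
        i = 0
        while i < rows.size:
            take = cfg.update_cadence - (counter % cfg.update_cadence)
            chunk = rows[i : i + take]
            preds[i : i + chunk.size] = scaler.inverse(
                np.atleast_1d(jumpnet.forward(params, zds.inputs[chunk]))
            )
            i += chunk.size
            counter += chunk.size
            if counter % cfg.update_cadence != 0:
                continue   # group ended mid-stride; cadence carries over
            a = int(chunk[-1]) + (M - 1)       # in-group anchor index of the update instant
            if a < W - 1:
                continue   # trailing window not yet refilled inside this group
            r_lo, r_hi = max(0, a - W + 1), a - PH - M + 1
            if r_hi < r_lo:
                continue
            Xw, yw = zds.inputs[r_lo : r_hi + 1], zds.targets[r_lo : r_hi + 1]
            for _ in range(cfg.online_epochs_per_update):
                e = yw - jumpnet.forward(params, Xw)
                # penalty thresholds are mg/dL, so weights come from unscaled errors
                w = losses.penalty(scaler.sd * e) if penalty_enabled else None
                grads = jumpnet.weighted_sse_gradients(params, Xw, yw, w)
                if cfg.clip_value is not None:
                    grads = jumpnet.clip_gradients(grads, cfg.clip_value)
                params = jumpnet.sgd_step(params, grads, cfg.lr_online)
            updates["count"] += 1
            updates["times"].append(ds.anchor_times[int(chunk[-1])])
            updates["max_targets"].append(ds.target_times[r_hi])
        pieces.append(
            dict(gi=gi, times=ds.target_times[rows], anchors=ds.anchor_times[rows],
                 truths=ds.targets[rows], preds=preds, pa=pa)
        )
    if not pieces:
        raise ProtocolError("no test timestamps beyond the training day")
    label = "online-penalty" if penalty_enabled else "online"
    return _collect(groups[0].patient_id, label, pieces, params_init, params.copy(), updates)


def run_persistence(
    groups: Sequence[ContinuousDayGroup],
    events: Iterable[ActivityEvent],
    cfg: ProtocolConfig,
) -> RunResult:
    """Naive baseline yhat(t + PH) = y(t) on the same test timestamps."""
    dummy = jumpnet.init_params(M=cfg.M, L=cfg.L, seed=cfg.seed)
    pieces = []
    for gi, ds, rows, pa in _iter_group_data(groups, events, cfg):
        pieces.append(
            dict(gi=gi, times=ds.target_times[rows], anchors=ds.anchor_times[rows],
                 truths=ds.targets[rows], preds=ds.inputs[rows, -1].copy(), pa=pa)
        )
    if not pieces:
        raise ProtocolError("no test timestamps beyond the training day")
    return _collect(groups[0].patient_id, "persistence", pieces, dummy, dummy)


def compare_configurations(
    groups: Sequence[ContinuousDayGroup],
    events: Iterable[ActivityEvent],
    cfg: ProtocolConfig,
) -> tuple[dict, pd.DataFrame]:
    """Run all three protocols from one shared warm start; tabulate their RMSEs."""
    from . import evaluation

    events = list(events)
    warm = train_warm_start(groups, cfg)
    results = {
        "offline": run_offline(groups, events, cfg, warm_start=warm),
        "online": run_online(groups, events, cfg, penalty_enabled=False, warm_start=warm),
        "online-penalty": run_online(groups, events, cfg, penalty_enabled=True, warm_start=warm),
    }
    pa_types = {ev.pa_type for ev in events}
    pa_type = pa_types.pop() if len(pa_types) == 1 else "mixed"
    table = evaluation.render_comparison(
        *([evaluation.summarize_run(results[label], pa_type)] for label in CONFIG_LABELS)
    )
    return results, table
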