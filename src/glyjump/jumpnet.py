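"""The jump feed-forward network and its gradient-descent training.

The forecaster maps the last M minutes of glucose I(t) to the value PH
minutes ahead:

    yhat(t + PH | t) = IOW . I(t)' + HOW . tanh(IHW . I(t)')

IOW are "jump" weights wiring every input directly to the output neuron
(the linear part of the response); IHW / HOW route the input through a
single hidden layer of L tangent-sigmoid neurons (the nonlinear part).
Bias terms exist but are disabled by default, matching the bias-free
written form; enabling ``biases_enabled`` makes them trainable.

Training is plain full-batch gradient descent on a (optionally
sample-weighted) mean squared error, with elementwise gradient clipping
and early stopping on validation MSE.  Everything is deterministic given
the seed, which keeps offline/online protocol comparisons exactly
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import losses
from .supervision import WindowedDataset


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


@dataclass
class JumpNetParams:
    """Weight sets of the jump network (shapes keyed on L hidden, M inputs)."""

    IHW: np.ndarray            # (L, M) input -> hidden
    HOW: np.ndarray            # (L,)   hidden -> output
    IOW: np.ndarray            # (M,)   input -> output (the jump path)
    hidden_bias: np.ndarray    # (L,)
    output_bias: float = 0.0
    biases_enabled: bool = False

    def __post_init__(self) -> None:
        self.IHW = np.asarray(self.IHW, dtype=float)
        self.HOW = np.asarray(self.HOW, dtype=float)
        self.IOW = np.asarray(self.IOW, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        L, M = self.IHW.shape
        if self.HOW.shape != (L,) or self.IOW.shape != (M,) or self.hidden_bias.shape != (L,):
            raise ValueError("parameter shapes inconsistent with (L, M)")
        for arr in (self.IHW, self.HOW, self.IOW, self.hidden_bias):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def L(self) -> int:
        return self.IHW.shape[0]

    @property
    def M(self) -> int:
        return self.IHW.shape[1]

    def copy(self) -> "JumpNetParams":
        return replace(
            self,
            IHW=self.IHW.copy(),
            HOW=self.HOW.copy(),
            IOW=self.IOW.copy(),
            hidden_bias=self.hidden_bias.copy(),
        )

    def to_json(self, path=None) -> str:
        payload = {
            "IHW": self.IHW.tolist(),
            "HOW": self.HOW.tolist(),
            "IOW": self.IOW.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_bias": self.output_bias,
            "biases_enabled": self.biases_enabled,
            "L": self.L,
            "M": self.M,
            "activation": "tanh",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "JumpNetParams":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            IHW=np.array(d["IHW"], dtype=float),
            HOW=np.array(d["HOW"], dtype=float),
            IOW=np.array(d["IOW"], dtype=float),
            hidden_bias=np.array(d["hidden_bias"], dtype=float),
            output_bias=float(d.get("output_bias", 0.0)),
            biases_enabled=bool(d.get("biases_enabled", False)),
        )


@dataclass
class JumpNetGrads:
    """Gradients, one array per weight set (same shapes as the parameters)."""

    IHW: np.ndarray
    HOW: np.ndarray
    IOW: np.ndarray
    hidden_bias: np.ndarray
    output_bias: float


@dataclass
class TrainingHyperparams:
    learning_rate: float
    max_epochs: int = 500
    clip_value: float | None = 0.3
    validation_check_every: int = 4
    patience_checks: int = 10
    batch_size: int | None = None    # None = full batch
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.validation_check_every < 1 or self.patience_checks < 1:
            raise ValueError("validation cadence and patience must be >= 1")
        if self.clip_value is not None and self.clip_value <= 0:
            raise ValueError("clip_value must be positive (or None to disable)")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def init_params(M: int = 10, L: int = 4, seed: int = 0) -> JumpNetParams:
    """Glorot-uniform weights (per weight set), zero biases, seed-deterministic."""
    if M < 1 or L < 1:
        raise ValueError("M and L must be >= 1")
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out, shape):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-bound, bound, size=shape)

    return JumpNetParams(
        IHW=glorot(M, L, (L, M)),
        HOW=glorot(L, 1, (L,)),
        IOW=glorot(M, 1, (M,)),
        hidden_bias=np.zeros(L),
    )


def forward(params: JumpNetParams, input_window) -> float | np.ndarray:
    """Network output for one M-window (scalar) or a batch of them (vector)."""
    X = np.asarray(input_window, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != params.M:
        raise ValueError(f"expected windows of length M={params.M}, got shape {X.shape}")
    h = np.tanh(X @ params.IHW.T + params.hidden_bias)
    out = X @ params.IOW + h @ params.HOW + params.output_bias
    return float(out[0]) if single else out


def weighted_sse_gradients(
    params: JumpNetParams,
    inputs,
    targets,
    sample_weights=None,
) -> JumpNetGrads:
    """Exact gradients of (1/N) sum_i w_i (y_i - yhat_i)^2.

    Sample weights are treated as constants (no gradient flows through the
    weight itself), which is what makes the penalty a per-sample weighting
    rather than part of the differentiated objective.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.atleast_1d(np.asarray(targets, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("batch must be nonempty")
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=float)
    z = X @ params.IHW.T + params.hidden_bias
    h = np.tanh(z)
    yhat = X @ params.IOW + h @ params.HOW + params.output_bias
    g = (-2.0 / n) * w * (y - yhat)          # dLoss/dyhat_i
    dIOW = X.T @ g
    dHOW = h.T @ g
    dz = g[:, None] * params.HOW[None, :] * (1.0 - h * h)
    dIHW = dz.T @ X
    if params.biases_enabled:
        dhb, dob = dz.sum(axis=0), float(g.sum())
    else:
        dhb, dob = np.zeros(params.L), 0.0
    return JumpNetGrads(IHW=dIHW, HOW=dHOW, IOW=dIOW, hidden_bias=dhb, output_bias=dob)


def clip_gradients(grads: JumpNetGrads, clip_value: float) -> JumpNetGrads:
    """Elementwise clamp of every gradient component into [-clip, +clip]."""
    if clip_value <= 0:
        raise ValueError("clip_value must be positive")
    c = clip_value
    return JumpNetGrads(
        IHW=np.clip(grads.IHW, -c, c),
        HOW=np.clip(grads.HOW, -c, c),
        IOW=np.clip(grads.IOW, -c, c),
        hidden_bias=np.clip(grads.hidden_bias, -c, c),
        output_bias=float(np.clip(grads.output_bias, -c, c)),
    )


def sgd_step(params: JumpNetParams, grads: JumpNetGrads, learning_rate: float) -> JumpNetParams:
    """One plain gradient-descent update; returns new parameters."""
    return replace(
        params,
        IHW=params.IHW - learning_rate * grads.IHW,
        HOW=params.HOW - learning_rate * grads.HOW,
        IOW=params.IOW - learning_rate * grads.IOW,
        hidden_bias=params.hidden_bias - learning_rate * grads.hidden_bias,
        output_bias=params.output_bias - learning_rate * grads.output_bias,
    )


def _epoch_weights(loss: str, errors: np.ndarray) -> np.ndarray | None:
    if loss == "mse":
        return None
    if loss == "penalized":
        return losses.penalty(errors)
    raise ValueError(f"unknown loss {loss!r}; expected 'mse' or 'penalized'")


def train_offline(
    params: JumpNetParams,
    train: WindowedDataset,
    val: WindowedDataset,
    hyper: TrainingHyperparams,
    loss: str = "mse",
) -> tuple[JumpNetParams, dict]:
    """Clipped gradient descent with early stopping on validation MSE.

    Validation is evaluated every ``validation_check_every`` epochs; after
    ``patience_checks`` consecutive checks without strict improvement the
    run stops and the parameters from the best check are returned.  Ties
    keep the earlier check.
    """
    hyper.validate()
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    _epoch_weights(loss, np.zeros(1))   # validate the loss name up front

    params = params.copy()
    rng = np.random.default_rng(hyper.seed)
    history: dict = {"train_loss": [], "val_checks": [], "best_epoch": None}
    best_params, best_val, bad = None, np.inf, 0

    for epoch in range(1, hyper.max_epochs + 1):
        if hyper.batch_size is None:
            batches = [np.arange(len(train))]
        else:
            order = rng.permutation(len(train))
            batches = np.array_split(order, max(1, int(np.ceil(len(train) / hyper.batch_size))))
        epoch_losses = []
        for idx in batches:
            X, y = train.inputs[idx], train.targets[idx]
            e = y - forward(params, X)
            w = _epoch_weights(loss, e)
            epoch_losses.append(np.mean(e * e if w is None else w * e * e))
            grads = weighted_sse_gradients(params, X, y, w)
            if hyper.clip_value is not None:
                grads = clip_gradients(grads, hyper.clip_value)
            try:
                params = sgd_step(params, grads, hyper.learning_rate)
            except ValueError as err:    # parameter validation: non-finite weights
                raise TrainingDivergedError(
                    f"non-finite parameters at epoch {epoch}"
                ) from err
        train_loss = float(np.mean(epoch_losses))
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(f"non-finite training loss at epoch {epoch}")
        history["train_loss"].append(train_loss)

        if epoch % hyper.validation_check_every == 0:
            val_mse = losses.mse(val.targets - forward(params, val.inputs))
            history["val_checks"].append((epoch, val_mse))
            if val_mse < best_val:
                best_val, best_params, bad = val_mse, params.copy(), 0
                history["best_epoch"] = epoch
            else:
                bad += 1
                if bad >= hyper.patience_checks:
                    break

    history["stopped_epoch"] = epoch
    return (best_params if best_params is not None else params), history
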