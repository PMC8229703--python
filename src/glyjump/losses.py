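"""Forecast error metrics and the piecewise error penalty.

The prediction error is e(t) = y(t) - yhat(t) (truth minus prediction,
mg/dL).  Training minimises its mean square; reporting uses the root mean
square.  The penalty-weighted variant scales each squared error by a
nonnegative weight that grows with the error magnitude, so the online
learner reacts rigidly to large misses and ignores small ones:

    weight = 0        for |e| <= 5 mg/dL
           = 1        for 5 < |e| <= 10
           = 2        for 10 < |e| <= 20
           = 0.5 |e|  for |e| > 20

By default the thresholds apply to |e|; the literal signed rule (under
which any large negative error would be un-penalised) is available via
``use_magnitude=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: breakpoints of the piecewise penalty, mg/dL
PENALTY_BREAKS = (5.0, 10.0, 20.0)
#: per-mg/dL slope of the top penalty branch
PENALTY_SLOPE = 0.5


@dataclass(frozen=True)
class PredictionErrorSeries:
    """e(t) = y(t) - yhat(t) with matching timestamps."""

    errors: np.ndarray
    times: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        errors = np.asarray(self.errors, dtype=float)
        if errors.ndim != 1 or errors.size == 0:
            raise ValueError("errors must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(errors)):
            raise ValueError("errors must be finite")
        if self.times is not None and len(self.times) != errors.size:
            raise ValueError("times and errors must have equal length")
        object.__setattr__(self, "errors", errors)

    def __len__(self) -> int:
        return self.errors.size


def error_series(truths, predictions, times=None) -> PredictionErrorSeries:
    """Elementwise truth minus prediction."""
    truths = np.asarray(truths, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if truths.shape != predictions.shape:
        raise ValueError(
            f"shape mismatch: truths {truths.shape} vs predictions {predictions.shape}"
        )
    return PredictionErrorSeries(errors=truths - predictions, times=times)


def _as_errors(errs) -> np.ndarray:
    e = errs.errors if isinstance(errs, PredictionErrorSeries) else np.asarray(errs, dtype=float)
    if e.size == 0:
        raise ValueError("cannot compute a metric of an empty error sequence")
    return e


def mse(errs) -> float:
    """Mean squared error, (mg/dL)^2."""
    e = _as_errors(errs)
    return float(np.mean(e * e))


def rmse(errs) -> float:
    """Root mean squared error, mg/dL."""
    return float(np.sqrt(mse(errs)))


def penalty(e, use_magnitude: bool = True):
    """Piecewise penalty weight of a prediction error (scalar or array).

    Boundary values take the lower branch: penalty(5) = 0, penalty(20) = 2.
    """
    arr = np.asarray(e, dtype=float)
    u = np.abs(arr) if use_magnitude else arr
    b1, b2, b3 = PENALTY_BREAKS
    out = np.select(
        [u <= b1, u <= b2, u <= b3],
        [0.0, 1.0, 2.0],
        default=PENALTY_SLOPE,
    )
    # the default branch multiplies by u afterwards so np.select stays scalar-safe
    top = u > b3
    out = np.where(top, PENALTY_SLOPE * u, out)
    return float(out) if np.isscalar(e) or arr.ndim == 0 else out


def penalized_loss(truths, predictions, use_magnitude: bool = True) -> float:
    """Mean of e(t)^2 * penalty(e(t)) over all timestamps."""
    e = error_series(truths, predictions).errors
    return float(np.mean(e * e * penalty(e, use_magnitude=use_magnitude)))
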