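"""Physical-activity-stratified RMSE reporting.

For each patient and protocol two numbers are reported: the RMSE pooled
over every test forecast ("total days") and the RMSE restricted to
forecasts whose target timestamp falls inside an activity interval
("PA").  Cohort rows are unweighted means across patients, overall and
within each activity stratum (aerobic / anaerobic).  Displayed values are
rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import losses
from .protocols import RunResult


@dataclass(frozen=True)
class PatientSummary:
    """Total-day and during-activity forecast RMSE for one patient."""

    patient_id: str
    pa_type: str
    rmse_total_days: float
    rmse_pa: float            # NaN when the patient has no PA forecasts
    n_predictions_total: int
    n_predictions_pa: int


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (20.75 -> 20.8), as opposed to banker's rounding."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_run(run: RunResult, pa_type: str) -> PatientSummary:
    """Pooled total-day RMSE and PA-only RMSE of one protocol run."""
    if len(run) == 0:
        raise ValueError("cannot summarize an empty run")
    errors = run.truths - run.predictions
    pa = np.asarray(run.pa_flags, dtype=bool)
    rmse_pa = losses.rmse(errors[pa]) if pa.any() else float("nan")
    return PatientSummary(
        patient_id=run.patient_id,
        pa_type=pa_type,
        rmse_total_days=losses.rmse(errors),
        rmse_pa=rmse_pa,
        n_predictions_total=int(errors.size),
        n_predictions_pa=int(pa.sum()),
    )


AVERAGE_ROWS = ("Average RMSE", "Average RMSE—AN", "Average RMSE—AE")
_STRATA = {"Average RMSE—AN": "anaerobic", "Average RMSE—AE": "aerobic"}


def aggregate_cohort(summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    """Per-patient table plus unweighted cohort averages (unrounded values).

    The bottom rows hold the mean RMSE over all patients and the mean
    PA RMSE within the anaerobic and aerobic strata.
    """
    if not summaries:
        raise ValueError("need at least one patient summary")
    rows = [
        {
            "patient_id": s.patient_id,
            "pa_type": s.pa_type,
            "rmse_total_days": s.rmse_total_days,
            "rmse_pa": s.rmse_pa,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows).set_index("patient_id")
    avg = {
        "patient_id": "Average RMSE",
        "pa_type": "-",
        "rmse_total_days": float(np.mean(df["rmse_total_days"])),
        "rmse_pa": float(np.nanmean(df["rmse_pa"])) if df["rmse_pa"].notna().any() else np.nan,
    }
    extra = [avg]
    for label, stratum in _STRATA.items():
        sub = df[df["pa_type"] == stratum]["rmse_pa"].dropna()
        if len(sub):
            extra.append(
                {"patient_id": label, "pa_type": "-",
                 "rmse_total_days": np.nan, "rmse_pa": float(sub.mean())}
            )
    return pd.concat([df, pd.DataFrame(extra).set_index("patient_id")])


def _fmt(x: float) -> str:
    return "-" if not np.isfinite(x) else f"{round_half_up(x, 1):.1f}"


def render_comparison(
    offline: Sequence[PatientSummary],
    online: Sequence[PatientSummary],
    online_penalty: Sequence[PatientSummary],
) -> pd.DataFrame:
    """Side-by-side table of the three protocols, one-decimal display rounding.

    Columns: total-day RMSE under each protocol, then PA RMSE under each;
    bottom rows are the cohort averages.  All three protocols must cover
    the same patients in the same order.
    """
    cols = {"offline": offline, "online": online, "online-penalty": online_penalty}
    ids = [s.patient_id for s in offline]
    for label, summaries in cols.items():
        if [s.patient_id for s in summaries] != ids:
            raise ValueError(f"patient set of {label!r} does not match the offline set")
    tables = {label: aggregate_cohort(s) for label, s in cols.items()}
    out = pd.DataFrame(index=tables["offline"].index)
    out["pa_type"] = tables["offline"]["pa_type"]
    for label, t in tables.items():
        out[f"total_{label}"] = t["rmse_total_days"].map(_fmt)
    for label, t in tables.items():
        out[f"pa_{label}"] = t["rmse_pa"].map(_fmt)
    return out


def plot_run_comparison(runs: dict, events=(), path=None, day: int | None = None):
    """Truth vs the prediction tracks of each protocol, activity shaded.

    ``day`` restricts the plot to one calendar day of the test span.
    Returns the matplotlib figure (saved to ``path`` when given).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    first = next(iter(runs.values()))
    sel = np.ones(len(first), dtype=bool)
    if day is not None:
        days = pd.DatetimeIndex(first.times).normalize()
        sel = days == sorted(set(days))[day]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(first.times[sel], first.truths[sel], color="crimson", lw=1.5, label="CGM")
    for label, run in runs.items():
        ax.plot(run.times[sel], run.predictions[sel], lw=1.0, label=label)
    lo, hi = first.times[sel].min(), first.times[sel].max()
    for ev in events:
        if ev.end >= lo and ev.start <= hi:
            ax.axvspan(ev.start, ev.end, color="0.85", zorder=0)
    ax.set_ylabel("glucose (mg/dL)")
    ax.legend(loc="upper right", fontsize=8)
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig
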