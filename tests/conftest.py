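import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import glyjump as gj

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

START = pd.Timestamp("2024-03-01")


def make_series(values, start=START, patient_id="p1", missing=None):
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.size, dtype=bool) if missing is None else np.asarray(missing, bool)
    vals = values.copy()
    vals[mask] = np.nan
    return gj.CgmSeries(patient_id=patient_id, start_time=start, values=vals, missing_mask=mask)


def make_group(values, start=START, patient_id="p1"):
    """Wrap a whole-day-multiple array of glucose values into a single group."""
    values = np.asarray(values, dtype=float)
    assert values.size % 1440 == 0
    n_days = values.size // 1440
    return gj.ContinuousDayGroup(
        patient_id=patient_id,
        day_start_times=tuple(start + pd.Timedelta(days=d) for d in range(n_days)),
        series=make_series(values, start=start, patient_id=patient_id),
    )


@pytest.fixture(scope="session")
def two_day_patient():
    """A 2-day low-noise synthetic patient: one group, one aerobic session on day 1."""
    cfg = gj.SimulationConfig(n_days=2, noise_sd=1.0, seed=11)
    series, events, truth = gj.simulate_patient(cfg)
    groups = gj.find_continuous_day_groups(series)
    assert len(groups) == 1 and groups[0].n_minutes == 2880
    return {"series": series, "events": events, "truth": truth, "groups": groups}


@pytest.fixture(scope="session")
def two_day_runs(two_day_patient):
    """Offline / online / persistence runs sharing one warm start (seed 11)."""
    cfg = gj.ProtocolConfig(seed=11)
    groups, events = two_day_patient["groups"], two_day_patient["events"]
    warm = gj.train_warm_start(groups, cfg)
    return {
        "cfg": cfg,
        "groups": groups,
        "events": events,
        "warm": warm,
        "offline": gj.run_offline(groups, events, cfg, warm_start=warm),
        "online": gj.run_online(groups, events, cfg, penalty_enabled=False, warm_start=warm),
        "persistence": gj.run_persistence(groups, events, cfg),
    }
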