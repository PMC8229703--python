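"""Phenomenological multi-day CGM simulator.

The private study data cannot be redistributed, so tests and examples run
on synthetic traces that reproduce the *statistical shape* the protocols
care about: a smooth baseline with a circadian swing, bi-exponential meal
excursions, glucose falls during aerobic exercise and rises during
anaerobic exercise (optionally preceded by a snack bump), AR(1)
autocorrelated sensor noise, hard clipping to the sensor range
40–400 mg/dL, and dropout intervals that exercise the continuous-24-h
day filter.  It is an additive component model, not a physiological
glucose–insulin ODE: adequate for testing forecasters, not for simulating
metabolism.

Component random streams are split from one seed in a fixed order
(meals, exercise, noise), so enabling or disabling one component never
perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cgm_data import MINUTES_PER_DAY, ActivityEvent, CgmSeries

#: minutes past which a meal excursion is treated as fully decayed
_MEAL_SPAN = 600


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that shapes one synthetic patient.

    Amplitudes are mg/dL, times and taus minutes.  ``pa_schedule`` entries
    are ``(day, start_minute, duration_minutes, pa_type)``; ``None`` means
    one 60-minute session of ``pa_type`` at 17:30 on every other day,
    which lands a multi-day patient inside the 2–8 events-per-patient
    range of a realistic sports cohort.  ``dropout_events`` entries are
    ``(day, start_minute, duration_minutes)``.
    """

    n_days: int = 10
    start_time: str = "2024-01-01"
    patient_id: str = "sim-001"
    baseline: float = 120.0
    circadian_amplitude: float = 15.0
    circadian_phase: int = 180
    meals_per_day: int = 3
    meal_times: tuple = (450, 750, 1140)     # 07:30, 12:30, 19:00
    meal_time_jitter: float = 30.0
    meal_amplitude: float = 60.0
    meal_amplitude_spread: float = 15.0
    meal_rise_tau: float = 20.0
    meal_decay_tau: float = 60.0
    pa_schedule: tuple | None = None
    pa_type: str = "aerobic"
    aerobic_drop_rate: float = 8.0           # mg/dL per 10 min of exercise
    anaerobic_rise: float = 30.0
    pre_exercise_snack: bool = False
    snack_amplitude: float = 20.0
    ar_coefficient: float = 0.8
    noise_sd: float = 3.0
    dropout_events: tuple = ()
    clip_range: tuple = (40.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range low must be below high")
        for amp in (self.circadian_amplitude, self.meal_amplitude, self.noise_sd,
                    self.aerobic_drop_rate, self.anaerobic_rise):
            if amp < 0:
                raise ValueError("amplitudes and rates must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free decomposition of a simulated trace."""

    noise_free: np.ndarray       # clip(baseline + circadian + meals + exercise)
    circadian: np.ndarray
    meals: np.ndarray
    exercise: np.ndarray
    noise: np.ndarray
    events: tuple


def meal_excursion(minutes_since_meal, amplitude: float, rise_tau: float, decay_tau: float):
    """Bi-exponential glucose bump, zero before the meal, peaking at ``amplitude``."""
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("taus must be positive")
    if rise_tau >= decay_tau:
        raise ValueError("rise_tau must be smaller than decay_tau")
    t = np.asarray(minutes_since_meal, dtype=float)
    t_peak = np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    norm = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    shape = np.exp(-np.maximum(t, 0.0) / decay_tau) - np.exp(-np.maximum(t, 0.0) / rise_tau)
    out = amplitude * np.where(t >= 0, shape / norm, 0.0)
    return float(out) if np.isscalar(minutes_since_meal) else out


def exercise_effect(
    minutes_since_start,
    duration: float,
    pa_type: str,
    aerobic_drop_rate: float = 8.0,
    anaerobic_rise: float = 30.0,
):
    """Glucose displacement of one exercise bout.

    Aerobic: linear fall at ``aerobic_drop_rate`` mg/dL per 10 min during
    the bout, then linear recovery back to zero over an equal span.
    Anaerobic: linear rise to ``+anaerobic_rise`` by mid-bout, hold until
    the end, then linear decay to zero within 120 min.
    """
    if duration <= 0:
        raise ValueError("event duration must be positive")
    t = np.asarray(minutes_since_start, dtype=float)
    if pa_type == "aerobic":
        drop_end = aerobic_drop_rate * duration / 10.0
        during = -aerobic_drop_rate * t / 10.0
        recovery = -drop_end * (1.0 - (t - duration) / duration)
        out = np.where(
            (t >= 0) & (t <= duration),
            during,
            np.where((t > duration) & (t <= 2 * duration), recovery, 0.0),
        )
    elif pa_type == "anaerobic":
        half = duration / 2.0
        rise = anaerobic_rise * t / half
        decay = anaerobic_rise * (1.0 - (t - duration) / 120.0)
        out = np.where(
            (t >= 0) & (t < half),
            rise,
            np.where(
                (t >= half) & (t <= duration),
                anaerobic_rise,
                np.where((t > duration) & (t <= duration + 120), decay, 0.0),
            ),
        )
    else:
        raise ValueError(f"unknown pa_type {pa_type!r}")
    return float(out) if np.isscalar(minutes_since_start) else out


def default_pa_schedule(cfg: SimulationConfig) -> tuple:
    """One 60-minute bout of ``cfg.pa_type`` at 17:30 on days 1, 3, 5, ..."""
    return tuple((day, 1050, 60, cfg.pa_type) for day in range(1, cfg.n_days, 2))


def ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with lag-1 autocorrelation phi and marginal sd."""
    if sd == 0.0:
        return np.zeros(n)
    innovations = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    return lfilter([1.0], [1.0, -phi], innovations)


def inject_dropouts(series: CgmSeries, dropout_events: Sequence[tuple]) -> CgmSeries:
    """Mark the listed (day, start_minute, duration) intervals as missing."""
    mask = series.missing_mask.copy()
    values = series.values.copy()
    for day, start, duration in dropout_events:
        lo = day * MINUTES_PER_DAY + int(start)
        hi = min(lo + int(duration), len(series))
        if lo < 0 or lo >= len(series):
            raise ValueError(f"dropout ({day}, {start}, {duration}) outside series span")
        mask[lo:hi] = True
        values[lo:hi] = np.nan
    return replace(series, values=values, missing_mask=mask)


def simulate_patient(cfg: SimulationConfig) -> tuple[CgmSeries, list[ActivityEvent], GroundTruth]:
    """Deterministically simulate one patient's minute-grid CGM trace."""
    n = cfg.n_days * MINUTES_PER_DAY
    t = np.arange(n, dtype=float)
    start = pd.Timestamp(cfg.start_time)
    meal_rng, exercise_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)
    )

    circadian = cfg.circadian_amplitude * np.sin(
        2.0 * np.pi * (t - cfg.circadian_phase) / MINUTES_PER_DAY
    )

    meals = np.zeros(n)
    for day in range(cfg.n_days):
        for k in range(cfg.meals_per_day):
            base_minute = cfg.meal_times[k % len(cfg.meal_times)]
            t_meal = day * MINUTES_PER_DAY + base_minute + meal_rng.uniform(
                -cfg.meal_time_jitter, cfg.meal_time_jitter
            )
            amp = max(0.0, cfg.meal_amplitude + meal_rng.uniform(
                -cfg.meal_amplitude_spread, cfg.meal_amplitude_spread
            ))
            lo = max(0, int(np.floor(t_meal)))
            hi = min(n, int(np.ceil(t_meal)) + _MEAL_SPAN)
            if lo < hi and amp > 0:
                meals[lo:hi] += meal_excursion(
                    t[lo:hi] - t_meal, amp, cfg.meal_rise_tau, cfg.meal_decay_tau
                )

    schedule = cfg.pa_schedule if cfg.pa_schedule is not None else default_pa_schedule(cfg)
    exercise = np.zeros(n)
    events: list[ActivityEvent] = []
    for day, start_minute, duration, pa_type in schedule:
        t0 = day * MINUTES_PER_DAY + int(start_minute)
        lo = max(0, t0)
        hi = min(n, t0 + int(duration) + max(2 * int(duration), 120) + 1)
        exercise[lo:hi] += exercise_effect(
            t[lo:hi] - t0, duration, pa_type,
            aerobic_drop_rate=cfg.aerobic_drop_rate,
            anaerobic_rise=cfg.anaerobic_rise,
        )
        if cfg.pre_exercise_snack and pa_type == "aerobic":
            s0 = max(0, t0 - 30)
            s_hi = min(n, s0 + _MEAL_SPAN)
            meals[s0:s_hi] += meal_excursion(
                t[s0:s_hi] - (t0 - 30.0), cfg.snack_amplitude,
                cfg.meal_rise_tau, cfg.meal_decay_tau,
            )
        events.append(
            ActivityEvent(
                start=start + pd.Timedelta(minutes=t0),
                end=start + pd.Timedelta(minutes=t0 + int(duration)),
                pa_type=pa_type,
            )
        )

    noise = ar1_noise(n, cfg.ar_coefficient, cfg.noise_sd, noise_rng)
    lo_clip, hi_clip = cfg.clip_range
    clean = cfg.baseline + circadian + meals + exercise
    values = np.clip(clean + noise, lo_clip, hi_clip)

    series = CgmSeries(
        patient_id=cfg.patient_id,
        start_time=start,
        values=values,
        missing_mask=np.zeros(n, dtype=bool),
    )
    if cfg.dropout_events:
        series = inject_dropouts(series, cfg.dropout_events)
    truth = GroundTruth(
        noise_free=np.clip(clean, lo_clip, hi_clip),
        circadian=circadian,
        meals=meals,
        exercise=exercise,
        noise=noise,
        events=tuple(events),
    )
    return series, events, truth
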