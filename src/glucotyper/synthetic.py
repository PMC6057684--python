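"""Synthetic multi-subject CGM cohorts with known variability regimes.

The generator is phenomenological: glucose(t) = regime baseline + circadian
sinusoid + a regime-characteristic train of pulses + additive AR(1) sensor
noise, clipped to the device reporting range [40, 400] mg/dL and sampled
every 5 minutes, with optional sensor dropout gaps.

The three regimes are stereotyped waveform classes rather than a single
shape at three amplitudes, because per-window z-scoring erases amplitude and
the clustering operates on shape alone:

* ``low`` — tight regulation: a fast, low-amplitude ultradian ripple
  (15-25 mg/dL bumps every 30 minutes). The ripple period is at most twice
  the Sakoe-Chiba band, so any two low windows align under banded DTW.
* ``moderate`` — broad single postprandial domes (40-60 mg/dL, ~1 h to
  peak) every 3 hours.
* ``severe`` — sharp high-amplitude spikes (80-120 mg/dL, ~20 min to peak)
  with a rebound undershoot, every 2.4 hours, as in dysglycemic responses
  with delayed counter-regulation.

Cohorts come with regime-correlated clinical records and standardized-meal
annotations so every pipeline stage is exercisable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from glucotyper.cgm_io import CGMSeries, ClinicalRecord, MealEvent

REGIMES = ("low", "moderate", "severe")

# standardized-meal pulse scaling relative to the subject's regime amplitude,
# graded by net carbohydrate content
MEAL_FACTORS = {
    "bread+peanut-butter": 0.8,
    "protein bar": 1.0,
    "cornflakes+milk": 1.3,
}


@dataclass
class RegimeDynamics:
    """Waveform parameters of one variability regime."""

    amplitude: tuple[float, float]  # uniform pulse-height range, mg/dL
    pulses_per_day: int
    peak_min: float  # time to pulse peak, minutes
    shape_sigma: float  # log-normal pulse width
    rebound: float  # undershoot depth as a fraction of pulse height
    baseline: float  # mg/dL
    circadian_amplitude: float  # mg/dL


DEFAULT_REGIMES: dict[str, RegimeDynamics] = {
    "low": RegimeDynamics((15.0, 25.0), 48, 15.0, 0.5, 0.0, 80.0, 5.0),
    "moderate": RegimeDynamics((40.0, 60.0), 8, 55.0, 0.6, 0.0, 90.0, 8.0),
    "severe": RegimeDynamics((80.0, 120.0), 10, 22.0, 0.35, 0.25, 120.0, 12.0),
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (glucose scales in mg/dL)."""

    n_subjects: int = 12
    days: float = 7.0
    seed: int = 0
    sampling_interval_min: float = 5.0
    regimes: dict[str, RegimeDynamics] = field(
        default_factory=lambda: dict(DEFAULT_REGIMES)
    )
    pulse_jitter_min: float = 5.0  # kept within the 10% DTW band (15 min)
    noise_sd: float = 4.0
    noise_rho: float = 0.7  # lag-1 autocorrelation of sensor noise
    gaps_per_day: float = 0.3
    gap_length_log_mean: float = np.log(20.0)  # minutes
    gap_length_log_sd: float = 0.6
    clip: tuple[float, float] = (40.0, 400.0)
    start_time: str = "2021-03-01 00:00"

    def __post_init__(self) -> None:
        for name, dyn in self.regimes.items():
            lo, hi = dyn.amplitude
            if lo <= 0 or hi < lo:
                raise ValueError(f"regime {name}: amplitude range must be positive and ordered")
            if dyn.pulses_per_day <= 0 or dyn.peak_min <= 0 or dyn.baseline <= 0:
                raise ValueError(f"regime {name}: scales must be positive")
        if self.noise_sd < 0 or not (0 <= self.noise_rho < 1):
            raise ValueError("invalid noise parameters")


def nearest_slot_min(offset_h: float, pulses_per_day: int) -> float:
    """Scheduled pulse time (minutes) nearest the requested hour offset."""
    spacing = 24.0 * 60 / pulses_per_day
    k = np.round(offset_h * 60 / spacing - 0.5)
    return float((k + 0.5) * spacing)


def _pulse_shape(t_min: np.ndarray, peak_min: float, sigma: float) -> np.ndarray:
    """Log-normal-shaped unit pulse: fast rise to a peak, slower decay."""
    out = np.zeros_like(t_min)
    pos = t_min > 0
    out[pos] = np.exp(-((np.log(t_min[pos] / peak_min)) ** 2) / (2 * sigma**2))
    return out


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(scale=sd * np.sqrt(1 - rho**2), size=n)
    x = np.empty(n)
    x[0] = rng.normal(scale=sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def simulate_subject(
    config: SimulationConfig,
    regime: str,
    seed: int,
    subject_id: str = "sim",
    standardized_meals: Sequence[tuple[str, float]] = (),
) -> tuple[CGMSeries, str]:
    """Simulate one subject's trace; returns (series, ground-truth regime).

    ``standardized_meals`` is a sequence of (meal_type, time offset in hours
    from the series start); each replaces the nearest scheduled pulse with
    one whose height is the regime's mean amplitude times the meal's
    net-carbohydrate factor.
    """
    if regime not in config.regimes:
        raise ValueError(f"regime {regime!r} not in {sorted(config.regimes)}")
    dyn = config.regimes[regime]
    rng = np.random.default_rng([int(seed), REGIMES.index(regime) if regime in REGIMES else 9])
    dt = config.sampling_interval_min
    total_min = config.days * 24 * 60
    n = int(round(total_min / dt))
    t_min = np.arange(n) * dt

    glucose = np.full(n, dyn.baseline, dtype=float)
    glucose += dyn.circadian_amplitude * np.sin(2 * np.pi * (t_min / 60 - 8.0) / 24.0)

    spacing = 24.0 * 60 / dyn.pulses_per_day
    n_pulses = int(np.ceil(total_min / spacing))
    pulse_times = (np.arange(n_pulses) + 0.5) * spacing + rng.uniform(
        -config.pulse_jitter_min, config.pulse_jitter_min, size=n_pulses
    )
    keep_p = (pulse_times >= 0) & (pulse_times < total_min)
    pulse_times = pulse_times[keep_p]
    lo, hi = dyn.amplitude
    amplitudes = rng.uniform(lo, hi, size=pulse_times.size)

    # standardized meals are eaten at the habitual (grid) mealtime nearest the
    # requested hour, so they perturb amplitude but not the pulse phase
    for meal_type, offset_h in standardized_meals:
        t_meal = nearest_slot_min(offset_h, dyn.pulses_per_day)
        if pulse_times.size:
            nearest = int(np.argmin(np.abs(pulse_times - t_meal)))
            pulse_times[nearest] = t_meal
            amplitudes[nearest] = 0.5 * (lo + hi) * MEAL_FACTORS[meal_type]

    for t0, amp in zip(pulse_times, amplitudes):
        glucose += amp * _pulse_shape(t_min - t0, dyn.peak_min, dyn.shape_sigma)
        if dyn.rebound > 0:
            glucose -= (
                dyn.rebound
                * amp
                * _pulse_shape(t_min - t0, dyn.peak_min * 3.0, 0.35)
            )

    glucose += _ar1(rng, n, config.noise_sd, config.noise_rho)
    glucose = np.clip(glucose, *config.clip)

    start = np.datetime64(pd.Timestamp(config.start_time), "ns")
    times = start + (t_min * 60_000_000_000).astype("timedelta64[ns]")

    # sensor dropout gaps
    keep = np.ones(n, dtype=bool)
    n_gaps = rng.poisson(config.gaps_per_day * config.days)
    total_gap = 0.0
    for _ in range(n_gaps):
        length = rng.lognormal(config.gap_length_log_mean, config.gap_length_log_sd)
        total_gap += length
        if total_gap > total_min / 2:
            raise ValueError("gap schedule infeasible: gaps cover more than half the trace")
        g0 = rng.uniform(0, total_min - length)
        keep &= ~((t_min >= g0) & (t_min < g0 + length))
    if not keep.any():
        raise ValueError("gap schedule removed every sample")
    series = CGMSeries(subject_id=subject_id, times=times[keep], glucose=glucose[keep])
    return series, regime


_CLINICAL_CENTERS = {
    # fbg, ogtt_2h, hba1c, sspg centers per regime (regime-correlated so that
    # diagnosis-vs-glucotype cross-tabulations have signal)
    "low": (88.0, 115.0, 5.2, 100.0),
    "moderate": (100.0, 155.0, 5.9, 160.0),
    "severe": (118.0, 205.0, 6.6, 230.0),
}


def simulate_cohort(
    config: SimulationConfig | None = None,
    regimes: Sequence[str] | None = None,
) -> dict:
    """Simulate a cohort: series, regime labels, clinical records, meal events.

    Regimes default to a balanced assignment over subjects. Each subject eats
    each standardized meal twice (breakfast on six consecutive days),
    mirroring a two-replicate standardized-meal design. Returns a dict with
    keys ``series``, ``regimes`` (subject_id -> regime), ``clinical``,
    ``meals``.
    """
    config = config or SimulationConfig()
    if config.n_subjects < 2:
        raise ValueError("need >= 2 subjects for clustering use")
    if regimes is None:
        regimes = [REGIMES[i % 3] for i in range(config.n_subjects)]
    if len(regimes) != config.n_subjects:
        raise ValueError("regimes length != n_subjects")
    rng = np.random.default_rng([int(config.seed), 977])
    series_list: list[CGMSeries] = []
    regime_map: dict[str, str] = {}
    clinical: list[ClinicalRecord] = []
    meals: list[MealEvent] = []
    meal_cycle = list(MEAL_FACTORS)  # 3 types, eaten twice each
    start = pd.Timestamp(config.start_time)
    for i, regime in enumerate(regimes):
        sid = f"S{i + 1:02d}"
        std_meals = []
        n_meal_days = min(6, int(config.days) - 1) if config.days >= 2 else 0
        for day in range(n_meal_days):
            meal_type = meal_cycle[day % 3]
            offset_h = day * 24 + 7.5  # breakfast
            std_meals.append((meal_type, offset_h))
        series, _ = simulate_subject(
            config, regime, seed=config.seed * 10_000 + i, subject_id=sid,
            standardized_meals=std_meals,
        )
        series_list.append(series)
        regime_map[sid] = regime
        reps: dict[str, int] = {}
        dyn = config.regimes[regime]
        for meal_type, offset_h in std_meals:
            reps[meal_type] = reps.get(meal_type, 0)
            eaten_min = nearest_slot_min(offset_h, dyn.pulses_per_day)
            meals.append(
                MealEvent(
                    subject_id=sid,
                    meal_type=meal_type,
                    timestamp=np.datetime64(start + pd.Timedelta(minutes=eaten_min), "ns"),
                    replicate_index=reps[meal_type],
                )
            )
            reps[meal_type] += 1
        fbg_c, ogtt_c, a1c_c, sspg_c = _CLINICAL_CENTERS.get(regime, (95.0, 140.0, 5.6, 150.0))
        clinical.append(
            ClinicalRecord(
                subject_id=sid,
                age=float(np.round(rng.uniform(25, 75), 1)),
                bmi=float(np.round(rng.normal(27, 4), 1)),
                hba1c=float(np.round(rng.normal(a1c_c, 0.15), 2)),
                fbg=float(np.round(rng.normal(fbg_c, 5), 1)),
                ogtt_2h=float(np.round(rng.normal(ogtt_c, 12), 1)),
                sspg=float(np.round(rng.normal(sspg_c, 30), 1)),
            )
        )
    return {
        "series": series_list,
        "regimes": regime_map,
        "clinical": clinical,
        "meals": meals,
    }
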