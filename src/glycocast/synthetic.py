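"""Synthetic labeled CGM cohorts with the statistical structure the method assumes.

The generator produces 14-day, 96-readings/day glucose traces whose mean level
tracks HbA1c through the ADAG linear map (mean BG = 28.7 x HbA1c - 46.7 mg/dL),
with three meal-time excursions per day (jittered morning / noon / evening
peaks), AR(1) sensor-scale noise whose amplitude grows with HbA1c, and
configurable point/block missingness.  Class-conditional mean glucose is
strictly increasing in class index — this is the signal the downstream
classifier must exploit; a cohort without it (shuffled labels) is the
negative control.

Meal excursions are centred to zero mean within each day so that the 24-hour
average stays on the ADAG line: HbA1c reflects average glucose by definition,
and postprandial peaks in real traces are balanced by lower fasting levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm import CGMSeries, HbA1cScheme, FOUR_CLASS, LabeledPatient, assign_class

__all__ = [
    "CohortSpec",
    "generate_patient",
    "generate_cohort",
    "inject_missingness",
    "adag_mean_glucose",
]

# ADAG regression of mean glucose (mg/dL) on HbA1c (%).
ADAG_SLOPE = 28.7
ADAG_INTERCEPT = -46.7

HBA1C_MIN, HBA1C_MAX = 5.0, 15.0
CLIP_LO, CLIP_HI = 40.0, 500.0


def adag_mean_glucose(hba1c_percent: float) -> float:
    """Estimated average glucose (mg/dL) for a given HbA1c (%)."""
    return ADAG_SLOPE * hba1c_percent + ADAG_INTERCEPT


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults give a realistically noisy but separable cohort: 60 mg/dL meal
    peaks with +/-45 min daily jitter, strongly autocorrelated AR(1) noise
    (15-minute lag-1 correlation 0.8), and glycemic variability that grows
    by 4 mg/dL innovation SD per HbA1c % above 6 — poorly controlled
    patients swing more, which is what makes CV informative.
    """

    n_per_class: int = 10
    scheme: HbA1cScheme = FOUR_CLASS
    days: int = 14
    meal_times: tuple = ("08:00", "13:00", "19:00")
    meal_amplitude_mgdl: float = 60.0
    meal_width_minutes: float = 40.0
    meal_jitter_minutes: float = 45.0
    noise_sd_mgdl: float = 8.0
    ar_coefficient: float = 0.8
    variability_slope: float = 4.0
    interval_minutes: int = 15
    adag_slope: float = ADAG_SLOPE
    adag_intercept: float = ADAG_INTERCEPT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.meal_amplitude_mgdl < 0 or self.noise_sd_mgdl < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.variability_slope < 0:
            raise ValueError("variability_slope must be >= 0")

    @property
    def slots_per_day(self) -> int:
        return 1440 // self.interval_minutes

    def meal_slots(self) -> np.ndarray:
        """Meal clock times as fractional slot positions."""
        out = []
        for t in self.meal_times:
            h, m = (int(p) for p in str(t).split(":"))
            out.append((h * 60 + m) / self.interval_minutes)
        return np.asarray(out, dtype=float)


def _daily_meal_profile(spec: CohortSpec, centers_slots: np.ndarray) -> np.ndarray:
    """Zero-mean within-day profile of Gaussian meal excursions."""
    spd = spec.slots_per_day
    t = np.arange(spd, dtype=float)
    width_slots = spec.meal_width_minutes / spec.interval_minutes
    profile = np.zeros(spd)
    for c in centers_slots:
        # wrap-around distance keeps late-evening bumps continuous at midnight
        d = np.minimum(np.abs(t - c), spd - np.abs(t - c))
        profile += spec.meal_amplitude_mgdl * np.exp(-0.5 * (d / width_slots) ** 2)
    return profile - profile.mean()


def generate_patient(
    hba1c_percent: float,
    spec: CohortSpec,
    seed: int,
    patient_id: str = "sim",
    start_time: str = "2020-01-01",
) -> CGMSeries:
    """Generate one complete synthetic series for a given HbA1c.

    The trace is baseline (ADAG map of HbA1c) + zero-mean daily meal
    excursions with per-day, per-meal timing jitter + AR(1) noise whose
    innovation SD is ``noise_sd + variability_slope * max(0, HbA1c - 6)``,
    clipped to [40, 500] mg/dL.  Deterministic given *seed*.
    """
    if not (HBA1C_MIN <= hba1c_percent <= HBA1C_MAX):
        raise ValueError(
            f"HbA1c must be in [{HBA1C_MIN:g}, {HBA1C_MAX:g}] %, got {hba1c_percent}"
        )
    rng = np.random.default_rng(seed)
    spd = spec.slots_per_day
    n = spec.days * spd
    baseline = spec.adag_slope * hba1c_percent + spec.adag_intercept

    meal_base = spec.meal_slots()
    jitter_slots = spec.meal_jitter_minutes / spec.interval_minutes
    days = []
    for _ in range(spec.days):
        centers = meal_base + rng.uniform(-jitter_slots, jitter_slots, meal_base.size)
        days.append(_daily_meal_profile(spec, centers))
    meals = np.concatenate(days) if days else np.zeros(0)

    sd = spec.noise_sd_mgdl + spec.variability_slope * max(0.0, hba1c_percent - 6.0)
    phi = spec.ar_coefficient
    innov = rng.normal(0.0, sd, n)
    noise = np.empty(n)
    prev = innov[0] / np.sqrt(1 - phi**2) if n else 0.0  # stationary start
    for i in range(n):
        prev = phi * prev + innov[i]
        noise[i] = prev

    values = np.clip(baseline + meals + noise, CLIP_LO, CLIP_HI)
    return CGMSeries(patient_id, pd.Timestamp(start_time), values, spec.interval_minutes)


def generate_cohort(spec: CohortSpec) -> list[LabeledPatient]:
    """Generate ``n_per_class`` labeled patients per class of the scheme.

    HbA1c is drawn uniformly inside each class range (clipped to the
    generator's [5, 15] support); labels are re-derived through
    :func:`assign_class` so label consistency holds by construction.
    """
    root = np.random.SeedSequence(spec.seed)
    patients: list[LabeledPatient] = []
    idx = 0
    for ci, (_, lo, hi) in enumerate(spec.scheme.classes):
        lo_c = max(lo, HBA1C_MIN)
        hi_c = min(hi, HBA1C_MAX)
        child = root.spawn(1)[0]
        rng = np.random.default_rng(child)
        seeds = child.spawn(spec.n_per_class)
        for j in range(spec.n_per_class):
            # strictly inside (lo_c, hi_c] so the label is unambiguous
            h = float(rng.uniform(lo_c, hi_c))
            if h <= lo:
                h = lo_c + 0.5 * (hi_c - lo_c)
            pid = f"sim{idx:04d}"
            series = generate_patient(
                h, spec, seed=int(np.random.default_rng(seeds[j]).integers(2**31)),
                patient_id=pid,
            )
            patients.append(LabeledPatient(series, h, assign_class(h, spec.scheme)))
            idx += 1
    return patients


def inject_missingness(
    series: CGMSeries,
    point_rate: float = 0.05,
    n_blocks: int = 0,
    block_len: int = 8,
    seed: int = 0,
) -> tuple[CGMSeries, np.ndarray]:
    """Mask random point and block gaps; return (gappy series, injected mask).

    ``round(point_rate * n_slots)`` single slots are masked uniformly at
    random, plus ``n_blocks`` contiguous runs of ``block_len`` slots
    (emulating sensor removal).  The returned boolean mask marks exactly the
    newly-missing slots so recovery error against the original is computable.
    """
    if not (0 <= point_rate < 1):
        raise ValueError("point_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(series.values)
    mask = np.zeros(n, dtype=bool)

    n_points = int(round(point_rate * n))
    if n_points:
        mask[rng.choice(n, size=n_points, replace=False)] = True
    for _ in range(n_blocks):
        start = int(rng.integers(0, max(1, n - block_len)))
        mask[start : start + block_len] = True

    values = series.values.copy()
    values[mask] = np.nan
    if np.all(np.isnan(values)):
        raise ValueError("injected missingness leaves no readings")
    return series.with_values(values), mask
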