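"""The 17 hand-crafted glycemic features computed directly from a CGM trace.

Features, in canonical order: three glucose-metabolising-capacity (GMC)
fractional-difference features of order 1, 1.5 and 2; four time-in-range
fractions (300-350, 70-180, 250-300, 180-250 mg/dL); the coefficient of
variability; integrated Welch spectral power; the low blood-glucose index
(LBGI); three Haar wavelet detail powers; and the mean readings at 10 AM,
8 PM, 9 AM and midnight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import welch

from .cgm import CGMSeries

__all__ = [
    "DSP_FEATURE_NAMES",
    "DSPFeatureVector",
    "gmc_feature",
    "tir",
    "cv",
    "psd_feature",
    "bg_risk_index",
    "haar_powers",
    "clock_time_features",
    "extract_dsp_vector",
]

DSP_FEATURE_NAMES = (
    "GMC_1",
    "GMC_1.5",
    "GMC_2",
    "TIR_300_350",
    "TIR_70_180",
    "TIR_250_300",
    "TIR_180_250",
    "CV",
    "PSD",
    "LGBI",
    "P_WD1",
    "P_WD2",
    "P_WD3",
    "BG_10AM",
    "BG_8PM",
    "BG_9AM",
    "BG_12AM",
)

# Clock times for the four time-of-day features, in canonical feature order.
CLOCK_TIMES = ((10, 0), (20, 0), (9, 0), (0, 0))


@dataclass(frozen=True)
class DSPFeatureVector:
    """The 17 features in canonical order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (17,):
            raise ValueError(f"expected 17 features, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("DSP features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DSP_FEATURE_NAMES, self.values))


def _complete_values(series: CGMSeries) -> np.ndarray:
    if not series.is_complete:
        raise ValueError("series has missing readings; impute first")
    return series.values


def gmc_feature(series: CGMSeries, k: float, h_hours: float | None = None) -> float:
    """Order-*k* fractional-difference feature, mean |GMC_i|.

    GMC_i = (BG_i - k * BG_{i+1}) / h^k with h the sampling step in hours
    (0.25 for the 15-minute grid).  For k = 1 this is a first difference
    (rate of change); non-integer k blends level and slope information.
    """
    x = _complete_values(series)
    if k <= 0 or (h_hours is not None and h_hours <= 0):
        raise ValueError("k and h_hours must be positive")
    if len(x) < 2:
        raise ValueError("need at least 2 readings")
    h = series.interval_minutes / 60.0 if h_hours is None else h_hours
    gmc = (x[:-1] - k * x[1:]) / h**k
    return float(np.mean(np.abs(gmc)))


def tir(series: CGMSeries, lo: float, hi: float) -> float:
    """Fraction of readings with lo <= x <= hi (both bounds inclusive)."""
    x = _complete_values(series)
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if len(x) == 0:
        raise ValueError("empty series")
    return float(np.count_nonzero((x >= lo) & (x <= hi)) / len(x))


def cv(series: CGMSeries) -> float:
    """Coefficient of variability: population SD divided by the mean."""
    x = _complete_values(series)
    m = x.mean()
    if m <= 0:
        raise ValueError("mean glucose must be positive")
    return float(x.std() / m)


def psd_feature(
    series: CGMSeries,
    band: tuple[float, float] | None = None,
    nperseg: int = 256,
) -> float:
    """Integrated Welch spectral power of the mean-removed trace.

    The periodogram uses Hann-windowed segments of ``nperseg`` samples with
    50% overlap; frequencies are in cycles/hour (the 15-minute grid samples
    at 4/hour).  Returns the power integrated over ``band`` (default: the
    full band up to Nyquist), which for the full band approximates the
    series variance.
    """
    x = _complete_values(series)
    if len(x) < nperseg:
        raise ValueError(f"need >= {nperseg} samples for the Welch estimate")
    fs = 60.0 / series.interval_minutes  # samples per hour
    f, pxx = welch(
        x - x.mean(), fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False,
    )
    if band is not None:
        sel = (f >= band[0]) & (f <= band[1])
        f, pxx = f[sel], pxx[sel]
    return float(np.trapezoid(pxx, f))


# Risk-curve constants: r(x) = 10 * g(x)^2 with
# g(x) = 1.509 * ((ln x)^1.084 - 5.381); g crosses zero near 112.9 mg/dL,
# negative below (hypoglycemic side), positive above (hyperglycemic side).
_RISK_SCALE = 1.509
_RISK_POWER = 1.084
_RISK_SHIFT = 5.381


def bg_risk_index(series: CGMSeries, side: str) -> float:
    """Low / high blood-glucose risk index.

    Averages the quadratic risk r(x) = 10 g(x)^2 over the whole series,
    counting only readings on the requested side of the risk curve's neutral
    point (g < 0 for ``side='low'``, g > 0 for ``side='high'``; the other
    readings contribute zero).  The canonical LBGI feature is the low side.
    """
    x = _complete_values(series)
    if np.any(x <= 0):
        raise ValueError("risk index requires positive readings")
    g = _RISK_SCALE * (np.log(x) ** _RISK_POWER - _RISK_SHIFT)
    r = 10.0 * g**2
    if side == "low":
        keep = g < 0
    elif side == "high":
        keep = g > 0
    else:
        raise ValueError("side must be 'low' or 'high'")
    return float(np.where(keep, r, 0.0).mean())


def haar_powers(series: CGMSeries) -> tuple[float, float, float]:
    """Mean squared Haar detail coefficients at decomposition levels 1-3.

    Uses the orthonormal (periodized) Haar transform of the mean-removed
    trace, so detail energies plus the final approximation energy sum to the
    total signal energy.
    """
    x = _complete_values(series)
    if len(x) < 8:
        raise ValueError("need >= 8 samples for a 3-level decomposition")
    coeffs = pywt.wavedec(x - x.mean(), "haar", level=3, mode="periodization")
    # coeffs = [cA3, cD3, cD2, cD1]
    d1, d2, d3 = coeffs[3], coeffs[2], coeffs[1]
    return (
        float(np.mean(d1**2)),
        float(np.mean(d2**2)),
        float(np.mean(d3**2)),
    )


def clock_time_features(series: CGMSeries) -> tuple[float, float, float, float]:
    """Mean reading across days at 10 AM, 8 PM, 9 AM and midnight."""
    x = _complete_values(series)
    G = x.reshape(series.n_days, series.slots_per_day)
    return tuple(
        float(G[:, series.slot_of_time(h, m)].mean()) for h, m in CLOCK_TIMES
    )


def extract_dsp_vector(series: CGMSeries) -> DSPFeatureVector:
    """All 17 features in canonical order."""
    p1, p2, p3 = haar_powers(series)
    clocks = clock_time_features(series)
    values = [
        gmc_feature(series, 1.0),
        gmc_feature(series, 1.5),
        gmc_feature(series, 2.0),
        tir(series, 300.0, 350.0),
        tir(series, 70.0, 180.0),
        tir(series, 250.0, 300.0),
        tir(series, 180.0, 250.0),
        cv(series),
        psd_feature(series),
        bg_risk_index(series, "low"),
        p1,
        p2,
        p3,
        *clocks,
    ]
    return DSPFeatureVector(np.asarray(values))
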