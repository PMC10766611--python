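"""Core CGM domain types: gridded glucose series, HbA1c class schemes, CSV I/O.

A continuous glucose monitor (CGM) samples interstitial glucose every 15
minutes, i.e. 96 readings per day.  All downstream stages operate on a
day x time-of-day grid: slot ``i`` of a series maps to day ``i // 96`` and
time-of-day slot ``i % 96``, with slot 0 at midnight.  Missing readings are
carried as NaN so the grid never loses alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CGMSeries",
    "HbA1cScheme",
    "FOUR_CLASS",
    "SIX_CLASS",
    "LabeledPatient",
    "assign_class",
    "read_cgm_csv",
    "write_cgm_csv",
    "read_labels_csv",
    "write_labels_csv",
    "window_series",
    "GLUCOSE_MIN",
    "GLUCOSE_MAX",
]

# Physiologically valid reporting range, mg/dL.  The upper edge matches the
# FreeStyle Libre display ceiling; readings outside are rejected on input.
GLUCOSE_MIN = 0.0
GLUCOSE_MAX = 600.0


@dataclass(frozen=True)
class CGMSeries:
    """One patient's glucose trace on the day x time-of-day grid.

    Parameters
    ----------
    patient_id
        Opaque identifier.
    start_time
        Timestamp of slot 0, aligned to a day boundary (midnight).
    values
        Glucose in mg/dL, one entry per 15-minute slot; NaN marks missing.
    interval_minutes
        Sampling step; 15 gives the canonical 96 slots/day.
    """

    patient_id: str
    start_time: pd.Timestamp
    values: np.ndarray
    interval_minutes: int = 15

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        ts = pd.Timestamp(self.start_time)
        object.__setattr__(self, "start_time", ts)
        if 1440 % self.interval_minutes != 0:
            raise ValueError("interval_minutes must divide 1440")
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(vals) % self.slots_per_day != 0:
            raise ValueError(
                f"series length {len(vals)} is not a whole number of days "
                f"({self.slots_per_day} slots/day)"
            )
        if ts != ts.normalize():
            raise ValueError("start_time must fall on a day boundary (midnight)")
        present = vals[~np.isnan(vals)]
        if present.size and (np.any(present <= GLUCOSE_MIN) or np.any(present > GLUCOSE_MAX)):
            raise ValueError(
                f"glucose values must lie in ({GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}] mg/dL"
            )

    @property
    def slots_per_day(self) -> int:
        return 1440 // self.interval_minutes

    @property
    def n_days(self) -> int:
        return len(self.values) // self.slots_per_day

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the reading is missing."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.values))

    def grid(self) -> np.ndarray:
        """Return the (n_days, slots_per_day) view of the values."""
        return self.values.reshape(self.n_days, self.slots_per_day)

    def with_values(self, values: np.ndarray) -> "CGMSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def slot_of_time(self, hour: int, minute: int = 0) -> int:
        """Time-of-day slot index for a clock time (e.g. 9:00 AM -> 36)."""
        return (hour * 60 + minute) // self.interval_minutes


@dataclass(frozen=True)
class HbA1cScheme:
    """Ordered partition of the HbA1c axis into control classes.

    Each class is a triple ``(label, lower_exclusive, upper_inclusive)`` in
    HbA1c %; the ranges are contiguous, lower-exclusive / upper-inclusive,
    and jointly cover (0, inf).
    """

    name: str
    classes: tuple  # of (label, lo_exclusive, hi_inclusive)

    def __post_init__(self) -> None:
        lo = 0.0
        for label, a, b in self.classes:
            if a != lo:
                raise ValueError(f"class {label}: ranges must be contiguous")
            if not (b > a):
                raise ValueError(f"class {label}: empty range")
            lo = b
        if not np.isinf(self.classes[-1][2]):
            raise ValueError("last class must be unbounded above")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def labels(self) -> list:
        return [c[0] for c in self.classes]

    def class_index(self, hba1c_percent: float) -> int:
        if not hba1c_percent > 0:
            raise ValueError(f"HbA1c must be positive, got {hba1c_percent}")
        for i, (_, a, b) in enumerate(self.classes):
            if a < hba1c_percent <= b:
                return i
        raise AssertionError("unreachable: scheme covers (0, inf)")


FOUR_CLASS = HbA1cScheme(
    "FOUR_CLASS",
    (
        ("C1 Good", 0.0, 7.5),
        ("C2 Medium", 7.5, 9.0),
        ("C3 Poor", 9.0, 12.5),
        ("C4 Uncontrolled", 12.5, np.inf),
    ),
)

SIX_CLASS = HbA1cScheme(
    "SIX_CLASS",
    (
        ("S1 Normal", 0.0, 6.5),
        ("S2 Good", 6.5, 7.5),
        ("S3 Average", 7.5, 8.25),
        ("S4 Medium", 8.25, 9.0),
        ("S5 Poor", 9.0, 10.5),
        ("S6 Uncontrolled", 10.5, np.inf),
    ),
)


def get_scheme(name: str) -> HbA1cScheme:
    """Look up a scheme by short name ('four'/'six') or full name."""
    key = name.strip().upper()
    if key in ("FOUR", "FOUR_CLASS", "4"):
        return FOUR_CLASS
    if key in ("SIX", "SIX_CLASS", "6"):
        return SIX_CLASS
    raise ValueError(f"unknown scheme {name!r}")


def assign_class(hba1c_percent: float, scheme: HbA1cScheme) -> int:
    """Map a clinical HbA1c (%) to its class index under *scheme*.

    Boundaries are upper-inclusive: 7.5% is Good in the four-class scheme,
    9.0% is Medium.
    """
    return scheme.class_index(hba1c_percent)


@dataclass(frozen=True)
class LabeledPatient:
    """A CGM series paired with its clinical HbA1c and class label."""

    series: CGMSeries
    hba1c_percent: float
    class_index: int

    @classmethod
    def from_hba1c(
        cls, series: CGMSeries, hba1c_percent: float, scheme: HbA1cScheme
    ) -> "LabeledPatient":
        return cls(series, hba1c_percent, assign_class(hba1c_percent, scheme))


# ---------------------------------------------------------------------------
# CSV input / output
#
# CGM CSV: header patient_id,timestamp,glucose_mg_dl with ISO-8601 timestamps.
# Labels CSV: header patient_id,hba1c_percent.
# ---------------------------------------------------------------------------

def read_cgm_csv(
    path,
    interval_minutes: int = 15,
    n_days: int | None = None,
) -> list[CGMSeries]:
    """Read per-patient CGM series from a long-format CSV.

    Timestamps are snapped to the nearest grid slot (tolerance half the
    sampling interval); multiple readings snapping to the same slot are
    averaged.  Slots with no reading are marked missing.  Glucose values
    outside (0, 600] mg/dL are dropped with a warning.

    Parameters
    ----------
    path
        CSV with columns ``patient_id,timestamp,glucose_mg_dl``.
    n_days
        Force every series to this many days (missing-padded / windowed);
        by default each patient spans their own observed day range.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "timestamp", "glucose_mg_dl"}
    if not required.issubset(df.columns):
        raise ValueError(f"CGM CSV must have columns {sorted(required)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = df.index[ts.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:20]]  # +2: header + 1-based
        raise ValueError(f"unparseable timestamps at CSV lines {lines}")
    glucose = pd.to_numeric(df["glucose_mg_dl"], errors="coerce")
    bad = df.index[glucose.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:20]]
        raise ValueError(f"unparseable glucose values at CSV lines {lines}")

    valid = (glucose > GLUCOSE_MIN) & (glucose <= GLUCOSE_MAX)
    n_rejected = int((~valid).sum())
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} glucose readings outside "
            f"({GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}] mg/dL",
            stacklevel=2,
        )
    df = df.loc[valid].copy()
    df["_ts"] = ts[valid]
    df["_glucose"] = glucose[valid]

    step = pd.Timedelta(minutes=interval_minutes)
    out: list[CGMSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        snapped = grp["_ts"].dt.round(step)
        day0 = snapped.min().normalize()
        slot = ((snapped - day0) / step).astype(int)
        per_slot = grp["_glucose"].groupby(slot.values).mean()
        spd = 1440 // interval_minutes
        total_days = int(per_slot.index.max()) // spd + 1
        values = np.full(total_days * spd, np.nan)
        values[per_slot.index.to_numpy()] = per_slot.to_numpy()
        series = CGMSeries(str(pid), day0, values, interval_minutes)
        if n_days is not None:
            series = window_series(series, n_days)
        out.append(series)
    return out


def write_cgm_csv(series_list: Iterable[CGMSeries], path) -> None:
    """Write series to the long-format CGM CSV (missing slots omitted)."""
    frames = []
    for s in series_list:
        idx = np.flatnonzero(~s.missing_mask)
        times = s.start_time + pd.to_timedelta(idx * s.interval_minutes, unit="m")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S"),
                    "glucose_mg_dl": s.values[idx],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_labels_csv(path) -> dict[str, float]:
    """Read ``patient_id,hba1c_percent`` into a dict."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not {"patient_id", "hba1c_percent"}.issubset(df.columns):
        raise ValueError("labels CSV must have columns patient_id,hba1c_percent")
    return dict(zip(df["patient_id"], df["hba1c_percent"].astype(float)))


def write_labels_csv(labels: dict[str, float], path) -> None:
    pd.DataFrame(
        {"patient_id": list(labels), "hba1c_percent": list(labels.values())}
    ).to_csv(path, index=False)


def window_series(series: CGMSeries, n_days: int = 14) -> CGMSeries:
    """Keep the most recent *n_days* whole days, preserving grid alignment."""
    if series.n_days < n_days:
        raise ValueError(
            f"series {series.patient_id!r} has {series.n_days} days, "
            f"{n_days} required"
        )
    if series.n_days == n_days:
        return series
    spd = series.slots_per_day
    skip = series.n_days - n_days
    return CGMSeries(
        series.patient_id,
        series.start_time + pd.Timedelta(days=skip),
        series.values[skip * spd :],
        series.interval_minutes,
    )
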