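"""Missing-reading estimation from the 8 grid-adjacent neighbors.

A glucose reading lives on a day x time-of-day grid, and is correlated both
with the readings directly before/after it and with readings at the same
clock time on adjacent days.  A single affine layer (8 inputs -> 1 output,
identity activation) is trained on standardized glucose to predict a reading
from its 8 grid neighbors; missing cells are then filled iteratively, and
cells the neighbor rule can never reach (grid edges, long gaps) fall back to
linear interpolation along the time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm import CGMSeries

__all__ = [
    "NeighborDataset",
    "ImputerModel",
    "build_neighbor_dataset",
    "fit_imputer",
    "impute_missing",
]

# Neighbor ordering: (day-1: slot-1, slot, slot+1), (day: slot-1, slot+1),
# (day+1: slot-1, slot, slot+1).
NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class NeighborDataset:
    """Training samples: 8 neighbor readings (mg/dL) and the center reading."""

    X: np.ndarray  # (n_samples, 8)
    y: np.ndarray  # (n_samples,)

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ImputerModel:
    """Affine 8->1 model on standardized glucose, plus the standardizer."""

    weights: np.ndarray  # (8,)
    bias: float
    mean: float
    sd: float

    def predict(self, neighbors_mgdl: np.ndarray) -> np.ndarray:
        """Predict center readings (mg/dL) from (n, 8) neighbor readings."""
        z = (np.asarray(neighbors_mgdl, dtype=float) - self.mean) / self.sd
        return (z @ self.weights + self.bias) * self.sd + self.mean


def build_neighbor_dataset(series_list) -> NeighborDataset:
    """Collect every present reading whose 8 grid neighbors are all present.

    Edge cells (first/last day, first/last slot of the day) have an off-grid
    neighbor and are excluded, so a complete 14-day series contributes
    (14-2) x (96-2) = 1128 samples.
    """
    Xs, ys = [], []
    for s in series_list:
        G = s.grid()
        d, w = G.shape
        if d < 3 or w < 3:
            continue
        center = G[1:-1, 1:-1]
        stack = np.stack(
            [G[1 + di : d - 1 + di, 1 + dj : w - 1 + dj] for di, dj in NEIGHBOR_OFFSETS],
            axis=-1,
        )  # (d-2, w-2, 8)
        ok = ~np.isnan(center) & ~np.isnan(stack).any(axis=-1)
        Xs.append(stack[ok])
        ys.append(center[ok])
    if not Xs or sum(len(y) for y in ys) == 0:
        raise ValueError(
            "no usable neighbor samples; provide more (or more complete) series"
        )
    return NeighborDataset(np.concatenate(Xs), np.concatenate(ys))


def fit_imputer(
    samples: NeighborDataset,
    val_fraction: float = 0.2,
    epochs: int = 200,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> tuple[ImputerModel, dict]:
    """Fit the one-layer imputer by full-batch gradient descent on MSE.

    Glucose is standardized by the training pool's mean/SD before fitting, so
    reported losses are in squared standardized units.  Returns the model and
    a history dict with per-epoch ``train_mse`` / ``val_mse`` (standardized)
    plus the same curves rescaled to mg^2/dL^2.

    Deterministic given *seed* (which controls only the train/validation
    split and the weight initialization).
    """
    if len(samples) < 100:
        raise ValueError(f"need >= 100 samples to fit the imputer, got {len(samples)}")
    rng = np.random.default_rng(seed)
    n = len(samples)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    mu = float(samples.y[train_idx].mean())
    sd = float(samples.y[train_idx].std())
    if sd == 0:
        sd = 1.0  # constant cohort: standardization degenerates to centering
    Xt = (samples.X[train_idx] - mu) / sd
    yt = (samples.y[train_idx] - mu) / sd
    Xv = (samples.X[val_idx] - mu) / sd
    yv = (samples.y[val_idx] - mu) / sd

    w = rng.normal(0.0, 0.01, 8)
    b = 0.0
    hist_train, hist_val = [], []
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(epochs):
            r = Xt @ w + b - yt
            grad_w = 2.0 * (Xt.T @ r) / len(yt)
            grad_b = 2.0 * float(r.mean())
            w -= learning_rate * grad_w
            b -= learning_rate * grad_b
            if not (np.all(np.isfinite(w)) and np.isfinite(b)):
                raise FloatingPointError(
                    "imputer training diverged; try a smaller learning_rate"
                )
            hist_train.append(float(np.mean((Xt @ w + b - yt) ** 2)))
            hist_val.append(
                float(np.mean((Xv @ w + b - yv) ** 2)) if len(yv) else float("nan")
            )
    history = {
        "train_mse": hist_train,
        "val_mse": hist_val,
        "train_mse_mgdl2": [m * sd**2 for m in hist_train],
        "val_mse_mgdl2": [m * sd**2 for m in hist_val],
    }
    return ImputerModel(w, float(b), mu, sd), history


def _neighbor_stack(G: np.ndarray) -> np.ndarray:
    """(d, w, 8) neighbor values for every cell; NaN where off-grid."""
    d, w = G.shape
    P = np.full((d + 2, w + 2), np.nan)
    P[1:-1, 1:-1] = G
    return np.stack(
        [P[1 + di : 1 + di + d, 1 + dj : 1 + dj + w] for di, dj in NEIGHBOR_OFFSETS],
        axis=-1,
    )


def impute_missing(
    series: CGMSeries, model: ImputerModel, max_rounds: int = 10
) -> CGMSeries:
    """Fill every missing cell; present readings are never altered.

    Rounds are Jacobi-style: each round fills all cells whose 8 neighbors are
    present in the previous round's grid simultaneously, so the result does
    not depend on cell order.  Cells still missing after ``max_rounds`` (or
    unreachable: edges, wide gaps) are linearly interpolated along the time
    axis, with forward/backward fill at the series ends.
    """
    if series.is_complete:
        return series
    G = series.grid().copy()
    for _ in range(max_rounds):
        missing = np.isnan(G)
        if not missing.any():
            break
        stack = _neighbor_stack(G)
        fillable = missing & ~np.isnan(stack).any(axis=-1)
        if not fillable.any():
            break
        pred = model.predict(stack[fillable])
        G = G.copy()
        G[fillable] = np.clip(pred, 1.0, 600.0)

    flat = G.reshape(-1)
    if np.isnan(flat).any():
        filled = (
            pd.Series(flat)
            .interpolate(method="linear", limit_direction="both")
            .to_numpy()
        )
        flat = filled
    return series.with_values(flat)
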