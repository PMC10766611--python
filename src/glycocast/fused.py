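"""Feature fusion, the FSLD pseudo-distance, and KNN classification.

The three per-patient representations — binary-image CNN features B (4096),
histogram-image CNN features H (4096) and the 17 standardized DSP features D
— are concatenated into an 8209-element vector I.  For a pair of patients
the element-wise FSLD transform

    FSLD(i1, i2) = 0                         if |i1 - i2| <= a
                 = |i1 - i2| / max(|i1|,|i2|)  otherwise

turns (I1, I2) into a normalized difference vector J, which a one-layer
logistic model maps to a pseudo-distance in (0, 1): trained toward 0 for
same-class pairs and 1 for different-class pairs.  A query is classified by
majority vote among the K = 10 gallery patients with the smallest learned
distance, with vote ties broken uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import nn

__all__ = [
    "FUSED_DIM",
    "Standardizer",
    "fuse",
    "fsld_elementwise",
    "fsld_transform",
    "DistanceModel",
    "train_distance_model",
    "knn_predict",
]

FUSED_DIM = 4096 + 4096 + 17  # 8209


@dataclass(frozen=True)
class Standardizer:
    """Column-wise zero-mean / unit-variance transform, fit on training data."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0)
        return cls(X.mean(axis=0), np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def fuse(
    B: np.ndarray | None,
    H: np.ndarray | None,
    D: np.ndarray | None,
    d_standardizer: Standardizer | None = None,
) -> np.ndarray:
    """Concatenate the selected channels in B, H, D order.

    With all three channels present the result has 8209 elements.  ``None``
    drops a channel (ablation mode).  DSP features are standardized before
    fusion when a standardizer is given, so the 17 clinical-scale features
    are commensurate with the CNN activations.
    """
    parts = []
    if B is not None:
        B = np.asarray(B, dtype=float).ravel()
        if B.size != 4096:
            raise ValueError(f"binary channel must have 4096 elements, got {B.size}")
        parts.append(B)
    if H is not None:
        H = np.asarray(H, dtype=float).ravel()
        if H.size != 4096:
            raise ValueError(f"histogram channel must have 4096 elements, got {H.size}")
        parts.append(H)
    if D is not None:
        D = np.asarray(D, dtype=float).ravel()
        if D.size != 17:
            raise ValueError(f"DSP channel must have 17 elements, got {D.size}")
        if d_standardizer is not None:
            D = d_standardizer.transform(D[None, :])[0]
        parts.append(D)
    if not parts:
        raise ValueError("at least one channel must be selected")
    out = np.concatenate(parts)
    if not np.all(np.isfinite(out)):
        raise ValueError("fused vector contains non-finite entries")
    return out


def fsld_elementwise(i1: float, i2: float, a: float) -> float:
    """Scalar FSLD: 0 if |i1-i2| <= a, else |i1-i2| / max(|i1|, |i2|)."""
    if a < 0:
        raise ValueError("threshold a must be >= 0")
    d = abs(i1 - i2)
    if d <= a:
        return 0.0
    m = max(abs(i1), abs(i2))
    return d / m if m > 0 else 0.0


def fsld_transform(I1: np.ndarray, I2: np.ndarray, a: float = 0.01) -> np.ndarray:
    """Element-wise FSLD over a pair of fused vectors."""
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if I1.shape != I2.shape:
        raise ValueError(f"shape mismatch: {I1.shape} vs {I2.shape}")
    if a < 0:
        raise ValueError("threshold a must be >= 0")
    d = np.abs(I1 - I2)
    m = np.maximum(np.abs(I1), np.abs(I2))
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where((d <= a) | (m == 0), 0.0, d / np.where(m == 0, 1.0, m))
    return J


@dataclass
class DistanceModel:
    """One-layer logistic pseudo-distance on FSLD-transformed vectors."""

    weights: np.ndarray
    bias: float
    threshold_a: float

    def logits(self, J: np.ndarray) -> np.ndarray:
        """Pre-sigmoid score; monotone in the distance and never saturates."""
        J = np.asarray(J, dtype=float)
        return np.atleast_1d(J @ self.weights + self.bias).astype(np.float64)

    def predict(self, J: np.ndarray) -> np.ndarray:
        """Distance in (0, 1) for one (n,) or many (m, n) J vectors."""
        return nn.sigmoid(self.logits(J))

    def distance(self, I1: np.ndarray, I2: np.ndarray) -> float:
        return float(self.predict(fsld_transform(I1, I2, self.threshold_a))[0])


def _pair_indices(labels: np.ndarray, pair_budget: int, rng) -> list:
    pairs = list(combinations(range(len(labels)), 2))
    if len(pairs) <= pair_budget:
        return pairs
    same = [p for p in pairs if labels[p[0]] == labels[p[1]]]
    diff = [p for p in pairs if labels[p[0]] != labels[p[1]]]
    n_half = pair_budget // 2
    keep = []
    for pool, n in ((same, n_half), (diff, pair_budget - n_half)):
        n = min(n, len(pool))
        keep += [pool[k] for k in rng.choice(len(pool), size=n, replace=False)]
    return keep


def train_distance_model(
    fused,
    labels,
    a: float = 0.01,
    epochs: int = 60,
    learning_rate: float = 0.05,
    seed: int = 0,
    pair_budget: int = 50_000,
) -> DistanceModel:
    """Fit the one-layer distance model on all (budgeted) patient pairs.

    Targets follow the pseudo-distance convention: 0 for same-class pairs,
    1 for different-class pairs; loss is class-balanced binary cross-entropy
    (same and different pairs carry equal total weight, since different-class
    pairs always outnumber same-class ones), minimized with Adam.  Above
    ``pair_budget`` unordered pairs, a seeded balanced subsample is used.
    Deterministic given *seed*.
    """
    X = np.asarray(fused, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train the distance model")
    rng = np.random.default_rng(seed)
    pairs = _pair_indices(labels, pair_budget, rng)
    J = np.stack([fsld_transform(X[i], X[j], a) for i, j in pairs])
    t = np.array([0.0 if labels[i] == labels[j] else 1.0 for i, j in pairs])

    n_same = int(np.sum(t == 0))
    n_diff = int(np.sum(t == 1))
    if n_same == 0 or n_diff == 0:
        raise ValueError("need both same-class and different-class pairs")
    sw = np.where(t == 0, 0.5 / n_same, 0.5 / n_diff)

    w = rng.normal(0.0, 0.01, X.shape[1])
    b = 0.0
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    mb = vb = 0.0
    b1, b2, eps = 0.9, 0.999, 1e-8
    for step in range(1, epochs + 1):
        p = nn.sigmoid(J @ w + b)
        g = sw * (p - t)
        gw = J.T @ g
        gb = float(g.sum())
        m = b1 * m + (1 - b1) * gw
        v = b2 * v + (1 - b2) * gw**2
        mb = b1 * mb + (1 - b1) * gb
        vb = b2 * vb + (1 - b2) * gb**2
        w -= learning_rate * (m / (1 - b1**step)) / (np.sqrt(v / (1 - b2**step)) + eps)
        b -= learning_rate * (mb / (1 - b1**step)) / (np.sqrt(vb / (1 - b2**step)) + eps)
        if not (np.all(np.isfinite(w)) and np.isfinite(b)):
            raise FloatingPointError("distance model training diverged")
    return DistanceModel(w, float(b), a)


def knn_predict(
    query: np.ndarray,
    gallery_vectors,
    gallery_classes,
    model: DistanceModel,
    k: int = 10,
    seed: int = 0,
) -> int:
    """Classify by majority vote among the K nearest learned distances.

    Distance ties at the K-th rank are broken by stable gallery order; a
    vote tie between classes is broken uniformly at random with *seed*.
    """
    G = np.asarray(gallery_vectors, dtype=float)
    classes = np.asarray(gallery_classes)
    if len(G) < k:
        raise ValueError(
            f"gallery has {len(G)} patients, fewer than K={k}; use a smaller K"
        )
    J = np.stack([fsld_transform(query, g, model.threshold_a) for g in G])
    # rank by the logit: same ordering as the sigmoid distance, but immune
    # to float saturation flattening the top of the ranking
    dists = model.logits(J)
    nearest = np.argsort(dists, kind="stable")[:k]
    votes, counts = np.unique(classes[nearest], return_counts=True)
    winners = votes[counts == counts.max()]
    if len(winners) == 1:
        return int(winners[0])
    return int(np.random.default_rng(seed).choice(np.sort(winners)))
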