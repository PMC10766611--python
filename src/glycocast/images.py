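"""Two spatial-image encodings of a 14-day CGM trace.

The *binary image* traces the glucose curve as a one-hot column per reading:
24 contiguous 20 mg/dL bins spanning [40, 520) on the rows (row 0 = lowest),
one column per 15-minute slot.  The *histogram image* is a 20 x 14 matrix of
per-day glucose frequency distributions (20 equal-width bins between each
day's min and max), normalized by its global maximum.  Both feed a small CNN
feature extractor; the binary image is first width-reduced by column
max-pooling so the one-hot trace shape survives at a quarter of the width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgm import CGMSeries

__all__ = [
    "BinaryImage",
    "HistogramImage",
    "to_binary_image",
    "to_histogram_image",
    "prepare_for_cnn",
    "BINARY_N_BINS",
    "BINARY_RANGE",
    "HIST_N_BINS",
]

BINARY_N_BINS = 24
BINARY_RANGE = (40.0, 520.0)  # 24 bins of 20 mg/dL
BINARY_BIN_WIDTH = 20.0
HIST_N_BINS = 20


@dataclass(frozen=True)
class BinaryImage:
    """One-hot trace image: (24, L), exactly one 1 per column."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", p)
        if p.ndim != 2 or p.shape[0] != BINARY_N_BINS:
            raise ValueError(f"binary image must be ({BINARY_N_BINS}, L)")


@dataclass(frozen=True)
class HistogramImage:
    """Per-day glucose histogram image: (20, n_days), values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", p)
        if p.ndim != 2 or p.shape[0] != HIST_N_BINS:
            raise ValueError(f"histogram image must be ({HIST_N_BINS}, n_days)")


def glucose_bin(values: np.ndarray) -> np.ndarray:
    """Row index of each glucose value; out-of-range values clamp to the ends."""
    idx = np.floor((np.asarray(values, dtype=float) - BINARY_RANGE[0]) / BINARY_BIN_WIDTH)
    return np.clip(idx, 0, BINARY_N_BINS - 1).astype(int)


def to_binary_image(series: CGMSeries) -> BinaryImage:
    """Encode a complete series as a (24, L) one-hot image."""
    if not series.is_complete:
        raise ValueError("series has missing readings; impute first")
    x = series.values
    img = np.zeros((BINARY_N_BINS, len(x)))
    img[glucose_bin(x), np.arange(len(x))] = 1.0
    return BinaryImage(img)


def to_histogram_image(series: CGMSeries) -> HistogramImage:
    """Encode a complete series as the (20, n_days) normalized histogram image.

    Each day's readings are binned into 20 equal-width intervals between
    that day's min and max; the day maximum is counted in the last bin, and
    a degenerate day (min == max) puts all its readings in bin 0.  The
    matrix is divided by its global maximum.
    """
    if not series.is_complete:
        raise ValueError("series has missing readings; impute first")
    G = series.grid()
    H = np.zeros((HIST_N_BINS, series.n_days))
    for d in range(series.n_days):
        day = G[d]
        lo, hi = day.min(), day.max()
        if hi == lo:
            H[0, d] = len(day)
            continue
        idx = np.floor((day - lo) / (hi - lo) * HIST_N_BINS).astype(int)
        idx = np.clip(idx, 0, HIST_N_BINS - 1)  # the day max lands in the last bin
        np.add.at(H[:, d], idx, 1.0)
    return HistogramImage(H / H.max())


def save_png(image, path) -> None:
    """Export an encoding as a grayscale PNG for visual inspection.

    Rows are flipped so low glucose sits at the bottom of the rendered
    image, matching how a glucose trace is usually drawn.
    """
    from matplotlib.image import imsave

    if not isinstance(image, (BinaryImage, HistogramImage)):
        raise TypeError(f"expected BinaryImage or HistogramImage, got {type(image)!r}")
    imsave(path, image.pixels[::-1], cmap="gray", vmin=0.0, vmax=1.0, format="png")


def prepare_for_cnn(image, pool_factor: int = 4) -> np.ndarray:
    """Fixed-size single-channel array in [0, 1] for the CNN extractor.

    Binary images are width-reduced by non-overlapping column max-pooling
    with ``pool_factor`` (24 x 1344 -> 24 x 336 by default), preserving the
    one-hot trace envelope; histogram images pass through unchanged.
    """
    if isinstance(image, HistogramImage):
        return image.pixels.copy()
    if isinstance(image, BinaryImage):
        p = image.pixels
        if pool_factor == 1:
            return p.copy()
        h, w = p.shape
        if w % pool_factor != 0:
            raise ValueError(
                f"image width {w} not divisible by pool factor {pool_factor}"
            )
        return p.reshape(h, w // pool_factor, pool_factor).max(axis=2)
    raise TypeError(f"expected BinaryImage or HistogramImage, got {type(image)!r}")
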