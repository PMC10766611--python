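"""Few-shot "separator": a twin-CNN trained on same/different class pairs.

One separator is trained per image channel (binary trace images, histogram
images).  Two identical 4-layer CNNs with shared weights map each image of a
pair to a 4096-dim non-negative feature vector; the head takes the
element-wise absolute difference of the two vectors through a single affine
unit and a sigmoid, and is trained with binary cross-entropy toward 0 for
same-class pairs and 1 for different-class pairs.  After training the CNN
alone serves as the feature extractor, on the premise that same-class images
land closer in feature space than different-class images.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np

from . import nn

__all__ = [
    "ExtractorConfig",
    "SeparatorModel",
    "make_pairs",
    "train_separator",
    "extract_features",
]

FEATURE_DIM = 4096


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture + optimization settings of one separator.

    Four conv stages (3x3 kernels, ReLU, 2x2 max-pool after the first three,
    adaptive average-pool to 4x8 after the last) feed a fully connected
    layer to the fixed 4096-dim feature space with a final ReLU.
    """

    channels: tuple = (16, 32, 64, 128)
    kernel: int = 3
    adaptive_hw: tuple = (4, 8)
    feature_dim: int = FEATURE_DIM
    epochs: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self) -> None:
        if len(self.channels) != 4:
            raise ValueError("exactly 4 convolutional layers are required")
        if self.feature_dim != FEATURE_DIM:
            raise ValueError(f"feature_dim is fixed at {FEATURE_DIM}")

    def build_extractor(self, rng: np.random.Generator) -> nn.Sequential:
        c1, c2, c3, c4 = self.channels
        ah, aw = self.adaptive_hw
        k = self.kernel
        return nn.Sequential(
            nn.Conv2d(1, c1, k, rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(c1, c2, k, rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(c2, c3, k, rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(c3, c4, k, rng), nn.ReLU(), nn.AdaptiveAvgPool(ah, aw),
            nn.Flatten(),
            nn.Dense(c4 * ah * aw, self.feature_dim, rng), nn.ReLU(),
        )


@dataclass
class SeparatorModel:
    """Trained twin-CNN: shared extractor + |f1 - f2| -> affine -> sigmoid head."""

    config: ExtractorConfig
    extractor: nn.Sequential
    head: nn.Dense
    training_state: dict = field(default_factory=dict)

    def features(self, images: np.ndarray) -> np.ndarray:
        """(N, 4096) non-negative feature vectors for a stack of images."""
        x = _as_batch(images)
        return self.extractor.forward(x).astype(np.float64)

    def pair_output(self, img1, img2) -> float:
        """Head output in (0, 1) for one pair: ~0 same class, ~1 different."""
        f = self.features(np.stack([np.asarray(img1), np.asarray(img2)]))
        d = np.abs(f[0] - f[1])[None, :]
        return float(nn.sigmoid(self.head.forward(d.astype(nn.DTYPE)))[0, 0])

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.extractor.params)}
        arrays["head_W"] = self.head.W
        arrays["head_b"] = self.head.b
        np.savez(
            path,
            config=json.dumps(asdict(self.config)),
            training_state=json.dumps(self.training_state),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SeparatorModel":
        with np.load(path, allow_pickle=False) as z:
            cfg_d = json.loads(str(z["config"]))
            for key in ("channels", "adaptive_hw"):
                cfg_d[key] = tuple(cfg_d[key])
            config = ExtractorConfig(**cfg_d)
            extractor = config.build_extractor(np.random.default_rng(0))
            extractor.load_state([z[f"p{i}"] for i in range(len(extractor.params))])
            head = nn.Dense(config.feature_dim, 1, np.random.default_rng(0))
            head.W[...] = z["head_W"]
            head.b[...] = z["head_b"]
            state = json.loads(str(z["training_state"]))
        return cls(config, extractor, head, state)


def _as_batch(images) -> np.ndarray:
    x = np.asarray(images, dtype=nn.DTYPE)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"expected (H, W) or (N, H, W) images, got shape {x.shape}")
    return x[:, None, :, :]


def make_pairs(
    labels, n_pairs: int, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Balanced same/different index pairs: (i, j, 0 if same class else 1).

    Half the pairs are same-class and half different-class, drawn without
    replacement from each category while possible (falling back to with-
    replacement when a category is exhausted).  Never pairs an index with
    itself.  A class with a single member contributes only different-class
    pairs (with a warning).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to form pairs")
    for cls_, cnt in zip(classes, counts):
        if cnt < 2:
            warnings.warn(
                f"class {cls_} has a single member; it contributes only "
                "different-class pairs",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    idx = np.arange(len(labels))
    same_pool = [
        (i, j)
        for c in classes
        for i, j in combinations(idx[labels == c], 2)
    ]
    diff_pool = [
        (i, j) for i, j in combinations(idx, 2) if labels[i] != labels[j]
    ]
    n_same = n_pairs // 2
    n_diff = n_pairs - n_same

    def draw(pool, n):
        if not pool:
            return []
        replace = n > len(pool)
        chosen = rng.choice(len(pool), size=n, replace=replace)
        return [pool[k] for k in chosen]

    pairs = [(i, j, 0) for i, j in draw(same_pool, n_same)]
    pairs += [(i, j, 1) for i, j in draw(diff_pool, n_diff)]
    order = rng.permutation(len(pairs))
    return [pairs[k] for k in order]


def train_separator(
    images,
    labels,
    config: ExtractorConfig | None = None,
    n_pairs: int | None = None,
    seed: int = 0,
) -> SeparatorModel:
    """Train one separator on prepared images (all the same shape).

    Pair targets are 0 for same-class and 1 for different-class pairs; the
    loss is binary cross-entropy on the head logit, minimized with Adam.
    Both branches are one network: each minibatch of pairs is stacked into a
    single forward pass, so weight sharing is structural.  Deterministic
    given (seed, config, data).
    """
    config = config or ExtractorConfig()
    x = _as_batch(images)
    labels = np.asarray(labels)
    if len(x) != len(labels):
        raise ValueError("images and labels length mismatch")
    if n_pairs is None:
        n_pairs = min(4 * len(x), 2000)
    rng = np.random.default_rng(seed)
    extractor = config.build_extractor(rng)
    head = nn.Dense(config.feature_dim, 1, rng)
    params = extractor.params + head.params
    grads = extractor.grads + head.grads
    opt = nn.Adam(params, grads, lr=config.learning_rate)

    pairs = make_pairs(labels, n_pairs, seed=int(rng.integers(2**31)))
    i1 = np.array([p[0] for p in pairs])
    i2 = np.array([p[1] for p in pairs])
    t = np.array([p[2] for p in pairs], dtype=np.float64)

    losses = []
    bs = config.batch_size
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for start in range(0, len(pairs), bs):
            sel = order[start : start + bs]
            xa, xb = x[i1[sel]], x[i2[sel]]
            f = extractor.forward(np.concatenate([xa, xb]))
            fa, fb = f[: len(sel)], f[len(sel) :]
            d = np.abs(fa - fb)
            z = head.forward(d)[:, 0]
            loss, dz = nn.bce_with_logits(z, t[sel])
            if not np.isfinite(loss):
                raise FloatingPointError("separator training diverged")
            dd = head.backward(dz[:, None])
            s = np.sign(fa - fb).astype(nn.DTYPE)
            extractor.backward(np.concatenate([dd * s, -dd * s]))
            opt.step()
            epoch_loss += loss * len(sel)
        losses.append(epoch_loss / len(pairs))

    return SeparatorModel(
        config,
        extractor,
        head,
        {"epochs": config.epochs, "losses": losses, "seed": seed, "n_pairs": n_pairs},
    )


def extract_features(model: SeparatorModel, image) -> np.ndarray:
    """4096-dim non-negative feature vector for one prepared image."""
    return model.features(np.asarray(image))[0]
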