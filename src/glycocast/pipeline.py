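"""End-to-end orchestration: train, predict, evaluate, ablate.

Training wires the stages together on a patient-level split: fit the
8-neighbor imputer on the training series, complete them, compute DSP
features and fit their standardizer, render and pool both image encodings,
train one separator per image channel, fuse everything into per-patient
vectors, train the FSLD distance model on training pairs, and keep the
training vectors as the KNN gallery.  Evaluation runs stratified
patient-level cross-validation (or repeated 80/20 holdout) with full
retraining per fold, reporting percent accuracy
(100 x correct / total) and per-fold confusion matrices; ablation loops the
seven non-empty channel subsets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cgm import CGMSeries, HbA1cScheme, LabeledPatient
from .dsp import extract_dsp_vector
from .fsl import ExtractorConfig, SeparatorModel, train_separator
from .fused import DistanceModel, Standardizer, fuse, knn_predict, train_distance_model
from .images import prepare_for_cnn, to_binary_image, to_histogram_image
from .impute import ImputerModel, build_neighbor_dataset, fit_imputer, impute_missing

__all__ = [
    "ALL_CHANNELS",
    "PipelineConfig",
    "TrainedPipeline",
    "EvaluationReport",
    "run_training",
    "evaluate",
    "evaluate_holdout",
    "ablation",
    "accuracy",
]

ALL_CHANNELS = ("binary", "histogram", "dsp")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything tunable in one place; defaults are the shipped settings."""

    channels: tuple = ALL_CHANNELS
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    n_pairs: int | None = None
    pool_factor: int = 4
    fsld_a: float = 0.01
    distance_epochs: int = 60
    distance_lr: float = 0.05
    pair_budget: int = 50_000
    knn_k: int = 10
    imputer_epochs: int = 150
    imputer_lr: float = 0.05
    impute_max_rounds: int = 10

    def __post_init__(self) -> None:
        bad = set(self.channels) - set(ALL_CHANNELS)
        if bad or not self.channels:
            raise ValueError(f"channels must be a non-empty subset of {ALL_CHANNELS}")

    @classmethod
    def desk_scale(cls, channels: tuple = ALL_CHANNELS) -> "PipelineConfig":
        """Reduced-epoch profile for CPU-scale runs and tests."""
        return cls(
            channels=channels,
            extractor=ExtractorConfig(epochs=3, batch_size=16),
            n_pairs=96,
            distance_epochs=40,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["extractor"]["channels"] = list(self.extractor.channels)
        d["extractor"]["adaptive_hw"] = list(self.extractor.adaptive_hw)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ext_d = dict(d.pop("extractor", {}))
        for key in ("channels", "adaptive_hw"):
            if key in ext_d:
                ext_d[key] = tuple(ext_d[key])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(extractor=ExtractorConfig(**ext_d), **d)


def accuracy(predictions, truth) -> float:
    """Percent accuracy: 100 x (# correct) / (total)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float(100.0 * np.mean(predictions == truth))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class TrainedPipeline:
    """All artifacts of one training run, ready for prediction."""

    scheme: HbA1cScheme
    config: PipelineConfig
    seed: int
    imputer: ImputerModel
    separators: dict  # channel -> SeparatorModel
    dsp_standardizer: Standardizer | None
    distance_model: DistanceModel
    gallery_vectors: np.ndarray
    gallery_classes: np.ndarray
    gallery_ids: tuple

    def _complete(self, series: CGMSeries) -> CGMSeries:
        if series.is_complete:
            return series
        return impute_missing(series, self.imputer, self.config.impute_max_rounds)

    def featurize(self, series: CGMSeries) -> np.ndarray:
        """Fused feature vector for one (possibly gappy) series."""
        s = self._complete(series)
        B = H = D = None
        if "binary" in self.config.channels:
            img = prepare_for_cnn(to_binary_image(s), self.config.pool_factor)
            B = self.separators["binary"].features(img)[0]
        if "histogram" in self.config.channels:
            img = prepare_for_cnn(to_histogram_image(s))
            H = self.separators["histogram"].features(img)[0]
        if "dsp" in self.config.channels:
            D = extract_dsp_vector(s).values
        return fuse(B, H, D, self.dsp_standardizer)

    def predict(self, series_list, seed: int | None = None) -> list[int]:
        """Predicted class index for each series (KNN over the gallery)."""
        root = np.random.SeedSequence(self.seed if seed is None else seed)
        out = []
        for q, series in enumerate(series_list):
            vec = self.featurize(series)
            tie_seed = _seed_int(np.random.SeedSequence((root.entropy, q)))
            out.append(
                knn_predict(
                    vec,
                    self.gallery_vectors,
                    self.gallery_classes,
                    self.distance_model,
                    k=self.config.knn_k,
                    seed=tie_seed,
                )
            )
        return out

    # -- persistence ---------------------------------------------------

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, sep in self.separators.items():
            fn = f"separator_{name}.npz"
            sep.save(d / fn)
            files[f"separator_{name}"] = fn
        np.savez(
            d / "imputer.npz",
            weights=self.imputer.weights,
            bias=self.imputer.bias,
            mean=self.imputer.mean,
            sd=self.imputer.sd,
        )
        files["imputer"] = "imputer.npz"
        np.savez(
            d / "distance.npz",
            weights=self.distance_model.weights,
            bias=self.distance_model.bias,
            threshold_a=self.distance_model.threshold_a,
        )
        files["distance"] = "distance.npz"
        gal = {
            "vectors": self.gallery_vectors,
            "classes": self.gallery_classes,
            "ids": np.array(self.gallery_ids, dtype=str),
        }
        if self.dsp_standardizer is not None:
            gal["dsp_mean"] = self.dsp_standardizer.mean
            gal["dsp_sd"] = self.dsp_standardizer.sd
        np.savez(d / "gallery.npz", **gal)
        files["gallery"] = "gallery.npz"
        manifest = {
            "scheme": self.scheme.name,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "files": files,
            "distance_target_convention": "0=same class, 1=different class",
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, model_dir) -> "TrainedPipeline":
        from .cgm import get_scheme

        d = Path(model_dir)
        manifest = json.loads((d / "manifest.json").read_text())
        config = PipelineConfig.from_dict(manifest["config"])
        seps = {
            name.removeprefix("separator_"): SeparatorModel.load(d / fn)
            for name, fn in manifest["files"].items()
            if name.startswith("separator_")
        }
        with np.load(d / "imputer.npz") as z:
            imputer = ImputerModel(
                z["weights"], float(z["bias"]), float(z["mean"]), float(z["sd"])
            )
        with np.load(d / "distance.npz") as z:
            dist = DistanceModel(z["weights"], float(z["bias"]), float(z["threshold_a"]))
        with np.load(d / "gallery.npz") as z:
            std = (
                Standardizer(z["dsp_mean"], z["dsp_sd"]) if "dsp_mean" in z else None
            )
            gal_v, gal_c = z["vectors"], z["classes"]
            gal_ids = tuple(str(s) for s in z["ids"])
        return cls(
            get_scheme(manifest["scheme"]),
            config,
            int(manifest["seed"]),
            imputer,
            seps,
            std,
            dist,
            gal_v,
            gal_c,
            gal_ids,
        )


def run_training(
    cohort,
    scheme: HbA1cScheme,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> TrainedPipeline:
    """Train every stage on a labeled cohort and return the pipeline.

    The cohort is the training side of a patient-level split: its fused
    vectors become the KNN gallery, so no held-out patient ever enters it.
    """
    config = config or PipelineConfig()
    cohort = list(cohort)
    classes = np.array([p.class_index for p in cohort])
    uniq, counts = np.unique(classes, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("every class needs >= 2 training patients")

    root = np.random.SeedSequence(seed)
    s_imp, s_bin, s_hist, s_dist = (_seed_int(c) for c in root.spawn(4))

    samples = build_neighbor_dataset([p.series for p in cohort])
    imputer, _ = fit_imputer(
        samples, epochs=config.imputer_epochs,
        learning_rate=config.imputer_lr, seed=s_imp,
    )
    complete = [
        p.series
        if p.series.is_complete
        else impute_missing(p.series, imputer, config.impute_max_rounds)
        for p in cohort
    ]

    std = None
    D = None
    if "dsp" in config.channels:
        D_raw = np.stack([extract_dsp_vector(s).values for s in complete])
        std = Standardizer.fit(D_raw)
        D = std.transform(D_raw)

    separators: dict[str, SeparatorModel] = {}
    feats: dict[str, np.ndarray] = {}
    if "binary" in config.channels:
        imgs = np.stack(
            [prepare_for_cnn(to_binary_image(s), config.pool_factor) for s in complete]
        )
        separators["binary"] = train_separator(
            imgs, classes, config.extractor, n_pairs=config.n_pairs, seed=s_bin
        )
        feats["binary"] = separators["binary"].features(imgs)
    if "histogram" in config.channels:
        imgs = np.stack([prepare_for_cnn(to_histogram_image(s)) for s in complete])
        separators["histogram"] = train_separator(
            imgs, classes, config.extractor, n_pairs=config.n_pairs, seed=s_hist
        )
        feats["histogram"] = separators["histogram"].features(imgs)

    fused_vecs = np.stack(
        [
            fuse(
                feats["binary"][i] if "binary" in feats else None,
                feats["histogram"][i] if "histogram" in feats else None,
                D[i] if D is not None else None,
                None,  # D already standardized above
            )
            for i in range(len(cohort))
        ]
    )
    dist = train_distance_model(
        fused_vecs,
        classes,
        a=config.fsld_a,
        epochs=config.distance_epochs,
        learning_rate=config.distance_lr,
        seed=s_dist,
        pair_budget=config.pair_budget,
    )
    return TrainedPipeline(
        scheme,
        config,
        seed,
        imputer,
        separators,
        std,
        dist,
        fused_vecs,
        classes,
        tuple(p.series.patient_id for p in cohort),
    )


@dataclass
class EvaluationReport:
    """Per-fold accuracies, confusion matrices, and the run's provenance."""

    scheme_name: str
    channels: tuple
    fold_accuracies: list
    confusion_matrices: list  # one (C, C) nested list per fold
    seed: int
    config: dict

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_name,
            "channels": list(self.channels),
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion_matrices": self.confusion_matrices,
            "seed": self.seed,
            "config": self.config,
        }

    def summary(self) -> str:
        lines = [
            f"scheme={self.scheme_name} channels={'+'.join(self.channels)}",
            f"folds={len(self.fold_accuracies)} "
            f"mean accuracy={self.mean_accuracy:.2f}% "
            f"(std {self.std_accuracy:.2f})",
        ]
        for i, acc in enumerate(self.fold_accuracies):
            lines.append(f"  fold {i}: {acc:.2f}%")
        return "\n".join(lines)


def _fold_report(scheme, channels, accs, cms, seed, config) -> EvaluationReport:
    return EvaluationReport(
        scheme.name,
        tuple(channels),
        [float(a) for a in accs],
        [np.asarray(c).tolist() for c in cms],
        seed,
        config.to_dict(),
    )


def evaluate(
    cohort,
    scheme: HbA1cScheme,
    config: PipelineConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified patient-level K-fold with full retraining per fold."""
    config = config or PipelineConfig()
    cohort = list(cohort)
    y = np.array([p.class_index for p in cohort])
    n_classes = len(np.unique(y))
    for attempt in range(3):
        fold_seed = seed + attempt
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == n_classes for tr, _ in splits):
            break
        warnings.warn("a fold lost a class; retrying stratification with a new seed")
    accs, cms = [], []
    for f, (tr, te) in enumerate(splits):
        pipe = run_training(
            [cohort[i] for i in tr], scheme, config,
            seed=_seed_int(np.random.SeedSequence((seed, f))),
        )
        preds = pipe.predict([cohort[i].series for i in te])
        accs.append(accuracy(preds, y[te]))
        cms.append(confusion_matrix(y[te], preds, labels=np.arange(scheme.n_classes)))
    return _fold_report(scheme, config.channels, accs, cms, seed, config)


def evaluate_holdout(
    cohort,
    scheme: HbA1cScheme,
    config: PipelineConfig | None = None,
    test_fraction: float = 0.2,
    n_seeds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified 80/20 holdout; one accuracy per repetition."""
    config = config or PipelineConfig()
    cohort = list(cohort)
    y = np.array([p.class_index for p in cohort])
    accs, cms = [], []
    for r in range(n_seeds):
        rs = _seed_int(np.random.SeedSequence((seed, r)))
        tr, te = train_test_split(
            np.arange(len(y)), test_size=test_fraction, stratify=y,
            random_state=rs % (2**31),
        )
        pipe = run_training([cohort[i] for i in tr], scheme, config, seed=rs)
        preds = pipe.predict([cohort[i].series for i in te])
        accs.append(accuracy(preds, y[te]))
        cms.append(confusion_matrix(y[te], preds, labels=np.arange(scheme.n_classes)))
    return _fold_report(scheme, config.channels, accs, cms, seed, config)


def ablation(
    cohort,
    scheme: HbA1cScheme,
    config: PipelineConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Evaluate all 7 non-empty channel subsets (distance model retrained per subset)."""
    from dataclasses import replace
    from itertools import combinations as combos

    config = config or PipelineConfig()
    subsets = [
        tuple(c)
        for r in (1, 2, 3)
        for c in combos(ALL_CHANNELS, r)
    ]
    return [
        evaluate(cohort, scheme, replace(config, channels=sub), folds=folds, seed=seed)
        for sub in subsets
    ]
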