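"""Model/Results facade over the pipeline, in the style of fitted-model APIs.

``HbA1cFewShot`` is constructed from a labeled cohort (or from the CSV pair
the package reads and writes); ``fit()`` cross-validates the full pipeline
and returns an ``HbA1cFewShotResults`` carrying per-fold accuracies, their
spread, confusion matrices, a pipeline retrained on all patients for
prediction, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgm import HbA1cScheme, LabeledPatient, read_cgm_csv, read_labels_csv
from .pipeline import (
    EvaluationReport,
    PipelineConfig,
    TrainedPipeline,
    evaluate,
    evaluate_holdout,
    run_training,
)

__all__ = ["HbA1cFewShot", "HbA1cFewShotResults"]


class HbA1cFewShot:
    """Few-shot HbA1c class predictor built from a labeled CGM cohort."""

    def __init__(
        self,
        cohort: list[LabeledPatient],
        scheme: HbA1cScheme,
        config: PipelineConfig | None = None,
    ):
        self.cohort = list(cohort)
        self.scheme = scheme
        self.config = config or PipelineConfig()
        if not self.cohort:
            raise ValueError("cohort is empty")

    @classmethod
    def from_csv(
        cls,
        cgm_path,
        labels_path,
        scheme: HbA1cScheme,
        config: PipelineConfig | None = None,
        n_days: int = 14,
    ) -> "HbA1cFewShot":
        series = read_cgm_csv(cgm_path, n_days=n_days)
        labels = read_labels_csv(labels_path)
        cohort = [
            LabeledPatient.from_hba1c(s, labels[s.patient_id], scheme)
            for s in series
            if s.patient_id in labels
        ]
        return cls(cohort, scheme, config)

    def fit(
        self,
        folds: int = 5,
        seed: int = 0,
        mode: str = "cv",
    ) -> "HbA1cFewShotResults":
        """Cross-validate, then retrain on all patients for prediction.

        ``mode='cv'`` runs stratified K-fold; ``mode='holdout'`` repeats a
        stratified 80/20 split ``folds`` times.
        """
        if mode == "cv":
            report = evaluate(self.cohort, self.scheme, self.config, folds, seed)
        elif mode == "holdout":
            report = evaluate_holdout(
                self.cohort, self.scheme, self.config, n_seeds=folds, seed=seed
            )
        else:
            raise ValueError("mode must be 'cv' or 'holdout'")
        pipeline = run_training(self.cohort, self.scheme, self.config, seed=seed)
        return HbA1cFewShotResults(self, report, pipeline)


@dataclass
class HbA1cFewShotResults:
    """Cross-validated accuracies plus a prediction-ready pipeline."""

    model: HbA1cFewShot
    report: EvaluationReport
    pipeline: TrainedPipeline

    @property
    def fold_accuracies(self) -> list[float]:
        return self.report.fold_accuracies

    @property
    def mean_accuracy(self) -> float:
        return self.report.mean_accuracy

    @property
    def std_accuracy(self) -> float:
        return self.report.std_accuracy

    @property
    def confusion_matrices(self) -> list:
        return self.report.confusion_matrices

    def predict(self, series_list) -> list[int]:
        return self.pipeline.predict(series_list)

    def predict_labels(self, series_list) -> list[str]:
        labels = self.model.scheme.labels
        return [labels[i] for i in self.predict(series_list)]

    def summary(self) -> str:
        scheme = self.model.scheme
        n = len(self.model.cohort)
        counts = np.bincount(
            [p.class_index for p in self.model.cohort], minlength=scheme.n_classes
        )
        lines = [
            "Few-shot HbA1c class prediction",
            "=" * 47,
            f"scheme: {scheme.name} ({scheme.n_classes} classes)",
            f"patients: {n}  per class: {counts.tolist()}",
            f"channels: {'+'.join(self.report.channels)}",
            "-" * 47,
            self.report.summary(),
            "-" * 47,
            "gallery size: "
            f"{len(self.pipeline.gallery_vectors)} "
            f"(fused dim {self.pipeline.gallery_vectors.shape[1]})",
        ]
        return "\n".join(lines)
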