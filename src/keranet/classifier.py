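"""Model/Results facade over the cross-validation pipeline.

:class:`DermoscopyClassifier` is built from a :class:`~keranet.dataio.DatasetIndex`
(or directly from a metadata CSV / synthetic config) and holds the
preprocessing, architecture, training and augmentation configuration.
Its :meth:`~DermoscopyClassifier.fit` runs seeded k-fold cross-validated
training and returns a :class:`CVResults` carrying per-fold metrics,
their mean ± 95% CI aggregates, ROC curves and the full run report.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .architecture import ModelConfig
from .augment import AugmentConfig
from .dataio import DatasetIndex, Dialect, RunReport, read_metadata, read_report, write_report
from .preprocess import PreprocessConfig
from .synthetic import SynthConfig, generate_corpus
from .train import METRIC_NAMES, TrainConfig, run_cv


class DermoscopyClassifier:
    """AK-vs-NAK dermoscopy classifier with k-fold cross-validated fitting."""

    def __init__(
        self,
        index: DatasetIndex,
        preprocess: PreprocessConfig = PreprocessConfig(),
        architecture: ModelConfig = ModelConfig(),
        training: TrainConfig = TrainConfig(),
        augmentation: AugmentConfig = AugmentConfig(),
    ):
        self.index = index
        self.preprocess = preprocess
        self.architecture = architecture
        self.training = training
        self.augmentation = augmentation

    @classmethod
    def from_metadata(cls, csv_path, image_dir, dialect=Dialect.HAM10000, **configs):
        """Build from a metadata CSV plus image directory."""
        return cls(read_metadata(csv_path, image_dir, dialect), **configs)

    @classmethod
    def from_synthetic(cls, synth_cfg: SynthConfig, **configs):
        """Generate a synthetic corpus and build a classifier over it."""
        return cls(generate_corpus(synth_cfg), **configs)

    def fit(self, seed: Optional[int] = None) -> "CVResults":
        """Run k-fold cross-validated training; returns :class:`CVResults`."""
        training = self.training
        if seed is not None:
            from dataclasses import replace
            training = replace(training, seed=seed)
        report = run_cv(
            self.index,
            pre_cfg=self.preprocess,
            model_cfg=self.architecture,
            train_cfg=training,
            aug_cfg=self.augmentation,
        )
        return CVResults(self, report)


class CVResults:
    """Cross-validation results: estimates, uncertainties, diagnostics."""

    def __init__(self, model: Optional[DermoscopyClassifier], report: RunReport):
        self.model = model
        self.report = report

    # -- accessors ---------------------------------------------------------
    @property
    def fold_metrics(self) -> pd.DataFrame:
        return pd.DataFrame(self.report.fold_metrics)

    @property
    def mean(self) -> dict[str, float]:
        return {k: v["mean"] for k, v in self.report.summaries.items()}

    @property
    def ci_half_width(self) -> dict[str, float]:
        return {k: v["ci_half_width"] for k, v in self.report.summaries.items()}

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Text table of per-fold metrics and mean ± 95% CI aggregates."""
        k = self.report.k
        lines = [
            "Cross-validated dermoscopy classification results",
            "=" * 58,
            f"folds: {k}    records: {len(self.report.predictions)}",
            "-" * 58,
            f"{'metric':<14}{'mean':>10}{'95% CI ±':>12}   per-fold",
        ]
        for name in METRIC_NAMES:
            s = self.report.summaries[name]
            vals = " ".join(f"{v:.3f}" for v in s["values"])
            lines.append(
                f"{name:<14}{s['mean']:>10.4f}{s['ci_half_width']:>12.4f}   {vals}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:
        m = self.mean
        return (f"<CVResults k={self.report.k} accuracy={m['accuracy']:.4f} "
                f"auc={m['auc']:.4f}>")

    def plot_roc(self, ax=None):
        """Plot the per-fold ROC curves (FPR vs TPR)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for fold, pts in self.report.roc_points.items():
            pts = np.asarray(pts)
            ax.plot(pts[:, 0], pts[:, 1], label=f"fold {fold}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize="small")
        return ax

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        write_report(self.report, path)

    @classmethod
    def load(cls, path) -> "CVResults":
        return cls(model=None, report=read_report(Path(path)))
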