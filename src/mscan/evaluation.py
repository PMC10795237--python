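"""Classification metrics, replicated t-test comparison and the
cross-modification validation matrix.

Threshold metrics use the standard confusion-table formulas (sensitivity,
specificity, accuracy, precision, F1, MCC) at a 0.5 cutoff with the >=
tie rule.  Ranking metrics are AUROC (Mann-Whitney convention) and AUPRC
(average-precision rank-walk, not trapezoidal PR interpolation).
Degenerate denominators return documented sentinels: precision with no
predicted positives -> 0, MCC with any zero factor -> 0, F1 with
precision + recall == 0 -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .sequence_io import MethylDataset

__all__ = [
    "ConfusionCounts", "MetricsReport", "CrossModMatrix", "confusion",
    "threshold_metrics", "auroc", "auprc", "metrics_report",
    "ttest_compare", "cross_modification_matrix", "plot_cross_modification",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    Sen: float
    Spe: float
    Acc: float
    Pre: float
    F1: float
    MCC: float
    AUROC: float
    AUPRC: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Sen": self.Sen, "Spe": self.Spe, "Acc": self.Acc,
            "Pre": self.Pre, "F1": self.F1, "MCC": self.MCC,
            "AUROC": self.AUROC, "AUPRC": self.AUPRC,
        }


def _as_arrays(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError(
            f"labels ({labels.shape}) and scores ({scores.shape}) differ"
        )
    return labels, scores


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion table; prediction is 1 iff p >= threshold."""
    labels, probs = _as_arrays(labels, probabilities)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def threshold_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sen, Spe, Acc, Pre, F1, MCC from a confusion table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / c.total
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(denom) if denom else 0.0
    return {"Sen": sen, "Spe": spe, "Acc": acc, "Pre": pre,
            "F1": f1, "MCC": mcc}


def auroc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney convention, ties get 1/2)."""
    labels, scores = _as_arrays(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels, scores = _as_arrays(labels, scores)
    if not np.any(labels == 1):
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, scores))


def metrics_report(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full eight-metric report for one model-dataset pair."""
    t = threshold_metrics(confusion(labels, scores, threshold))
    return MetricsReport(**t, AUROC=auroc(labels, scores),
                         AUPRC=auprc(labels, scores))


def ttest_compare(metric_samples_a: Sequence[float],
                  metric_samples_b: Sequence[float],
                  welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample Student t-test on replicate metric values.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.  Two zero-variance samples with equal means return
    (0, 1) by convention.
    """
    a = np.asarray(metric_samples_a, dtype=np.float64)
    b = np.asarray(metric_samples_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 replicates")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass
class CrossModMatrix:
    """Square grid of reports: rows are test sets, columns are models."""

    tags: tuple[str, ...]
    cells: dict[tuple[str, str], MetricsReport] = field(default_factory=dict)

    def report(self, test_tag: str, model_tag: str) -> MetricsReport:
        return self.cells[(test_tag, model_tag)]

    def to_frame(self, metric: str = "AUROC") -> pd.DataFrame:
        """rows = test-set tag, columns = model tag."""
        data = {
            model: [getattr(self.cells[(test, model)], metric)
                    for test in self.tags]
            for model in self.tags
        }
        return pd.DataFrame(data, index=list(self.tags))


def cross_modification_matrix(models: Mapping[str, object],
                              testsets: Mapping[str, MethylDataset],
                              threshold: float = 0.5) -> CrossModMatrix:
    """Score every model on every test set.

    ``models`` maps modification tag to a predictor exposing
    ``predict_proba(dataset)``.  Cell (test=i, model=j) is model j scored
    on test set i; the diagonal holds matched pairs.
    """
    missing = set(testsets) - set(models)
    if missing:
        raise ValueError(f"no model for tag(s): {sorted(missing)}")
    tags = tuple(testsets.keys())
    matrix = CrossModMatrix(tags=tags)
    for test_tag, dataset in testsets.items():
        labels = dataset.labels()
        for model_tag in tags:
            scores = models[model_tag].predict_proba(dataset)
            matrix.cells[(test_tag, model_tag)] = metrics_report(
                labels, scores, threshold
            )
    return matrix


def plot_cross_modification(matrix: CrossModMatrix, path,
                            metric: str = "AUROC") -> None:
    """Heatmap with models on the horizontal axis, test data on the vertical."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = matrix.to_frame(metric)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(frame), 1.0 + 0.6 * len(frame)))
    im = ax.imshow(frame.to_numpy(), cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=45)
    ax.set_yticks(range(len(frame.index)), frame.index)
    ax.set_xlabel("model")
    ax.set_ylabel("test data")
    fig.colorbar(im, ax=ax, label=metric)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
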