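"""Binary-classification metrics and the one-vs-all orchestration helpers.

The figure of merit driving the whole system is Youden's informedness
J = sensitivity + specificity - 1, reported in its normalized form
J_bar = (J + 1) / 2 in [0, 1]; J_bar is robust to class imbalance and,
unlike the F-score, rewards true negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    informedness_normalized: float
    auc: float | None = None
    sparsity: float | None = None

    def as_row(self) -> dict:
        return {
            "Accuracy": self.accuracy,
            "Precision": self.precision,
            "Recall": self.recall,
            "Informedness": self.informedness_normalized,
            "AUC": self.auc,
            "Sparsity": self.sparsity,
        }


def informedness(c: ConfusionCounts) -> tuple[float, float]:
    """(J, J_bar): Youden's index and its [0, 1]-normalized form."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("informedness needs both classes present")
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    j = sensitivity + specificity - 1.0
    return j, (j + 1.0) / 2.0


def basic_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and normalized informedness."""
    if c.total == 0:
        raise UndefinedMetricError("no evaluated patterns")
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive patterns")
    _, j_bar = informedness(c)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=c.tp / (c.tp + c.fp),
        recall=c.tp / (c.tp + c.fn),
        informedness_normalized=j_bar,
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr columns) and AUC from decision scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def one_vs_all_labels(labels, positive_class: int) -> np.ndarray:
    """Recode 1..7 class labels to +/-1 for one binary subproblem."""
    labels = np.asarray(labels)
    if positive_class not in labels:
        raise ValueError(f"class {positive_class} absent from labels")
    return np.where(labels == positive_class, 1, -1)


def stratified_split(
    labels, fractions=(0.6, 0.2, 0.2), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index sets preserving the
    per-class label proportions (within one pattern per class)."""
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    labels = np.asarray(labels)
    indices = np.arange(len(labels))
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        raise ValueError("every class needs at least one pattern per split")
    train_idx, rest_idx = train_test_split(
        indices,
        train_size=fractions[0],
        stratify=labels,
        random_state=seed,
    )
    val_share = fractions[1] / (fractions[1] + fractions[2])
    val_idx, test_idx = train_test_split(
        rest_idx,
        train_size=val_share,
        stratify=labels[rest_idx],
        random_state=seed + 1,
    )
    return np.sort(train_idx), np.sort(val_idx), np.sort(test_idx)


def knowledge_reports(runs: list[tuple]) -> tuple[np.ndarray, dict]:
    """Aggregate the two knowledge-discovery artefacts over GA runs.

    runs: list of (genome, metrics) pairs where genome exposes .beta and
    .mask.  Returns the per-representation mean beta, and a prototype
    report with per-pattern selection frequencies and mean sparsity.
    """
    if not runs:
        raise ValueError("need at least one run")
    betas = np.vstack([np.asarray(genome.beta, dtype=float) for genome, _ in runs])
    beta_profile = betas.mean(axis=0)
    masks = np.vstack([np.asarray(genome.mask.bits, dtype=float) for genome, _ in runs])
    frequency = masks.mean(axis=0)
    prototype_report = {
        "selection_frequency": frequency,
        "selected_any_run": np.nonzero(frequency > 0)[0],
        "per_run_selected": [np.nonzero(row)[0] for row in masks],
        "mean_sparsity_percent": float(100.0 * masks.mean()),
    }
    return beta_profile, prototype_report
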