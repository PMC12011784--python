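"""Two-class evaluation: confusion counts, scalar metrics, ROC/AUC.

The positive class is 2 (malignant); labels are coded {1 = normal,
2 = malignant}.  Metrics:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)            (recall of the malignant class)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    AUC         = integral of TPR over FPR  (trapezoidal, tie-grouped sweep)
    kappa       = (p_o - p_e) / (1 - p_e)   (p_o = accuracy, p_e from marginals)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Zero-denominator conventions (each emitted with a warning flag in the
report): precision, sensitivity and specificity are 0 when their denominator
is 0; F1 is 0 when precision + sensitivity = 0; kappa is 0 when p_e = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "confusion",
    "scalar_metrics",
    "roc_auc",
    "evaluate",
    "report_table",
    "plot_confusion",
]

POSITIVE_CLASS = 2


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    kappa: float
    f1: float
    auc: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc": self.auc,
            "kappa": self.kappa,
            "f1": self.f1,
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class ROCCurve:
    """Ordered (FPR, TPR) points including (0,0) and (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.size and not np.isin(y, (1, 2)).all():
        raise ValueError("labels must be drawn from {1, 2}")
    return y


def confusion(y_true, y_pred, positive: int = POSITIVE_CLASS) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; the counts partition the evaluated items."""
    y_true = _check_labels(y_true)
    y_pred = _check_labels(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def scalar_metrics(c: ConfusionCounts) -> MetricsReport:
    """All threshold-free metrics from the counts (AUC left unset)."""
    n = c.total
    if n < 1:
        raise ValueError("confusion counts are empty")
    warnings: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            warnings.append(f"{name} denominator is 0; reported as 0")
            return 0.0
        return num / den

    accuracy = (c.tp + c.tn) / n
    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    if precision + sensitivity == 0:
        warnings.append("precision + sensitivity is 0; F1 reported as 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n ** 2
    if p_e == 1.0:
        warnings.append("chance agreement p_e is 1; kappa reported as 0")
        kappa = 0.0
    else:
        kappa = (accuracy - p_e) / (1.0 - p_e)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, precision=precision,
                         kappa=kappa, f1=f1, warnings=warnings)


def roc_auc(y_true, scores, positive: int = POSITIVE_CLASS) -> tuple[ROCCurve, float]:
    """ROC via a tie-grouped threshold sweep and trapezoidal AUC.

    Grouped thresholds make the curve equivalent to the half-tie
    Mann-Whitney pairwise-concordance statistic.
    """
    y_true = _check_labels(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined unless both classes are present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    # group ties: cumulative counts at the end of each distinct-score block
    boundary = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    ends = np.concatenate([boundary, [len(s) - 1]])
    cum_tp = np.cumsum(p)[ends]
    cum_fp = np.cumsum(~p)[ends]
    tpr = np.concatenate([[0.0], cum_tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], cum_fp / n_neg, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr), auc


def evaluate(y_true, y_pred, scores=None) -> tuple[ConfusionCounts, MetricsReport]:
    """Convenience wrapper: confusion + scalar metrics (+ AUC with scores)."""
    c = confusion(y_true, y_pred)
    report = scalar_metrics(c)
    if scores is not None:
        _, report.auc = roc_auc(y_true, scores)
    return c, report


def report_table(c: ConfusionCounts, report: MetricsReport) -> str:
    """Plain-text rendering of the confusion matrix and metric values."""
    lines = [
        "confusion matrix (rows: true, cols: predicted; class 2 = malignant)",
        f"            pred 1    pred 2",
        f"  true 1  {c.tn:8d}  {c.fp:8d}",
        f"  true 2  {c.fn:8d}  {c.tp:8d}",
        "",
    ]
    for name in ("accuracy", "sensitivity", "specificity", "precision",
                 "auc", "kappa", "f1"):
        value = getattr(report, name)
        lines.append(f"  {name:<12} {'--' if value is None else f'{value:.4f}'}")
    for w in report.warnings:
        lines.append(f"  warning: {w}")
    return "\n".join(lines)


def plot_confusion(c: ConfusionCounts, path) -> None:
    """Render the 2x2 confusion matrix to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.array([[c.tn, c.fp], [c.fn, c.tp]])
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center",
                color="black" if v < mat.max() * 0.6 else "white")
    ax.set_xticks([0, 1], ["pred 1", "pred 2"])
    ax.set_yticks([0, 1], ["true 1", "true 2"])
    ax.set_title("confusion matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
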