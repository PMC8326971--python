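"""Binary-classifier evaluation: the seven guideline measures, ROC/PR, curves.

The seven measures (accuracy, precision/PPV, recall/sensitivity,
specificity, F1, NPV, MCC) follow the standard confusion-matrix formulas
recommended for reporting variant-effect predictors. Zero-denominator cases
yield an explicit ``None`` ("undefined") rather than NaN, and undefined
values are excluded from fold averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """Simultaneous class swap (positive <-> negative)."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class MetricsReport:
    """The seven guideline measures; ``None`` marks an undefined value."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    npv: float | None
    mcc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self, ndigits: int = 3) -> dict[str, float | None]:
        """Report-precision values (round-half-even, as in printed tables)."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.as_dict().items()
        }


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All seven measures from TP/FP/FN/TN.

    accuracy=(TP+TN)/N, precision=TP/(TP+FP), recall=TP/(TP+FN),
    specificity=TN/(FP+TN), F1=2PR/(P+R), NPV=TN/(TN+FN),
    MCC=(TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = (
        None
        if precision is None or recall is None or (precision + recall) == 0
        else 2 * precision * recall / (precision + recall)
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        accuracy=_ratio(tp + tn, cm.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(tn, fp + tn),
        f1=f1,
        npv=_ratio(tn, tn + fn),
        mcc=mcc,
    )


def confusion_from_predictions(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion matrix at a probability threshold; p >= threshold is positive."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} scores")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = p >= threshold
    return ConfusionMatrix(
        tp=int(((y == 1) & pred).sum()),
        fp=int(((y == 0) & pred).sum()),
        fn=int(((y == 1) & ~pred).sum()),
        tn=int(((y == 0) & ~pred).sum()),
    )


def roc_curve(
    labels: Sequence[int], probabilities: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) points over the unique-score threshold sweep, plus AUROC.

    Equal scores are grouped (one threshold per unique score); the area uses
    trapezoidal integration.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(y, np.asarray(probabilities, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist())), float(_skm.auc(fpr, tpr))


def pr_curve(
    labels: Sequence[int], probabilities: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """(recall, precision) points plus AUPR by right-continuous step
    integration (average precision), which avoids the optimistic bias of
    trapezoidal PR areas."""
    y = np.asarray(labels)
    if (y == 1).sum() < 1:
        raise ValueError("PR needs at least one positive")
    p = np.asarray(probabilities, dtype=float)
    precision, recall, _ = _skm.precision_recall_curve(y, p)
    aupr = float(_skm.average_precision_score(y, p))
    return list(zip(recall.tolist(), precision.tolist())), aupr


def mean_curves(
    per_fold_curves: Sequence[Sequence[tuple[float, float]]],
    grid_size: int = 101,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical average of fold curves on a fixed x-grid.

    Returns (grid_x, mean_y, sd_y); each fold is linearly interpolated onto a
    ``grid_size``-point grid of the x axis (FPR for ROC, recall for PR). The
    sd is the unbiased (n-1) standard deviation across folds.
    """
    if len(per_fold_curves) < 2:
        raise ValueError("need at least two folds to average")
    grid = np.linspace(0.0, 1.0, grid_size)
    ys = []
    for curve in per_fold_curves:
        if len(curve) < 2:
            raise ValueError("fold curve has fewer than 2 points")
        pts = sorted(curve)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        ys.append(np.interp(grid, x, y))
    ys = np.vstack(ys)
    return grid, ys.mean(axis=0), ys.std(axis=0, ddof=1)


def mean_defined(values: Sequence[float | None]) -> float | None:
    """Arithmetic mean over defined values; None if all are undefined."""
    vals = [v for v in values if v is not None]
    return None if not vals else float(np.mean(vals))


def plot_curves(per_fold_curves, path, kind: str = "roc") -> None:
    """Optional PNG/SVG of fold curves with the vertical mean (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid, mean_y, sd_y = mean_curves(per_fold_curves)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for i, curve in enumerate(per_fold_curves, 1):
        xs, ys = zip(*sorted(curve))
        ax.plot(xs, ys, lw=0.8, alpha=0.6, label=f"fold {i}")
    ax.plot(grid, mean_y, lw=2, color="black", label="mean")
    ax.fill_between(grid, mean_y - sd_y, mean_y + sd_y, alpha=0.2, color="black")
    if kind == "roc":
        ax.set_xlabel("False-positive rate")
        ax.set_ylabel("True-positive rate")
    else:
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
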