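"""Discrimination metrics: ROC/AUROC, bootstrap CIs, threshold metrics.

AUROC is the Mann-Whitney pair-counting statistic — the probability that a
random positive outscores a random negative, with ties credited one half —
computed via midranks.  Confidence intervals use a stratified percentile
bootstrap (resampling within class, so every resample retains both classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "MetricsReport",
    "ROCCurve",
    "auroc",
    "roc_curve",
    "bootstrap_auroc_ci",
    "threshold_metrics",
    "evaluate_scores",
]


def _check_labels(labels: np.ndarray) -> None:
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pair-counting AUROC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    ranks = rankdata(s)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class ROCCurve:
    """ROC points from (0,0) to (1,1); one point per distinct threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # threshold at which (fpr, tpr) is reached

    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve whose trapezoidal area equals the pair-counting AUROC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return ROCCurve(fpr, tpr, thresholds)


def _auroc_rows(score_matrix: np.ndarray, n_pos: int, n_neg: int) -> np.ndarray:
    """Row-wise AUROC for a (B, n_pos + n_neg) matrix, positives first."""
    ranks = rankdata(score_matrix, axis=1)
    return (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def bootstrap_auroc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUROC.

    Positives and negatives are resampled within class, so class counts are
    fixed and no resample can degenerate to a single class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    pos = s[y == 1]
    neg = s[y == 0]
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    bn = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    aucs = _auroc_rows(np.hstack([bp, bn]), len(pos), len(neg))
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


@dataclass(frozen=True)
class MetricsReport:
    """Per-model discrimination summary (positive class = sensitive)."""

    auroc: float
    auroc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict[str, float]:
        d = {
            "auroc": self.auroc,
            "auroc_ci_lower": self.auroc_ci[0],
            "auroc_ci_upper": self.auroc_ci[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        return d


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict[str, float]:
    """Confusion-matrix metrics at a fixed threshold (predict positive iff
    score >= threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
        "n_pos": tp + fn,
        "n_neg": tn + fp,
    }


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricsReport:
    """Full MetricsReport: AUROC with bootstrap CI plus threshold metrics."""
    point = auroc(scores, labels)
    ci = bootstrap_auroc_ci(scores, labels, n_boot=n_boot, level=level, seed=seed)
    tm = threshold_metrics(scores, labels, threshold)
    return MetricsReport(
        auroc=point,
        auroc_ci=ci,
        sensitivity=tm["sensitivity"],
        specificity=tm["specificity"],
        accuracy=tm["accuracy"],
        f1=tm["f1"],
        threshold=threshold,
        n_pos=int(tm["n_pos"]),
        n_neg=int(tm["n_neg"]),
    )
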