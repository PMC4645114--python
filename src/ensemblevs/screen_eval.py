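"""Classifier and campaign evaluation: ROC/AUC, confusion metrics, hit
rates, potency-threshold counts, and top-N hit-list overlap."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class EvalReport:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float

    def __post_init__(self) -> None:
        for name in ("auc", "sensitivity", "specificity", "accuracy"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "threshold": self.threshold,
        }


def _check_labels(labels: np.ndarray) -> None:
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney identity U/(n1*n0), ties counted 1/2.

    Higher score = predicted active.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    _check_labels(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.0
) -> EvalReport:
    """Sensitivity/specificity/accuracy at ``score >= threshold`` =>
    predicted active.  The default threshold 0 is the naive-Bayes neutral
    (no-information) point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    predicted = scores >= threshold
    actual = labels == 1
    tp = int(np.sum(predicted & actual))
    tn = int(np.sum(~predicted & ~actual))
    fp = int(np.sum(predicted & ~actual))
    fn = int(np.sum(~predicted & actual))
    return EvalReport(
        auc=roc_auc(scores, labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / labels.size,
        threshold=float(threshold),
    )


def hit_rate(n_hits: int, n_tested: int) -> float:
    """Percentage of tested compounds that proved active, to 2 decimals."""
    if n_tested <= 0:
        raise ValueError("n_tested must be > 0")
    if not 0 <= n_hits <= n_tested:
        raise ValueError("need 0 <= n_hits <= n_tested")
    return round(100.0 * n_hits / n_tested, 2)


def count_below_threshold(values: Sequence[float], cutoff: float) -> int:
    """Strict less-than count (e.g. IC50 values below a potency cutoff)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        raise ValueError("values must be finite and positive")
    return int(np.sum(arr < cutoff))


def hitlist_similarity(
    ranking_a: Sequence[str], ranking_b: Sequence[str], n: int = 500
) -> float:
    """Jaccard index of the two top-``n`` id sets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranking_a) or n > len(ranking_b):
        raise ValueError("n exceeds a ranking's length")
    top_a = set(ranking_a[:n])
    top_b = set(ranking_b[:n])
    if len(top_a) != n or len(top_b) != n:
        raise ValueError("rankings contain duplicate ids in their top-n")
    union = top_a | top_b
    if not union:
        return 0.0
    return len(top_a & top_b) / len(union)
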