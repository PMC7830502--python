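"""Discrimination metrics (AUC, TSS) and binarization thresholds (MTP, MTSS).

Conventions: a score >= threshold is predicted suitable. Ties being
classed suitable is what makes the minimum-training-presence rule honest:
binarizing at MTP keeps every training presence suitable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "confusion_at",
    "tss",
    "auc",
    "find_mtss",
    "find_mtp",
    "binarize",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    """Held-out discrimination scores and thresholds for one model.

    ``tss`` is sensitivity + specificity - 1 evaluated at ``threshold_mtss``.
    """

    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold_mtss: float
    threshold_mtp: float


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.size == 0:
        raise ValueError("empty score list")
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with 'predicted suitable iff score >= threshold'."""
    scores, labels = _check_binary(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def tss(counts: ConfusionCounts) -> float:
    """True Skill Statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("TSS undefined: one class is absent")
    return counts.sensitivity + counts.specificity - 1.0


def auc(scores, labels) -> float:
    """ROC AUC by the Mann-Whitney pair-counting estimator (ties = 0.5)."""
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class is absent")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def find_mtss(scores, labels) -> tuple[float, float]:
    """Threshold maximizing sensitivity + specificity (candidate = unique scores).

    Returns ``(threshold, tss_at_threshold)``; ties broken toward the
    smallest qualifying threshold.
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("MTSS undefined: one class is absent")
    candidates = np.unique(scores)
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        score = sens + spec - 1.0
        if score > best_tss + 1e-12:
            best_t, best_tss = t, score
    return float(best_t), float(best_tss)


def find_mtp(presence_scores) -> float:
    """Minimum training presence: the lowest score at any training presence."""
    presence_scores = np.asarray(presence_scores, dtype=float).ravel()
    if presence_scores.size == 0:
        raise ValueError("no presence scores")
    return float(presence_scores.min())


def binarize(surface, threshold: float):
    """Binary suitability map: 1 iff value >= threshold; nodata propagated.

    Accepts a RasterGrid (returns a RasterGrid) or a bare array.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = surface.values if hasattr(surface, "values") else np.asarray(surface, float)
    out = np.where(np.isfinite(values), (values >= threshold).astype(float), np.nan)
    if hasattr(surface, "with_values"):
        return surface.with_values(out)
    return out
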