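"""Ordinal evaluation statistics for K-grade classification.

Implements the evaluation protocol used to compare graders and grading
models on ordinal scales: quadratic-weighted Cohen's kappa (the standard
inter-observer agreement statistic for disease grading), the pairwise-
averaged multiclass AUROC (Hand-Till construction), support-weighted
precision / recall / F1, and the multiclass Matthews correlation
coefficient.  All confusion-matrix statistics operate on a plain K x K
count table with rows = true grade and columns = predicted grade.

Predicted grades are the arg-max of the per-sample score vector; score ties
resolve to the lowest (least severe) grade, deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "UndefinedMetricError",
    "ScoreTable",
    "confusion_matrix",
    "quadratic_weight_matrix",
    "quadratic_weighted_kappa",
    "weighted_prf",
    "multiclass_mcc",
    "pairwise_average_auroc",
    "METRIC_FUNCTIONS",
    "evaluate_table",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given input."""


@dataclass
class ScoreTable:
    """Per-sample predicted class scores plus true grades.

    Fields
    ------
    ids:
        Sample identifiers (any hashable scalar type).
    y_true:
        Integer true grades in 0..K-1.
    scores:
        (n, K) array of per-class scores (need not be normalized).
    """

    ids: np.ndarray
    y_true: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        n = len(self.ids)
        if not (len(self.y_true) == self.scores.shape[0] == n):
            raise ValueError("ids, y_true and scores must have equal length")
        if n and (self.y_true.min() < 0 or self.y_true.max() >= self.K):
            raise ValueError("y_true outside 0..K-1")

    @property
    def K(self) -> int:
        return self.scores.shape[1]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def y_pred(self) -> np.ndarray:
        # np.argmax returns the first maximum, i.e. ties break to the
        # lowest (least severe) grade
        return np.argmax(self.scores, axis=1)

    def subset(self, indices: np.ndarray) -> "ScoreTable":
        """A new table restricted (or resampled) to ``indices``."""
        return ScoreTable(
            ids=self.ids[indices],
            y_true=self.y_true[indices],
            scores=self.scores[indices],
        )


def confusion_matrix(table: ScoreTable) -> np.ndarray:
    """K x K integer count table; rows = true grade, columns = predicted."""
    if table.n == 0:
        raise ValueError("cannot build a confusion matrix from an empty table")
    K = table.K
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (table.y_true, table.y_pred), 1)
    return cm


def quadratic_weight_matrix(K: int) -> np.ndarray:
    """Disagreement weights ``w_ij = (i - j)^2 / (K - 1)^2``."""
    idx = np.arange(K)
    return (idx[:, None] - idx[None, :]) ** 2 / (K - 1) ** 2


def quadratic_weighted_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement with squared-distance penalties.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` where O is the observed
    proportion matrix and E the outer product of its marginals.  Raises
    :class:`UndefinedMetricError` when both raters place every sample in
    one identical class (expected disagreement zero).
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise UndefinedMetricError("empty confusion matrix")
    O = cm / total
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    w = quadratic_weight_matrix(cm.shape[0])
    denom = (w * E).sum()
    if denom == 0.0:
        raise UndefinedMetricError(
            "quadratic-weighted kappa undefined: zero expected disagreement"
        )
    return float(1.0 - (w * O).sum() / denom)


def weighted_prf(cm: np.ndarray) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 from a confusion matrix.

    Per-class scores are averaged with weights proportional to the true
    class supports.  A class with zero predicted (resp. true) samples
    contributes 0 to the weighted precision (resp. recall), with a warning.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise UndefinedMetricError("empty confusion matrix")
    tp = np.diag(cm)
    pred_tot = cm.sum(axis=0)
    true_tot = cm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / np.where(pred_tot > 0, pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.where(true_tot > 0, true_tot, 1), 0.0)
        pr_sum = precision + recall
        f1 = np.where(pr_sum > 0, 2 * precision * recall / np.where(pr_sum > 0, pr_sum, 1), 0.0)
    if np.any((pred_tot == 0) & (true_tot > 0)):
        warnings.warn(
            "some classes received no predictions; their precision counts 0",
            RuntimeWarning,
            stacklevel=2,
        )
    weights = true_tot / total
    return (
        float((weights * precision).sum()),
        float((weights * recall).sum()),
        float((weights * f1).sum()),
    )


def multiclass_mcc(cm: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (R_K statistic).

    Covariance of true/predicted indicator vectors over the geometric mean
    of their marginal variances; returns 0 by convention when a marginal
    variance vanishes (e.g. all predictions in one class).
    """
    cm = np.asarray(cm, dtype=float)
    s = cm.sum()
    if s <= 0:
        raise UndefinedMetricError("empty confusion matrix")
    c = np.trace(cm)
    t = cm.sum(axis=1)  # true-class counts
    p = cm.sum(axis=0)  # predicted-class counts
    cov_yp = c * s - (t * p).sum()
    cov_yy = s * s - (t * t).sum()
    cov_pp = s * s - (p * p).sum()
    denom = np.sqrt(cov_yy) * np.sqrt(cov_pp)
    if denom == 0.0:
        return 0.0
    return float(cov_yp / denom)


def pairwise_average_auroc(table: ScoreTable) -> float:
    """Pairwise-averaged multiclass AUROC (Hand-Till construction).

    For every unordered pair of classes (i, j) both present in the data,
    the rank-based (Mann-Whitney) AUROC of class i's score restricted to
    samples truly in {i, j} is averaged with its mirror for class j; the
    result is the mean of these pair separabilities over all present pairs.
    Score ties count 1/2.
    """
    present = np.unique(table.y_true)
    if len(present) < 2:
        raise UndefinedMetricError(
            "pairwise AUROC needs at least two classes present"
        )
    pair_values = []
    for a_idx in range(len(present)):
        for b_idx in range(a_idx + 1, len(present)):
            i, j = int(present[a_idx]), int(present[b_idx])
            mask = (table.y_true == i) | (table.y_true == j)
            y = table.y_true[mask]
            a_ij = _binary_rank_auc(table.scores[mask, i], y == i)
            a_ji = _binary_rank_auc(table.scores[mask, j], y == j)
            pair_values.append(0.5 * (a_ij + a_ji))
    return float(np.mean(pair_values))


def _binary_rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for the ``positive`` mask; ties at 1/2."""
    n_pos = int(positive.sum())
    n_neg = int(len(scores) - n_pos)
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum = ranks[positive].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _kappa_of_table(table: ScoreTable) -> float:
    return quadratic_weighted_kappa(confusion_matrix(table))


def _mcc_of_table(table: ScoreTable) -> float:
    return multiclass_mcc(confusion_matrix(table))


def _prf_component(which: int) -> Callable[[ScoreTable], float]:
    def metric(table: ScoreTable) -> float:
        return weighted_prf(confusion_matrix(table))[which]

    return metric


#: the full evaluation protocol: metric name -> function of a ScoreTable
METRIC_FUNCTIONS: dict[str, Callable[[ScoreTable], float]] = {
    "quad_kappa": _kappa_of_table,
    "auroc": pairwise_average_auroc,
    "f1": _prf_component(2),
    "precision": _prf_component(0),
    "recall": _prf_component(1),
    "mcc": _mcc_of_table,
}


def evaluate_table(table: ScoreTable) -> dict[str, float]:
    """All protocol metrics of a score table, by name."""
    return {name: fn(table) for name, fn in METRIC_FUNCTIONS.items()}
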