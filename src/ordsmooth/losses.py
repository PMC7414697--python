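"""Soft-target cross-entropy.

The single objective connecting any label scheme to classifier training:
``L(p, q) = -sum_k q_k * log(p_k)`` for a predictive probability vector p
and a soft target q.  With a one-hot q this is the ordinary cross-entropy;
the loss is linear in q, so unnormalized Gaussian-smoothed targets (corner
grades summing to < 1) are consumed as-is, without rescaling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_cross_entropy", "batch_loss", "LOG_EPS"]

#: probabilities are clamped at this floor before the log
LOG_EPS = 1e-12


def soft_cross_entropy(p: np.ndarray, q: np.ndarray) -> float:
    """Cross-entropy of soft target ``q`` under predicted probabilities ``p``."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: p{p.shape} vs q{q.shape}")
    return float(-(q * np.log(np.clip(p, LOG_EPS, None))).sum())


def batch_loss(
    ps: np.ndarray, qs: np.ndarray, reduction: str = "mean"
) -> float:
    """Reduced per-sample soft cross-entropy over a batch.

    ``ps`` and ``qs`` are (n, K) arrays of predicted probabilities and soft
    targets; ``reduction`` is ``"mean"`` (default) or ``"sum"``.
    """
    ps = np.atleast_2d(np.asarray(ps, dtype=float))
    qs = np.atleast_2d(np.asarray(qs, dtype=float))
    if ps.shape != qs.shape:
        raise ValueError(f"shape mismatch: ps{ps.shape} vs qs{qs.shape}")
    if ps.shape[0] == 0:
        raise ValueError("empty batch")
    per_sample = -(qs * np.log(np.clip(ps, LOG_EPS, None))).sum(axis=1)
    if reduction == "mean":
        return float(per_sample.mean())
    if reduction == "sum":
        return float(per_sample.sum())
    raise ValueError(f"unknown reduction {reduction!r}")
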