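"""Scale-anchored performance metrics.

Both metrics are calibrated so the uninformed baseline lands on a fixed
number: a constant-mean predictor scores a standardized MSE of exactly 100,
and uniform probability guessing scores a normalized Brier of exactly 25
for every class count.
"""

from __future__ import annotations

import numpy as np

__all__ = ["standardized_mse", "brier_score", "misclassification_rate"]


def standardized_mse(y: np.ndarray, yhat: np.ndarray, var_y: float | None = None) -> float:
    """100 * MSE / Var(y), with the population variance (denominator n).

    ``var_y`` optionally supplies an external variance (e.g. the full
    response variance when pooling cross-validation folds).
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length vectors")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    v = float(np.var(y)) if var_y is None else float(var_y)
    if v <= 0:
        raise ValueError("response variance must be positive")
    return 100.0 * float(np.mean((y - yhat) ** 2)) / v


def brier_score(probs: np.ndarray, labels: np.ndarray, atol: float = 1e-8) -> float:
    """Normalized multiclass Brier score, times 100.

    100 * (J / (4(J-1))) * mean_i sum_j (p_ij - 1{y_i = j})^2 — the unique
    linear scaling of the sum-over-classes Brier for which uniform guessing
    scores 25 regardless of J.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2:
        raise ValueError("probs must be an n x J matrix")
    n, J = probs.shape
    if J < 2:
        raise ValueError("need J >= 2 classes")
    if labels.shape != (n,):
        raise ValueError("labels must be a length-n vector")
    labels = labels.astype(np.int64)
    if labels.min() < 0 or labels.max() >= J:
        raise ValueError("labels must lie in 0..J-1")
    if (probs < -atol).any() or np.abs(probs.sum(axis=1) - 1.0).max() > atol:
        raise ValueError("probs rows must be non-negative and sum to 1")
    onehot = np.zeros((n, J))
    onehot[np.arange(n), labels] = 1.0
    raw = float(np.mean(((probs - onehot) ** 2).sum(axis=1)))
    return 100.0 * raw * J / (4.0 * (J - 1))


def misclassification_rate(probs: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of cases whose argmax class differs from the true label."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    return float(np.mean(probs.argmax(axis=1) != labels))
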