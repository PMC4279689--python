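"""COBRA-style regression collective: zero-one proximity-of-predictions weights.

A training point is a neighbour of a test point when, for enough of the
constituent machines, the two points' predictions under that machine are
within ``eps``. The collective's prediction is the plain average of the
outcomes of the neighbours — outcomes are weighted by exactly 0 or 1, in
contrast to a forest's arbitrary convex weights. ``eps`` is calibrated by
brute-force risk minimisation over a linear grid (200 points by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CollectivePredictions",
    "CobraParams",
    "cobra_weights",
    "cobra_predict",
    "eps_grid",
    "calibrate_eps",
]


@dataclass(frozen=True)
class CollectivePredictions:
    """Constituent-machine predictions at the training points plus outcomes."""

    train_preds: np.ndarray  # (n_train, M)
    train_y: np.ndarray  # (n_train,)

    def __post_init__(self) -> None:
        preds = np.asarray(self.train_preds, dtype=np.float64)
        y = np.asarray(self.train_y, dtype=np.float64)
        if preds.ndim != 2 or preds.shape[1] < 1:
            raise ValueError("train_preds must be an n x M matrix with M >= 1")
        if y.shape != (preds.shape[0],):
            raise ValueError("train_y length must match train_preds rows")
        if not (np.isfinite(preds).all() and np.isfinite(y).all()):
            raise ValueError("collective contains non-finite entries")
        object.__setattr__(self, "train_preds", preds)
        object.__setattr__(self, "train_y", y)

    @property
    def M(self) -> int:
        return self.train_preds.shape[1]


@dataclass(frozen=True)
class CobraParams:
    """Closeness threshold, agreement fraction, and calibration grid size.

    ``alpha_frac=1.0`` demands unanimity among machines (the reference
    method's default); ``0.5`` reproduces a simple-majority rule.
    """

    eps: float = 0.0
    alpha_frac: float = 1.0
    grid_size: int = 200

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be non-negative")
        if not 0 < self.alpha_frac <= 1:
            raise ValueError("alpha_frac must lie in (0, 1]")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")


def _pair_thresholds(
    collective: CollectivePredictions, test_preds: np.ndarray, alpha_frac: float
) -> np.ndarray:
    """For each (test, train) pair: the smallest eps at which the pair is
    close, i.e. the k-th smallest per-machine |prediction difference| with
    k = ceil(alpha_frac * M)."""
    train = collective.train_preds
    k = int(np.ceil(alpha_frac * collective.M))
    out = np.empty((test_preds.shape[0], train.shape[0]))
    # chunk test rows to keep broadcast temporaries small
    step = max(1, 4_000_000 // (train.shape[0] * collective.M))
    for i in range(0, test_preds.shape[0], step):
        diffs = np.abs(test_preds[i : i + step, None, :] - train[None, :, :])
        if k >= collective.M:
            out[i : i + step] = diffs.max(axis=2)
        else:
            out[i : i + step] = np.partition(diffs, k - 1, axis=2)[:, :, k - 1]
    return out


def _as_batch(test_preds: np.ndarray, M: int) -> tuple[np.ndarray, bool]:
    test_preds = np.asarray(test_preds, dtype=np.float64)
    single = test_preds.ndim == 1
    if single:
        test_preds = test_preds.reshape(1, -1)
    if test_preds.shape[1] != M:
        raise ValueError(f"expected {M} machine predictions per test point")
    return test_preds, single


def cobra_weights(
    collective: CollectivePredictions, test_preds: np.ndarray, params: CobraParams
) -> np.ndarray:
    """Zero-one weight matrix (n_test, n_train): 1 iff the training point is
    within eps of the test point for at least ceil(alpha_frac * M) machines."""
    test_preds, single = _as_batch(test_preds, collective.M)
    w = _pair_thresholds(collective, test_preds, params.alpha_frac) <= params.eps
    return w[0] if single else w


def cobra_predict(
    collective: CollectivePredictions, test_preds: np.ndarray, params: CobraParams
) -> float | np.ndarray:
    """Mean training outcome over the weight-1 neighbours.

    Accepts a single M-vector (returns a float) or an (n_test, M) batch.
    A test point with no neighbours falls back to the global training mean
    (with a warning) so that prediction stays total.
    """
    test_preds, single = _as_batch(test_preds, collective.M)
    w = cobra_weights(collective, test_preds, params)
    counts = w.sum(axis=1)
    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} test point(s) had no eps-neighbours; "
            "falling back to the global training mean",
            stacklevel=2,
        )
    out = np.where(
        empty,
        collective.train_y.mean(),
        (w @ collective.train_y) / np.maximum(counts, 1),
    )
    return float(out[0]) if single else out


def eps_grid(collective: CollectivePredictions, grid_size: int = 200) -> np.ndarray:
    """Linear grid of ``grid_size`` values over (0, s] where s is the
    largest per-machine training-prediction spread."""
    spread = float(np.ptp(collective.train_preds, axis=0).max())
    if spread <= 0:
        warnings.warn(
            "all machine predictions are identical; eps grid degenerates to 0",
            stacklevel=2,
        )
        return np.zeros(1)
    return np.linspace(spread / grid_size, spread, grid_size)


def calibrate_eps(
    collective: CollectivePredictions,
    holdout_preds: np.ndarray,
    holdout_y: np.ndarray,
    params: CobraParams | None = None,
    exclude_self: bool = False,
) -> float:
    """Brute-force squared-error risk scan over the eps grid.

    Evaluates the collective's prediction of ``holdout_y`` from
    ``holdout_preds`` at each grid value and returns the risk minimiser
    (ties go to the smallest eps). With ``exclude_self=True`` the holdout is
    taken to be the training set itself and each point is barred from its
    own neighbourhood (leave-one-out calibration on OOB machine
    predictions).
    """
    params = params or CobraParams()
    holdout_preds, _ = _as_batch(holdout_preds, collective.M)
    holdout_y = np.asarray(holdout_y, dtype=np.float64)
    if holdout_y.shape != (holdout_preds.shape[0],):
        raise ValueError("holdout_y length must match holdout_preds rows")
    if holdout_y.size == 0:
        raise ValueError("holdout must be non-empty")
    if exclude_self and holdout_preds.shape[0] != collective.train_preds.shape[0]:
        raise ValueError("exclude_self requires the holdout to be the training set")
    thresholds = _pair_thresholds(collective, holdout_preds, params.alpha_frac)
    if exclude_self:
        np.fill_diagonal(thresholds, np.inf)
    grid = eps_grid(collective, params.grid_size)
    y_mean = collective.train_y.mean()
    risks = np.empty(grid.size)
    for i, eps in enumerate(grid):
        w = thresholds <= eps
        counts = w.sum(axis=1)
        preds = np.where(
            counts == 0, y_mean, (w @ collective.train_y) / np.maximum(counts, 1)
        )
        risks[i] = np.mean((holdout_y - preds) ** 2)
    return float(grid[int(np.argmin(risks))])
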