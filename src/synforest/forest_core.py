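"""Base random-forest layer with explicit bootstrap bookkeeping.

Forests are trained through scikit-learn, but the per-tree bootstrap
multiplicity ("inbag") matrix is reconstructed from the estimator seeds so
that out-of-bag aggregation is done explicitly and can be audited: the OOB
value for a case provably uses no tree whose bootstrap contained it.

Nodesize semantics: by default ("split") a node with fewer than 2*nodesize
cases is terminal, matching the effective behaviour of the reference forest
engine (terminal nodes then average about nodesize cases). The strict
reading — every terminal node holds at least nodesize unique in-bag cases —
is available as ``nodesize_semantics="leaf"`` (sklearn's
``min_samples_leaf``, which excludes zero-weight cases from its counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.ensemble._forest import _generate_sample_indices

TaskKind = Literal["regression", "multiclass"]

__all__ = [
    "Dataset",
    "ForestParams",
    "FittedForest",
    "OOBPrediction",
    "compute_mtry",
    "fit_forest",
    "predict_forest",
    "oob_predict",
    "save_forest",
    "load_forest",
]


@dataclass(frozen=True)
class Dataset:
    """A fully numeric feature matrix plus response, the unit every stage consumes.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Feature matrix; categorical features must already be integer-coded.
    y : ndarray of shape (n,)
        Real-valued response (regression) or labels ``0..J-1`` (multiclass).
    task : {"regression", "multiclass"}
    J : int, optional
        Number of classes; required iff ``task == "multiclass"``.
    feature_names : tuple of str, optional
    """

    X: np.ndarray
    y: np.ndarray
    task: TaskKind
    J: int | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        object.__setattr__(self, "X", X)
        n, p = X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if self.task not in ("regression", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "regression":
            y = np.asarray(self.y, dtype=np.float64)
            if self.J is not None:
                raise ValueError("J only applies to multiclass data")
            if not np.isfinite(y).all():
                raise ValueError("y contains non-finite values")
        else:
            y = np.asarray(self.y)
            if self.J is None or self.J < 2:
                raise ValueError("multiclass data requires J >= 2")
            y = y.astype(np.int64)
            present = np.unique(y)
            if not np.array_equal(present, np.arange(self.J)):
                raise ValueError(
                    f"multiclass labels must cover 0..{self.J - 1}; saw {present}"
                )
        if y.shape != (n,):
            raise ValueError(f"y must have shape ({n},), got {y.shape}")
        object.__setattr__(self, "y", y)
        if self.feature_names is not None:
            names = tuple(self.feature_names)
            if len(names) != p:
                raise ValueError("feature_names length must equal p")
            object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def compute_mtry(p: int, rule: str = "strict") -> int:
    """Number of candidate split features: the p/3 default rule.

    ``rule="strict"`` returns the first integer strictly greater than p/3
    (so p=3 gives 2); ``rule="ceil"`` returns ceil(p/3) (p=3 gives 1).
    Both are clamped to ``[1, p]``.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if rule == "strict":
        m = p // 3 + 1
    elif rule == "ceil":
        m = math.ceil(p / 3)
    else:
        raise ValueError(f"unknown mtry rule {rule!r}")
    return max(1, min(p, m))


@dataclass(frozen=True)
class ForestParams:
    """The (ntree, mtry, nodesize) tuning triple plus a seed.

    ``nodesize_semantics`` selects how nodesize is enforced:

    - ``"split"`` (default): a node with fewer than 2*nodesize cases is
      terminal, matching the effective behaviour of the reference forest
      engine (terminal nodes then hold nodesize cases on average);
    - ``"leaf"``: every terminal node holds at least nodesize cases — the
      strict minimum-leaf reading, which smooths noticeably more at equal
      nodesize.
    """

    ntree: int
    mtry: int
    nodesize: int
    seed: int = 0
    nodesize_semantics: str = "split"

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if self.nodesize_semantics not in ("split", "leaf"):
            raise ValueError("nodesize_semantics must be 'split' or 'leaf'")


@dataclass
class FittedForest:
    """A trained ensemble with its bootstrap multiplicity matrix.

    ``inbag[t, i]`` is the number of times case ``i`` appeared in tree
    ``t``'s bootstrap sample; each row sums to the training sample size.
    """

    params: ForestParams
    task: TaskKind
    inbag: np.ndarray
    predictor: RandomForestRegressor | RandomForestClassifier
    training_n: int
    training_p: int
    J: int | None = None

    def __post_init__(self) -> None:
        assert self.inbag.shape == (self.params.ntree, self.training_n)


@dataclass
class OOBPrediction:
    """Out-of-bag aggregated predictions with a coverage mask.

    ``covered[i]`` is True iff case ``i`` was out-of-bag for at least one
    tree; uncovered entries of ``values`` are NaN, never silently zero.
    """

    values: np.ndarray
    covered: np.ndarray

    @property
    def n_covered(self) -> int:
        return int(self.covered.sum())


def fit_forest(data: Dataset, params: ForestParams) -> FittedForest:
    """Grow a seeded forest of ``ntree`` bootstrap trees on ``data``.

    Deterministic given (data, params): refitting yields bit-identical
    predictions. Splits consider ``mtry`` random candidate features and
    terminal nodes keep at least ``nodesize`` unique in-bag cases.
    """
    if params.mtry > data.p:
        raise ValueError(f"mtry={params.mtry} exceeds p={data.p}")
    if params.nodesize > data.n:
        raise ValueError(f"nodesize={params.nodesize} exceeds n={data.n}")
    if params.nodesize_semantics == "leaf":
        size_constraint = dict(min_samples_leaf=params.nodesize)
    else:
        size_constraint = dict(min_samples_split=max(2 * params.nodesize, 2))
    common = dict(
        n_estimators=params.ntree,
        max_features=params.mtry,
        bootstrap=True,
        random_state=params.seed % 2**32,  # sklearn requires a uint32
        n_jobs=1,
        **size_constraint,
    )
    if data.task == "regression":
        model: RandomForestRegressor | RandomForestClassifier = RandomForestRegressor(
            criterion="squared_error", **common
        )
    else:
        model = RandomForestClassifier(criterion="gini", **common)
    model.fit(data.X, data.y)
    inbag = np.stack(
        [
            np.bincount(
                _generate_sample_indices(est.random_state, data.n, data.n, None),
                minlength=data.n,
            )
            for est in model.estimators_
        ]
    )
    return FittedForest(
        params=params,
        task=data.task,
        inbag=inbag,
        predictor=model,
        training_n=data.n,
        training_p=data.p,
        J=data.J,
    )


def predict_forest(forest: FittedForest, Xnew: np.ndarray) -> np.ndarray:
    """Full-forest prediction: a value vector (regression) or a row-stochastic
    n_new x J probability matrix (multiclass)."""
    Xnew = np.asarray(Xnew, dtype=np.float64)
    if Xnew.ndim == 1:
        Xnew = Xnew.reshape(1, -1)
    if Xnew.shape[1] != forest.training_p:
        raise ValueError(
            f"expected {forest.training_p} feature columns, got {Xnew.shape[1]}"
        )
    if forest.task == "regression":
        return forest.predictor.predict(Xnew)
    return forest.predictor.predict_proba(Xnew)


def _per_tree_predictions(forest: FittedForest, X: np.ndarray) -> np.ndarray:
    # one C-level apply() call instead of ntree Python-level predict calls
    leaves = forest.predictor.apply(X)  # (n, ntree)
    if forest.task == "regression":
        out = np.empty((forest.params.ntree, X.shape[0]))
        for t, est in enumerate(forest.predictor.estimators_):
            out[t] = est.tree_.value[leaves[:, t], 0, 0]
        return out
    out = np.empty((forest.params.ntree, X.shape[0], forest.J))
    for t, est in enumerate(forest.predictor.estimators_):
        counts = est.tree_.value[leaves[:, t], 0, :]
        out[t] = counts / counts.sum(axis=1, keepdims=True)
    return out


def oob_predict(forest: FittedForest, data: Dataset) -> OOBPrediction:
    """Aggregate, for each training case, only the trees that did not see it.

    The result is an out-of-sample estimate: the value for case ``i`` never
    uses ``y[i]``. Cases that were in-bag for every tree are flagged
    uncovered and returned as NaN.
    """
    if data.n != forest.training_n or data.p != forest.training_p:
        raise ValueError("forest was not fitted on a dataset of this shape")
    preds = _per_tree_predictions(forest, data.X)
    oob_mask = forest.inbag == 0  # (ntree, n)
    counts = oob_mask.sum(axis=0).astype(np.float64)
    covered = counts > 0
    if forest.task == "regression":
        num = np.where(oob_mask, preds, 0.0).sum(axis=0)
        values = np.divide(num, counts, out=np.full(data.n, np.nan), where=covered)
    else:
        w = oob_mask[:, :, None]
        num = np.where(w, preds, 0.0).sum(axis=0)
        values = np.divide(
            num,
            counts[:, None],
            out=np.full((data.n, preds.shape[2]), np.nan),
            where=covered[:, None],
        )
    return OOBPrediction(values=values, covered=covered)


def save_forest(forest: FittedForest, path) -> None:
    """Serialize a fitted forest to ``path`` (joblib archive)."""
    joblib.dump({"format": "synforest.forest.v1", "forest": forest}, path)


def load_forest(path) -> FittedForest:
    payload = joblib.load(path)
    if payload.get("format") != "synforest.forest.v1":
        raise ValueError(f"{path} is not a synforest forest archive")
    return payload["forest"]
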