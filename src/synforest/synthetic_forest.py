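"""Synthetic random forests.

A grid of forests is grown over increasing terminal-node sizes; each grid
forest contributes its out-of-bag predictions as new "synthetic" feature
columns (one per machine in regression, the first J-1 class probabilities
in multiclass). A secondary forest — the hyperforest — is then fitted on the
original features plus the synthetic columns, letting individual node splits
choose locally among smoothing bandwidths. The grid also yields the
baselines: the plain forest (grid value equal to the hyperforest nodesize)
and the globally OOB-optimal forest (RFopt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np

from .forest_core import (
    Dataset,
    FittedForest,
    ForestParams,
    compute_mtry,
    fit_forest,
    oob_predict,
    predict_forest,
)
from .metrics import brier_score, misclassification_rate

__all__ = [
    "DEFAULT_NODESIZE_GRID",
    "SyntheticConfig",
    "SyntheticFeatureSet",
    "SRFModel",
    "build_synthetic_features",
    "fit_srf",
    "predict_srf",
    "select_rfopt",
    "oob_error",
    "save_srf",
    "load_srf",
]

#: a handful of small values, a few intermediate, a few large
DEFAULT_NODESIZE_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 30, 50, 100)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic-forest pipeline.

    ``nodesize_grid`` must be strictly ascending; values >= n are pruned at
    fit time. ``hyper_mtry_on`` controls whether the hyperforest's mtry is
    computed on the augmented dimension p+q (default) or the original p.
    """

    nodesize_grid: tuple[int, ...] = DEFAULT_NODESIZE_GRID
    ntree: int = 500
    hyper_nodesize: int = 5
    mtry_rule: str = "strict"
    hyper_mtry_on: str = "augmented"
    nodesize_semantics: str = "split"
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(int(v) for v in self.nodesize_grid)
        if len(grid) < 2:
            raise ValueError("nodesize_grid needs at least 2 values")
        if any(v < 1 for v in grid):
            raise ValueError("nodesize values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("nodesize_grid must be strictly ascending")
        object.__setattr__(self, "nodesize_grid", grid)
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.hyper_nodesize < 1:
            raise ValueError("hyper_nodesize must be >= 1")
        if self.hyper_mtry_on not in ("augmented", "original"):
            raise ValueError("hyper_mtry_on must be 'augmented' or 'original'")
        if self.nodesize_semantics not in ("split", "leaf"):
            raise ValueError("nodesize_semantics must be 'split' or 'leaf'")

    def pruned_grid(self, n: int) -> tuple[int, ...]:
        grid = tuple(v for v in self.nodesize_grid if v < n)
        if not grid:
            raise ValueError(f"no nodesize grid values remain below n={n}")
        return grid


@dataclass
class SyntheticFeatureSet:
    """OOB synthetic columns plus the machine -> column bookkeeping."""

    columns: np.ndarray
    machine_map: list[tuple[int, np.ndarray]]

    @property
    def q(self) -> int:
        return self.columns.shape[1]


@dataclass
class SRFModel:
    """Grid forests plus the hyperforest fitted on the augmented matrix.

    The hyperforest's training columns are the original p features followed
    by the synthetic columns in ``machine_map`` order (ascending nodesize;
    within a machine, class-probability columns 0..J-2).
    """

    component_forests: list[FittedForest]
    hyperforest: FittedForest
    config: SyntheticConfig
    grid: tuple[int, ...]
    machine_map: list[tuple[int, np.ndarray]]
    rfopt_nodesize: int
    task: str
    p: int
    includes_synthetic: bool = True
    train_synthetic: np.ndarray | None = None

    @property
    def q(self) -> int:
        return sum(len(cols) for _, cols in self.machine_map)


def _oob_error_from(oob, data: Dataset, multiclass_metric: str = "brier") -> float:
    covered = oob.covered
    if not covered.any():
        raise ValueError("no case has an OOB prediction")
    if data.task == "regression":
        return float(np.mean((data.y[covered] - oob.values[covered]) ** 2))
    if multiclass_metric == "brier":
        return brier_score(oob.values[covered], data.y[covered])
    if multiclass_metric == "misclassification":
        return misclassification_rate(oob.values[covered], data.y[covered])
    raise ValueError(f"unknown multiclass metric {multiclass_metric!r}")


def _machine_columns(forest: FittedForest, data: Dataset, oob) -> np.ndarray:
    """OOB prediction columns for one machine, uncovered cases imputed with
    the full-forest prediction (out-of-sample character is preserved for
    the covered, in practice ~all, cases)."""
    values = oob.values
    if not oob.covered.all():
        full = predict_forest(forest, data.X)
        if data.task == "regression":
            values = np.where(oob.covered, values, full)
        else:
            values = np.where(oob.covered[:, None], values, full)
    if data.task == "regression":
        return values.reshape(-1, 1)
    return values[:, : data.J - 1]  # drop the linearly dependent last column


def _fit_machines(
    data: Dataset, config: SyntheticConfig
) -> tuple[SyntheticFeatureSet, list[FittedForest], list[float]]:
    grid = config.pruned_grid(data.n)
    mtry = compute_mtry(data.p, config.mtry_rule)
    forests: list[FittedForest] = []
    blocks: list[np.ndarray] = []
    errors: list[float] = []
    machine_map: list[tuple[int, np.ndarray]] = []
    offset = 0
    for j, nodesize in enumerate(grid):
        params = ForestParams(
            ntree=config.ntree,
            mtry=mtry,
            nodesize=nodesize,
            seed=config.seed + j,
            nodesize_semantics=config.nodesize_semantics,
        )
        forest = fit_forest(data, params)
        oob = oob_predict(forest, data)
        cols = _machine_columns(forest, data, oob)
        forests.append(forest)
        blocks.append(cols)
        errors.append(_oob_error_from(oob, data))
        machine_map.append((nodesize, offset + np.arange(cols.shape[1])))
        offset += cols.shape[1]
    features = SyntheticFeatureSet(columns=np.hstack(blocks), machine_map=machine_map)
    return features, forests, errors


def build_synthetic_features(
    data: Dataset, config: SyntheticConfig
) -> tuple[SyntheticFeatureSet, list[FittedForest]]:
    """Fit one forest per grid nodesize and collect their OOB columns.

    Machine j uses (ntree, mtry(p), grid[j]) and seed ``config.seed + j``.
    """
    features, forests, _ = _fit_machines(data, config)
    return features, forests


def oob_error(
    forest: FittedForest, data: Dataset, multiclass_metric: str = "brier"
) -> float:
    """OOB prediction error of one forest: MSE for regression, normalized
    Brier (default) or misclassification rate for multiclass."""
    return _oob_error_from(oob_predict(forest, data), data, multiclass_metric)


def select_rfopt(
    component_forests: list[FittedForest],
    data: Dataset,
    multiclass_metric: str = "brier",
) -> tuple[int, FittedForest]:
    """The grid forest with the smallest OOB error; ties go to the smaller
    nodesize (forests are in ascending-nodesize order)."""
    if not component_forests:
        raise ValueError("need at least one component forest")
    errors = [oob_error(f, data, multiclass_metric) for f in component_forests]
    best = int(np.argmin(errors))
    return component_forests[best].params.nodesize, component_forests[best]


def fit_srf(
    data: Dataset,
    config: SyntheticConfig | None = None,
    include_synthetic: bool = True,
) -> SRFModel:
    """Fit the full synthetic-forest pipeline.

    ``include_synthetic=False`` is the ablation switch: the hyperforest is
    fitted on the original features only (mtry recomputed on p), which
    should recover plain-forest behaviour.
    """
    config = config or SyntheticConfig()
    features, forests, oob_errors = _fit_machines(data, config)
    grid = config.pruned_grid(data.n)
    rfopt_nodesize = forests[int(np.argmin(oob_errors))].params.nodesize
    if include_synthetic:
        X_aug = np.hstack([data.X, features.columns])
        machine_map = [(ns, data.p + cols) for ns, cols in features.machine_map]
    else:
        X_aug = data.X
        machine_map = []
    hyper_dim = X_aug.shape[1] if config.hyper_mtry_on == "augmented" else data.p
    hyper_params = ForestParams(
        ntree=config.ntree,
        mtry=compute_mtry(hyper_dim, config.mtry_rule),
        nodesize=config.hyper_nodesize,
        seed=config.seed - 1,
        nodesize_semantics=config.nodesize_semantics,
    )
    aug_data = Dataset(X=X_aug, y=data.y, task=data.task, J=data.J)
    hyperforest = fit_forest(aug_data, hyper_params)
    return SRFModel(
        component_forests=forests,
        hyperforest=hyperforest,
        config=config,
        grid=grid,
        machine_map=machine_map,
        rfopt_nodesize=rfopt_nodesize,
        task=data.task,
        p=data.p,
        includes_synthetic=include_synthetic,
        train_synthetic=features.columns,
    )


def synthetic_test_columns(model: SRFModel, Xnew: np.ndarray) -> np.ndarray:
    """Synthetic columns for out-of-sample rows: full-forest predictions of
    the stored grid machines (new rows are out-of-sample by construction,
    so the OOB restriction is unnecessary)."""
    blocks = []
    for forest in model.component_forests:
        pred = predict_forest(forest, Xnew)
        if model.task == "regression":
            blocks.append(pred.reshape(-1, 1))
        else:
            blocks.append(pred[:, : forest.J - 1])
    return np.hstack(blocks)


def predict_srf(model: SRFModel, Xnew: np.ndarray) -> np.ndarray:
    """Hyperforest prediction for new rows (p original columns)."""
    Xnew = np.asarray(Xnew, dtype=np.float64)
    if Xnew.ndim == 1:
        Xnew = Xnew.reshape(1, -1)
    if Xnew.shape[1] != model.p:
        raise ValueError(f"expected {model.p} feature columns, got {Xnew.shape[1]}")
    if model.includes_synthetic:
        Xnew = np.hstack([Xnew, synthetic_test_columns(model, Xnew)])
    return predict_forest(model.hyperforest, Xnew)


def save_srf(model: SRFModel, path) -> None:
    """Serialize the whole model (grid forests + hyperforest + config)."""
    joblib.dump({"format": "synforest.srf.v1", "model": model}, path)


def load_srf(path) -> SRFModel:
    payload = joblib.load(path)
    if payload.get("format") != "synforest.srf.v1":
        raise ValueError(f"{path} is not a synforest SRF archive")
    return payload["model"]
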