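"""Cross-validation / replication harness and nonparametric comparison tests.

The harness evaluates the four methods (RF, RFopt, SRF, COBRA) under two
protocols: k-fold cross-validation on a fixed dataset, and independent
train/test replications of a simulated benchmark. Method comparison across
datasets uses the exact Wilcoxon signed-rank test (pairwise) and the
Iman-Davenport F-corrected Friedman rank test (overall).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cobra import CobraParams, CollectivePredictions, calibrate_eps, cobra_predict
from .datagen import GeneratorSpec, generate
from .forest_core import Dataset, ForestParams, compute_mtry, fit_forest, predict_forest
from .metrics import brier_score, standardized_mse
from .synthetic_forest import (
    SRFModel,
    SyntheticConfig,
    fit_srf,
    predict_srf,
    synthetic_test_columns,
)

__all__ = [
    "METHODS",
    "RankSummary",
    "kfold_indices",
    "kfold_cv",
    "replicate_benchmark",
    "summarize_benchmark",
    "wilcoxon_signed_rank",
    "friedman_iman_davenport",
]

METHODS = ("RF", "RFopt", "SRF", "COBRA")


# ---------------------------------------------------------------------------
# method dispatch

def _score(data_test: Dataset, preds: np.ndarray, var_y: float | None = None) -> float:
    if data_test.task == "regression":
        return standardized_mse(data_test.y, preds, var_y=var_y)
    return brier_score(preds, data_test.y)


def _plain_rf_predictions(
    model: SRFModel, train: Dataset, X_test: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Standard forest at the hyperforest nodesize; reuses the grid machine
    when the value is on the grid, else fits one."""
    for forest in model.component_forests:
        if forest.params.nodesize == config.hyper_nodesize:
            return predict_forest(forest, X_test)
    params = ForestParams(
        ntree=config.ntree,
        mtry=compute_mtry(train.p, config.mtry_rule),
        nodesize=config.hyper_nodesize,
        seed=config.seed - 2,
        nodesize_semantics=config.nodesize_semantics,
    )
    return predict_forest(fit_forest(train, params), X_test)


def _rfopt_predictions(model: SRFModel, X_test: np.ndarray) -> np.ndarray:
    for forest in model.component_forests:
        if forest.params.nodesize == model.rfopt_nodesize:
            return predict_forest(forest, X_test)
    raise RuntimeError("rfopt nodesize not among component forests")


def _cobra_predictions(
    model: SRFModel,
    train: Dataset,
    X_test: np.ndarray,
    cobra_params: CobraParams,
    test_synthetic: np.ndarray | None = None,
) -> np.ndarray:
    if train.task != "regression":
        raise ValueError("the COBRA collective supports regression only")
    if model.train_synthetic is None:
        raise ValueError("model does not retain training synthetic columns")
    # constituents = the same grid machines; OOB columns at training points
    collective = CollectivePredictions(
        train_preds=model.train_synthetic,
        train_y=train.y,
    )
    eps = calibrate_eps(
        collective,
        collective.train_preds,
        train.y,
        cobra_params,
        exclude_self=True,
    )
    tuned = CobraParams(
        eps=eps, alpha_frac=cobra_params.alpha_frac, grid_size=cobra_params.grid_size
    )
    test_preds = (
        synthetic_test_columns(model, X_test)
        if test_synthetic is None
        else test_synthetic
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-neighbourhood fallback is fine here
        return np.asarray(cobra_predict(collective, test_preds, tuned))


def method_predictions(
    method: str,
    model: SRFModel,
    train: Dataset,
    X_test: np.ndarray,
    config: SyntheticConfig,
    cobra_params: CobraParams,
    test_synthetic: np.ndarray | None = None,
) -> np.ndarray:
    """Test-set predictions of one method, given a fitted SRF pipeline.

    ``test_synthetic`` optionally passes precomputed full-forest grid
    predictions at the test rows, shared between SRF and COBRA.
    """
    if method == "SRF":
        if test_synthetic is not None and model.includes_synthetic:
            X_aug = np.hstack([X_test, test_synthetic])
            return predict_forest(model.hyperforest, X_aug)
        return predict_srf(model, X_test)
    if method == "RF":
        return _plain_rf_predictions(model, train, X_test, config)
    if method == "RFopt":
        return _rfopt_predictions(model, X_test)
    if method == "COBRA":
        return _cobra_predictions(model, train, X_test, cobra_params, test_synthetic)
    raise ValueError(f"unknown method {method!r}; known: {METHODS}")


# ---------------------------------------------------------------------------
# cross-validation

def kfold_indices(
    n: int, k: int, seed: int, labels: np.ndarray | None = None
) -> list[np.ndarray]:
    """Seeded partition of 0..n-1 into k near-equal folds (stratified when
    ``labels`` is given)."""
    from sklearn.model_selection import KFold, StratifiedKFold

    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(np.zeros(n))]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), labels)]


def kfold_cv(
    data: Dataset,
    method: str = "SRF",
    k: int = 10,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    cobra_params: CobraParams | None = None,
) -> float:
    """Metric on pooled out-of-fold predictions under a seeded k-fold split.

    Regression is scored as standardized MSE against the full-response
    variance (so a constant-mean predictor scores exactly 100); multiclass
    is scored with the normalized Brier (folds stratified by class).
    """
    config = config or SyntheticConfig(seed=seed)
    cobra_params = cobra_params or CobraParams()
    labels = data.y if data.task == "multiclass" else None
    folds = kfold_indices(data.n, k, seed, labels)
    if data.task == "regression":
        pooled = np.empty(data.n)
    else:
        pooled = np.empty((data.n, data.J))
    for fold in folds:
        mask = np.ones(data.n, dtype=bool)
        mask[fold] = False
        train = Dataset(X=data.X[mask], y=data.y[mask], task=data.task, J=data.J)
        model = fit_srf(train, config)
        pooled[fold] = method_predictions(
            method, model, train, data.X[fold], config, cobra_params
        )
    if data.task == "regression":
        return standardized_mse(data.y, pooled, var_y=float(np.var(data.y)))
    return brier_score(pooled, data.y)


# ---------------------------------------------------------------------------
# simulated-benchmark replications

def replicate_benchmark(
    spec: GeneratorSpec,
    methods: tuple[str, ...] = ("RF", "RFopt", "SRF"),
    reps: int = 100,
    n_test: int = 5000,
    config: SyntheticConfig | None = None,
    cobra_params: CobraParams | None = None,
) -> pd.DataFrame:
    """Independent train/test replications of one simulated benchmark.

    Per replication a fresh training set of ``spec.n`` and test set of
    ``n_test`` are drawn; all methods share the identical train and test
    draws. Returns tidy rows (dataset, rep, method, value, train_seed,
    test_seed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base_config = config or SyntheticConfig()
    cobra_params = cobra_params or CobraParams()
    rows = []
    for rep in range(reps):
        ss = np.random.SeedSequence(entropy=(spec.seed, rep))
        train_seed, test_seed, model_seed = (
            int(s) for s in ss.generate_state(3, dtype=np.uint32)
        )
        train = generate(
            GeneratorSpec(
                name=spec.name,
                n=spec.n,
                extra_noise_features=spec.extra_noise_features,
                noise_sd=spec.noise_sd,
                seed=train_seed,
            )
        )
        test = generate(
            GeneratorSpec(
                name=spec.name,
                n=n_test,
                extra_noise_features=spec.extra_noise_features,
                noise_sd=spec.noise_sd,
                seed=test_seed,
            )
        )
        rep_config = replace(base_config, seed=model_seed)
        model = fit_srf(train, rep_config)
        test_synthetic = None
        if {"SRF", "COBRA"} & set(methods):
            test_synthetic = synthetic_test_columns(model, test.X)
        for method in methods:
            preds = method_predictions(
                method, model, train, test.X, rep_config, cobra_params, test_synthetic
            )
            rows.append(
                {
                    "dataset": spec.name,
                    "rep": rep,
                    "method": method,
                    "value": _score(test, preds),
                    "train_seed": train_seed,
                    "test_seed": test_seed,
                }
            )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean metric per (dataset, method), one row per dataset."""
    dup = results.duplicated(["dataset", "rep", "method"])
    if dup.any():
        raise ValueError("duplicate (dataset, rep, method) rows")
    return results.pivot_table(
        index="dataset", columns="method", values="value", aggfunc="mean"
    )


# ---------------------------------------------------------------------------
# nonparametric comparison statistics

def wilcoxon_signed_rank(
    diffs: np.ndarray,
    alternative: str = "two-sided",
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; tied magnitudes get midranks. Returns (W, p) where W
    is the sum of ranks of positive differences. The p-value is exact (full
    enumeration of sign patterns, computed by subset-sum counting over
    doubled ranks) up to ``exact_limit`` non-zero differences, and a normal
    approximation with Var = sum(r_i^2)/4 beyond.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p-value is 1", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_limit:
        scaled = np.rint(2 * ranks).astype(np.int64)
        total = int(scaled.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for s in scaled:
            counts[s:] += counts[: total + 1 - s]
        counts /= 2.0**n
        w2 = int(round(2 * w))
        p_ge = float(counts[w2:].sum())
        p_le = float(counts[: w2 + 1].sum())
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt((ranks**2).sum() / 4.0)
        z = (w - mu) / sigma
        p_ge = float(stats.norm.sf(z))
        p_le = float(stats.norm.cdf(z))
    if alternative == "greater":
        return w, min(1.0, p_ge)
    if alternative == "less":
        return w, min(1.0, p_le)
    return w, min(1.0, 2.0 * min(p_ge, p_le))


@dataclass
class RankSummary:
    """Per-method average ranks plus the overall and pairwise test results."""

    average_ranks: pd.Series
    chi2_friedman: float
    f_iman_davenport: float
    p_value: float
    wilcoxon_stat: pd.DataFrame
    wilcoxon_p: pd.DataFrame


def friedman_iman_davenport(
    table: pd.DataFrame, alternative: str = "two-sided"
) -> RankSummary:
    """Rank-based comparison of k methods over b datasets (smaller = better).

    Per-dataset ranks use midranks for ties; chi2_F is the Friedman
    statistic and F_ID its Iman-Davenport correction, referred to an
    F(k-1, (b-1)(k-1)) distribution. Pairwise Wilcoxon signed-rank tests
    are run on each method pair's per-dataset differences.
    """
    if isinstance(table, np.ndarray):
        table = pd.DataFrame(table)
    if table.isna().any().any():
        raise ValueError("table has missing cells")
    b, k = table.shape
    if b < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 methods")
    ranks = table.rank(axis=1, method="average")
    avg = ranks.mean(axis=0)
    chi2 = 12.0 * b / (k * (k + 1)) * (float((avg**2).sum()) - k * (k + 1) ** 2 / 4.0)
    denom = b * (k - 1) - chi2
    if denom <= 0:
        f_id, p = np.inf, 0.0
    else:
        f_id = (b - 1) * chi2 / denom
        p = float(stats.f.sf(f_id, k - 1, (b - 1) * (k - 1)))
    methods = list(table.columns)
    wstat = pd.DataFrame(np.nan, index=methods, columns=methods)
    wp = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for j, mj in enumerate(methods):
            if i == j:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, pval = wilcoxon_signed_rank(
                    (table[mi] - table[mj]).to_numpy(), alternative=alternative
                )
            wstat.loc[mi, mj] = stat
            wp.loc[mi, mj] = pval
    return RankSummary(
        average_ranks=avg,
        chi2_friedman=float(chi2),
        f_iman_davenport=float(f_id),
        p_value=float(p),
        wilcoxon_stat=wstat,
        wilcoxon_p=wp,
    )
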