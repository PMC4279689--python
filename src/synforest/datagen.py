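"""Seeded generators for the simulated regression and classification benchmarks.

Regression surfaces are the canonical Friedman #1/#2/#3 benchmarks (delegated
to :mod:`sklearn.datasets`); the two-class Gaussian mixtures follow the
conventions of the standard R benchmark collection: exactly balanced classes,
``a = 2/sqrt(d)`` for twonorm/threenorm and ``a = 1/sqrt(d)`` for the
ringnorm mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.datasets import make_friedman1, make_friedman2, make_friedman3

from .forest_core import Dataset

__all__ = [
    "GeneratorSpec",
    "GENERATORS",
    "gen_friedman1",
    "gen_friedman2",
    "gen_friedman3",
    "gen_gaussian_classif",
    "add_noise_features",
    "generate",
]

#: generator name -> (task, default noise_sd or None)
GENERATORS = {
    "friedman1": ("regression", 1.0),
    "friedman2": ("regression", 125.0),
    "friedman3": ("regression", 0.1),
    "twonorm": ("multiclass", None),
    "threenorm": ("multiclass", None),
    "ringnorm": ("multiclass", None),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one simulated dataset draw."""

    name: str
    n: int
    extra_noise_features: int = 0
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in GENERATORS:
            raise ValueError(
                f"unknown generator {self.name!r}; known: {sorted(GENERATORS)}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.extra_noise_features < 0:
            raise ValueError("extra_noise_features must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def task(self) -> str:
        return GENERATORS[self.name][0]


def gen_friedman1(n: int, noise_sd: float = 1.0, seed: int = 0) -> Dataset:
    """Friedman #1: X ~ U(0,1)^10,
    y = 10 sin(pi x1 x2) + 20 (x3 - 0.5)^2 + 10 x4 + 5 x5 + N(0, noise_sd^2).

    Columns 6-10 carry no signal.
    """
    X, y = make_friedman1(n_samples=n, n_features=10, noise=noise_sd, random_state=seed)
    return Dataset(X=X, y=y, task="regression")


def gen_friedman2(n: int, noise_sd: float = 125.0, seed: int = 0) -> Dataset:
    """Friedman #2: y = sqrt(x1^2 + (x2 x3 - 1/(x2 x4))^2) + noise, p = 4."""
    X, y = make_friedman2(n_samples=n, noise=noise_sd, random_state=seed)
    return Dataset(X=X, y=y, task="regression")


def gen_friedman3(n: int, noise_sd: float = 0.1, seed: int = 0) -> Dataset:
    """Friedman #3: y = atan((x2 x3 - 1/(x2 x4)) / x1) + noise, p = 4."""
    X, y = make_friedman3(n_samples=n, noise=noise_sd, random_state=seed)
    return Dataset(X=X, y=y, task="regression")


def _balanced_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    y = np.zeros(n, dtype=np.int64)
    y[: n // 2] = 1
    rng.shuffle(y)
    return y


def gen_gaussian_classif(
    name: str,
    n: int,
    d: int = 20,
    seed: int = 0,
    ringnorm_a: float | None = None,
) -> Dataset:
    """Balanced two-class draws from the Breiman Gaussian mixtures.

    twonorm: N(+a 1, I) vs N(-a 1, I) with a = 2/sqrt(d).
    threenorm: 1/2 N(+a 1, I) + 1/2 N(-a 1, I) vs N((a,-a,a,-a,...), I).
    ringnorm: N(0, 4I) vs N(a' 1, I) with a' = 1/sqrt(d) by default
    (``ringnorm_a`` overrides, accommodating the 2/sqrt(d) variant).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    y = _balanced_labels(n, rng)
    X = np.empty((n, d))
    if name == "twonorm":
        a = 2.0 / np.sqrt(d)
        mu = np.where(y[:, None] == 0, a, -a)
        X[:] = rng.standard_normal((n, d)) + mu
    elif name == "threenorm":
        a = 2.0 / np.sqrt(d)
        alt = np.resize([a, -a], d)
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        mu = np.where(y[:, None] == 0, sign[:, None] * a, alt[None, :])
        X[:] = rng.standard_normal((n, d)) + mu
    elif name == "ringnorm":
        a = 1.0 / np.sqrt(d) if ringnorm_a is None else ringnorm_a
        scale = np.where(y[:, None] == 0, 2.0, 1.0)
        mu = np.where(y[:, None] == 0, 0.0, a)
        X[:] = rng.standard_normal((n, d)) * scale + mu
    else:
        raise ValueError(f"unknown Gaussian mixture {name!r}")
    return Dataset(X=X, y=y, task="multiclass", J=2)


def add_noise_features(data: Dataset, extra: int, seed: int = 0) -> Dataset:
    """Append ``extra`` independent U(0,1) columns; the response is untouched."""
    if extra < 0:
        raise ValueError("extra must be >= 0")
    if extra == 0:
        return data
    rng = np.random.default_rng(seed)
    noise = rng.random((data.n, extra))
    names = None
    if data.feature_names is not None:
        names = data.feature_names + tuple(
            f"noise{j + 1}" for j in range(extra)
        )
    return Dataset(
        X=np.hstack([data.X, noise]),
        y=data.y,
        task=data.task,
        J=data.J,
        feature_names=names,
    )


def generate(spec: GeneratorSpec) -> Dataset:
    """Materialize a :class:`GeneratorSpec` into a Dataset."""
    task, default_sd = GENERATORS[spec.name]
    if task == "regression":
        sd = default_sd if spec.noise_sd is None else spec.noise_sd
        fn = {
            "friedman1": gen_friedman1,
            "friedman2": gen_friedman2,
            "friedman3": gen_friedman3,
        }[spec.name]
        data = fn(spec.n, noise_sd=sd, seed=spec.seed)
    else:
        if spec.noise_sd is not None:
            raise ValueError("noise_sd does not apply to classification mixtures")
        data = gen_gaussian_classif(spec.name, spec.n, seed=spec.seed)
    if spec.extra_noise_features:
        # decorrelate the noise-column stream from the base draw
        data = add_noise_features(
            data, spec.extra_noise_features, seed=spec.seed + 986_419
        )
    return data
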