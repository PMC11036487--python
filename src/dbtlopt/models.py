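"""Regression model families, tuning protocol, and repeated evaluation.

Four regressor families map one-hot-encoded designs to production titers:
multiple linear regression (MLR), support vector regression (SVR), kernel
ridge regression (KRR) and random forest regression (RFR).  Hyperparameters
for all families except MLR are chosen by leave-one-out cross-validation on
the training set, scored by the *maximum absolute error* across held-out
points (a conservative criterion suited to very small datasets, where a
single badly predicted strain matters).  Families are compared by their
mean test-set R^2 over repeated stratified train/test splits.

The one-hot encoding keeps every level, so the linear design matrix is
exactly collinear; MLR therefore uses the minimum-norm least-squares
solution (scikit-learn's ``LinearRegression``), which is well defined
under collinearity.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.svm import SVR

from .datasets import DesignDataset, stratified_split, subsample_training
from .design_space import LibrarySpec, encode_designs

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "DEFAULT_FAMILIES_BY_KIND",
    "ModelSpec",
    "EvaluationReport",
    "tune_hyperparameters",
    "fit",
    "evaluate_families",
    "data_size_sweep",
]

log = logging.getLogger(__name__)

FAMILIES = ("linear", "support_vector", "kernel_ridge", "random_forest")

# Tuning grids are conventions, overridable per call.  The random-forest
# grid is kept deliberately small: each LOOCV tune fits n_train * |grid|
# forests, and forests dominate the runtime of the whole pipeline.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear": {},
    "kernel_ridge": {
        "alpha": [1e-3, 1e-2, 1e-1, 1.0, 10.0],
        "gamma": [0.01, 0.1, 1.0, 10.0],
    },
    "support_vector": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "epsilon": [0.01, 0.05, 0.1],
        "gamma": [0.01, 0.1, 1.0, 10.0],
    },
    "random_forest": {
        "n_estimators": [100],
        "max_depth": [None, 8],
        "min_samples_leaf": [1],
    },
}

# Which families feed the ranking ensemble for each dataset kind.  On the
# complete dataset the linear and kernel-ridge models are the default
# predictors; on the producers dataset all four families are used.
DEFAULT_FAMILIES_BY_KIND: dict[str, tuple[str, ...]] = {
    "complete": ("linear", "kernel_ridge"),
    "producers": FAMILIES,
}


@dataclass
class ModelSpec:
    """A (possibly fitted) member of one regressor family."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    estimator: Any = None
    train_fingerprint: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def fitted(self) -> bool:
        return self.estimator is not None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError(f"{self.family} model is not fitted")
        return np.asarray(self.estimator.predict(X), dtype=float)


def make_estimator(family: str, params: Mapping[str, Any], seed: int = 0):
    if family == "linear":
        return LinearRegression()
    if family == "kernel_ridge":
        return KernelRidge(kernel="rbf", **params)
    if family == "support_vector":
        return SVR(kernel="rbf", **params)
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown model family {family!r}")


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict[str, Any]]:
    """Grid points in declaration order (first axis slowest)."""
    if not grid:
        return [{}]
    names = list(grid)
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(grid[n] for n in names))
    ]


def loocv_max_error(
    family: str,
    params: Mapping[str, Any],
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> float:
    """Maximum absolute held-out error over leave-one-out folds."""
    n = len(y)
    worst = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = make_estimator(family, params, seed)
        est.fit(X[mask], y[mask])
        pred = float(est.predict(X[i : i + 1])[0])
        worst = max(worst, abs(pred - y[i]))
    return worst


def tune_hyperparameters(
    family: str,
    train: DesignDataset,
    library: LibrarySpec | None = None,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> ModelSpec:
    """Pick the grid point minimizing the LOOCV maximum absolute error.

    MLR has no hyperparameters and skips cross-validation entirely.  Ties
    are broken by grid declaration order.
    """
    library = library or train.library
    X, _ = encode_designs(train.designs, library)
    return tune_xy(family, X, train.titers, grid=grid, seed=seed)


def tune_xy(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> ModelSpec:
    if family == "linear":
        return ModelSpec("linear", {})
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    points = _grid_points(grid)
    if points == [{}]:
        raise ValueError(f"empty hyperparameter grid for family {family!r}")
    if len(y) < 3:
        raise ValueError("need at least 3 training rows to tune")
    if len(points) == 1:  # nothing to compare
        return ModelSpec(family, dict(points[0]))
    best_params, best_err = None, np.inf
    for params in points:
        err = loocv_max_error(family, params, X, y, seed)
        if err < best_err:  # strict: ties keep the earlier grid point
            best_params, best_err = params, err
    return ModelSpec(family, dict(best_params))


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def fit(
    spec: ModelSpec,
    train: DesignDataset,
    library: LibrarySpec | None = None,
    seed: int = 0,
) -> ModelSpec:
    """Fit a tuned spec on a dataset; records a training-set fingerprint."""
    library = library or train.library
    X, _ = encode_designs(train.designs, library)
    return fit_xy(spec, X, train.titers, seed=seed)


def fit_xy(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> ModelSpec:
    est = make_estimator(spec.family, spec.hyperparameters, seed)
    est.fit(X, y)
    pred = est.predict(X)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError(
            f"{spec.family} fit produced non-finite predictions"
        )
    return replace(
        spec, estimator=est, train_fingerprint=_fingerprint(X, y)
    )


@dataclass
class EvaluationReport:
    """Per-repeat and summary R^2 of the model families on one dataset."""

    frame: pd.DataFrame  # family, repeat, r2, n_train, n_test, params
    dataset_kind: str
    n_repeats: int

    def summary(self) -> pd.DataFrame:
        g = self.frame.groupby("family", sort=False)["r2"]
        out = g.agg(mean_r2="mean", sd_r2="std", n_repeats="size").reset_index()
        return out


def _repeat_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def evaluate_families(
    ds: DesignDataset,
    families: Sequence[str] = FAMILIES,
    n_repeats: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
) -> EvaluationReport:
    """Repeated stratified-split evaluation of model families.

    Each repeat draws a fresh stratified train/test split, tunes each
    family on the train rows only, fits, and scores R^2 on the held-out
    test rows; families are compared by mean +/- sd over repeats.
    """
    sweep = data_size_sweep(
        ds,
        families=families,
        fractions=(1.0,),
        stratified_options=(True,),
        n_repeats=n_repeats,
        test_fraction=test_fraction,
        seed=seed,
        grids=grids,
    )
    frame = sweep.drop(columns=["fraction", "stratified"]).reset_index(drop=True)
    return EvaluationReport(frame=frame, dataset_kind=ds.kind, n_repeats=n_repeats)


def data_size_sweep(
    ds: DesignDataset,
    families: Sequence[str] = FAMILIES,
    fractions: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0),
    stratified_options: Sequence[bool] = (True, False),
    n_repeats: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
    grids: Mapping[str, Mapping[str, Sequence]] | None = None,
    retune: bool = True,
) -> pd.DataFrame:
    """Training-size sensitivity: test-set R^2 as the training set is
    subsampled to each fraction, with and without stratification.

    The ``stratified`` flag governs the whole protocol of its arm: the
    stratified arm splits train/test by production class and subsamples
    preserving class proportions, while the unstratified arm splits and
    subsamples uniformly at random — dropping stratification everywhere,
    which is the comparison that matters when deciding whether the
    screening workflow must support production classes at all.  Within an
    arm, each repeat draws one split and scores every fraction against
    that repeat's untouched test rows.

    With ``retune=False`` hyperparameters are tuned once per repeat on the
    full training set and reused at every fraction.  Fractions yielding
    fewer than 3 training rows are skipped with a log message.  At
    ``fractions=(1.0,)`` the stratified arm reproduces
    :func:`evaluate_families`.
    """
    from .datasets import random_split

    grids = grids or {}
    rows = []
    split_seeds = _repeat_seeds(seed, n_repeats)
    library = ds.library
    for rep, rep_seed in enumerate(split_seeds):
        for stratified in stratified_options:
            if stratified:
                train, test = stratified_split(
                    ds, test_fraction, seed=int(rep_seed)
                )
            else:
                train, test = random_split(
                    ds, test_fraction, seed=int(rep_seed)
                )
            X_test, _ = encode_designs(test.designs, library)
            y_test = test.titers
            full_specs = {}
            if not retune:
                for fam in families:
                    full_specs[fam] = tune_hyperparameters(
                        fam, train, library, grid=grids.get(fam),
                        seed=int(rep_seed),
                    )
            for fraction in fractions:
                if fraction == 1.0:
                    sub = train
                else:
                    try:
                        sub = subsample_training(
                            train, fraction, stratified, seed=int(rep_seed)
                        )
                    except ValueError as exc:
                        log.info("skipping fraction %.2f: %s", fraction, exc)
                        continue
                if len(sub) < 3:
                    log.info(
                        "skipping fraction %.2f: only %d rows", fraction, len(sub)
                    )
                    continue
                for fam in families:
                    if retune:
                        spec = tune_hyperparameters(
                            fam, sub, library, grid=grids.get(fam),
                            seed=int(rep_seed),
                        )
                    else:
                        spec = full_specs[fam]
                    fitted = fit(spec, sub, library, seed=int(rep_seed))
                    r2 = r2_score(y_test, fitted.predict(X_test))
                    rows.append(
                        {
                            "family": fam,
                            "fraction": fraction,
                            "stratified": stratified,
                            "repeat": rep,
                            "r2": float(r2),
                            "n_train": len(sub),
                            "n_test": len(test),
                            "params": repr(fitted.hyperparameters),
                        }
                    )
    return pd.DataFrame(rows)
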