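"""Model validation: six regression metrics, LOO-CV, and exhaustive grid search.

The six metrics for an (observed, predicted) pair are R^2, RMSE, MAE, MAPE,
MSLE and MedAE. RMSE is the square root of the mean squared error; MSLE uses
the natural logarithm of ``1 + y``. Leave-one-out cross-validation predicts
each sample from a model trained on the remaining ``n - 1``; grid search
evaluates every hyperparameter cell under LOO-CV and picks the best by a
declared selection metric (maximize R^2, minimize the rest), breaking ties
by grid order.

Learner families (random forest, multilayer perceptron) are consumed through
the scikit-learn fit/predict contract; the harness and metrics are the
surface this module owns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .errors import DomainError, SchemaError
from .met_data import METDataset, validate_balance
from .errors import BalanceError

METRIC_NAMES = ("r2", "rmse", "mae", "mape", "msle", "medae")
_MINIMIZE = {"rmse", "mae", "mape", "msle", "medae"}


@dataclass
class MetricSet:
    """The six validation metrics for one (observed, predicted) pair.

    Metrics whose domain condition fails (MAPE with a zero observation,
    MSLE with values <= -1, R^2 with zero-variance observations) are NaN
    and named in ``flags``.
    """

    r2: float
    rmse: float
    mae: float
    mape: float
    msle: float
    medae: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def compute_metrics(observed, predicted) -> MetricSet:
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise SchemaError("observed and predicted must be equal-length, nonempty")
    err = y - yhat
    flags: list[str] = []
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r2, flags = np.nan, flags + ["r2"]
    else:
        r2 = 1.0 - float(np.sum(err**2)) / sst
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.any(y == 0):
        mape = np.nan
        flags.append("mape")
    else:
        with np.errstate(over="ignore"):  # tiny observed values are legal
            mape = float(100.0 * np.mean(np.abs(err / y)))
    if np.any(y <= -1) or np.any(yhat <= -1):
        msle = np.nan
        flags.append("msle")
    else:
        msle = float(np.mean((np.log1p(y) - np.log1p(yhat)) ** 2))
    medae = float(np.median(np.abs(err)))
    return MetricSet(r2=r2, rmse=rmse, mae=mae, mape=mape, msle=msle,
                     medae=medae, flags=flags)


@dataclass
class ModelSpec:
    """A learner family with a hyperparameter grid and a selection metric."""

    family: str  # "random_forest" | "mlp" | "mean" (intercept-only baseline)
    grid: dict[str, Sequence] = field(default_factory=dict)
    selection_metric: str = "rmse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_metric not in METRIC_NAMES:
            raise SchemaError(f"unknown selection metric {self.selection_metric!r}")


class MeanPredictor:
    """Intercept-only baseline with the sklearn fit/predict contract."""

    def __init__(self):
        self.mean_ = None

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def make_estimator(family: str, params: Mapping | None = None, seed: int = 0):
    params = dict(params or {})
    if family == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, **params)
    if family == "mlp":
        params.setdefault("max_iter", 2000)
        return MLPRegressor(random_state=seed, **params)
    if family == "mean":
        return MeanPredictor()
    raise SchemaError(f"unknown model family {family!r}")


def loo_cv(estimator, features, target) -> np.ndarray:
    """Out-of-fold predictions: sample i predicted by a model fit without i."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    n = len(y)
    if n < 2:
        raise DomainError("LOO-CV needs at least two samples")
    if X.shape[0] != n:
        raise SchemaError("features and target length mismatch")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = clone(estimator) if hasattr(estimator, "get_params") else estimator
        try:
            model.fit(X[mask], y[mask])
        except Exception as exc:
            raise DomainError(f"training failed in fold {i}: {exc}") from exc
        preds[i] = float(np.asarray(model.predict(X[i: i + 1])).ravel()[0])
    return preds


@dataclass
class GridSearchResult:
    best_params: dict
    best_metrics: MetricSet
    best_predictions: np.ndarray
    table: pd.DataFrame  # one row per grid cell with all six metrics


def grid_search(spec: ModelSpec, features, target) -> GridSearchResult:
    """Exhaustive LOO-CV evaluation of every grid cell; first-best tie-break."""
    names = list(spec.grid)
    cells = [dict(zip(names, combo))
             for combo in itertools.product(*(spec.grid[n] for n in names))] or [{}]
    rows, results, failures = [], [], []
    for cell in cells:
        try:
            est = make_estimator(spec.family, cell, seed=spec.seed)
            preds = loo_cv(est, features, target)
        except Exception as exc:
            failures.append((cell, exc))
            continue
        metrics = compute_metrics(target, preds)
        rows.append({**cell, **metrics.as_dict()})
        results.append((cell, metrics, preds))
    if not results:
        raise DomainError(f"all {len(cells)} grid cells failed: {failures[:3]}")
    metric = spec.selection_metric
    sign = 1.0 if metric in _MINIMIZE else -1.0

    def score(item):
        value = item[1][metric]
        return np.inf if np.isnan(value) else sign * value

    best_cell, best_metrics, best_preds = min(results, key=score)  # stable: grid order
    return GridSearchResult(
        best_params=best_cell,
        best_metrics=best_metrics,
        best_predictions=best_preds,
        table=pd.DataFrame(rows),
    )


def build_feature_matrix(
    dataset: METDataset, target_trait: str, encoding: str = "onehot"
) -> tuple[pd.DataFrame, pd.Series]:
    """Indicator features per genotype and environment, one row per record.

    The default encoding is one 0/1 column per genotype and per environment,
    so each row sums to 2. This is an explicit design choice of the harness,
    not a claim about any particular published feature set.
    """
    if encoding != "onehot":
        raise SchemaError(f"unknown encoding {encoding!r}")
    if target_trait not in dataset.trait_names:
        raise SchemaError(f"unknown trait {target_trait!r}")
    report = validate_balance(dataset)
    if not report.complete:
        raise BalanceError("feature matrix requires a balanced dataset",
                           report.offending_cells)
    gdum = pd.get_dummies(
        pd.Categorical(dataset.data["genotype"], categories=dataset.genotype_order),
        prefix="g", dtype=float,
    )
    edum = pd.get_dummies(
        pd.Categorical(dataset.data["environment"], categories=dataset.environment_order),
        prefix="e", dtype=float,
    )
    X = pd.concat([gdum, edum], axis=1)
    X.index = dataset.data.index
    y = dataset.data[target_trait].rename(target_trait)
    return X, y
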