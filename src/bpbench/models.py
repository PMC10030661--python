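"""Reference Feat2Lab model zoo behind one fit/predict contract.

Five classical feature-to-label regressor families (kernel SVR, gradient-
boosted trees, random forest, boosted trees/stumps, feed-forward net) plus a
nearest-neighbour regressor used by the leakage experiments and the naive
constant predictor.  Signal-input (Sig2Lab/Sig2Sig) deep models enter the
harness only through the plugin contract: any object with ``fit(X, y)`` and
``predict(X)`` (Sig2Sig plugins return waveforms routed through
``evaluate.labels_from_predicted_abp``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigurationError

__all__ = ["ModelSpec", "build_model", "default_grid", "MODEL_NAMES",
           "NaiveMean", "SELECTION_RATES"]

SELECTION_RATES = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.7, 0.9, 1.0)


class NaiveMean(BaseEstimator, RegressorMixin):
    """Constant training-mean predictor (the MASE denominator model)."""

    def fit(self, X, y):
        self.mean_ = float(np.asarray(y, dtype=float).mean())
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


@dataclass
class ModelSpec:
    """A named model family with its hyperparameter grid."""

    name: str
    category: str = "Feat2Lab"
    grid: dict = field(default_factory=dict)
    selection_rates: tuple = SELECTION_RATES

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ConfigurationError(
                f"unknown model {self.name!r}; one of {sorted(MODEL_NAMES)}")
        if not self.grid:
            self.grid = default_grid(self.name)


# Search spaces for the classical families (grid-search tuned on inner-fold
# validation MAE).
_GRIDS = {
    "svr": {"C": [1.0, 5.4, 10, 100, 170, 1001],
            "gamma": [0.001, 0.008, 0.1, 0.7, 1],
            "epsilon": [0.0003, 0.007, 0.01, 0.05, 0.1, 0.15, 0.2]},
    "mlp": {"hidden_layer_sizes": [(32,), (64,), (256,), (256, 64),
                                   (512, 64)]},
    "adaboost": {"n_estimators": [5, 10, 50, 100, 150, 200],
                 "max_depth": [1, 3, 5, 8, None],
                 "min_samples_leaf": [5, 25, 50]},
    "rf": {"n_estimators": [10, 50, 100, 150, 200, 300, 400],
           "max_depth": [1, 3, 5, 8, None],
           "min_samples_leaf": [5, 25, 50],
           "max_samples": [0.5, 0.7, 0.9],
           "max_features": [0.3, 0.7, 1.0]},
    "lightgbm": {"n_estimators": [10, 50, 100, 150, 200, 300, 400],
                 "learning_rate": [0.01, 0.05, 0.1],
                 "max_depth": [1, 3, 5, 8, -1],
                 "min_child_samples": [5, 25, 50],
                 "subsample": [0.5, 0.7, 1.0]},
    "knn": {"n_neighbors": [1, 3, 5, 10]},
    "naive": {},
}

MODEL_NAMES = tuple(_GRIDS)


def default_grid(name: str) -> dict:
    return {k: list(v) for k, v in _GRIDS[name].items()}


def build_model(name: str, params: dict | None = None, seed: int = 0):
    """Instantiate a model by family name with the given hyperparameters."""
    params = dict(params or {})
    if name == "naive":
        return NaiveMean()
    if name == "svr":
        return make_pipeline(StandardScaler(),
                             SVR(kernel="rbf", **params))
    if name == "mlp":
        params.setdefault("max_iter", 500)
        return make_pipeline(StandardScaler(),
                             MLPRegressor(random_state=seed, **params))
    if name == "adaboost":
        tree_kw = {k: params.pop(k) for k in ("max_depth", "min_samples_leaf")
                   if k in params}
        return AdaBoostRegressor(
            estimator=DecisionTreeRegressor(random_state=seed, **tree_kw),
            random_state=seed, **params)
    if name == "rf":
        if params.get("max_samples") is not None and \
                float(params.get("max_samples", 1.0)) >= 1.0:
            params["max_samples"] = None
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "lightgbm":
        from lightgbm import LGBMRegressor
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1,
                             **params)
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsRegressor(**params))
    raise ConfigurationError(f"unknown model {name!r}")
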