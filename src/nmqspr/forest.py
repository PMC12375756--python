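"""Random-forest regression of properties on the index feature matrix.

An ensemble of regression trees is fitted per property with the eight
neighborhood indices as features.  Because the published protocol (tree
count, split, seed) is unstated, two evaluation modes are produced:

* ``in_sample`` — fit on all drugs, predict the same drugs (optimistic);
* ``leave_one_out`` — each drug predicted by a forest trained on the other
  fourteen; the headline mode, since nonzero published errors imply some
  form of held-out prediction.

Metrics: R^2 = 1 - RSS/TSS, MAE, RMSE, and per-drug percent error
100*|actual - predicted|/|actual|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import LeaveOneOut

__all__ = [
    "ForestConfig",
    "ForestEval",
    "fit_predict",
    "r_squared",
    "mae",
    "rmse",
    "percent_error",
]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    seed: int = 0
    max_depth: int | None = None
    evaluation: str = "leave_one_out"  # or "in_sample"

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.evaluation not in ("in_sample", "leave_one_out"):
            raise ValueError(f"unknown evaluation mode {self.evaluation!r}")


@dataclass(frozen=True)
class ForestEval:
    property_name: str
    R2: float
    MAE: float
    RMSE: float
    per_drug: pd.DataFrame = field(repr=False)  # actual, predicted, percent_error

    def to_table(self, decimals: int = 2) -> pd.DataFrame:
        """Actual / Predicted / Error (%) layout."""
        return self.per_drug.round(decimals)


def _as_vectors(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be aligned 1-d vectors")
    if a.size == 0:
        raise ValueError("empty input")
    return a, p


def r_squared(actual, predicted) -> float:
    """Coefficient of determination; may be negative for bad predictors."""
    a, p = _as_vectors(actual, predicted)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    tss = float(np.sum((a - a.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("R^2 undefined for constant actual values")
    return 1.0 - float(np.sum((a - p) ** 2)) / tss


def mae(actual, predicted) -> float:
    a, p = _as_vectors(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def rmse(actual, predicted) -> float:
    a, p = _as_vectors(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def percent_error(actual: float, predicted: float) -> float:
    if actual == 0:
        raise ValueError("percent error undefined for zero actual value")
    return 100.0 * abs(actual - predicted) / abs(actual)


def _forest(cfg: ForestConfig) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
    )


def fit_predict(features: pd.DataFrame, y, cfg: ForestConfig,
                property_name: str = "") -> ForestEval:
    """Fit the forest and evaluate per ``cfg.evaluation``.

    ``features`` is the drugs x indices matrix; ``y`` the aligned property
    vector.  Deterministic under a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    yv = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != yv.size:
        raise ValueError("features and y are not aligned")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if cfg.evaluation == "leave_one_out" and n < 5:
        raise ValueError("leave-one-out evaluation needs at least 5 samples")

    if cfg.evaluation == "in_sample":
        model = _forest(cfg).fit(X, yv)
        pred = model.predict(X)
    else:
        pred = np.empty(n)
        for train_idx, test_idx in LeaveOneOut().split(X):
            model = _forest(cfg).fit(X[train_idx], yv[train_idx])
            pred[test_idx] = model.predict(X[test_idx])

    index = features.index if isinstance(features, pd.DataFrame) else range(n)
    per_drug = pd.DataFrame(
        {
            "actual": yv,
            "predicted": pred,
            "percent_error": [percent_error(a, p) for a, p in zip(yv, pred)],
        },
        index=index,
    )
    if np.ptp(yv) == 0.0:
        # constant target: R^2 is 0/0; report 1 for exact prediction, nan else
        r2 = 1.0 if np.array_equal(pred, yv) else float("nan")
    else:
        r2 = r_squared(yv, pred)
    return ForestEval(
        property_name=property_name,
        R2=r2,
        MAE=mae(yv, pred),
        RMSE=rmse(yv, pred),
        per_drug=per_drug,
    )
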