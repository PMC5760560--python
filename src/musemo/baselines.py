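"""Comparison arms: stepwise forward regression ensembles and random forests.

Stepwise forward regression follows the classic p-of-F scheme: at each step
the candidate whose partial F-test p-value is smallest enters if p <= p_enter
(default 0.05); after every entry, included variables with p >= p_remove
(default 0.10) are dropped.  A fold can legitimately produce no model at all
("no model") when nothing meets the entry criterion — for physiology-derived
arousal models this is the expected outcome, not an error.

Random forests are trained once on the full training pool (no cross
validation, bagging already resamples) via scikit-learn behind this module's
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "StepwiseModel",
    "ForestConfig",
    "ResultsReport",
    "stepwise_forward",
    "stepwise_predict",
    "stepwise_ensemble_predict",
    "fit_forest",
    "forest_predict",
    "build_report",
    "NO_MODEL",
]

NO_MODEL = "no model"


@dataclass
class StepwiseModel:
    """Selected features (in entry order) with OLS coefficients, or no model."""

    features: list[str] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    entry_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def no_model(self) -> bool:
        return not self.features

    def to_dict(self) -> dict:
        return {"features": self.features, "coefficients": self.coefficients,
                "intercept": self.intercept, "entry_pvalues": self.entry_pvalues,
                "no_model": self.no_model}


@dataclass
class ForestConfig:
    n_trees: int = 500
    features_per_split: int | None = None  # default floor(p / 3), min 1
    min_leaf_size: int = 5
    bootstrap: bool = True
    seed: int = 0

    def resolved_features_per_split(self, p: int) -> int:
        m = self.features_per_split if self.features_per_split is not None \
            else max(1, p // 3)
        if not 1 <= m <= p:
            raise ValueError(f"features_per_split must lie in 1..{p}")
        return m


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_forward(X: pd.DataFrame, y: np.ndarray,
                     p_enter: float = 0.05, p_remove: float = 0.10) -> StepwiseModel:
    """Forward selection with backward pruning by p-of-F thresholds."""
    if p_enter >= p_remove:
        raise ValueError("p_enter must be < p_remove (cycling hazard)")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if len(X) != n:
        raise ValueError("X and y lengths differ")
    candidates = list(X.columns)
    selected: list[str] = []
    entry_p: dict[str, float] = {}
    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        # entry step: any candidate fit needs n > (#selected + 1) + 1 rows
        if remaining and n > len(selected) + 2:
            best_c, best_p = None, np.inf
            for c in remaining:
                res = _ols(y, X[selected + [c]].to_numpy(dtype=float))
                p_val = float(res.pvalues[-1])  # partial F p == t-test p, 1 df
                if p_val < best_p:
                    best_c, best_p = c, p_val
            if best_c is not None and best_p <= p_enter:
                selected.append(best_c)
                entry_p[best_c] = best_p
                changed = True
        # removal step
        while len(selected) > 1:
            res = _ols(y, X[selected].to_numpy(dtype=float))
            pvals = dict(zip(selected, res.pvalues[1:]))
            worst = max(pvals, key=pvals.get)
            if pvals[worst] >= p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        return StepwiseModel()
    res = _ols(y, X[selected].to_numpy(dtype=float))
    coeffs = dict(zip(selected, (float(v) for v in res.params[1:])))
    return StepwiseModel(features=selected, coefficients=coeffs,
                         intercept=float(res.params[0]),
                         entry_pvalues={k: float(v) for k, v in entry_p.items()})


def stepwise_predict(model: StepwiseModel, X: pd.DataFrame) -> np.ndarray:
    if model.no_model:
        raise ValueError("cannot predict from a no-model outcome")
    pred = np.full(len(X), model.intercept, dtype=float)
    for f in model.features:
        pred += model.coefficients[f] * X[f].to_numpy(dtype=float)
    return pred


def stepwise_ensemble_predict(models: list[StepwiseModel], X: pd.DataFrame
                              ) -> np.ndarray | None:
    """Mean prediction over the fitted (non-no-model) members; None if none."""
    fitted = [m for m in models if not m.no_model]
    if not fitted:
        return None
    return np.mean([stepwise_predict(m, X) for m in fitted], axis=0)


@dataclass
class ForestModel:
    regressor: RandomForestRegressor
    feature_names: list[str]


def fit_forest(X: pd.DataFrame, y: np.ndarray, config: ForestConfig) -> ForestModel:
    """Bagged regression-tree ensemble on the full training pool."""
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if config.n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    reg = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.resolved_features_per_split(X.shape[1]),
        min_samples_leaf=config.min_leaf_size,
        bootstrap=config.bootstrap,
        random_state=config.seed,
    )
    reg.fit(X.to_numpy(dtype=float), y)
    return ForestModel(regressor=reg, feature_names=list(X.columns))


def forest_predict(model: ForestModel, X: pd.DataFrame) -> np.ndarray:
    return model.regressor.predict(X[model.feature_names].to_numpy(dtype=float))


@dataclass
class ResultsReport:
    """Summary grid: {method} x {dimension} x {feature set} -> test RMSE."""

    cells: dict  # nested: method -> feature_set -> dimension -> value
    committee: dict  # "CMEA"/"CMLR" -> dimension -> rmse; plus contributions
    n_models: dict  # method -> feature_set -> dimension -> fitted model count
    test_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, by_fs in self.cells.items():
            for fs, by_dim in by_fs.items():
                for dim, v in by_dim.items():
                    rows.append({
                        "method": method, "feature_set": fs, "dimension": dim,
                        "test_rmse": NO_MODEL if v is None else v,
                        "n_models": self.n_models.get(method, {}).get(fs, {}).get(dim),
                    })
        for name, by_dim in self.committee.items():
            if name in ("CMEA", "CMLR"):
                for dim, v in by_dim.items():
                    rows.append({"method": name, "feature_set": "audio+physio",
                                 "dimension": dim, "test_rmse": v, "n_models": None})
        return pd.DataFrame(rows)


def build_report(cells: dict, committee: dict, n_models: dict,
                 test_ids_by_arm: dict[str, list[str]]) -> ResultsReport:
    """Assemble the summary grid, insisting every arm used the same test set."""
    test_sets = {tuple(sorted(v)) for v in test_ids_by_arm.values()}
    if len(test_sets) > 1:
        raise ValueError(f"inconsistent test sets across arms: {sorted(test_ids_by_arm)}")
    for method, by_fs in cells.items():
        for fs, by_dim in by_fs.items():
            for dim, v in by_dim.items():
                if v is not None and v < 0:
                    raise ValueError(f"negative RMSE in cell {method}/{fs}/{dim}")
    test_ids = sorted(next(iter(test_sets))) if test_sets else []
    return ResultsReport(cells=cells, committee=committee, n_models=n_models,
                         test_ids=test_ids)
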