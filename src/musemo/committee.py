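"""Fold-network ensembles and the two committee machines.

An ensemble is the unweighted mean of the five fold-trained networks for one
(dimension, feature set).  The committee machines combine the perception
(audio-input) and feeling (physiology-input) ensemble outputs:

* CMEA — equal 0.5/0.5 averaging of the two ensemble outputs;
* CMLR — coefficients fit by ordinary least squares of the mean ratings
  (0-1 scale) on the two ensemble outputs plus an intercept.

The salience of each channel is summarized as contribution percentages,
100 * |b| / (|b_perc| + |b_feel|), ignoring the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import statsmodels.api as sm

from .mlp import NetworkModel, forward

__all__ = [
    "EnsembleModel",
    "CommitteeModel",
    "ContributionReport",
    "ensemble_predict",
    "cmea_predict",
    "fit_cmlr",
    "cmlr_predict",
    "contributions",
    "round_half_up",
]


@dataclass
class EnsembleModel:
    """Five fold networks for one (dimension, feature set)."""

    members: list[NetworkModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member network")
        schema = self.members[0].feature_names
        dim = self.members[0].dimension
        for m in self.members[1:]:
            if m.feature_names != schema or m.dimension != dim:
                raise ValueError("ensemble members must share input schema and dimension")

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].feature_names

    @property
    def dimension(self) -> str:
        return self.members[0].dimension

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ensemble_predict(self, X)


@dataclass
class CommitteeModel:
    """Linear stack y = b_perc * x1 + b_feel * x2 + intercept for one dimension."""

    dimension: str
    b_perc: float
    b_feel: float
    intercept: float

    def to_dict(self) -> dict:
        return {"dimension": self.dimension, "b_perc": self.b_perc,
                "b_feel": self.b_feel, "intercept": self.intercept}


@dataclass
class ContributionReport:
    perc_pct: float
    feel_pct: float


def ensemble_predict(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the member networks' outputs."""
    preds = np.stack([forward(m.weights, X) for m in ensemble.members])
    return preds.mean(axis=0)


def cmea_predict(p_out, f_out):
    """Equal-weight committee: 0.5 * perception + 0.5 * feeling."""
    return 0.5 * np.asarray(p_out, dtype=float) + 0.5 * np.asarray(f_out, dtype=float)


def fit_cmlr(p_outs: np.ndarray, f_outs: np.ndarray, targets: np.ndarray,
             dimension: str = "") -> CommitteeModel:
    """OLS fit of mean ratings on the two ensemble outputs plus intercept."""
    p = np.asarray(p_outs, dtype=float).ravel()
    f = np.asarray(f_outs, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if not len(p) == len(f) == len(t) or len(p) < 3:
        raise ValueError("need >= 3 aligned (perception, feeling, target) triples")
    X = sm.add_constant(np.column_stack([p, f]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design is rank deficient: perception and feeling outputs (or an "
            "output and the constant) are exactly collinear")
    res = sm.OLS(t, X).fit()
    const, b_p, b_f = res.params
    return CommitteeModel(dimension=dimension, b_perc=float(b_p),
                          b_feel=float(b_f), intercept=float(const))


def cmlr_predict(model: CommitteeModel, p_out, f_out):
    return (model.b_perc * np.asarray(p_out, dtype=float)
            + model.b_feel * np.asarray(f_out, dtype=float) + model.intercept)


def contributions(model: CommitteeModel) -> ContributionReport:
    """Percent contribution of each channel from coefficient magnitudes.

    The intercept is ignored; absolute values guard against sign flips on
    synthetic data (the study's printed coefficients are all positive).
    """
    denom = abs(model.b_perc) + abs(model.b_feel)
    if denom == 0:
        raise ValueError("both committee coefficients are zero")
    perc = 100.0 * abs(model.b_perc) / denom
    return ContributionReport(perc_pct=perc, feel_pct=100.0 - perc)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of the reported percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
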