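"""Feature reduction, scaling, and first-pass correlation analyses.

Feature reduction removes, greedily, any feature whose pairwise Pearson
correlation with another feature exceeds a threshold (default |r| > 0.8):
while a violating pair remains, the feature with the most violating partners
is dropped (ties broken by larger mean |r| to the remaining features, then by
input order).  All inputs to the regression models are then min-max scaled to
[0, 1], and mean ratings are mapped from the [-1, 1] grid to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "ScalingParams",
    "correlation_matrix",
    "reduce_features",
    "fit_minmax",
    "apply_minmax",
    "rescale_rating",
    "unscale_rating",
    "baseline_subtract",
    "feature_rating_correlations",
]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations plus bookkeeping for feature reduction."""

    r: pd.DataFrame
    zero_variance: list[str] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return list(self.r.columns)

    def violations(self, threshold: float = 0.8) -> dict[str, list[str]]:
        """Per-feature list of partners with |r| strictly above the threshold."""
        out: dict[str, list[str]] = {f: [] for f in self.features}
        for i, fi in enumerate(self.features):
            for fj in self.features[i + 1:]:
                rij = self.r.loc[fi, fj]
                if np.isfinite(rij) and abs(rij) > threshold:
                    out[fi].append(fj)
                    out[fj].append(fi)
        return out


@dataclass
class ScalingParams:
    """Observed per-feature min/max from the fitting table."""

    mins: dict[str, float]
    maxs: dict[str, float]

    def to_dict(self) -> dict:
        return {"mins": self.mins, "maxs": self.maxs}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(mins=dict(d["mins"]), maxs=dict(d["maxs"]))


def correlation_matrix(table: pd.DataFrame) -> CorrelationReport:
    """Pearson correlation matrix of every column pair.

    Zero-variance columns yield undefined correlations (NaN off-diagonal);
    they are flagged and never counted as threshold violations.
    """
    if len(table) < 3:
        raise ValueError("correlation matrix needs at least 3 rows")
    if table.isna().any().any():
        raise ValueError("missing values are rejected at ingest, not imputed")
    values = table.to_numpy(dtype=float)
    sd = values.std(axis=0)
    zero_var = [c for c, s in zip(table.columns, sd) if s == 0.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationReport(
        r=pd.DataFrame(r, index=table.columns, columns=table.columns),
        zero_variance=zero_var,
    )


def reduce_features(report: CorrelationReport, threshold: float = 0.8
                    ) -> tuple[list[str], list[dict]]:
    """Greedy correlation-threshold feature removal.

    Returns the retained features (input order preserved) and a removal trace:
    one entry per removed feature with its violating partners at removal time.
    """
    remaining = list(report.features)
    trace: list[dict] = []
    while True:
        sub = report.r.loc[remaining, remaining]
        viol = {f: [] for f in remaining}
        for i, fi in enumerate(remaining):
            for fj in remaining[i + 1:]:
                rij = sub.loc[fi, fj]
                if np.isfinite(rij) and abs(rij) > threshold:
                    viol[fi].append(fj)
                    viol[fj].append(fi)
        worst = max((len(v) for v in viol.values()), default=0)
        if worst == 0:
            break

        def mean_abs_r(f: str) -> float:
            others = [g for g in remaining if g != f]
            vals = np.abs(sub.loc[f, others].to_numpy(dtype=float))
            vals = vals[np.isfinite(vals)]
            return float(vals.mean()) if len(vals) else 0.0

        candidates = [f for f in remaining if len(viol[f]) == worst]
        # tie-break: larger mean |r| to remaining features, then input order
        candidates.sort(key=lambda f: (-mean_abs_r(f), remaining.index(f)))
        removed = candidates[0]
        trace.append({
            "feature": removed,
            "n_violations": worst,
            "partners": list(viol[removed]),
            "mean_abs_r": mean_abs_r(removed),
        })
        remaining.remove(removed)
    return remaining, trace


def fit_minmax(table: pd.DataFrame, features: list[str] | None = None) -> ScalingParams:
    """Record the observed min and max of each feature column."""
    features = list(features) if features is not None else list(table.columns)
    mins = {f: float(table[f].min()) for f in features}
    maxs = {f: float(table[f].max()) for f in features}
    return ScalingParams(mins=mins, maxs=maxs)


def apply_minmax(params: ScalingParams, table: pd.DataFrame) -> pd.DataFrame:
    """Affine-map each feature so the fitted min -> 0 and max -> 1.

    Values outside the fitted range map outside [0, 1] (no clipping).  A
    constant feature maps everywhere to 0.5, with a warning.
    """
    out = {}
    for f in params.mins:
        lo, hi = params.mins[f], params.maxs[f]
        if hi == lo:
            warnings.warn(f"feature {f!r} is constant; scaled values set to 0.5")
            out[f] = np.full(len(table), 0.5)
        else:
            out[f] = (table[f].to_numpy(dtype=float) - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


def rescale_rating(v):
    """Map a rating from the [-1, 1] grid to the [0, 1] network scale."""
    return (np.asarray(v, dtype=float) + 1.0) / 2.0


def unscale_rating(v):
    """Inverse of :func:`rescale_rating`."""
    return 2.0 * np.asarray(v, dtype=float) - 1.0


def baseline_subtract(excerpt_value, baseline_value):
    """Excerpt-period feature minus its white-noise-baseline counterpart."""
    e = np.asarray(excerpt_value, dtype=float)
    b = np.asarray(baseline_value, dtype=float)
    if np.isnan(e).any() or np.isnan(b).any():
        raise ValueError("missing excerpt or baseline value; refusing silent zero")
    return e - b


def feature_rating_correlations(features: pd.DataFrame, ratings: pd.DataFrame
                                ) -> pd.DataFrame:
    """Pearson r of every feature against each mean-rating dimension.

    Returns a tidy frame (feature, dimension, r, df, p) with df = n - 2 and a
    two-sided p from the t distribution; zero-variance features are flagged
    with NaN statistics.
    """
    n = len(features)
    if n < 4:
        raise ValueError("need at least 4 excerpts for correlation inference")
    rows = []
    for dim in ratings.columns:
        y = ratings[dim].to_numpy(dtype=float)
        for f in features.columns:
            x = features[f].to_numpy(dtype=float)
            if x.std() == 0.0 or y.std() == 0.0:
                rows.append({"feature": f, "dimension": dim, "r": np.nan,
                             "df": n - 2, "p": np.nan, "zero_variance": True})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"feature": f, "dimension": dim, "r": float(r),
                         "df": n - 2, "p": float(p), "zero_variance": False})
    return pd.DataFrame(rows)
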