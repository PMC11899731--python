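"""Outcome constructions and OLS on selected logratios.

Covers the health-outcome side of the pipeline: the chronic disease index
(count of 8 self-reported conditions), the deficit-accumulation frailty
index and its four-level categorization, ordinary least squares of each
outcome on the top selected logratios plus covariate tiers, and the
adjusted-R² comparison against the model spanned by all pairwise logratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .logratios import LogratioSet
from .logcontrast import covariate_design

__all__ = [
    "LogratioRegressionFit",
    "fit_logratio_ols",
    "compare_r2",
    "categorize_frailty",
    "chronic_disease_index",
]

#: Frailty cut points: robust < 0.15 ≤ prefrail < 0.25 ≤ mildly frail
#: < 0.35 ≤ moderate-to-severely frail.  Half-open bins keep the printed
#: two-decimal ranges (0.15–0.24, 0.25–0.34) exhaustive and disjoint.
FRAILTY_CUTS = (0.15, 0.25, 0.35)


def categorize_frailty(index) -> np.ndarray | int:
    """Map a continuous deficit-accumulation index in [0,1] to levels 1–4."""
    arr = np.asarray(index, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("frailty index must lie in [0, 1]")
    level = 1 + (arr >= FRAILTY_CUTS[0]).astype(int) \
              + (arr >= FRAILTY_CUTS[1]).astype(int) \
              + (arr >= FRAILTY_CUTS[2]).astype(int)
    return int(level) if np.isscalar(index) else level


def chronic_disease_index(conditions) -> np.ndarray | int:
    """Sum of 8 binary self-reported chronic-condition flags (0–8)."""
    arr = np.asarray(conditions)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 8:
        raise ValueError("exactly 8 condition flags are required")
    if np.isnan(arr.astype(float)).any():
        raise ValueError("missing condition flag")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("condition flags must be 0/1")
    total = arr.sum(axis=1).astype(int)
    return int(total[0]) if total.shape[0] == 1 and np.ndim(conditions) == 1 else total


@dataclass
class LogratioRegressionFit:
    """OLS of an outcome on selected logratios + covariates."""

    params: pd.Series
    conf_int: pd.DataFrame  # columns ci_lo, ci_hi
    adjusted_r2: float
    r2: float
    dropped: list[str]  # aliased columns removed to reach full rank
    tier: int | None = None

    def tidy(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "ci_lo": self.conf_int["ci_lo"].values,
                "ci_hi": self.conf_int["ci_hi"].values,
            }
        )
        out["adj_r2"] = self.adjusted_r2
        return out


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that do not increase matrix rank."""
    keep: list[str] = []
    dropped: list[str] = []
    rank = 0
    for col in X.columns:
        trial = X[keep + [col]].to_numpy(dtype=float)
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(col)
            rank = r
        else:
            dropped.append(col)
    return X[keep], dropped


def fit_logratio_ols(
    lrs_selected: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    tier: int = 1,
) -> LogratioRegressionFit:
    """Classical OLS with 95% CIs on the selected logratio columns."""
    y = np.asarray(outcome, dtype=float).ravel()
    W = covariate_design(covariates, tier, n=len(y))
    X = pd.concat(
        [W.reset_index(drop=True), lrs_selected.reset_index(drop=True)], axis=1
    )
    X, dropped = _drop_aliased(X)
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    params = pd.Series(res.params, index=X.columns)
    ci = pd.DataFrame(res.conf_int(alpha=0.05), index=X.columns, columns=["ci_lo", "ci_hi"])
    return LogratioRegressionFit(
        params=params,
        conf_int=ci,
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        dropped=dropped,
        tier=tier,
    )


def _minimum_norm_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Minimum-norm least squares; returns fitted values and effective rank."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef, int(rank)


def compare_r2(
    lrs_all: LogratioSet | pd.DataFrame,
    lrs_selected: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    tier: int = 1,
) -> dict:
    """Adjusted R² of the full-logratio-span model vs the selected model.

    The full set of pairwise logratios spans a rank-(D−1) space, so the full
    model is fit by minimum-norm least squares and its adjusted R² uses the
    design's effective rank as the degrees of freedom.
    """
    full_df = lrs_all.values if isinstance(lrs_all, LogratioSet) else lrs_all
    y = np.asarray(outcome, dtype=float).ravel()
    n = len(y)
    W = covariate_design(covariates, tier, n=n).to_numpy(dtype=float)
    Xf = np.hstack([W, full_df.to_numpy(dtype=float)])
    fitted, rank = _minimum_norm_fit(Xf, y)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2_full = 1 - ss_res / ss_tot
    adj_full = 1 - (1 - r2_full) * (n - 1) / (n - rank)
    sel = fit_logratio_ols(lrs_selected, y, covariates, tier=tier)
    return {
        "r2_full": r2_full,
        "adj_r2_full": adj_full,
        "r2_selected": sel.r2,
        "adj_r2_selected": sel.adjusted_r2,
        "delta_adj_r2": adj_full - sel.adjusted_r2,
        "rank_full": rank,
    }
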