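"""Penalized log-contrast regression of health outcomes on compositions.

The log-contrast model regresses an outcome on the log-parts of a
composition under the constraint that the coefficients sum to zero:

    y = Z beta + W gamma + e,   sum(beta) = 0,

with Z the centred ln-composition columns and W unpenalized covariates
(always including an intercept).  The zero-sum constraint makes the fit
invariant to per-subject rescaling of the raw parts — only relative
information enters.  Sparsity in beta comes from an L1 penalty

    min (1/2n) ||y − Z beta − W gamma||² + lambda ||beta||₁,  s.t. Σbeta = 0,

solved by an augmented-Lagrangian coordinate-descent scheme.  The penalty is
tuned by BIC and uncertainty quantified by a case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import CompositionMatrix

__all__ = [
    "LogContrastFit",
    "covariate_design",
    "fit_penalized_logcontrast",
    "bic_select",
    "bootstrap_ci",
    "lambda_grid",
]

RACE_LEVELS = ["white", "black", "hispanic", "other"]
EDUCATION_LEVELS = [
    "below_secondary",
    "lower_secondary",
    "upper_secondary",
    "above_upper_secondary",
]


def covariate_design(covariates: pd.DataFrame | None, tier: int, n: int | None = None) -> pd.DataFrame:
    """Covariate matrix for a model tier.

    Tier 1: intercept only.  Tier 2: + age and sex (female indicator).
    Tier 3: + race, education (dummy-coded against the first level) and CMV
    serostatus (reactive indicator).
    """
    if tier not in (1, 2, 3):
        raise ValueError("tier must be 1, 2 or 3")
    if covariates is None:
        if tier != 1:
            raise ValueError("tiers 2-3 need covariates")
        if n is None:
            raise ValueError("give n for an intercept-only design")
        return pd.DataFrame({"intercept": np.ones(n)})
    W = pd.DataFrame(index=covariates.index)
    W["intercept"] = 1.0
    if tier >= 2:
        W["age"] = covariates["age"].astype(float)
        W["sex_female"] = (covariates["sex"] == "female").astype(float)
    if tier >= 3:
        for lvl in RACE_LEVELS[1:]:
            W[f"race_{lvl}"] = (covariates["race"] == lvl).astype(float)
        for lvl in EDUCATION_LEVELS[1:]:
            W[f"education_{lvl}"] = (covariates["education"] == lvl).astype(float)
        W["cmv_reactive"] = (covariates["cmv"] == "reactive").astype(float)
    return W


@dataclass
class LogContrastFit:
    """Result of one penalized log-contrast fit."""

    beta: pd.Series  # zero-sum coefficients over the leaf log-parts
    gamma: pd.Series  # unpenalized covariate coefficients (incl. intercept)
    lam: float
    objective: float
    tier: int | None = None
    bic_path: pd.DataFrame | None = None
    ci: pd.DataFrame | None = None

    @property
    def active(self) -> list[str]:
        return list(self.beta.index[self.beta != 0.0])


def _log_design(comp: CompositionMatrix | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    df = comp.proportions if isinstance(comp, CompositionMatrix) else comp
    x = df.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("composition has non-positive parts; run replace_zeros first")
    Z = np.log(x)
    return Z, list(df.columns)


def _soft(u: float, t: float) -> float:
    return np.sign(u) * max(abs(u) - t, 0.0)


def _constrained_lasso_gram(
    G: np.ndarray,
    b: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 2000,
) -> np.ndarray:
    """Zero-sum L1 problem in Gram form.

    Minimises (1/2) betaᵀG beta − bᵀbeta + lam‖beta‖₁ subject to Σbeta = 0,
    where G = ZᵀZ/n and b = Zᵀy/n for column-centred, covariate-residualised
    data.  Augmented Lagrangian on the constraint with coordinate descent on
    the inner lasso; the active set is re-projected to the constraint at the
    end so Σbeta = 0 holds exactly.
    """
    p = G.shape[0]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    u = 0.0
    mu = max(1.0, lam)
    prev_gap = np.inf
    for _ in range(100):  # outer augmented-Lagrangian loop
        for _ in range(max_sweeps):
            max_delta = 0.0
            s = beta.sum()
            for j in range(p):
                gj = G[j] @ beta - G[j, j] * beta[j]
                sj = s - beta[j]
                a = G[j, j] + mu
                c = b[j] - gj - u - mu * sj
                new = _soft(c, lam) / a
                if new != beta[j]:
                    max_delta = max(max_delta, abs(new - beta[j]) * np.sqrt(G[j, j] + 1e-12))
                    s += new - beta[j]
                    beta[j] = new
            if max_delta < tol:
                break
        gap = abs(beta.sum())
        if gap < 1e-12:
            break
        u += mu * gap * np.sign(beta.sum())
        if gap > 0.25 * prev_gap:
            mu *= 10.0
        prev_gap = gap
    # exact re-projection onto the constraint over the active set
    act = beta != 0.0
    if act.any():
        beta[act] -= beta[act].mean()
    return beta


def fit_penalized_logcontrast(
    comp: CompositionMatrix | pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    lam: float = 0.0,
    tier: int | None = None,
    W: pd.DataFrame | None = None,
) -> LogContrastFit:
    """Fit the zero-sum L1 log-contrast model at a fixed penalty.

    Covariates may be given either as a raw covariate table plus ``tier``
    (see :func:`covariate_design`) or as a prebuilt design ``W``; when both
    are absent an intercept-only design is used.  The unpenalized block is
    handled exactly by residualising y and Z on W before the coordinate
    descent and recovering gamma afterwards.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Z, parts = _log_design(comp)
    y = np.asarray(outcome, dtype=float).ravel()
    n = len(y)
    if Z.shape[0] != n:
        raise ValueError("outcome and composition row counts differ")
    if W is None:
        W = covariate_design(covariates, tier or 1, n=n)
    Wm = W.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Wm) < Wm.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    # residualise out the unpenalized block (exact for unpenalized covariates)
    WtW_inv = np.linalg.inv(Wm.T @ Wm)
    H = WtW_inv @ Wm.T
    y_r = y - Wm @ (H @ y)
    Z_r = Z - Wm @ (H @ Z)
    G = Z_r.T @ Z_r / n
    b = Z_r.T @ y_r / n
    beta = _constrained_lasso_gram(G, b, lam)
    gamma = H @ (y - Z @ beta)
    resid = y - Z @ beta - Wm @ gamma
    obj = 0.5 * float(resid @ resid) / n + lam * float(np.abs(beta).sum())
    return LogContrastFit(
        beta=pd.Series(beta, index=parts, name="beta"),
        gamma=pd.Series(gamma, index=list(W.columns), name="gamma"),
        lam=float(lam),
        objective=obj,
        tier=tier,
    )


def lambda_grid(
    comp: CompositionMatrix | pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    tier: int | None = None,
    n_lambdas: int = 30,
    ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced grid from the all-zero-beta penalty down."""
    Z, _ = _log_design(comp)
    y = np.asarray(outcome, dtype=float).ravel()
    W = covariate_design(covariates, tier or 1, n=len(y)).to_numpy(dtype=float)
    H = np.linalg.inv(W.T @ W) @ W.T
    y_r = y - W @ (H @ y)
    Z_r = Z - W @ (H @ Z)
    lam_max = float(np.abs(Z_r.T @ y_r).max() / len(y)) * 1.05
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def bic_select(
    comp: CompositionMatrix | pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    tier: int | None = None,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the penalty minimising BIC(λ) = n·ln(RSS/n) + df(λ)·ln(n).

    df counts the nonzero beta coefficients plus the fixed covariate block.
    Ties resolve to the larger penalty (the grid is scanned descending and a
    strictly smaller BIC is required to displace the incumbent).
    """
    if grid is None:
        grid = lambda_grid(comp, outcome, covariates, tier)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if len(grid) == 0:
        raise ValueError("empty penalty grid")
    y = np.asarray(outcome, dtype=float).ravel()
    n = len(y)
    Z, _ = _log_design(comp)
    W = covariate_design(covariates, tier or 1, n=n)
    rows = []
    best_lam, best_bic = None, np.inf
    for lam in grid:
        fit = fit_penalized_logcontrast(comp, outcome, covariates, lam=lam, tier=tier, W=W)
        resid = y - Z @ fit.beta.to_numpy() - W.to_numpy(dtype=float) @ fit.gamma.to_numpy()
        rss = float(resid @ resid)
        df = int((fit.beta != 0).sum()) + W.shape[1]
        bic = n * np.log(max(rss, 1e-300) / n) + df * np.log(n)
        rows.append({"lambda": lam, "rss": rss, "df": df, "bic": bic})
        if bic < best_bic - 1e-12:
            best_bic, best_lam = bic, lam
    return float(best_lam), pd.DataFrame(rows)


def bootstrap_ci(
    comp: CompositionMatrix | pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    lam: float = 0.0,
    tier: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    retune: bool = False,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Case-resampling percentile bootstrap intervals at a fixed penalty.

    Each replicate refits the model at the originally selected lambda
    (``retune=True`` re-runs BIC per replicate); degenerate resamples with a
    constant outcome are skipped and counted.  Deterministic under ``seed``.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap repetitions")
    df_in = comp.proportions if isinstance(comp, CompositionMatrix) else comp
    y = np.asarray(outcome, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    draws = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.ptp(yb) == 0:
            skipped += 1
            continue
        cb = df_in.iloc[idx].reset_index(drop=True)
        covb = None if covariates is None else covariates.iloc[idx].reset_index(drop=True)
        lamb = lam
        if retune:
            lamb, _ = bic_select(cb, yb, covb, tier=tier, grid=grid)
        fit = fit_penalized_logcontrast(cb, yb, covb, lam=lamb, tier=tier)
        draws.append(pd.concat([fit.beta, fit.gamma]))
    if not draws:
        raise ValueError("all bootstrap resamples degenerate")
    mat = pd.DataFrame(draws)
    alpha = (1 - level) / 2
    out = pd.DataFrame(
        {
            "ci_lo": mat.quantile(alpha),
            "ci_hi": mat.quantile(1 - alpha),
        }
    )
    out.attrs["n_replicates"] = len(draws)
    out.attrs["n_skipped"] = skipped
    return out


def fit_with_inference(
    comp: CompositionMatrix | pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    tier: int = 1,
    n_boot: int = 200,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> LogContrastFit:
    """BIC-tuned fit with bootstrap percentile intervals (one model tier)."""
    lam, path = bic_select(comp, outcome, covariates, tier=tier, grid=grid)
    fit = fit_penalized_logcontrast(comp, outcome, covariates, lam=lam, tier=tier)
    fit.bic_path = path
    ci = bootstrap_ci(
        comp, outcome, covariates, lam=lam, tier=tier, n_boot=n_boot, seed=seed
    )
    point = pd.concat([fit.beta, fit.gamma])
    ci["estimate"] = point
    fit.ci = ci[["estimate", "ci_lo", "ci_hi"]]
    return fit
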