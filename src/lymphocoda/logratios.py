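"""Pairwise logratios, total logratio variance, and stepwise selection.

A D-part composition carries only relative information, so its natural
coordinates are the C(D,2) pairwise logratios ln(x_i/x_j).  For the 16
terminal lymphocyte subsets that is 120 logratios, of which at most D−1 = 15
are linearly independent.  Stepwise redundancy analysis (SRDA) greedily picks
logratios that maximise the cumulative share of the total logratio variance
they explain, yielding a small, interpretable coordinate set that still
captures the composition's geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .tree import CompositionMatrix

__all__ = [
    "LogratioSet",
    "SelectionTrace",
    "all_pairwise_logratios",
    "total_logratio_variance",
    "srda_select",
    "pairwise_correlations",
    "clr_matrix",
]


def _positive_values(comp: CompositionMatrix | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    df = comp.proportions if isinstance(comp, CompositionMatrix) else comp
    x = df.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError(
            "composition has non-positive parts; run replace_zeros first"
        )
    return x, list(df.columns)


def clr_matrix(comp: CompositionMatrix | pd.DataFrame) -> np.ndarray:
    """Centred log-ratio coordinates: ln(x) minus the per-row mean of ln(x)."""
    x, _ = _positive_values(comp)
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


@dataclass
class LogratioSet:
    """All pairwise logratios ln(x_i/x_j), i<j in canonical leaf order."""

    pairs: list[tuple[str, str]]
    values: pd.DataFrame  # n × C(D,2), columns labelled "A/B"
    parts: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def clr(self) -> np.ndarray:
        """Reconstruct CLR coordinates from the pairwise logratios.

        clr_i = (1/D) Σ_j ln(x_i/x_j); pairwise logratios determine the CLR
        matrix exactly, which SRDA uses as the full-geometry response.
        """
        D = len(self.parts)
        n = len(self.values)
        clr = np.zeros((n, D))
        vals = self.values.to_numpy(dtype=float)
        idx = {p: k for k, p in enumerate(self.parts)}
        for col, (a, b) in enumerate(self.pairs):
            ia, ib = idx[a], idx[b]
            clr[:, ia] += vals[:, col]
            clr[:, ib] -= vals[:, col]
        return clr / D


def all_pairwise_logratios(comp: CompositionMatrix | pd.DataFrame) -> LogratioSet:
    """Construct the C(D,2) pairwise logratio columns (natural log)."""
    x, parts = _positive_values(comp)
    logx = np.log(x)
    pairs = list(combinations(parts, 2))
    idx = {p: k for k, p in enumerate(parts)}
    cols = {f"{a}/{b}": logx[:, idx[a]] - logx[:, idx[b]] for a, b in pairs}
    index = (comp.proportions if isinstance(comp, CompositionMatrix) else comp).index
    return LogratioSet(pairs=pairs, values=pd.DataFrame(cols, index=index), parts=parts)


def total_logratio_variance(
    comp: CompositionMatrix | pd.DataFrame,
    weights: str = "uniform",
) -> float:
    """Aggregate variance of all pairwise logratios.

    With uniform part weights 1/D the total is
    T = (1/D²) Σ_{i<j} Var(ln(x_i/x_j)), identically (1/D)·trace of the CLR
    covariance.  ``weights="part_means"`` instead weights each pair by the
    product of the mean (closed) part proportions, the easyCODA-style
    convention.  Sample variances use denominator n−1.
    """
    x, parts = _positive_values(comp)
    n, D = x.shape
    if n < 2:
        raise ValueError("total logratio variance undefined for n < 2")
    logx = np.log(x)
    if weights == "uniform":
        w = np.full(D, 1.0 / D)
    elif weights == "part_means":
        closed = x / x.sum(axis=1, keepdims=True)
        w = closed.mean(axis=0)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    total = 0.0
    for i in range(D):
        for j in range(i + 1, D):
            total += w[i] * w[j] * np.var(logx[:, i] - logx[:, j], ddof=1)
    return float(total)


@dataclass
class SelectionTrace:
    """Greedy selection record: per-step pair and variance fractions."""

    steps: pd.DataFrame  # columns: step, pair, additional, cumulative
    total_variance: float

    @property
    def selected_pairs(self) -> list[str]:
        return list(self.steps["pair"])

    def to_csv(self, path) -> None:
        out = self.steps.copy()
        out["additional_pct"] = 100 * out["additional"]
        out["cumulative_pct"] = 100 * out["cumulative"]
        out.to_csv(path, index=False)


def srda_select(
    lrs: LogratioSet,
    target_fraction: float | None = None,
    max_steps: int | None = None,
    rank_tol: float = 1e-10,
) -> SelectionTrace:
    """Stepwise redundancy analysis over the pairwise logratios.

    At each step the procedure adds the logratio whose inclusion maximises
    the fraction of total logratio variance explained, where explained
    variance is the (uniformly weighted) variance of the least-squares
    projection of the centred CLR matrix onto the span of the selected
    logratio columns.  Iteration stops at ``target_fraction``, after
    ``max_steps``, or when no candidate adds variance (cumulative 1, at most
    rank(CLR) ≤ D−1 steps).  Ties are broken by lexicographic pair order.
    """
    if target_fraction is None and max_steps is None:
        raise ValueError("provide target_fraction and/or max_steps")
    n = len(lrs.values)
    Y = lrs.clr()
    Y = Y - Y.mean(axis=0, keepdims=True)
    D = Y.shape[1]
    # total weighted variance × (n−1)·D: the projection bookkeeping scale
    denom = float((Y**2).sum())
    if denom <= 0:
        raise ValueError("zero total variance: composition constant across subjects")
    total_variance = denom / ((n - 1) * D)

    C = lrs.values.to_numpy(dtype=float)
    C = C - C.mean(axis=0, keepdims=True)
    col_norm0 = (C**2).sum(axis=0)
    labels = list(lrs.values.columns)

    Q = np.empty((n, 0))
    remaining = list(range(C.shape[1]))
    rows = []
    cumulative = 0.0
    step = 0
    while remaining:
        if max_steps is not None and step >= max_steps:
            break
        R = C[:, remaining] - Q @ (Q.T @ C[:, remaining])
        rn = (R**2).sum(axis=0)
        ok = rn > rank_tol * np.maximum(col_norm0[remaining], 1.0)
        if not ok.any():
            break
        gains = np.full(len(remaining), -np.inf)
        proj = R.T @ Y  # candidate × D
        gains[ok] = (proj[ok] ** 2).sum(axis=1) / rn[ok]
        # lexicographically first among candidates within float noise of the
        # max: distinct pairs can span identical subspaces (exact ties), so
        # a tolerance keeps the choice deterministic across reorderings
        gmax = gains.max()
        best = int(np.argmax(gains >= gmax - 1e-10 * max(denom, 1.0)))
        add = float(gains[best]) / denom
        j = remaining[best]
        q = R[:, best] / np.sqrt(rn[best])
        Q = np.hstack([Q, q[:, None]])
        cumulative += add
        step += 1
        rows.append(
            {
                "step": step,
                "pair": labels[j],
                "additional": add,
                "cumulative": min(cumulative, 1.0) if cumulative > 1 else cumulative,
            }
        )
        remaining.pop(best)
        if target_fraction is not None and cumulative >= target_fraction - 1e-12:
            break
    steps = pd.DataFrame(rows, columns=["step", "pair", "additional", "cumulative"])
    return SelectionTrace(steps=steps, total_variance=total_variance)


def pairwise_correlations(
    comp: CompositionMatrix | pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation matrix of the leaf proportions (Pearson by default)."""
    df = comp.proportions if isinstance(comp, CompositionMatrix) else comp
    if (df.std(ddof=1) == 0).any():
        flat = df.columns[df.std(ddof=1) == 0].tolist()
        raise ValueError(f"zero-variance columns make correlations undefined: {flat}")
    return df.corr(method=method)
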