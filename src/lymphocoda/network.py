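"""Conditional-dependence networks on CLR-transformed compositions.

Edges represent conditional dependence between subsets after adjusting for
all other subsets: the composition is CLR-transformed and a sparse graph is
estimated either by penalized inverse-covariance estimation (glasso) or by
node-wise L1 neighborhood selection (MB).  Sparsity is chosen by stability
selection under subsampling (StARS): the densest graph whose edge set is
reproducible across subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path


def graphical_lasso(emp_cov, alpha, **kw):
    """sklearn glasso with near-convergence warnings silenced.

    At the smallest grid penalties the CLR covariance is close to singular
    and the duality gap stalls at ~1e-3; the support is unaffected, so the
    warning is noise for the stability loop.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return _graphical_lasso(emp_cov, alpha, **kw)

from .tree import CompositionMatrix
from .logratios import clr_matrix

__all__ = [
    "ConditionalNetwork",
    "clr_transform",
    "fit_glasso",
    "fit_mb",
    "select_sparsity_stars",
    "default_penalty_grid",
]

_EDGE_EPS = 1e-8


def clr_transform(comp: CompositionMatrix | pd.DataFrame) -> pd.DataFrame:
    """CLR coordinates as a DataFrame; each row sums to zero."""
    df = comp.proportions if isinstance(comp, CompositionMatrix) else comp
    z = clr_matrix(comp)
    return pd.DataFrame(z, index=df.index, columns=df.columns)


@dataclass
class ConditionalNetwork:
    """Signed, weighted conditional-dependence graph over the leaf subsets."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: i, j, sign, weight
    method: str  # "glasso" | "mb"
    penalty: float
    precision: np.ndarray | None = None  # glasso only
    stability_path: pd.DataFrame | None = None

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in zip(self.edges["i"], self.edges["j"])}

    def signed_edges(self) -> dict[tuple[str, str], int]:
        return {
            tuple(sorted((a, b))): int(s)
            for a, b, s in zip(self.edges["i"], self.edges["j"], self.edges["sign"])
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["i"], row["j"], sign=int(row["sign"]), weight=float(row["weight"]))
        return g


def _edges_frame(nodes, rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["i", "j", "sign", "weight"])


def fit_glasso(z: pd.DataFrame, penalty: float, ridge: float = 1e-6) -> ConditionalNetwork:
    """Sparse precision estimate of the CLR data at an L1 penalty.

    The edge (i, j) is present iff the precision entry is non-zero; its sign
    is that of the partial correlation −Θ_ij/√(Θ_ii·Θ_jj), which is also the
    reported weight.  Because the CLR covariance is singular (rank ≤ D−1) a
    small diagonal ridge (``ridge`` × mean variance) is added when the
    penalty is zero; positive penalties need none.
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    x = z.to_numpy(dtype=float)
    emp = np.cov(x, rowvar=False)
    if penalty == 0:
        emp = emp + ridge * np.mean(np.diag(emp)) * np.eye(emp.shape[0])
    try:
        _, prec = graphical_lasso(emp, alpha=max(penalty, 1e-12), max_iter=200)
    except FloatingPointError as err:  # pragma: no cover - solver diagnostics
        raise RuntimeError(f"glasso failed to converge at penalty {penalty}: {err}")
    nodes = list(z.columns)
    rows = []
    d = np.sqrt(np.diag(prec))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if abs(prec[i, j]) > _EDGE_EPS:
                pcor = -prec[i, j] / (d[i] * d[j])
                rows.append((nodes[i], nodes[j], int(np.sign(pcor)), float(pcor)))
    return ConditionalNetwork(
        nodes=nodes, edges=_edges_frame(nodes, rows), method="glasso",
        penalty=float(penalty), precision=prec,
    )


def _mb_coef_matrix(x: np.ndarray, penalties: np.ndarray) -> np.ndarray:
    """Node-wise lasso coefficients for every penalty.

    Returns an array of shape (len(penalties), p, p): entry [a, k, j] is the
    coefficient of column j in the regression of column k at penalty a
    (diagonal zero).  Uses a shared descending path per node.
    """
    n, p = x.shape
    xc = x - x.mean(axis=0, keepdims=True)
    order = np.argsort(penalties)[::-1]  # lasso_path wants descending
    out = np.zeros((len(penalties), p, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(p):
            others = [j for j in range(p) if j != k]
            _, coefs, _ = lasso_path(xc[:, others], xc[:, k], alphas=penalties[order])
            for a_pos, a_idx in enumerate(order):
                out[a_idx, k, others] = coefs[:, a_pos]
    return out


def fit_mb(z: pd.DataFrame, penalty: float, rule: str = "or") -> ConditionalNetwork:
    """Neighborhood-selection (MB) graph at an L1 penalty.

    Each CLR column is lasso-regressed on all others; with the OR rule an
    edge appears when either direction selects it (AND requires both).  The
    weight is the mean of the two directed coefficients and the sign comes
    from that mean.
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    x = z.to_numpy(dtype=float)
    coefs = _mb_coef_matrix(x, np.array([penalty]))[0]
    nodes = list(z.columns)
    rows = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = coefs[i, j], coefs[j, i]
            hit_a, hit_b = abs(a) > _EDGE_EPS, abs(b) > _EDGE_EPS
            present = (hit_a or hit_b) if rule == "or" else (hit_a and hit_b)
            if present:
                w = 0.5 * (a + b)
                if w == 0:  # opposite-signed, equal-magnitude: keep larger |.|
                    w = a if abs(a) >= abs(b) else b
                rows.append((nodes[i], nodes[j], int(np.sign(w)), float(w)))
    return ConditionalNetwork(
        nodes=nodes, edges=_edges_frame(nodes, rows), method="mb", penalty=float(penalty)
    )


def default_penalty_grid(z: pd.DataFrame, n_penalties: int = 30, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalties from the empty-graph level down (descending)."""
    x = z.to_numpy(dtype=float)
    emp = np.cov(x, rowvar=False)
    off = emp - np.diag(np.diag(emp))
    lam_max = float(np.abs(off).max())
    return np.geomspace(lam_max, lam_max * ratio, n_penalties)


def _adjacency(x: np.ndarray, penalty_grid: np.ndarray, method: str) -> np.ndarray:
    """Boolean adjacency (grid × p × p upper triangle flattened) per penalty."""
    p = x.shape[1]
    iu = np.triu_indices(p, 1)
    out = np.zeros((len(penalty_grid), len(iu[0])), dtype=bool)
    if method == "glasso":
        emp = np.cov(x, rowvar=False)
        for a, lam in enumerate(penalty_grid):
            try:
                _, prec = graphical_lasso(emp, alpha=lam, max_iter=200)
            except FloatingPointError:
                continue
            out[a] = np.abs(prec[iu]) > _EDGE_EPS
    elif method == "mb":
        coefs = _mb_coef_matrix(x, penalty_grid)
        sel = np.abs(coefs) > _EDGE_EPS
        sym = sel | np.transpose(sel, (0, 2, 1))  # OR rule
        out = sym[:, iu[0], iu[1]]
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def select_sparsity_stars(
    z: pd.DataFrame,
    method: str = "glasso",
    grid: np.ndarray | None = None,
    n_subsamples: int = 50,
    threshold: float = 0.05,
    seed: int | None = 0,
) -> tuple[float, pd.DataFrame]:
    """Stability-based (StARS) penalty selection.

    For each penalty, the graph is refit on ``n_subsamples`` subsamples
    (without replacement, size min(⌊10√n⌋, ⌊0.8n⌋)) and per-edge selection
    frequencies ξ give the mean edge instability 2ξ(1−ξ).  After monotonizing
    the instability curve (running max as the penalty decreases), the
    smallest penalty keeping instability ≤ ``threshold`` is returned — the
    densest stable graph.  If no penalty is stable, the largest grid penalty
    is returned with a warning flag in the path.

    Returns (selected penalty, stability path DataFrame).
    """
    x = z.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 50:
        raise ValueError("StARS needs n >= 50")
    grid = default_penalty_grid(z) if grid is None else np.sort(np.asarray(grid))[::-1]
    if len(grid) < 10:
        raise ValueError("penalty grid should have at least 10 values")
    m = min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n)))
    rng = np.random.default_rng(seed)
    p = x.shape[1]
    n_edges = p * (p - 1) // 2
    freq = np.zeros((len(grid), n_edges))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        freq += _adjacency(x[idx], grid, method)
    xi = freq / n_subsamples
    instability = (2 * xi * (1 - xi)).mean(axis=1)
    mono = np.maximum.accumulate(instability)  # nondecreasing as penalty shrinks
    stable = mono <= threshold
    path = pd.DataFrame(
        {
            "penalty": grid,
            "instability": instability,
            "monotonized": mono,
            "stable": stable,
        }
    )
    if stable.any():
        sel = float(grid[np.where(stable)[0].max()])  # smallest stable penalty
    else:
        import warnings

        warnings.warn("no penalty met the stability threshold; returning grid max")
        sel = float(grid[0])
    return sel, path


def infer_network(
    comp: CompositionMatrix,
    method: str = "glasso",
    penalty: float | None = None,
    stars_kwargs: dict | None = None,
) -> ConditionalNetwork:
    """CLR-transform, select sparsity by StARS if needed, and fit the graph."""
    z = clr_transform(comp)
    path = None
    if penalty is None:
        penalty, path = select_sparsity_stars(z, method=method, **(stars_kwargs or {}))
    net = fit_glasso(z, penalty) if method == "glasso" else fit_mb(z, penalty)
    net.stability_path = path
    return net
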