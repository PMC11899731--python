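"""Hierarchical T/B-subset tree and percentage→composition conversion.

Flow-cytometry panels report each lymphocyte subset as a percentage of its
*parent* population (T cells as % of lymphocytes, naïve CD4+ as % of CD4+,
and so on).  Those percentages use different denominators, so they cannot be
analysed jointly as a composition.  This module encodes the four-level
hierarchy of the measured subsets, completes every internal node with a
derived "other" child (the mass its measured children do not account for),
validates per-subject panels, and multiplies relative proportions down each
root→leaf path to obtain a 16-part composition on the simplex — the
proportion of every terminal subset relative to total lymphocytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "CompositionTree",
    "CompositionMatrix",
    "LEAVES",
    "MEASURED_NODES",
    "build_tree",
    "default_tree",
    "derive_other",
    "validate_subjects",
    "to_composition",
    "replace_zeros",
    "read_panel_csv",
]

#: Canonical ordering of the 16 terminal subsets (leaves).  All downstream
#: matrices, pair indices and outputs follow this order.
LEAVES = [
    "TCD4N", "TCD4CM", "TCD4EM", "TCD4TDEM", "TCD4O",
    "TCD8N", "TCD8CM", "TCD8EM", "TCD8TDEM", "TCD8O",
    "TO",
    "BN", "BMIgD-", "BMIgD+", "BO",
    "LYMPO",
]

#: The 15 measured nodes (name, parent) as reported by the panel; the root
#: is the total live-lymphocyte gate.
MEASURED_NODES = [
    ("T", "root"),
    ("TCD4", "T"),
    ("TCD4N", "TCD4"),
    ("TCD4CM", "TCD4"),
    ("TCD4EM", "TCD4"),
    ("TCD4TDEM", "TCD4"),
    ("TCD8", "T"),
    ("TCD8N", "TCD8"),
    ("TCD8CM", "TCD8"),
    ("TCD8EM", "TCD8"),
    ("TCD8TDEM", "TCD8"),
    ("B", "root"),
    ("BN", "B"),
    ("BMIgD-", "B"),
    ("BMIgD+", "B"),
]

# Common aliases seen in panel exports ("TCD4+" style suffixes).
_COLUMN_ALIASES = {"TCD4+": "TCD4", "TCD8+": "TCD8", "T+": "T", "B+": "B"}

# Name given to the derived complement child of each internal node.
_OTHER_NAMES = {"root": "LYMPO", "T": "TO", "TCD4": "TCD4O", "TCD8": "TCD8O", "B": "BO"}


@dataclass(frozen=True)
class TreeNode:
    name: str
    parent: str | None  # None only for the root
    derived: bool = False  # True for complement ("other") nodes


@dataclass
class CompositionTree:
    """The subset hierarchy: measured nodes plus derived complements."""

    nodes: dict[str, TreeNode]
    leaves: list[str]

    def children(self, name: str) -> list[str]:
        return [n.name for n in self.nodes.values() if n.parent == name]

    def internal_nodes(self) -> list[str]:
        childful = {n.parent for n in self.nodes.values() if n.parent is not None}
        return [n for n in self.nodes if n in childful]

    def measured_children(self, name: str) -> list[str]:
        return [c for c in self.children(name) if not self.nodes[c].derived]

    def path_to_root(self, name: str) -> list[str]:
        """Node names from ``name`` up to (excluding) the root."""
        path = []
        cur = name
        while cur != "root":
            path.append(cur)
            cur = self.nodes[cur].parent
        return path

    def depth(self, name: str) -> int:
        return len(self.path_to_root(name))

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"name": n.name, "parent": n.parent, "derived": n.derived}
                    for n in self.nodes.values()
                ],
                "leaves": self.leaves,
            },
            indent=2,
        )


def build_tree(measured: list[tuple[str, str]] | None = None) -> CompositionTree:
    """Build the hierarchy from measured (name, parent) links.

    Every internal node (including the root) receives exactly one derived
    complement child holding the mass its measured children do not cover.

    Raises
    ------
    ValueError
        on duplicate node names or a node whose parent is not part of the
        tree (no path to the root).
    """
    if measured is None:
        measured = MEASURED_NODES
    names = [m[0] for m in measured]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate node names: {dupes}")
    nodes: dict[str, TreeNode] = {"root": TreeNode("root", None, derived=False)}
    if "root" in names:
        raise ValueError("'root' is reserved for the total-lymphocyte gate")
    for name, parent in measured:
        nodes[name] = TreeNode(name, parent, derived=False)
    # connectivity: every node must reach the root through declared parents
    for name, parent in measured:
        seen = set()
        cur = parent
        while cur != "root":
            if cur not in nodes or cur in seen:
                raise ValueError(f"node {name!r}: parent path broken at {cur!r}")
            seen.add(cur)
            cur = nodes[cur].parent
    # insert one derived "other" child under every internal node
    internal = ["root"] + sorted(
        {p for _, p in measured if p != "root"},
        key=lambda n: [m[0] for m in measured].index(n),
    )
    for node in internal:
        other = _OTHER_NAMES.get(node, node + "O")
        if other in nodes:
            raise ValueError(f"derived name {other!r} collides with a measured node")
        nodes[other] = TreeNode(other, node, derived=True)
    childful = {n.parent for n in nodes.values() if n.parent is not None}
    leaves = [n for n in nodes if n not in childful]
    # order canonically where possible, otherwise keep insertion order
    if set(leaves) == set(LEAVES):
        leaves = list(LEAVES)
    return CompositionTree(nodes=nodes, leaves=leaves)


def default_tree() -> CompositionTree:
    """The canonical 21-node, 16-leaf T/B-subset tree."""
    return build_tree(MEASURED_NODES)


@dataclass
class CompositionMatrix:
    """n × D leaf proportions on the simplex (rows sum to 1).

    ``zero_replaced`` flags cells whose exact-zero value was substituted by
    the smallest positive value of that leaf column (detection-limit style
    replacement); ``None`` until :func:`replace_zeros` has run.
    """

    proportions: pd.DataFrame
    zero_replaced: pd.DataFrame | None = None

    @property
    def leaves(self) -> list[str]:
        return list(self.proportions.columns)

    @property
    def values(self) -> np.ndarray:
        return self.proportions.to_numpy(dtype=float)

    def copy(self) -> "CompositionMatrix":
        return CompositionMatrix(
            self.proportions.copy(),
            None if self.zero_replaced is None else self.zero_replaced.copy(),
        )


def _measured_columns(tree: CompositionTree) -> list[str]:
    return [n.name for n in tree.nodes.values() if not n.derived and n.name != "root"]


def read_panel_csv(path, tree: CompositionTree | None = None) -> pd.DataFrame:
    """Read a percentage panel CSV (subject_id + measured columns, 0–100)."""
    tree = tree or default_tree()
    df = pd.read_csv(path)
    df = df.rename(columns=_COLUMN_ALIASES)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    missing = [c for c in _measured_columns(tree) if c not in df.columns]
    if missing:
        raise ValueError(f"panel is missing measured columns: {missing}")
    return df[_measured_columns(tree)].astype(float)


def validate_subjects(
    panel: pd.DataFrame,
    tree: CompositionTree | None = None,
    tol: float = 1e-9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude malformed subjects; return (kept panel, exclusion log).

    Exclusion reasons, applied in order per subject:

    ``missing``
        any measured percentage absent;
    ``out_of_range``
        a value outside [0, 100];
    ``oversum``
        the measured children of some node summing beyond 100 (tolerance
        ``tol`` on the 0–100 scale).  Sums of exactly 100 are valid and give
        a zero "other" part.
    """
    tree = tree or default_tree()
    cols = [c for c in _measured_columns(tree) if c in panel.columns]
    sub = panel[cols]
    reasons = pd.Series(index=panel.index, dtype=object)

    miss = sub.isna().any(axis=1)
    reasons[miss] = "missing"

    vals = sub.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        oor = ((vals < 0) | (vals > 100)).any(axis=1)
    reasons[oor & ~miss] = "out_of_range"

    over = np.zeros(len(sub), dtype=bool)
    for node in tree.internal_nodes():
        kids = [c for c in tree.measured_children(node) if c in sub.columns]
        if kids:
            over |= sub[kids].sum(axis=1).to_numpy() > 100.0 + tol
    reasons[over & ~miss & ~oor] = "oversum"

    excluded = reasons.dropna()
    log = pd.DataFrame({"subject_id": excluded.index, "reason": excluded.values})
    kept = panel.loc[reasons.isna()]
    if len(panel) and not len(kept):
        raise ValueError("all subjects excluded; input unusable")
    return kept, log


def derive_other(panel: pd.DataFrame, tree: CompositionTree | None = None) -> pd.DataFrame:
    """Append the five complement ("other") columns.

    For each internal node the complement is 100 minus the sum of its
    measured children, on that node's relative (percent-of-parent) scale.
    Assumes the panel has passed :func:`validate_subjects`.
    """
    tree = tree or default_tree()
    out = panel.copy()
    for node in tree.internal_nodes():
        kids = tree.measured_children(node)
        other = [c for c in tree.children(node) if tree.nodes[c].derived]
        if not other:
            continue
        val = 100.0 - out[kids].sum(axis=1)
        # clip float fuzz only; true oversums were excluded upstream.  Values
        # within the closure tolerance of zero are snapped to exact 0 so that
        # subtraction noise is not mistaken for a tiny positive part.
        val = val.clip(lower=0.0)
        val[val < 1e-9] = 0.0
        out[other[0]] = val
    return out


def to_composition(panel: pd.DataFrame, tree: CompositionTree | None = None) -> CompositionMatrix:
    """Convert the extended panel to leaf proportions of total lymphocytes.

    Each leaf's proportion is the product of relative proportions (value/100)
    along its root→leaf path, so all 16 leaves share the same denominator and
    each row closes to 1.
    """
    tree = tree or default_tree()
    n = len(panel)
    comp = pd.DataFrame(index=panel.index, columns=tree.leaves, dtype=float)
    for leaf in tree.leaves:
        prod = np.ones(n)
        for node in tree.path_to_root(leaf):
            prod = prod * panel[node].to_numpy(dtype=float) / 100.0
        if (prod < 0).any():
            raise ValueError(f"negative intermediate proportion on path to {leaf}")
        comp[leaf] = prod
    sums = comp.sum(axis=1).to_numpy()
    if not np.allclose(sums, 1.0, atol=1e-9):
        bad = comp.index[np.abs(sums - 1.0) > 1e-9][:5].tolist()
        raise ValueError(f"rows do not close to 1 (first offenders: {bad})")
    return CompositionMatrix(proportions=comp)


def replace_zeros(
    comp: CompositionMatrix,
    renormalize: bool = False,
) -> CompositionMatrix:
    """Substitute exact zeros by the smallest positive value of their column.

    Mirrors the detection-limit convention for compositional zeros: a zero
    reading for a given cell type is replaced by the smallest non-zero value
    observed for that same cell type across the dataset.  By default the rows
    are left un-reclosed (the perturbation is tiny relative to the parts);
    pass ``renormalize=True`` to re-close rows to 1 afterwards.
    """
    x = comp.proportions.to_numpy(dtype=float).copy()
    flags = x == 0.0
    if flags.any():
        for j in range(x.shape[1]):
            col = x[:, j]
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError(
                    f"column {comp.proportions.columns[j]!r} is entirely zero"
                )
            col[col == 0.0] = pos.min()
    if renormalize:
        x = x / x.sum(axis=1, keepdims=True)
    props = pd.DataFrame(x, index=comp.proportions.index, columns=comp.proportions.columns)
    zr = pd.DataFrame(flags, index=props.index, columns=props.columns)
    return CompositionMatrix(proportions=props, zero_replaced=zr)
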