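"""CART regression tree on model-predicted median survival.

The tree translates the (otherwise opaque) survival ensemble into a small
set of recipient-donor rules: every patient's median survival is
pre-computed with the survival model — with the transplant era fixed to the
latest era, so the rules read as current-practice expectations — and a
binary regression tree is grown on those predictions by greedy
within-node sum-of-squares minimization.  Continuous features split at
observed midpoints; categorical features (up to 10 levels) are searched
over all level subsets.  Weakest-link cost-complexity pruning with the
per-split error reduction normalized by the root sum of squares trims the
tree; variable importance is the fraction of root variability accounted
for by each variable's splits.

Node ids use heap numbering (root 1, children 2i / 2i+1), so leaf labels
are stable under pruning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import kaplan_meier, log_rank
from .registry import Cohort, ERA_LEVELS, SCHEMA_BY_NAME

__all__ = [
    "DEFAULT_TREE_FEATURES",
    "TreeNode",
    "SurvivalTree",
    "fit_tree",
    "prune_tree",
    "importance",
    "validate_leaves",
    "adjust_to_latest_era",
    "tree_to_dict",
    "tree_to_dot",
]

#: Recipient/donor variables offered to the tree.  Era is excluded: targets
#: are era-adjusted before fitting, so it is constant by construction.
DEFAULT_TREE_FEATURES: tuple[str, ...] = (
    "recipient_age",
    "recipient_sex",
    "recipient_height",
    "recipient_weight",
    "diagnosis",
    "diabetes",
    "hypertension",
    "infection_2wk",
    "prior_transplant",
    "prior_cardiac_surgery",
    "icu",
    "ventilator",
    "ecmo",
    "vad",
    "creatinine",
    "bilirubin",
    "recipient_bg",
    "donor_age",
    "donor_sex",
    "donor_weight",
    "ischemia_min",
    "codd_head_trauma",
    "codd_cva",
    "donor_bg",
)


@dataclass
class TreeNode:
    node_id: int
    n: int
    mean: float
    sd: float
    sse: float
    variable: str | None = None
    kind: str | None = None  # 'continuous' | 'categorical'
    threshold: float | None = None
    left_levels: frozenset | None = None
    reduction: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_leaf(self) -> None:
        self.left = self.right = None
        self.variable = self.kind = self.threshold = self.left_levels = None
        self.reduction = 0.0


@dataclass
class SurvivalTree:
    root: TreeNode
    features: tuple[str, ...]
    root_sst: float
    n: int
    cc_alpha: float = 0.0

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def route(self, features: pd.DataFrame) -> np.ndarray:
        """Leaf node id for every row."""
        n = len(features)
        out = np.empty(n, dtype=int)

        def walk(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.node_id
                return
            col = features[node.variable].iloc[idx] if False else features[node.variable].to_numpy()[idx]
            if node.kind == "continuous":
                go_left = col.astype(float) < node.threshold
            else:
                go_left = np.isin(col, list(node.left_levels))
            walk(node.left, idx[go_left])
            walk(node.right, idx[~go_left])

        walk(self.root, np.arange(n))
        return out

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Leaf training-target mean per routed record."""
        ids = self.route(features)
        means = {leaf.node_id: leaf.mean for leaf in self.leaves()}
        return np.array([means[i] for i in ids])


def _best_continuous_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    csum = np.cumsum(ys)
    total = csum[-1]
    csq = np.cumsum(ys**2)
    # candidate cuts between distinct consecutive values
    nl = np.arange(1, n)
    valid = (xs[1:] != xs[:-1]) & (nl >= min_leaf) & (n - nl >= min_leaf)
    if not valid.any():
        return None
    left_sum = csum[:-1]
    nr = n - nl
    red = left_sum**2 / nl + (total - left_sum) ** 2 / nr - total**2 / n
    red = np.where(valid, red, -np.inf)
    j = int(np.argmax(red))
    threshold = 0.5 * (xs[j] + xs[j + 1])
    return float(red[j]), ("continuous", threshold, None)


def _best_categorical_split(codes: np.ndarray, levels: list, y: np.ndarray, min_leaf: int):
    L = len(levels)
    counts = np.bincount(codes, minlength=L).astype(float)
    sums = np.bincount(codes, weights=y, minlength=L)
    present = np.flatnonzero(counts > 0)
    if len(present) < 2:
        return None
    total_n, total_sum = counts.sum(), sums.sum()
    if len(present) > 10:
        # mean-ordering shortcut for wide categoricals
        order = present[np.argsort(sums[present] / counts[present])]
        best = None
        for cut in range(1, len(order)):
            S = order[:cut]
            nl, sl = counts[S].sum(), sums[S].sum()
            nr = total_n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            red = sl**2 / nl + (total_sum - sl) ** 2 / nr - total_sum**2 / total_n
            if best is None or red > best[0]:
                best = (red, frozenset(levels[i] for i in S))
        if best is None:
            return None
        return float(best[0]), ("categorical", None, best[1])
    # exhaustive subsets containing the first present level (mirror-free)
    anchor = present[0]
    others = present[1:]
    best = None
    for mask in range(1 << len(others)):
        S = [anchor] + [others[i] for i in range(len(others)) if mask >> i & 1]
        nl, sl = counts[S].sum(), sums[S].sum()
        nr = total_n - nl
        if nl < min_leaf or nr < min_leaf:
            continue
        red = sl**2 / nl + (total_sum - sl) ** 2 / nr - total_sum**2 / total_n
        if best is None or red > best[0]:
            best = (red, frozenset(levels[i] for i in S))
    if best is None:
        return None
    return float(best[0]), ("categorical", None, best[1])


def fit_tree(
    features: pd.DataFrame,
    target: np.ndarray,
    min_leaf: int = 50,
    feature_names: Sequence[str] | None = None,
) -> SurvivalTree:
    """Grow a regression tree on (complete) features and a finite target.

    Greedy binary recursive partitioning minimizing within-node SSE; a node
    smaller than 2 * min_leaf, or with no strictly improving split, becomes
    a leaf.  ``min_leaf >= n`` yields a single-leaf tree.
    """
    y = np.asarray(target, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("tree targets must be finite")
    names = tuple(feature_names) if feature_names is not None else tuple(features.columns)
    feats = features[list(names)]
    if feats.isna().any().any():
        raise ValueError("tree features must be complete")
    n = len(y)

    cont: dict[str, np.ndarray] = {}
    cat: dict[str, tuple[np.ndarray, list]] = {}
    for name in names:
        col = feats[name]
        if col.dtype == object:
            levels = sorted(map(str, pd.unique(col.astype(str))))
            lut = {lv: i for i, lv in enumerate(levels)}
            cat[name] = (col.astype(str).map(lut).to_numpy(int), levels)
        else:
            cont[name] = col.to_numpy(float)

    counter = {"next": 1}

    def grow(idx: np.ndarray, node_id: int) -> TreeNode:
        yy = y[idx]
        mean = float(yy.mean())
        sse = float(((yy - mean) ** 2).sum())
        node = TreeNode(
            node_id=node_id, n=len(idx), mean=mean,
            sd=float(yy.std(ddof=1)) if len(idx) > 1 else 0.0, sse=sse,
        )
        if len(idx) < 2 * min_leaf or sse <= 0:
            return node
        best = None
        for name in names:
            if name in cont:
                res = _best_continuous_split(cont[name][idx], yy, min_leaf)
            else:
                codes, levels = cat[name]
                res = _best_categorical_split(codes[idx], levels, yy, min_leaf)
            if res is None:
                continue
            red, spec = res
            if red > 1e-12 and (best is None or red > best[0]):
                best = (red, name, spec)
        if best is None:
            return node
        red, name, (kind, threshold, left_levels) = best
        if kind == "continuous":
            go_left = cont[name][idx] < threshold
        else:
            codes, levels = cat[name]
            lset = {levels.index(lv) for lv in left_levels}
            go_left = np.isin(codes[idx], list(lset))
        node.variable = name
        node.kind = kind
        node.threshold = threshold
        node.left_levels = left_levels
        node.reduction = float(red)
        node.left = grow(idx[go_left], 2 * node_id)
        node.right = grow(idx[~go_left], 2 * node_id + 1)
        return node

    root = grow(np.arange(n), 1)
    grand_mean = y.mean()
    sst = float(((y - grand_mean) ** 2).sum())
    return SurvivalTree(root=root, features=names, root_sst=sst, n=n)


def _subtree_stats(node: TreeNode) -> tuple[float, int]:
    """(sum of leaf SSEs, leaf count) of the subtree rooted at node."""
    if node.is_leaf:
        return node.sse, 1
    sl, cl = _subtree_stats(node.left)
    sr, cr = _subtree_stats(node.right)
    return sl + sr, cl + cr


def prune_tree(tree: SurvivalTree, cc_alpha: float = 0.0035) -> SurvivalTree:
    """Weakest-link cost-complexity pruning.

    A subtree is collapsed while its per-split error reduction, normalized
    by the root total sum of squares, falls below ``cc_alpha``;
    ``cc_alpha = 0`` returns the tree unchanged.  The pruned tree's leaves
    are a coarsening of the original's.
    """
    if cc_alpha < 0:
        raise ValueError("cc_alpha must be >= 0")
    import copy

    out = copy.deepcopy(tree)
    out.cc_alpha = cc_alpha
    if cc_alpha == 0:
        return out
    sst = out.root_sst if out.root_sst > 0 else 1.0
    while True:
        internals = out.internal_nodes()
        if not internals:
            break
        g = []
        for node in internals:
            leaf_sse, leaves = _subtree_stats(node)
            g.append((node.sse - leaf_sse) / max(leaves - 1, 1) / sst)
        weakest = int(np.argmin(g))
        if g[weakest] >= cc_alpha:
            break
        internals[weakest].to_leaf()
    return out


def importance(tree: SurvivalTree) -> dict[str, float]:
    """Proportion of root variability accounted for by each variable's
    splits (fractions; a root-only tree gives an empty map)."""
    sst = tree.root_sst if tree.root_sst > 0 else 1.0
    out: dict[str, float] = {}
    for node in tree.internal_nodes():
        out[node.variable] = out.get(node.variable, 0.0) + node.reduction / sst
    return dict(sorted(out.items(), key=lambda kv: -kv[1]))


def tree_to_dict(tree: SurvivalTree) -> dict:
    """Versioned JSON-ready representation of a fitted tree."""

    def node_dict(node: TreeNode) -> dict:
        d = {
            "id": node.node_id,
            "n": node.n,
            "median_years": node.mean,
            "sd_years": node.sd,
        }
        if not node.is_leaf:
            d.update(
                variable=node.variable,
                kind=node.kind,
                threshold=node.threshold,
                left_levels=sorted(map(str, node.left_levels)) if node.left_levels else None,
                reduction=node.reduction,
                left=node_dict(node.left),
                right=node_dict(node.right),
            )
        return d

    return {
        "format": "ihtsa-tree",
        "version": 1,
        "n": tree.n,
        "root_sst": tree.root_sst,
        "cc_alpha": tree.cc_alpha,
        "features": list(tree.features),
        "importance": importance(tree),
        "root": node_dict(tree.root),
    }


def tree_to_dot(tree: SurvivalTree) -> str:
    """Graphviz description of the tree for rendering."""
    lines = ["digraph survival_tree {", "  node [shape=box];"]

    def walk(node: TreeNode) -> None:
        label = f"{node.mean:.1f}y (SD {node.sd:.1f})\\nn={node.n}"
        color = "salmon" if node.is_leaf else "lightblue"
        lines.append(f'  n{node.node_id} [label="{label}", style=filled, fillcolor={color}];')
        if node.is_leaf:
            return
        if node.kind == "continuous":
            cond = f"{node.variable} < {node.threshold:.3g}"
        else:
            cond = f"{node.variable} in {{{', '.join(sorted(map(str, node.left_levels)))}}}"
        lines.append(f'  n{node.node_id} -> n{node.left.node_id} [label="{cond}", style=dotted];')
        lines.append(f'  n{node.node_id} -> n{node.right.node_id} [label="else", style=dotted];')
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)


def adjust_to_latest_era(cohort: Cohort) -> Cohort:
    """Copy of the cohort with every transplant assigned to the latest era,
    so predicted survival reads on the current-practice scale."""
    out = cohort.copy()
    out.df["era"] = ERA_LEVELS[-1]
    return out


def validate_leaves(
    tree: SurvivalTree,
    cohort_dc: Cohort,
    cohort_ivc: Cohort,
    leaf_ids: Sequence[int] | None = None,
) -> dict[int, dict]:
    """Observed Kaplan-Meier per leaf per cohort plus a derivation-vs-
    validation log-rank p within each leaf.  Leaves empty in either cohort
    are skipped with a warning."""
    wanted = set(leaf_ids) if leaf_ids is not None else {l.node_id for l in tree.leaves()}
    out: dict[int, dict] = {}
    route_dc = tree.route(cohort_dc.df)
    route_ivc = tree.route(cohort_ivc.df)
    t_dc = cohort_dc.df["followup_years"].to_numpy(float)
    d_dc = cohort_dc.df["death"].to_numpy(float)
    t_iv = cohort_ivc.df["followup_years"].to_numpy(float)
    d_iv = cohort_ivc.df["death"].to_numpy(float)
    for leaf in tree.leaves():
        if leaf.node_id not in wanted:
            continue
        sel_dc = route_dc == leaf.node_id
        sel_iv = route_ivc == leaf.node_id
        if not sel_dc.any() or not sel_iv.any():
            warnings.warn(f"leaf {leaf.node_id}: empty in one cohort, skipped", stacklevel=2)
            continue
        chi2, p = log_rank(t_dc[sel_dc], d_dc[sel_dc], t_iv[sel_iv], d_iv[sel_iv])
        out[leaf.node_id] = {
            "predicted_median": leaf.mean,
            "n_dc": int(sel_dc.sum()),
            "n_ivc": int(sel_iv.sum()),
            "km_dc": kaplan_meier(t_dc[sel_dc], d_dc[sel_dc]),
            "km_ivc": kaplan_meier(t_iv[sel_iv], d_iv[sel_iv]),
            "log_rank_chi2": chi2,
            "log_rank_p": p,
        }
    return out
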