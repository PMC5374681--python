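"""Binary classification trees (CART, Gini impurity) over the filter
annotations, with explicit per-node true/false-variant counts.

The tree is deliberately small and fully deterministic: candidate
thresholds are midpoints between consecutive distinct sorted feature
values, the split maximizing the Gini impurity decrease wins, and ties
break by feature-list order then by smaller threshold.  Left children
take ``feature < threshold``, right children ``feature >= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import FEATURE_NAMES

_TIE_EPS = 1e-12


class ModelError(ValueError):
    """Raised on invalid tree-fitting input."""


@dataclass(frozen=True)
class TreeParams:
    max_depth: int = 4
    min_node_size: int = 20
    min_gini_gain: float = 1e-4


@dataclass
class DecisionTreeNode:
    node_id: int
    depth: int
    n_tv: int
    n_fv: int
    feature: str | None = None  # None for leaves
    threshold: float | None = None
    parent: "DecisionTreeNode | None" = field(default=None, repr=False)
    left: "DecisionTreeNode | None" = None  # feature < threshold
    right: "DecisionTreeNode | None" = None  # feature >= threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return self.n_tv + self.n_fv

    def children(self) -> list["DecisionTreeNode"]:
        return [c for c in (self.left, self.right) if c is not None]

    def descendants(self) -> list["DecisionTreeNode"]:
        out = []
        stack = self.children()
        while stack:
            node = stack.pop(0)
            out.append(node)
            stack = node.children() + stack
        return out

    def path_conditions(self) -> list[tuple[str, str, float]]:
        """Split conditions on the root -> this-node path, in path order."""
        conds: list[tuple[str, str, float]] = []
        node = self
        while node.parent is not None:
            p = node.parent
            op = "<" if node is p.left else ">="
            conds.append((p.feature, op, p.threshold))
            node = p
        conds.reverse()
        return conds


def _gini(n_tv: int, n_fv: int) -> float:
    n = n_tv + n_fv
    if n == 0:
        return 0.0
    p = n_tv / n
    return 2.0 * p * (1.0 - p)


def best_split(
    X: np.ndarray, y: np.ndarray, feature_names
) -> tuple[int, float, float] | None:
    """Exhaustively score every (feature, midpoint threshold) pair and
    return (feature index, threshold, gini gain) for the best one, or
    None when no split separates anything.

    Ties within 1e-12 resolve to the earlier feature, then the smaller
    threshold; this function is also the reference used by the oracle
    tests, so its scan order is part of the contract.
    """
    n = len(y)
    n_tv_all = int(y.sum())
    parent_gini = _gini(n_tv_all, n - n_tv_all)
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        values = X[:, f]
        order = np.argsort(values, kind="stable")
        sv = values[order]
        sy = y[order]
        distinct = np.flatnonzero(np.diff(sv) > 0)
        if distinct.size == 0:
            continue
        cum_tv = np.cumsum(sy)
        for i in distinct:
            thr = (sv[i] + sv[i + 1]) / 2.0
            nl = i + 1
            nl_tv = int(cum_tv[i])
            nr = n - nl
            nr_tv = n_tv_all - nl_tv
            gain = (
                parent_gini
                - nl / n * _gini(nl_tv, nl - nl_tv)
                - nr / n * _gini(nr_tv, nr - nr_tv)
            )
            if best is None or gain > best[2] + _TIE_EPS:
                best = (f, float(thr), float(gain))
    return best


def fit_tree(
    data: pd.DataFrame,
    features=FEATURE_NAMES,
    params: TreeParams | None = None,
    label_column: str = "label",
) -> DecisionTreeNode:
    """Fit a CART on a labeled-call table.

    ``data`` must carry the feature columns and a label column with
    values "TV"/"FV".  Missing feature values are imputed to the column
    median (of this stratum) before fitting.
    """
    params = params or TreeParams()
    if len(data) == 0:
        raise ModelError("cannot fit a tree on an empty call set")
    features = list(features)
    X = data[features].to_numpy(dtype=float, copy=True)
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = np.isnan(col)
        if bad.any():
            med = np.nanmedian(col) if not bad.all() else 0.0
            col[bad] = med
    y = (data[label_column].to_numpy() == "TV")

    counter = [0]

    def build(idx: np.ndarray, depth: int, parent) -> DecisionTreeNode:
        n_tv = int(y[idx].sum())
        n_fv = int(idx.size - n_tv)
        node = DecisionTreeNode(
            node_id=counter[0], depth=depth, n_tv=n_tv, n_fv=n_fv, parent=parent
        )
        counter[0] += 1
        if (
            depth >= params.max_depth
            or idx.size < params.min_node_size
            or n_tv == 0
            or n_fv == 0
        ):
            return node
        found = best_split(X[idx], y[idx], features)
        if found is None or found[2] < params.min_gini_gain:
            return node
        f, thr, _ = found
        node.feature = features[f]
        node.threshold = thr
        left_mask = X[idx, f] < thr
        node.left = build(idx[left_mask], depth + 1, node)
        node.right = build(idx[~left_mask], depth + 1, node)
        return node

    return build(np.arange(len(y)), 0, None)
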