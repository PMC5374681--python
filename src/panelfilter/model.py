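"""Model/results interface for hard-filter tuning.

:class:`HardFilterModel` wraps a labeled-call table (one row per call
with the ten filter features, a TV/FV label and stratum columns);
``fit()`` grows one classification tree per stratum, runs the node
targeting/selection procedure and returns a :class:`HardFilterResults`
carrying the per-stratum rule sets, the fitted trees and evaluation
tables, with ``summary()`` as the human-readable report.
"""

from __future__ import annotations

import pandas as pd

from .annotations import FEATURE_NAMES
from .evaluation import (
    SelectionCounts,
    auc_table,
    descriptive_stats,
    selection_report,
)
from .labeling import ALL_STRATA, LabeledCall, calls_to_frame
from .rules import FilterRuleSet, NodeSelectionParams, apply_rules, learn_rules
from .tree import DecisionTreeNode, ModelError, TreeParams, fit_tree

_STRATUM_COLS = ("vtype", "zygosity", "arm")


def stratum_name(stratum: tuple[str, str, str]) -> str:
    vtype, zyg, arm = stratum
    return f"{arm}_{vtype}_{zyg}"


class HardFilterModel:
    """Per-stratum hard-filter rule learner.

    Parameters
    ----------
    calls : pandas.DataFrame
        Labeled-call table with the feature columns, a ``label`` column
        ("TV"/"FV") and the stratum columns ``vtype``/``zygosity``/
        ``arm`` (plus ``replicate`` for the descriptive statistics).
    features : sequence of str
        Filter annotations offered to the trees.
    tree_params, selection_params
        Hyperparameters of the CART fit and of the node
        targeting/selection procedure.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        features=FEATURE_NAMES,
        tree_params: TreeParams | None = None,
        selection_params: NodeSelectionParams | None = None,
    ) -> None:
        missing = [c for c in (*_STRATUM_COLS, "label") if c not in calls.columns]
        if missing:
            raise ModelError(f"calls table lacks columns {missing}")
        self.calls = calls.reset_index(drop=True)
        self.features = list(features)
        self.tree_params = tree_params or TreeParams()
        self.selection_params = selection_params or NodeSelectionParams()

    @classmethod
    def from_labeled_calls(cls, labeled: list[LabeledCall], **kwargs) -> "HardFilterModel":
        return cls(calls_to_frame(labeled), **kwargs)

    def stratum_frame(self, stratum: tuple[str, str, str]) -> pd.DataFrame:
        vtype, zyg, arm = stratum
        df = self.calls
        return df[
            (df["vtype"] == vtype) & (df["zygosity"] == zyg) & (df["arm"] == arm)
        ]

    def fit(self) -> "HardFilterResults":
        """Fit one tree per stratum (pooled across replicates) and learn
        the hard-filter rules.

        Strata without calls, with a single label, or smaller than the
        minimum node size yield no tree and a retain-all rule set.
        """
        trees: dict[tuple[str, str, str], DecisionTreeNode | None] = {}
        rule_sets: dict[tuple[str, str, str], FilterRuleSet] = {}
        for stratum in ALL_STRATA:
            sub = self.stratum_frame(stratum)
            labels = set(sub["label"].unique())
            if (
                len(sub) < self.tree_params.min_node_size
                or labels != {"TV", "FV"}
            ):
                trees[stratum] = None
                rule_sets[stratum] = FilterRuleSet(stratum=stratum, rules=())
                continue
            root = fit_tree(sub, self.features, self.tree_params)
            trees[stratum] = root
            rule_sets[stratum] = learn_rules(root, stratum, self.selection_params)
        return HardFilterResults(self, trees, rule_sets)


class HardFilterResults:
    """Fitted rule sets with evaluation and application helpers."""

    def __init__(
        self,
        model: HardFilterModel,
        trees: dict[tuple[str, str, str], DecisionTreeNode | None],
        rule_sets: dict[tuple[str, str, str], FilterRuleSet],
    ) -> None:
        self.model = model
        self.trees = trees
        self.rule_sets = rule_sets

    def apply(
        self, calls: pd.DataFrame | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Hard-filter a call table with the learned per-stratum rules;
        returns (retained, removed) preserving row order."""
        df = self.model.calls if calls is None else calls
        retained_idx = []
        for stratum, rule_set in self.rule_sets.items():
            vtype, zyg, arm = stratum
            sub = df[
                (df["vtype"] == vtype)
                & (df["zygosity"] == zyg)
                & (df["arm"] == arm)
            ]
            kept, _ = apply_rules(rule_set, sub)
            retained_idx.append(kept.index)
        keep = df.index.isin(
            retained_idx[0].append(retained_idx[1:]) if retained_idx else []
        )
        return df[keep], df[~keep]

    def selection_table(
        self, calls: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Per-stratum pre/post-filter counts and selected percentage."""
        df = self.model.calls if calls is None else calls
        retained, _ = self.apply(df)
        rows = []
        for stratum in self.rule_sets:
            vtype, zyg, arm = stratum
            mask = (
                (df["vtype"] == vtype)
                & (df["zygosity"] == zyg)
                & (df["arm"] == arm)
            )
            rmask = (
                (retained["vtype"] == vtype)
                & (retained["zygosity"] == zyg)
                & (retained["arm"] == arm)
            )
            counts = selection_report(df[mask], retained[rmask])
            rows.append(
                {
                    "stratum": stratum_name(stratum),
                    "n_tv": counts.n_tv,
                    "n_fv": counts.n_fv,
                    "overall_tv_percent": counts.overall_tv_percent,
                    "overall_fv_percent": counts.overall_fv_percent,
                    "retained_tv": counts.retained_tv,
                    "retained_fv": counts.retained_fv,
                    "retained_tv_percent": counts.retained_tv_percent,
                    "retained_fv_percent": counts.retained_fv_percent,
                    "selected_percent": counts.selected_percent,
                }
            )
        return pd.DataFrame(rows)

    def stratum_selection(
        self, stratum: tuple[str, str, str], calls: pd.DataFrame | None = None
    ) -> SelectionCounts:
        df = self.model.calls if calls is None else calls
        vtype, zyg, arm = stratum
        sub = df[
            (df["vtype"] == vtype) & (df["zygosity"] == zyg) & (df["arm"] == arm)
        ]
        kept, _ = apply_rules(self.rule_sets[stratum], sub)
        return selection_report(sub, kept)

    def auc_by_stratum(self) -> pd.DataFrame:
        """Per-filter AUC in every stratum (Table-4 shaped)."""
        cols = {}
        for stratum in self.rule_sets:
            sub = self.model.stratum_frame(stratum)
            cols[stratum_name(stratum)] = auc_table(sub, self.model.features)
        return pd.DataFrame(cols)

    def descriptive_table(self, arm: str, vtype: str) -> pd.DataFrame:
        """Descriptive TV/FV statistics of one arm x variant-type cell."""
        df = self.model.calls
        sub = df[(df["arm"] == arm) & (df["vtype"] == vtype)]
        return descriptive_stats(sub, self.model.features)

    def summary(self) -> str:
        """Table of learned rules and filtering outcome per stratum."""
        lines = [
            "Hard-filter rule sets (one classification tree per stratum)",
            "=" * 78,
            f"{'stratum':<16}{'n_TV':>8}{'n_FV':>8}  rule",
            "-" * 78,
        ]
        sel = {s: self.stratum_selection(s) for s in self.rule_sets}
        for stratum, rule_set in self.rule_sets.items():
            c = sel[stratum]
            expr = rule_set.expression()
            lines.append(
                f"{stratum_name(stratum):<16}{c.n_tv:>8}{c.n_fv:>8}  {expr}"
            )
            if not rule_set.retain_all:
                lines.append(
                    f"{'':<16}{'':>8}{'':>8}  -> retains "
                    f"{c.retained_tv}/{c.n_tv} TV, {c.retained_fv}/{c.n_fv} FV "
                    f"({c.selected_percent:.1f}% selected)"
                )
        lines.append("=" * 78)
        return "\n".join(lines)
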