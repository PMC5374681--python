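"""Hard-filter rule extraction from fitted trees and rule application.

The procedure mirrors tree-based filter tuning for small panels:

1. *Targeting*: among the descendants of the root (down to a configured
   extraction depth), keep nodes holding at least 10% of the root's
   true calls whose TV/FV ratio exceeds 3.
2. *Selection*: to trade rule complexity against retention, each
   targeted node ``l`` is compared with its parent ``u``; ``u`` replaces
   ``l`` when ``l`` keeps less than 80% of ``u``'s true calls or more
   than 70% of ``u``'s false calls.
3. *Extraction*: each selected node becomes one conjunctive rule — the
   split conditions on its root path; several selected nodes form a
   disjunction.  An empty selection means no reliable filter was found
   and everything is retained.

A call passes a rule set when it satisfies every conjunct of at least
one rule; missing feature values never satisfy a conjunct.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .annotations import FEATURE_NAMES
from .tree import DecisionTreeNode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NodeSelectionParams:
    """Procedural constants of the targeting/selection steps."""

    min_tv_fraction: float = 0.10  # node must hold >= 10% of root TVs
    min_tv_fv_ratio: float = 3.0  # node TV/FV must exceed 3
    keep_l_tv_fraction: float = 0.80  # keep l only if >= 80% of u's TVs
    keep_l_fv_fraction: float = 0.70  # keep l only if <= 70% of u's FVs
    extraction_depth: int = 4  # levels of splits considered
    max_conjuncts: int = 7  # cap on conditions per rule

    def __post_init__(self) -> None:
        if not 0 < self.min_tv_fraction <= 1:
            raise ValueError("min_tv_fraction must be in (0, 1]")
        if self.min_tv_fv_ratio <= 0:
            raise ValueError("min_tv_fv_ratio must be positive")
        if not 0 < self.keep_l_tv_fraction <= 1:
            raise ValueError("keep_l_tv_fraction must be in (0, 1]")
        if not 0 <= self.keep_l_fv_fraction <= 1:
            raise ValueError("keep_l_fv_fraction must be in [0, 1]")
        if self.extraction_depth < 1 or self.max_conjuncts < 1:
            raise ValueError("extraction_depth and max_conjuncts must be >= 1")


@dataclass(frozen=True)
class FilterRule:
    """Conjunction of threshold conditions, e.g. ADT < 0.26 & GQ >= 98.5."""

    conjuncts: tuple[tuple[str, str, float], ...]  # (feature, "<"|">=", thr)

    def __post_init__(self) -> None:
        if not self.conjuncts:
            raise ValueError("a rule needs at least one conjunct")
        for feat, op, _ in self.conjuncts:
            if feat not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {feat!r}")
            if op not in ("<", ">="):
                raise ValueError(f"unknown comparator {op!r}")

    def satisfied(self, row) -> bool:
        for feat, op, thr in self.conjuncts:
            v = row[feat]
            if v is None or pd.isna(v):
                return False
            if op == "<" and not v < thr:
                return False
            if op == ">=" and not v >= thr:
                return False
        return True

    def expression(self) -> str:
        return " && ".join(
            f"{feat} {op} {thr:g}" for feat, op, thr in self.conjuncts
        )


@dataclass(frozen=True)
class FilterRuleSet:
    """Disjunction of rules for one stratum; empty means retain all."""

    stratum: tuple[str, str, str] | None
    rules: tuple[FilterRule, ...] = ()

    @property
    def retain_all(self) -> bool:
        return len(self.rules) == 0

    def expression(self) -> str:
        if self.retain_all:
            return "N/A"
        return " || ".join(f"({r.expression()})" for r in self.rules)


def target_nodes(
    root: DecisionTreeNode, params: NodeSelectionParams | None = None
) -> list[DecisionTreeNode]:
    """Descendant nodes (within the extraction depth) holding at least
    ``min_tv_fraction`` of the root's TVs with TV/FV ratio above
    ``min_tv_fv_ratio`` (a node with zero FVs passes the ratio test
    whenever it has any TVs)."""
    params = params or NodeSelectionParams()
    out = []
    for node in root.descendants():
        if node.depth > params.extraction_depth:
            continue
        if node.n_tv < params.min_tv_fraction * root.n_tv:
            continue
        if node.n_tv <= params.min_tv_fv_ratio * node.n_fv:
            continue
        out.append(node)
    return out


def select_nodes(
    targeted: list[DecisionTreeNode],
    root: DecisionTreeNode,
    params: NodeSelectionParams | None = None,
) -> list[DecisionTreeNode]:
    """Replace a targeted node ``l`` by its upper connected node ``u``
    (the parent, one level closer to the root) when ``l`` retains too
    few of ``u``'s true calls or too many of its false calls; the
    replacement is kept whether or not ``u`` itself passed targeting."""
    params = params or NodeSelectionParams()
    chosen: list[DecisionTreeNode] = []
    for l in targeted:
        u = l.parent
        if u is None:
            chosen.append(l)
            continue
        too_few_tv = l.n_tv < params.keep_l_tv_fraction * u.n_tv
        too_many_fv = l.n_fv > params.keep_l_fv_fraction * u.n_fv
        chosen.append(u if (too_few_tv or too_many_fv) else l)
    seen: set[int] = set()
    unique = []
    for node in sorted(chosen, key=lambda n: n.node_id):
        if node.node_id not in seen:
            seen.add(node.node_id)
            unique.append(node)
    # a node below another selected node yields a strictly narrower rule
    # that the disjunction already covers; dropping it keeps the retained
    # set identical while minimizing rule complexity
    out = []
    for node in unique:
        anc = node.parent
        has_selected_ancestor = False
        while anc is not None:
            if anc.node_id in seen:
                has_selected_ancestor = True
                break
            anc = anc.parent
        if not has_selected_ancestor:
            out.append(node)
    return out


def extract_rules(
    selected: list[DecisionTreeNode],
    root: DecisionTreeNode,
    stratum: tuple[str, str, str] | None = None,
    params: NodeSelectionParams | None = None,
) -> FilterRuleSet:
    """One conjunctive rule per selected node (root-path conditions, in
    path order); empty selection, or a selection that degenerates to the
    root itself, yields a retain-all set."""
    params = params or NodeSelectionParams()
    rules: list[FilterRule] = []
    for node in selected:
        conds = node.path_conditions()
        if not conds:
            # the root carries no condition: the set cannot filter anything
            logger.warning("selection degenerated to the root; retaining all")
            return FilterRuleSet(stratum=stratum, rules=())
        if len(conds) > params.max_conjuncts:
            logger.warning(
                "rule with %d conjuncts truncated to %d",
                len(conds), params.max_conjuncts,
            )
            conds = conds[: params.max_conjuncts]
        rules.append(FilterRule(conjuncts=tuple(conds)))
    return FilterRuleSet(stratum=stratum, rules=tuple(rules))


def learn_rules(
    root: DecisionTreeNode,
    stratum: tuple[str, str, str] | None = None,
    params: NodeSelectionParams | None = None,
) -> FilterRuleSet:
    """Targeting + selection + extraction in one step."""
    params = params or NodeSelectionParams()
    targeted = target_nodes(root, params)
    selected = select_nodes(targeted, root, params)
    return extract_rules(selected, root, stratum, params)


def apply_rules(
    rule_set: FilterRuleSet, calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split ``calls`` into (retained, removed) under the rule set.

    A call is retained iff it satisfies all conjuncts of at least one
    rule; a retain-all set keeps everything.  Rows with missing feature
    values satisfy no conjunct and are removed (conservative), with a
    debug log of the reason.
    """
    if rule_set.retain_all:
        return calls, calls.iloc[0:0]
    mask = pd.Series(False, index=calls.index)
    for rule in rule_set.rules:
        rule_mask = pd.Series(True, index=calls.index)
        for feat, op, thr in rule.conjuncts:
            col = calls[feat]
            cond = (col < thr) if op == "<" else (col >= thr)
            rule_mask &= cond.fillna(False)
        mask |= rule_mask
    n_missing = calls[[f for r in rule_set.rules for f, _, _ in r.conjuncts]].isna().any(axis=1).sum()
    if n_missing:
        logger.debug("%d calls had missing rule features (treated as failing)", n_missing)
    return calls[mask], calls[~mask]


# --- serialization ---------------------------------------------------------

_COND_RE = re.compile(r"^\s*(\w+)\s*(<|>=)\s*([-+0-9.eE]+)\s*$")


def rule_set_to_dict(rule_set: FilterRuleSet) -> dict:
    return {
        "stratum": list(rule_set.stratum) if rule_set.stratum else None,
        "retain_all": rule_set.retain_all,
        "rules": [
            [{"feature": f, "op": op, "threshold": thr} for f, op, thr in r.conjuncts]
            for r in rule_set.rules
        ],
    }


def rule_set_from_dict(d: dict) -> FilterRuleSet:
    stratum = tuple(d["stratum"]) if d.get("stratum") else None
    rules = tuple(
        FilterRule(
            conjuncts=tuple(
                (c["feature"], c["op"], float(c["threshold"])) for c in conds
            )
        )
        for conds in d.get("rules", [])
    )
    return FilterRuleSet(stratum=stratum, rules=rules)


def rule_sets_to_json(rule_sets: dict[tuple[str, str, str], FilterRuleSet]) -> str:
    payload = [rule_set_to_dict(rs) for _, rs in sorted(rule_sets.items())]
    return json.dumps(payload, indent=2)


def rule_sets_from_json(text: str) -> dict[tuple[str, str, str], FilterRuleSet]:
    out = {}
    for d in json.loads(text):
        rs = rule_set_from_dict(d)
        out[rs.stratum] = rs
    return out


def parse_expression(expr: str) -> FilterRuleSet:
    """Parse a GATK-style expression like
    ``(ADT < 0.26 && GQ >= 98.5) || (GQ >= 99)`` into a rule set."""
    expr = expr.strip()
    if expr in ("", "N/A"):
        return FilterRuleSet(stratum=None, rules=())
    rules = []
    for part in expr.split("||"):
        part = part.strip()
        if part.startswith("(") and part.endswith(")"):
            part = part[1:-1]
        conds = []
        for cond in part.split("&&"):
            m = _COND_RE.match(cond)
            if m is None:
                raise ValueError(f"cannot parse condition {cond!r}")
            conds.append((m.group(1), m.group(2), float(m.group(3))))
        rules.append(FilterRule(conjuncts=tuple(conds)))
    return FilterRuleSet(stratum=None, rules=tuple(rules))
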