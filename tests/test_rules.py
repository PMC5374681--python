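"""Node targeting, the u-vs-l selection procedure, rule extraction and
rule application semantics."""

import numpy as np
import pandas as pd
import pytest

from panelfilter import (
    FilterRule,
    FilterRuleSet,
    NodeSelectionParams,
    apply_rules,
    extract_rules,
    fit_tree,
    learn_rules,
    select_nodes,
    target_nodes,
)
from panelfilter.rules import (
    parse_expression,
    rule_set_from_dict,
    rule_set_to_dict,
)
from panelfilter.tree import DecisionTreeNode, TreeParams


def node(node_id, depth, n_tv, n_fv, parent=None):
    n = DecisionTreeNode(node_id=node_id, depth=depth, n_tv=n_tv, n_fv=n_fv,
                         parent=parent)
    return n


def attach(parent, left, right, feature="ADT", threshold=0.5):
    parent.feature = feature
    parent.threshold = threshold
    parent.left = left
    parent.right = right
    left.parent = parent
    right.parent = parent
    return parent


class TestTargetNodes:
    def test_worked_example(self):
        root = node(0, 0, 100, 100)
        left = node(1, 1, 95, 10)
        right = node(2, 1, 5, 90)
        attach(root, left, right)
        targeted = target_nodes(root)
        # L: 95 >= 10 and 95 > 3*10; R fails both criteria
        assert targeted == [left]

    def test_pure_fv_tree_empty(self):
        root = node(0, 0, 0, 50)
        assert target_nodes(root) == []

    def test_ten_percent_threshold(self):
        root = node(0, 0, 100, 0)
        left = node(1, 1, 9, 0)
        right = node(2, 1, 91, 0)
        attach(root, left, right)
        targeted = target_nodes(root)
        assert left not in targeted and right in targeted

    def test_zero_fv_passes_ratio(self):
        root = node(0, 0, 100, 50)
        left = node(1, 1, 40, 0)
        right = node(2, 1, 60, 50)
        attach(root, left, right)
        assert left in target_nodes(root)


class TestSelectNodes:
    def make_pair(self, l_tv, l_fv, u_tv=90, u_fv=200):
        u = node(1, 1, u_tv, u_fv)
        root = node(0, 0, u_tv + 10, u_fv + 100)
        sib0 = node(2, 1, 10, 100)
        attach(root, u, sib0)
        l = node(3, 2, l_tv, l_fv)
        sib = node(4, 2, u_tv - l_tv, u_fv - l_fv)
        attach(u, l, sib, feature="GQ", threshold=50)
        return l, u, root

    def test_keep_l_when_both_criteria_hold(self):
        # 78/90 = 86.7% >= 80% and 20/200 = 10% <= 70%
        l, u, root = self.make_pair(78, 20)
        assert select_nodes([l], root) == [l]

    def test_select_u_on_low_tv_retention(self):
        # 70/90 = 77.8% < 80%
        l, u, root = self.make_pair(70, 20)
        assert select_nodes([l], root) == [u]

    def test_select_u_on_high_fv_share(self):
        # 150/200 = 75% > 70%
        l, u, root = self.make_pair(88, 150)
        assert select_nodes([l], root) == [u]

    def test_deduplication(self):
        l1, u, root = self.make_pair(70, 20)
        assert select_nodes([l1, l1], root) == [u]

    def test_descendant_of_selected_ancestor_dropped(self):
        # u and its child l both kept individually; l's rule is subsumed
        l, u, root = self.make_pair(88, 20)
        assert select_nodes([u, l], root) == [u]


class TestExtractRules:
    def test_single_conjunct_shape(self):
        root = node(0, 0, 100, 100)
        left = node(1, 1, 5, 95)
        right = node(2, 1, 95, 5)
        attach(root, left, right, feature="ADT", threshold=0.98)
        rs = extract_rules([right], root, stratum=("SNV", "hom", "LC"))
        assert len(rs.rules) == 1
        assert rs.rules[0].conjuncts == (("ADT", ">=", 0.98),)
        assert rs.rules[0].expression() == "ADT >= 0.98"

    def test_two_nodes_make_disjunction(self):
        root = node(0, 0, 100, 100)
        left = node(1, 1, 45, 5)
        right = node(2, 1, 55, 95)
        attach(root, left, right, feature="GQ", threshold=98.5)
        rs = extract_rules([left, right], root)
        assert len(rs.rules) == 2

    def test_empty_selection_retains_all(self):
        root = node(0, 0, 10, 200)
        rs = extract_rules([], root)
        assert rs.retain_all and rs.rules == ()

    def test_root_selection_degenerates_to_retain_all(self):
        root = node(0, 0, 100, 10)
        rs = extract_rules([root], root)
        assert rs.retain_all


class TestApplyRules:
    def frame(self, **cols):
        return pd.DataFrame(cols)

    def test_retain_all(self):
        rs = FilterRuleSet(stratum=None, rules=())
        df = self.frame(ADT=np.linspace(0, 1, 10), label=["TV"] * 10)
        kept, removed = apply_rules(rs, df)
        assert len(kept) == 10 and len(removed) == 0

    def test_inclusive_boundary(self):
        rs = FilterRuleSet(
            stratum=None, rules=(FilterRule(conjuncts=(("ADT", ">=", 0.98),)),)
        )
        df = self.frame(ADT=[1.0, 0.98, 0.97])
        kept, removed = apply_rules(rs, df)
        assert list(kept["ADT"]) == [1.0, 0.98]
        assert list(removed["ADT"]) == [0.97]

    def test_disjunction_semantics(self):
        rs = parse_expression("(ADT < 0.26 && DP >= 23.5) || (GQ >= 98.5)")
        df = self.frame(ADT=[0.5], DP=[10.0], GQ=[99.0])
        kept, _ = apply_rules(rs, df)
        assert len(kept) == 1  # retained via the second rule

    def test_missing_feature_value_fails_conjunct(self):
        rs = parse_expression("GQ >= 50")
        df = self.frame(GQ=[np.nan, 60.0])
        kept, removed = apply_rules(rs, df)
        assert list(kept["GQ"]) == [60.0] and len(removed) == 1

    def test_idempotence(self):
        rs = parse_expression("(ADT >= 0.5) || (GQ >= 90 && DP >= 10)")
        rng = np.random.default_rng(3)
        df = self.frame(
            ADT=rng.random(50), GQ=rng.integers(0, 100, 50).astype(float),
            DP=rng.integers(5, 40, 50).astype(float),
        )
        kept1, _ = apply_rules(rs, df)
        kept2, _ = apply_rules(rs, kept1)
        assert kept1.equals(kept2)


class TestEndToEndRuleLearning:
    def test_planted_threshold_recovery_small(self):
        rng = np.random.default_rng(11)
        n = 400
        df = pd.DataFrame(
            {
                "ADT": np.concatenate(
                    [rng.uniform(0.9, 1.0, n), rng.uniform(0.0, 0.8, n)]
                ),
                "GQ": np.full(2 * n, 99.0),
                "label": ["TV"] * n + ["FV"] * n,
            }
        )
        root = fit_tree(df, features=["ADT", "GQ"], params=TreeParams())
        rs = learn_rules(root)
        assert len(rs.rules) == 1
        ((feat, op, thr),) = rs.rules[0].conjuncts
        assert feat == "ADT" and op == ">="
        assert 0.8 <= thr <= 0.9  # inside the planted gap


class TestSerialization:
    def test_json_round_trip(self):
        rs = FilterRuleSet(
            stratum=("INDEL", "het", "LC"),
            rules=(
                FilterRule(conjuncts=(("ADT", "<", 0.26), ("GQ", ">=", 98.5))),
                FilterRule(conjuncts=(("RPRS", "<", -1.55),)),
            ),
        )
        assert rule_set_from_dict(rule_set_to_dict(rs)) == rs

    def test_expression_round_trip(self):
        rs = FilterRuleSet(
            stratum=None,
            rules=(
                FilterRule(conjuncts=(("ADT", "<", 0.26), ("DP", ">=", 23.5))),
                FilterRule(conjuncts=(("GQ", ">=", 68.5),)),
            ),
        )
        parsed = parse_expression(rs.expression())
        assert parsed.rules == rs.rules

    def test_retain_all_expression(self):
        rs = FilterRuleSet(stratum=None, rules=())
        assert parse_expression(rs.expression()).retain_all
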