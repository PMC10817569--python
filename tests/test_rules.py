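"""Rule mining, knowledge-base management and probability adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from ruleboost import (
    Literal,
    Rule,
    RuleKB,
    apply_rules,
    apply_rules_frame,
    assign_ranks,
    enumerate_antecedents,
    mine_rules,
    score_antecedent,
    select_kb,
)
from ruleboost.rules import DEFAULT_RANK_DELTAS, RuleError, RuleStats, antecedent_key

from conftest import make_cohort


def simple_kb(rules):
    return RuleKB(tuple(rules), dict(DEFAULT_RANK_DELTAS))


class TestEnumerateAntecedents:
    @pytest.mark.parametrize(
        "n_features, max_arity, polarities, expected",
        [
            (3, 3, "both", 26),  # sum C(3,a) * 2^a
            (35, 3, "positive_only", 35 + 595 + 6545),
            (1, 1, "positive_only", 1),
        ],
    )
    def test_counts(self, n_features, max_arity, polarities, expected):
        names = [f"f{i}" for i in range(n_features)]
        items = list(enumerate_antecedents(names, max_arity, polarities))
        assert len(items) == expected
        assert len({antecedent_key(a) for a in items}) == expected  # no duplicates

    def test_arity_exceeding_features_rejected(self):
        with pytest.raises(RuleError, match="exceeds"):
            list(enumerate_antecedents(["a", "b"], 3))

    def test_deterministic_order(self):
        names = ["x", "y", "z"]
        assert list(enumerate_antecedents(names, 2)) == list(enumerate_antecedents(names, 2))


class TestScoreAntecedent:
    def test_hand_counted_example(self, toy_cohort):
        rule = score_antecedent((Literal("f1", 1),), toy_cohort)
        assert rule.stats.support == 5
        assert rule.stats.subgroup_rate == pytest.approx(0.4)
        assert rule.stats.baseline_rate == pytest.approx(0.2)
        assert rule.direction == "increase"
        assert rule.stats.effect_ratio == pytest.approx(2.0)

    def test_universal_antecedent_is_a_tie(self):
        t = make_cohort({"f": [1, 1, 1, 1]}, [1, 0, 0, 1])
        rule = score_antecedent((Literal("f", 1),), t)
        assert rule.stats.direction_tie
        assert rule.stats.subgroup_rate == rule.stats.baseline_rate

    def test_zero_support_flagged_unusable(self):
        t = make_cohort({"f": [0, 0, 0]}, [1, 0, 0])
        rule = score_antecedent((Literal("f", 1),), t)
        assert rule.stats.support == 0
        assert not rule.stats.usable


def brute_force_mine(t, min_support, min_effect_ratio, max_arity):
    """Independent enumeration + filter, nested loops over raw arrays."""
    X = t.features.to_numpy()
    y = t.outcome.to_numpy()
    names = list(t.features.columns)
    baseline = y.mean()
    survivors = set()
    for arity in range(1, max_arity + 1):
        for combo in itertools.combinations(range(len(names)), arity):
            for pols in itertools.product((0, 1), repeat=arity):
                mask = np.ones(len(y), dtype=bool)
                for j, p in zip(combo, pols):
                    mask &= X[:, j] == p
                support = mask.sum()
                if support < min_support:
                    continue
                rate = y[mask].mean()
                if rate == baseline:
                    continue
                ratio = rate / baseline
                strength = math.inf if ratio == 0 else max(ratio, 1 / ratio)
                if strength >= min_effect_ratio:
                    key = antecedent_key(
                        Literal(names[j], p) for j, p in zip(combo, pols)
                    )
                    survivors.add(key)
    return survivors


class TestMineRules:
    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        t = make_cohort(
            {f"f{i}": rng.integers(0, 2, 60).tolist() for i in range(6)},
            rng.integers(0, 2, 60).tolist(),
        )
        mined = mine_rules(t, min_support=8, min_effect_ratio=1.4, max_arity=3)
        expected = brute_force_mine(t, 8, 1.4, 3)
        assert {r.key for r in mined} == expected

    def test_min_support_above_n_gives_empty_list(self, toy_cohort):
        assert mine_rules(toy_cohort, min_support=11) == []

    def test_sorted_by_strength_then_support(self):
        rng = np.random.default_rng(2)
        t = make_cohort(
            {f"f{i}": rng.integers(0, 2, 80).tolist() for i in range(5)},
            rng.integers(0, 2, 80).tolist(),
        )
        mined = mine_rules(t, min_support=5, min_effect_ratio=1.2, max_arity=2)
        keys = [(-(r.stats.strength), -r.stats.support, r.key) for r in mined]
        assert keys == sorted(keys)

    def test_label_flip_flips_directions(self):
        rng = np.random.default_rng(8)
        t = make_cohort(
            {f"f{i}": rng.integers(0, 2, 50).tolist() for i in range(4)},
            rng.integers(0, 2, 50).tolist(),
        )
        flipped = make_cohort(
            {c: t.features[c].tolist() for c in t.features.columns},
            (1 - t.outcome).tolist(),
        )
        directions = {
            r.key: r.direction for r in mine_rules(t, min_support=5, min_effect_ratio=1.0)
        }
        for rule in mine_rules(flipped, min_support=5, min_effect_ratio=1.0):
            if rule.key in directions:
                assert rule.direction != directions[rule.key]


class TestAssignRanks:
    def _rules(self, strengths):
        rules = []
        for i, s in enumerate(strengths):
            stats = RuleStats(support=50 - i, subgroup_rate=0.0, baseline_rate=0.2,
                              effect_ratio=s)
            rules.append(Rule((Literal(f"f{i}", 1),), "increase", stats=stats))
        return rules

    def test_three_distinct_rules_one_per_rank(self):
        ranked = assign_ranks(self._rules([5.0, 3.0, 1.6]))
        assert [r.rank for r in ranked] == ["high", "medium", "low"]

    def test_six_rules_two_per_rank(self):
        ranked = assign_ranks(self._rules([6, 5, 4, 3, 2.5, 2]))
        assert [r.rank for r in ranked] == ["high"] * 2 + ["medium"] * 2 + ["low"] * 2

    def test_curation_override_respected(self):
        rules = self._rules([5.0, 3.0, 1.6])
        ranked = assign_ranks(rules, curation={rules[0].key: "low"})
        assert ranked[0].rank == "low"

    def test_curation_of_unmined_rule_rejected(self):
        with pytest.raises(RuleError, match="unmined"):
            assign_ranks(self._rules([2.0]), curation={"ghost=1": "high"})

    def test_file_mode_requires_full_coverage(self):
        rules = self._rules([2.0, 3.0])
        with pytest.raises(RuleError, match="no curated rank"):
            assign_ranks(rules, mode="file", curation={rules[0].key: "high"})

    def test_empty_list_rejected(self):
        with pytest.raises(RuleError, match="empty"):
            assign_ranks([])


class TestSelectKb:
    def test_cap_of_twenty(self):
        ranked = assign_ranks(
            TestAssignRanks()._rules(np.linspace(6, 2, 50).tolist())
        )
        kb = select_kb(ranked)
        assert len(kb.rules) == 20
        assert kb.rules[0].key == ranked[0].key

    def test_fewer_candidates_all_kept(self):
        ranked = assign_ranks(TestAssignRanks()._rules([3.0, 2.0]))
        assert len(select_kb(ranked).rules) == 2

    def test_cap_zero_gives_empty_kb(self):
        ranked = assign_ranks(TestAssignRanks()._rules([3.0]))
        kb = select_kb(ranked, max_rules=0)
        assert kb.rules == ()


class TestApplyRules:
    def test_no_fired_rule_is_identity(self):
        kb = simple_kb([Rule((Literal("f", 1),), "increase", "high")])
        assert apply_rules(kb, {"f": 0}, 0.3) == pytest.approx(0.3, abs=1e-9)

    def test_single_increase_rule_logistic_shift(self):
        kb = RuleKB(
            (Rule((Literal("f", 1),), "increase", "high"),),
            {"low": 0.25, "medium": 0.5, "high": 1.0},
        )
        assert apply_rules(kb, {"f": 1}, 0.5) == pytest.approx(expit(1.0), abs=1e-9)

    def test_opposite_equal_rank_rules_cancel(self):
        kb = simple_kb(
            [
                Rule((Literal("a", 1),), "increase", "medium"),
                Rule((Literal("b", 1),), "decrease", "medium"),
            ]
        )
        assert apply_rules(kb, {"a": 1, "b": 1}, 0.37) == pytest.approx(0.37, abs=1e-9)

    def test_missing_kb_feature_rejected(self):
        kb = simple_kb([Rule((Literal("f", 1),), "increase", "low")])
        with pytest.raises(RuleError, match="lack"):
            apply_rules_frame(kb, pd.DataFrame({"g": [1]}), [0.5])

    @given(
        p=st.floats(min_value=1e-6, max_value=1 - 1e-6),
        fired_up=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_output_in_unit_interval_and_monotone(self, p, fired_up):
        rules = [
            Rule((Literal(f"f{i}", 1),), "increase", "medium") for i in range(3)
        ]
        kb = simple_kb(rules)
        row = {f"f{i}": 1 if i < fired_up else 0 for i in range(3)}
        out = apply_rules(kb, row, p)
        assert 0.0 < out < 1.0
        if fired_up:
            weaker = {f"f{i}": 1 if i < fired_up - 1 else 0 for i in range(3)}
            assert out > apply_rules(kb, weaker, p)
        assert apply_rules(kb, row, min(p + 0.1, 1 - 1e-6)) >= out

    def test_rank_deltas_must_increase(self):
        with pytest.raises(RuleError, match="increase"):
            RuleKB((), {"low": 1.0, "medium": 0.5, "high": 1.2})


class TestSerialization:
    def _kb(self):
        stats = RuleStats(12, 0.5, 0.2, 2.5)
        rules = (
            Rule((Literal("a", 1), Literal("b", 0)), "increase", "high", stats),
            Rule((Literal("c", 1),), "decrease", "low"),
        )
        return simple_kb(rules)

    def test_json_round_trip_exact(self, tmp_path):
        kb = self._kb()
        path = tmp_path / "kb.json"
        kb.to_json(path)
        back = RuleKB.from_json(path)
        assert back.rank_deltas == kb.rank_deltas
        assert [(r.key, r.direction, r.rank) for r in back.rules] == [
            (r.key, r.direction, r.rank) for r in kb.rules
        ]
        assert back.rules[0].stats.effect_ratio == kb.rules[0].stats.effect_ratio
        # a second round trip is byte-identical
        path2 = tmp_path / "kb2.json"
        back.to_json(path2)
        assert path.read_text() == path2.read_text()

    def test_csv_round_trip_exact(self, tmp_path):
        kb = self._kb()
        path = tmp_path / "kb.csv"
        kb.to_csv(path)
        back = RuleKB.from_csv(path)
        path2 = tmp_path / "kb2.csv"
        back.to_csv(path2)
        assert path.read_text() == path2.read_text()
        assert [(r.key, r.direction, r.rank) for r in back.rules] == [
            (r.key, r.direction, r.rank) for r in kb.rules
        ]

    def test_literal_parse_round_trip(self):
        lit = Literal("heart_rate_lt_40", 0)
        assert Literal.parse(str(lit)) == lit
        with pytest.raises(RuleError):
            Literal.parse("bad literal")
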