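"""Mining core: support counting, Apriori search, rule generation, pruning,
and differential agreement with the brute-force oracle."""

from itertools import combinations

import numpy as np
import pytest

import traumaprofiles as tp
from traumaprofiles.mining import _min_count

from conftest import make_items, random_dataset


class TestSupport:
    def test_worked_example_supports(self, f1):
        assert tp.support(["A"], f1) == 0.8
        assert tp.support(["A", "B", "O"], f1) == 0.1

    def test_saturated_itemset(self):
        ds = tp.TransactionDataset(
            items=make_items(["a", "b"]), matrix=np.ones((5, 2), dtype=bool)
        )
        assert tp.support(["a", "b"], ds) == 1.0

    def test_unknown_item_rejected(self, f1):
        with pytest.raises(tp.DataError, match="unknown item"):
            tp.support(["Z"], f1)

    def test_anti_monotone_in_the_itemset(self):
        """support(X) >= support(Y) whenever X is a subset of Y."""
        rng = np.random.default_rng(11)
        ds = random_dataset(rng, n_items=7, n_rows=120)
        ids = ds.antecedent_ids
        for _ in range(200):
            size = rng.integers(2, 5)
            y = list(rng.choice(ids, size=size, replace=False))
            x = [i for i in y if rng.random() < 0.6] or [y[0]]
            assert tp.support(x, ds) >= tp.support(y, ds)


class TestFrequentItemsets:
    def test_worked_example_at_two_thresholds(self, f1):
        found = tp.frequent_itemsets(f1, 0.4, 3)
        assert set(found) == {
            frozenset("A"),
            frozenset("B"),
            frozenset("O"),
            frozenset(("A", "O")),
        }
        assert found[frozenset(("A", "O"))] == 0.5
        # permissive threshold: all 7 non-empty itemsets over {A, B, O}
        assert len(tp.frequent_itemsets(f1, 0.05, 3)) == 7

    def test_nothing_is_frequent_at_full_support_with_an_empty_row(self, f1):
        # F1 contains the {O}-only row, so no itemset reaches support 1.0
        assert tp.frequent_itemsets(f1, 1.0, 3, item_ids=("A", "B")) == {}

    def test_counted_candidates_always_have_frequent_subsets(self):
        """Apriori obligation: a candidate is only counted when every proper
        subset is frequent (checked through the counting trace)."""
        rng = np.random.default_rng(23)
        ds = random_dataset(rng, n_items=9, n_rows=200)
        trace: list = []
        found = tp.frequent_itemsets(ds, 0.15, 4, trace=trace)
        counted_multi = [c for c in trace if len(c) >= 2]
        assert counted_multi, "trace should include multi-item candidates"
        for cand in counted_multi:
            for sub in combinations(sorted(cand), len(cand) - 1):
                assert frozenset(sub) in found

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, n_items=6, n_rows=80)
        ids = ds.item_ids
        threshold = 0.2
        expected = {}
        for size in range(1, 4):
            for combo in combinations(ids, size):
                s = tp.support(combo, ds)
                if s >= threshold:
                    expected[frozenset(combo)] = s
        assert tp.frequent_itemsets(ds, threshold, 3) == expected


class TestGenerateRules:
    def test_worked_example_rules(self, f1):
        cfg = tp.MiningConfig(0.1, 0.3, consequent_ids=("O",))
        rules = {r.lhs: r for r in tp.generate_rules(f1, cfg)}
        assert set(rules) == {
            frozenset("A"),
            frozenset("B"),
            frozenset(("A", "B")),
        }
        assert rules[frozenset("A")].support_rule == 0.5
        assert rules[frozenset("A")].confidence == 0.625
        assert rules[frozenset("B")].support_rule == 0.2
        assert rules[frozenset("B")].confidence == 0.5
        assert rules[frozenset(("A", "B"))].support_rule == 0.1
        assert rules[frozenset(("A", "B"))].confidence == pytest.approx(1 / 3)

    def test_certain_rule_retained_at_full_confidence(self):
        # every row holding the antecedent also holds the consequent
        items = make_items(["a"], ["o"])
        matrix = np.array([[1, 1], [1, 1], [0, 0], [0, 1]], dtype=bool)
        ds = tp.TransactionDataset(items=items, matrix=matrix)
        rules = tp.generate_rules(
            ds, tp.MiningConfig(0.1, 1.0, consequent_ids=("o",))
        )
        assert [(set(r.lhs), r.confidence) for r in rules] == [({"a"}, 1.0)]

    def test_confidence_bounds(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n_items=6, n_rows=100)
        cfg = tp.MiningConfig(
            0.05, 0.05, consequent_ids=("o0",)
        )
        for r in tp.generate_rules(ds, cfg):
            assert 0 <= r.confidence <= 1
            assert r.confidence >= r.support_rule
            assert r.support_rule <= r.support_lhs
            assert r.confidence == r.n_rule / r.n_lhs

    def test_consequent_must_have_consequent_role(self, f1):
        with pytest.raises(tp.MiningError, match="antecedent"):
            tp.generate_rules(
                f1, tp.MiningConfig(0.1, 0.5, consequent_ids=("A",))
            )
        with pytest.raises(tp.MiningError, match="at least one consequent"):
            tp.generate_rules(f1, tp.MiningConfig(0.1, 0.5))

    def test_threshold_validation(self):
        with pytest.raises(tp.MiningError):
            tp.MiningConfig(1.5, 0.9, consequent_ids=("o",))
        with pytest.raises(tp.MiningError):
            tp.MiningConfig(0.3, 0.0, consequent_ids=("o",))
        with pytest.raises(tp.MiningError):
            tp.MiningConfig(0.3, 0.9, max_rule_length=1, consequent_ids=("o",))

    def test_inclusive_support_count(self):
        # count c passes iff c / n >= threshold, never strictly-greater
        assert _min_count(0.3, 10) == 3
        assert _min_count(0.3, 337) == 102
        assert _min_count(0.25, 8) == 2
        assert _min_count(0.001, 100) == 1


class TestPruneRedundant:
    def test_worked_example_pruning(self, f1):
        cfg = tp.MiningConfig(0.1, 0.3, consequent_ids=("O",))
        pruned = tp.prune_redundant(tp.generate_rules(f1, cfg))
        assert {r.lhs for r in pruned} == {frozenset("A"), frozenset("B")}

    def test_single_rule_is_untouched(self, f1):
        cfg = tp.MiningConfig(0.4, 0.6, consequent_ids=("O",))
        rules = tp.generate_rules(f1, cfg)
        assert len(rules) == 1
        assert tp.prune_redundant(rules) == rules

    def test_strictly_more_confident_super_rule_survives(self):
        """Adding an antecedent that raises confidence keeps both rules:
        dropping the extra item must genuinely cost accuracy."""
        items = make_items(["a", "b"], ["o"])
        # a alone: 6/8 flagged (0.75); b alone: 4/5 (0.8); a&b: 4/4 (1.0)
        blocks = [
            (4, ("a", "b", "o")),
            (2, ("a", "o")),
            (2, ("a",)),
            (1, ("b",)),
            (1, ("o",)),
        ]
        ds = tp.dataset_from_blocks(items, blocks)
        rs = tp.mine_profiles(
            ds, tp.MiningConfig(0.1, 0.7, consequent_ids=("o",))
        )
        assert {tuple(sorted(r.lhs)) for r in rs.rules} == {
            ("a",),
            ("b",),
            ("a", "b"),
        }

    def test_pruning_compares_within_consequent_only(self):
        items = make_items(["a", "b"], ["o1", "o2"])
        matrix = np.array(
            [[1, 1, 1, 1]] * 6 + [[1, 0, 1, 0]] * 2 + [[0, 1, 0, 1]] * 2,
            dtype=bool,
        )
        ds = tp.TransactionDataset(items=items, matrix=matrix)
        cfg = tp.MiningConfig(0.1, 0.5, consequent_ids=("o1", "o2"))
        rs = tp.mine_profiles(ds, cfg)
        # each consequent keeps its own minimal antecedents
        assert rs.for_consequent("o1") and rs.for_consequent("o2")


class TestMineProfiles:
    def test_composition_matches_generate_then_prune(self, f1):
        cfg = tp.MiningConfig(0.4, 0.6, consequent_ids=("O",))
        rs = tp.mine_profiles(f1, cfg)
        assert [(set(r.lhs), r.rhs) for r in rs.rules] == [({"A"}, "O")]
        assert rs.rules[0].confidence == 0.625
        assert rs.dataset_fingerprint == f1.fingerprint()

    def test_empty_dataset_is_an_error(self):
        items = make_items(["a"], ["o"])
        ds = tp.TransactionDataset(items=items, matrix=np.zeros((0, 2), bool))
        with pytest.raises(tp.MiningError, match="empty"):
            tp.mine_profiles(ds, tp.MiningConfig(0.3, 0.9, consequent_ids=("o",)))

    def test_length_cap_limits_antecedent_size(self):
        rng = np.random.default_rng(17)
        ds = random_dataset(rng, n_items=6, n_rows=150)
        cfg = tp.MiningConfig(
            0.05, 0.3, max_rule_length=2, consequent_ids=("o0",)
        )
        rs = tp.mine_profiles(ds, cfg)
        assert rs.rules and all(len(r.lhs) == 1 for r in rs.rules)
        oracle = tp.brute_force_oracle(ds, cfg)
        assert tuple(rs.rules) == tuple(oracle.rules)

    def test_determinism_byte_identical_serialization(self):
        rng = np.random.default_rng(29)
        ds = random_dataset(rng, n_items=8, n_rows=200)
        cfg = tp.MiningConfig(0.08, 0.4, consequent_ids=("o0",))
        a = tp.mine_profiles(ds, cfg).to_json()
        b = tp.mine_profiles(ds, cfg).to_json()
        assert a == b
        assert tp.RuleSet.from_json(a).rules == tp.mine_profiles(ds, cfg).rules

    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(41)
        for trial in range(8):
            ds = random_dataset(
                rng,
                n_items=int(rng.integers(4, 11)),
                n_rows=int(rng.integers(30, 200)),
            )
            cfg = tp.MiningConfig(
                min_support=float(rng.uniform(0.05, 0.4)),
                min_confidence=float(rng.uniform(0.4, 0.95)),
                max_rule_length=int(rng.integers(2, 6)),
                consequent_ids=("o0",),
            )
            assert tuple(tp.mine_profiles(ds, cfg).rules) == tuple(
                tp.brute_force_oracle(ds, cfg).rules
            ), f"disagreement on trial {trial}"

    def test_oracle_refuses_large_item_universes(self):
        rng = np.random.default_rng(2)
        ds = random_dataset(rng, n_items=tp.MAX_ORACLE_ITEMS + 1, n_rows=20)
        with pytest.raises(tp.MiningError, match="oracle bound"):
            tp.brute_force_oracle(
                ds, tp.MiningConfig(0.2, 0.5, consequent_ids=("o0",))
            )
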