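"""Synthetic generators: calibration, determinism, planting, full instrument."""

import numpy as np
import pytest

import traumaprofiles as tp

from conftest import make_items


def _three_se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestBinaryItems:
    def test_degenerate_prevalences(self):
        ds = tp.generate_binary_items(50, [("zero", 0.0), ("one", 1.0)], seed=1)
        assert not ds.column("zero").any()
        assert ds.column("one").all()

    def test_marginal_calibration_within_three_standard_errors(self):
        n = 20000
        specs = [("a", 0.475), ("b", 0.125), ("c", 0.9)]
        ds = tp.generate_binary_items(n, specs, seed=8)
        for item_id, p in specs:
            assert abs(ds.column(item_id).mean() - p) <= _three_se(p, n)

    def test_same_seed_reproduces_exactly_distinct_seeds_differ(self):
        specs = [("a", 0.3), ("b", 0.6)]
        m1 = tp.generate_binary_items(300, specs, seed=5).matrix
        m2 = tp.generate_binary_items(300, specs, seed=5).matrix
        m3 = tp.generate_binary_items(300, specs, seed=6).matrix
        assert np.array_equal(m1, m2)
        assert not np.array_equal(m1, m3)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(tp.SynthesisError, match="outside"):
            tp.generate_binary_items(10, [("a", 1.5)], seed=0)


class TestLikertSubscale:
    def test_extreme_targets_pin_every_mean(self):
        all_some = tp.generate_likert_subscale(200, 4, 1.0, 0.0, seed=2)
        assert (all_some.values.mean(axis=1) >= 2.0).all()
        none = tp.generate_likert_subscale(200, 4, 0.0, 0.0, seed=2)
        assert (none.values.mean(axis=1) < 2.0).all()

    def test_scores_are_integers_one_to_four(self):
        lik = tp.generate_likert_subscale(500, 5, 0.6, 0.2, seed=3)
        assert lik.values.shape == (500, 5)
        assert np.isin(lik.values, [1, 2, 3, 4]).all()

    def test_discretized_prevalences_hit_both_targets(self):
        n, some, severe = 20000, 0.671, 0.214
        lik = tp.generate_likert_subscale(n, 5, some, severe, seed=4)
        f_some = tp.discretize_outcome(
            lik, tp.OutcomeSpec("sm", lik.item_ids, 2.0)
        ).mean()
        f_severe = tp.discretize_outcome(
            lik, tp.OutcomeSpec("sv", lik.item_ids, 3.0)
        ).mean()
        assert abs(f_some - some) <= _three_se(some, n)
        assert abs(f_severe - severe) <= _three_se(severe, n)

    def test_deterministic_under_seed(self):
        a = tp.generate_likert_subscale(100, 3, 0.5, 0.1, seed=9).values
        b = tp.generate_likert_subscale(100, 3, 0.5, 0.1, seed=9).values
        assert np.array_equal(a, b)

    def test_severe_cannot_exceed_some(self):
        with pytest.raises(tp.SynthesisError):
            tp.generate_likert_subscale(10, 3, 0.2, 0.5, seed=0)


def _planting_dataset(n=2000, seed=3, p_items=0.6, p_out=0.671):
    items = make_items(["a", "b", "c"], ["o"])
    base = tp.generate_binary_items(
        n, [("a", p_items), ("b", p_items), ("c", p_items)], seed=seed
    )
    out = np.random.default_rng(seed + 1) .random(n) < p_out
    return tp.TransactionDataset(
        items=items, matrix=np.column_stack([base.matrix, out])
    )


class TestPlantRule:
    def test_full_confidence_is_exact(self):
        ds = _planting_dataset(n=500)
        rule = tp.PlantedRule(frozenset(("a", "b")), "o", 0.3, 1.0)
        planted = tp.plant_rule(ds, rule, seed=7)
        lhs = planted.column("a") & planted.column("b")
        assert (planted.column("o")[lhs]).all()

    def test_targets_realized_within_tolerance(self):
        ds = _planting_dataset()
        rule = tp.PlantedRule(frozenset(("a", "b", "c")), "o", 0.33, 0.92)
        planted = tp.plant_rule(ds, rule, seed=11)
        lhs = (
            planted.column("a") & planted.column("b") & planted.column("c")
        )
        joint = lhs & planted.column("o")
        support = joint.mean()
        confidence = joint.sum() / lhs.sum()
        assert abs(support - 0.33) <= 0.03
        assert abs(confidence - 0.92) <= 0.03
        # realized statistics are exact count ratios, consistent by construction
        assert joint.sum() <= lhs.sum()

    def test_untouched_rows_are_not_perturbed(self):
        ds = _planting_dataset(n=800)
        rule = tp.PlantedRule(frozenset(("a", "b", "c")), "o", 0.3, 0.9)
        planted = tp.plant_rule(ds, rule, seed=13)
        lhs_before = ds.matrix[:, :3].all(axis=1)
        lhs_after = planted.matrix[:, :3].all(axis=1)
        untouched = ~lhs_before & ~lhs_after
        assert np.array_equal(ds.matrix[untouched], planted.matrix[untouched])

    def test_planted_rule_is_recovered_by_the_miner(self):
        ds = _planting_dataset()
        rule = tp.PlantedRule(frozenset(("a", "b", "c")), "o", 0.33, 0.92)
        planted = tp.plant_rule(ds, rule, seed=19)
        rs = tp.mine_profiles(
            planted, tp.MiningConfig(0.3, 0.9, consequent_ids=("o",))
        )
        assert frozenset(("a", "b", "c")) in {r.lhs for r in rs.rules}
        oracle = tp.brute_force_oracle(
            planted, tp.MiningConfig(0.3, 0.9, consequent_ids=("o",))
        )
        assert tuple(rs.rules) == tuple(oracle.rules)

    def test_infeasible_targets_are_reported(self):
        with pytest.raises(tp.SynthesisError, match="cannot exceed"):
            tp.PlantedRule(frozenset(("a",)), "o", 0.9, 0.5)
        ds = _planting_dataset(n=10)
        tiny = tp.PlantedRule(frozenset(("a",)), "o", 0.01, 0.9)
        with pytest.raises(tp.SynthesisError, match="empty antecedent block"):
            tp.plant_rule(ds, tiny, seed=0)

    def test_unknown_items_rejected(self):
        ds = _planting_dataset(n=50)
        rule = tp.PlantedRule(frozenset(("zz",)), "o", 0.3, 0.9)
        with pytest.raises(tp.SynthesisError, match="unknown item"):
            tp.plant_rule(ds, rule, seed=0)


class TestFullInstrument:
    def test_catalog_profile_shapes(self):
        dataset, likert, manifest = tp.generate_prpwpq_like(
            tp.default_profile(n=337, seed=21)
        )
        assert dataset.matrix.shape == (337, 110)  # 106 items + 4 outcomes
        assert likert.values.shape == (337, 10)
        assert manifest["n_dropped"] == 0
        assert set(dataset.consequent_ids) == {
            "some_anxiety",
            "severe_anxiety",
            "some_depression",
            "severe_depression",
        }

    def test_single_respondent_profile(self):
        profile = tp.SyntheticProfile(
            n_respondents=1,
            item_specs=(("a", 0.5),),
            subscale_specs=(("anx", 3, 0.6, 0.2),),
            seed=1,
        )
        dataset, likert, _ = tp.generate_prpwpq_like(profile)
        assert dataset.matrix.shape == (1, 3)
        assert likert.values.shape == (1, 3)

    def test_two_seeds_same_schema_different_matrices(self):
        d1, _, _ = tp.generate_prpwpq_like(tp.default_profile(n=60, seed=1))
        d2, _, _ = tp.generate_prpwpq_like(tp.default_profile(n=60, seed=2))
        assert d1.item_ids == d2.item_ids
        assert not np.array_equal(d1.matrix, d2.matrix)

    def test_manifest_realized_statistics_are_recomputable(self):
        rule = tp.PlantedRule(
            frozenset(("body_aches", "problems_travel")),
            "some_anxiety",
            0.3,
            0.92,
        )
        profile = tp.default_profile(n=1000, seed=33, planted_rules=[rule])
        dataset, likert, manifest = tp.generate_prpwpq_like(profile)
        stats = manifest["planted_rules"][0]
        lhs = dataset.column("body_aches") & dataset.column("problems_travel")
        joint = lhs & dataset.column("some_anxiety")
        assert stats["n_rule"] == int(joint.sum())
        assert stats["realized_confidence"] == joint.sum() / lhs.sum()
        assert abs(stats["realized_support"] - 0.3) <= 0.03
        assert abs(stats["realized_confidence"] - 0.92) <= 0.03

    def test_likert_rediscretization_matches_planted_flags(self):
        """Planting edits outcome flags; the Likert rows are re-drawn so the
        returned matrices stay mutually consistent."""
        rule = tp.PlantedRule(
            frozenset(("body_aches", "backache")), "severe_anxiety", 0.25, 0.95
        )
        profile = tp.default_profile(n=400, seed=45, planted_rules=[rule])
        dataset, likert, _ = tp.generate_prpwpq_like(profile)
        for name in ("anxiety", "depression"):
            ids = tuple(f"{name}_{j+1}" for j in range(5))
            for prefix, thr in (("some", 2.0), ("severe", 3.0)):
                flags = tp.discretize_outcome(
                    likert, tp.OutcomeSpec("x", ids, thr)
                )
                assert np.array_equal(
                    flags > 0.5, dataset.column(f"{prefix}_{name}")
                )

    def test_severe_implies_some_after_planting(self):
        rule = tp.PlantedRule(
            frozenset(("lack_food",)), "severe_depression", 0.3, 0.9
        )
        dataset, _, _ = tp.generate_prpwpq_like(
            tp.default_profile(n=300, seed=50, planted_rules=[rule])
        )
        assert (
            dataset.column("some_depression") >= dataset.column("severe_depression")
        ).all()


class TestDatasetFromBlocks:
    def test_blocks_build_exact_counts(self):
        items = make_items(["x", "y"])
        ds = tp.dataset_from_blocks(items, [(3, ("x",)), (2, ("x", "y"))])
        assert ds.n_respondents == 5
        assert ds.column("x").sum() == 5
        assert ds.column("y").sum() == 2

    def test_unknown_block_item_rejected(self):
        with pytest.raises(tp.SynthesisError, match="unknown item"):
            tp.dataset_from_blocks(make_items(["x"]), [(1, ("z",))])
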