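"""Impactful-value scoring and top-k mining."""

import random
from fractions import Fraction

import pytest

from tiim.impact import ImpactDegreeTable
from tiim.miner import (
    appearance_pattern,
    brute_force_top_k,
    cluster_items,
    item_value,
    itemset_value,
    mine_top_k,
    run_mode,
)
from tiim.synthetic import toy_example
from tiim.transactions import DOWN, UP, GeneItem

from .conftest import make_db, make_degrees, random_instance

G1U = GeneItem("G1", UP)
G5U = GeneItem("G5", UP)
G5D = GeneItem("G5", DOWN)


@pytest.fixture()
def worked_db():
    """The Condition-2 differentiated DB of the worked example, built directly:
    q(G1up,T1)=2, q(G5up,T1)=1, q(G5up,T2)=2, q(G5down,T4)=3."""
    return make_db([{G1U: 2, G5U: 1}, {G5U: 2}, {}, {G5D: 3}])


@pytest.fixture()
def worked_degrees():
    return make_degrees({"G1": 3, "G5": 1})


class TestValues:
    def test_item_value_worked_example(self, worked_db, worked_degrees):
        """d=1 with quantities 1 and 2 gives 1*1 + 1*2 = 3."""
        assert item_value(G5U, worked_db, worked_degrees) == 3

    def test_itemset_value_worked_example(self, worked_db, worked_degrees):
        """{G1up, G5up} co-occur only in T1: (1/2)(3*2 + 1*1) = 3.5."""
        assert itemset_value([G1U, G5U], worked_db, worked_degrees) == Fraction(7, 2)

    def test_singleton_itemset_equals_item_value(self, worked_db, worked_degrees):
        for it in (G1U, G5U, G5D):
            assert itemset_value([it], worked_db, worked_degrees) == item_value(
                it, worked_db, worked_degrees
            )

    def test_absent_item_scores_zero(self, worked_db, worked_degrees):
        assert item_value(GeneItem("G9", UP), worked_db, worked_degrees) == 0

    def test_never_cooccurring_itemset_scores_zero(self, worked_db, worked_degrees):
        assert itemset_value([G1U, G5D], worked_db, worked_degrees) == 0

    def test_value_linear_in_quantities(self, worked_db, worked_degrees):
        doubled = make_db([{i: 2 * q for i, q in t.items()} for t in worked_db.transactions])
        assert item_value(G5U, doubled, worked_degrees) == 2 * item_value(
            G5U, worked_db, worked_degrees
        )

    def test_value_invariant_to_transaction_order(self, worked_db, worked_degrees):
        reordered = make_db(list(reversed(worked_db.transactions)))
        for s in ([G5U], [G1U, G5U]):
            assert itemset_value(s, reordered, worked_degrees) == itemset_value(
                s, worked_db, worked_degrees
            )

    def test_degree_scaling_scales_values_and_keeps_ranking(self):
        rng = random.Random(11)
        db, degrees = random_instance(rng)
        scaled = make_degrees({g: 3 * d for g, d in degrees.degrees.items()})
        a = brute_force_top_k(db, degrees, k=10)
        b = brute_force_top_k(db, scaled, k=10)
        assert [s.items for s in a.itemsets] == [s.items for s in b.itemsets]
        assert [3 * s.value for s in a.itemsets] == [s.value for s in b.itemsets]


class TestPatternsAndClusters:
    def test_appearance_pattern_marks_positive_quantities(self, worked_db):
        assert appearance_pattern(G5U, worked_db) == (1, 1, 0, 0)
        assert appearance_pattern(G1U, worked_db) == (1, 0, 0, 0)
        assert appearance_pattern(GeneItem("G9", UP), worked_db) == (0, 0, 0, 0)

    def test_itemset_support_is_and_of_member_patterns(self, worked_db, worked_degrees):
        topk = brute_force_top_k(worked_db, worked_degrees, k=1)
        (best,) = topk.itemsets
        combined = tuple(
            min(appearance_pattern(i, worked_db)[y] for i in best.items)
            for y in range(worked_db.n)
        )
        assert best.support == tuple(y + 1 for y, e in enumerate(combined) if e)

    def test_identical_patterns_share_a_cluster(self):
        a, b, c = GeneItem("a", UP), GeneItem("b", UP), GeneItem("c", UP)
        db = make_db([{a: 1, b: 2}, {}, {a: 1, b: 1, c: 3}])
        clusters = cluster_items(db)
        assert [a, b] in clusters and [c] in clusters

    def test_distinct_patterns_make_singleton_clusters(self):
        # m items with pairwise-distinct patterns -> m singleton clusters
        items = [GeneItem(f"g{i}", UP) for i in range(4)]
        db = make_db([{items[i]: 1} for i in range(4)])
        assert cluster_items(db) == [[i] for i in items]


class TestMineTopK:
    def test_worked_example_top1(self, toy_dbs):
        db = toy_dbs["diff"]["Condition2"]
        degrees = make_degrees({"G1": 3, "G2": 1, "G3": 1, "G4": 1, "G5": 1})
        topk = mine_top_k(db, degrees, k=1)
        (best,) = topk.itemsets
        assert best.value == Fraction(7, 2)
        assert set(best.items) == {G1U, G5U}

    def test_single_item_db_yields_empty_result(self):
        db = make_db([{G1U: 2}])
        assert mine_top_k(db, make_degrees({"G1": 1}), k=3).itemsets == []

    def test_all_zero_quantities_yield_empty_result(self):
        db = make_db([{}, {}])
        assert mine_top_k(db, make_degrees({}), k=3).itemsets == []
        assert brute_force_top_k(db, make_degrees({}), k=3).itemsets == []

    def test_zero_degree_items_pruned_by_default(self):
        a, b, z = GeneItem("a", UP), GeneItem("b", UP), GeneItem("z", UP)
        db = make_db([{a: 1, b: 1, z: 3}])
        degrees = make_degrees({"a": 2, "b": 2, "z": 0})
        topk = mine_top_k(db, degrees, k=10)
        assert all(z not in s.items for s in topk.itemsets)
        kept = mine_top_k(db, degrees, k=10, keep_zero_degree=True)
        assert any(z in s.items for s in kept.itemsets)
        # a zero-weight item can never raise an itemset's average value,
        # so the best values coincide
        assert topk.itemsets[0].value == kept.itemsets[0].value

    def test_values_nonincreasing_and_length_at_least_two(self):
        rng = random.Random(3)
        db, degrees = random_instance(rng)
        topk = mine_top_k(db, degrees, k=8)
        vals = topk.values()
        assert vals == sorted(vals, reverse=True)
        assert all(s.length >= 2 and s.value > 0 for s in topk.itemsets)

    def test_max_len_caps_itemset_length(self):
        rng = random.Random(5)
        db, degrees = random_instance(rng)
        topk = mine_top_k(db, degrees, k=10, max_len=2)
        oracle = brute_force_top_k(db, degrees, k=10, max_len=2)
        assert all(s.length == 2 for s in topk.itemsets)
        assert [(s.items, s.value) for s in topk.itemsets] == [
            (s.items, s.value) for s in oracle.itemsets
        ]

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_brute_force_on_random_instances(self, k):
        for seed in range(40):
            rng = random.Random(seed)
            db, degrees = random_instance(rng)
            a = mine_top_k(db, degrees, k)
            b = brute_force_top_k(db, degrees, k)
            assert [(s.items, s.value) for s in a.itemsets] == [
                (s.items, s.value) for s in b.itemsets
            ], f"seed {seed}"

    def test_brute_force_guard(self):
        items = [GeneItem(f"g{i}", UP) for i in range(25)]
        db = make_db([{i: 1 for i in items}])
        with pytest.raises(ValueError, match="guard"):
            brute_force_top_k(db, make_degrees({i.gene: 1 for i in items}), k=1)

    def test_subset_value_dominates_superset(self):
        """Average-utility bound: some (l-1)-subset scores at least the l-itemset."""
        from itertools import combinations

        rng = random.Random(99)
        checked = 0
        while checked < 300:
            db, degrees = random_instance(rng)
            items = db.items()
            if len(items) < 3:
                continue
            size = rng.randint(3, min(4, len(items)))
            s = rng.sample(items, size)
            v = itemset_value(s, db, degrees)
            best_sub = max(
                itemset_value(list(sub), db, degrees)
                for sub in combinations(s, size - 1)
            )
            assert best_sub >= v
            checked += 1


class TestRunMode:
    def _identical_condition_dataset(self):
        import pandas as pd

        from tiim.transactions import ExpressionDataset

        rng = random.Random(4)
        probes = [f"p{i}" for i in range(6)]
        base = {tp: [round(rng.uniform(-0.5, 0.5), 3) for _ in probes] for tp in (1, 2)}
        cols, rows = {}, []
        for cond in ("A", "B"):
            for rep in (1, 2, 3):
                for tp in (1, 2):
                    sid = f"{cond}{rep}t{tp}"
                    cols[sid] = base[tp]
                    rows.append({"sample_id": sid, "condition": cond,
                                 "replicate": rep, "timepoint": tp})
        return ExpressionDataset(
            pd.DataFrame(cols, index=probes),
            pd.DataFrame(rows).set_index("sample_id"),
        )

    def test_tiim_on_identical_conditions_is_empty(self):
        """Differentiation cancels identical conditions completely."""
        from tiim.impact import build_grn

        ds = self._identical_condition_dataset()
        grn = build_grn([("p0", "p1"), ("p1", "p2")])
        res = run_mode(ds, grn, k=5, mode="tiim")
        assert all(len(t) == 0 for t in res.values())

    def test_undifferentiation_on_identical_conditions_is_symmetric(self):
        from tiim.impact import build_grn

        ds = self._identical_condition_dataset()
        grn = build_grn([("p0", "p1")])
        res = run_mode(ds, grn, k=5, mode="undifferentiation")
        a, b = res.values()
        assert [(s.items, s.value) for s in a.itemsets] == [
            (s.items, s.value) for s in b.itemsets
        ]
        assert len(a) > 0

    def test_constant_degree_matches_tiim_under_uniform_degrees(self, toy_dbs):
        """When every real degree is equal, constant-degree ranking equals tiim's."""
        db = toy_dbs["diff"]["Condition2"]
        uniform = make_degrees({g: 2 for g in ("G1", "G2", "G3", "G4", "G5")})
        constant = make_degrees({g: 1 for g in ("G1", "G2", "G3", "G4", "G5")})
        a = mine_top_k(db, uniform, k=5)
        b = mine_top_k(db, constant, k=5)
        assert [s.items for s in a.itemsets] == [s.items for s in b.itemsets]

    def test_unknown_mode_rejected(self, toy):
        dataset, grn = toy
        with pytest.raises(ValueError, match="mode"):
            run_mode(dataset, grn, k=1, mode="bogus")
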