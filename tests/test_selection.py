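"""Greedy and exact validation-set selectors and the random baseline."""

import warnings

import numpy as np
import pytest

from helpers import (
    discordant_oracle,
    greedy_best_key,
    hamming_vector,
    min_subset_size_oracle,
    random_matrix,
)
from vda.core import PredictionMatrix, discordant_set
from vda.selection import (
    NothingToDiscriminateError,
    UnachievableDistanceError,
    add_reference_algorithms,
    evda_min_set,
    evda_sort,
    gvda_sort,
    random_sort,
)


def matrix_with_discordance(rng, n, m):
    """Random matrix guaranteed to contain at least one discordant instance."""
    while True:
        pm = random_matrix(rng, n, m)
        if discordant_oracle(pm):
            return pm


class TestGvda:
    def test_two_algorithms_every_pick_raises_min_by_one(self, rng):
        col = rng.integers(0, 2, size=10)
        pm = PredictionMatrix(
            tuple(f"i{k}" for k in range(10)),
            ("a", "b"),
            np.column_stack([col, 1 - col]),
        )
        plan = gvda_sort(pm, "all", seed=0)
        assert [s.min_hamming_after for s in plan.steps] == list(range(1, 11))

    def test_three_fingerprint_panel_covers_all_pairs_in_two_picks(self):
        # fingerprints (1,0,0) x5, (0,1,1) x5, (1,1,0) x1: exhaustive leximin
        # evaluation shows the first two picks always combine two distinct
        # fingerprints that jointly raise every pairwise distance to >= 1
        patterns = [(1, 0, 0)] * 5 + [(0, 1, 1)] * 5 + [(1, 1, 0)]
        pm = PredictionMatrix(
            tuple(f"i{k}" for k in range(11)),
            ("a", "b", "c"),
            np.array(patterns),
        )
        for seed in range(10):
            plan = gvda_sort(pm, 3, seed=seed)
            assert plan.steps[0].fingerprint != plan.steps[1].fingerprint
            assert plan.steps[0].min_hamming_after == 0
            assert plan.steps[1].min_hamming_after == 1

    def test_each_choice_attains_brute_force_leximin_maximum(self, rng):
        for _ in range(30):
            pm = matrix_with_discordance(rng, 12, 3)
            plan = gvda_sort(pm, "all", seed=int(rng.integers(2**31)))
            selected: list[str] = []
            remaining = set(discordant_oracle(pm))
            for step in plan.steps:
                best = greedy_best_key(pm, selected, remaining)
                chosen_key = tuple(
                    sorted(hamming_vector(pm, selected + [step.instance_id]))
                )
                assert chosen_key == best
                selected.append(step.instance_id)
                remaining.discard(step.instance_id)

    def test_min_hamming_non_decreasing_and_audit_consistent(self, rng):
        pm = matrix_with_discordance(rng, 40, 4)
        plan = gvda_sort(pm, "all", seed=7)
        mins = [s.min_hamming_after for s in plan.steps]
        assert mins == sorted(mins)
        for k, step in enumerate(plan.steps):
            assert tuple(hamming_vector(pm, list(plan.prefix(k + 1)))) == step.hamming_after

    def test_plan_only_contains_discordant_instances_once(self, rng):
        pm = matrix_with_discordance(rng, 30, 3)
        plan = gvda_sort(pm, "all", seed=1)
        assert len(set(plan.instance_ids)) == len(plan)
        assert set(plan.instance_ids) == discordant_set(pm)

    def test_deterministic_given_seed(self, rng):
        pm = matrix_with_discordance(rng, 30, 4)
        a = gvda_sort(pm, "all", seed=42)
        b = gvda_sort(pm, "all", seed=42)
        assert a == b

    def test_empty_discordant_set_raises(self):
        pm = PredictionMatrix(
            ("i0", "i1"), ("a", "b"), np.array([[1, 1], [0, 0]])
        )
        with pytest.raises(NothingToDiscriminateError):
            gvda_sort(pm, "all", seed=0)

    def test_oversized_budget_truncates_with_warning(self, rng):
        pm = matrix_with_discordance(rng, 10, 2)
        d = len(discordant_set(pm))
        with pytest.warns(UserWarning, match="exceeds"):
            plan = gvda_sort(pm, d + 5, seed=0)
        assert len(plan) == d

    def test_prefix_beats_median_random_prefix(self, rng):
        """A greedy prefix's min Hamming distance is at least the random median."""
        # imbalanced panel: lopsided fingerprint multiplicities
        patterns = [(1, 0, 0)] * 30 + [(0, 1, 1)] * 3 + [(1, 1, 0)] * 2 + [(0, 0, 1)]
        pm = PredictionMatrix(
            tuple(f"i{k}" for k in range(36)),
            ("a", "b", "c"),
            np.array(patterns),
        )
        for k in (3, 6, 9):
            greedy_min = min(hamming_vector(pm, list(gvda_sort(pm, k, seed=0).prefix(k))))
            randoms = []
            for s in range(100):
                prefix = list(random_sort(pm, "D", seed=s).prefix(k))
                randoms.append(min(hamming_vector(pm, prefix)))
            assert greedy_min >= np.median(randoms)


class TestEvda:
    def test_h_zero_returns_empty_set(self, rng):
        pm = matrix_with_discordance(rng, 10, 3)
        assert evda_min_set(pm, 0) == set()

    def test_two_algorithms_size_equals_h(self, rng):
        col = rng.integers(0, 2, size=12)
        pm = PredictionMatrix(
            tuple(f"i{k}" for k in range(12)),
            ("a", "b"),
            np.column_stack([col, 1 - col]),
        )
        chosen = evda_min_set(pm, 3)
        assert len(chosen) == 3
        assert chosen <= discordant_set(pm)

    @pytest.mark.parametrize("h", [1, 2])
    def test_cardinality_matches_exhaustive_enumeration(self, rng, h):
        checked = 0
        while checked < 30:
            pm = matrix_with_discordance(rng, 10, 3)
            try:
                chosen = evda_min_set(pm, h)
            except UnachievableDistanceError:
                continue
            checked += 1
            assert min(hamming_vector(pm, sorted(chosen))) >= h
            assert len(chosen) == min_subset_size_oracle(pm, h)

    def test_size_non_decreasing_in_h(self, rng):
        pm = matrix_with_discordance(rng, 15, 3)
        sizes = []
        h = 1
        while True:
            try:
                sizes.append(len(evda_min_set(pm, h)))
            except UnachievableDistanceError:
                break
            h += 1
        assert sizes == sorted(sizes)

    def test_unachievable_h_reports_maximum(self, rng):
        pm = matrix_with_discordance(rng, 8, 3)
        with pytest.raises(UnachievableDistanceError) as exc:
            evda_min_set(pm, 10**6)
        achievable = exc.value.achievable
        if achievable >= 1:
            evda_min_set(pm, achievable)  # the reported maximum is attainable

    def test_sorted_plan_prefixes_satisfy_level_constraints(self, rng):
        for _ in range(10):
            pm = matrix_with_discordance(rng, 12, 3)
            try:
                plan = evda_sort(pm, "auto")
            except NothingToDiscriminateError:
                continue
            # replay: find where each level's minimal set is complete
            for h in range(1, plan.steps[-1].min_hamming_after + 1):
                level = evda_min_set(pm, h)
                cut = max(
                    plan.instance_ids.index(iid) for iid in level
                    if iid in plan.instance_ids
                ) + 1
                assert min(hamming_vector(pm, list(plan.prefix(cut)))) >= h


class TestRandomSort:
    def test_pool_of_one(self):
        pm = PredictionMatrix(
            ("i0", "i1"), ("a", "b"), np.array([[0, 1], [1, 1]])
        )
        plan = random_sort(pm, "D", seed=0)
        assert plan.instance_ids == ("i0",)

    def test_same_seed_identical_order(self, rng):
        pm = matrix_with_discordance(rng, 25, 3)
        assert random_sort(pm, "D", seed=9) == random_sort(pm, "D", seed=9)

    def test_uprime_pool_is_rows_with_any_call(self, rng):
        pm = matrix_with_discordance(rng, 25, 3)
        plan = random_sort(pm, "Uprime", seed=0)
        expected = {
            iid for iid, row in zip(pm.instance_ids, pm.calls) if row.max() == 1
        }
        assert set(plan.instance_ids) == expected

    def test_first_element_uniform(self):
        pm = PredictionMatrix(
            tuple(f"i{k}" for k in range(5)),
            ("a", "b"),
            np.column_stack([np.ones(5, dtype=int), np.zeros(5, dtype=int)]),
        )
        counts = {iid: 0 for iid in pm.instance_ids}
        reps = 10_000
        for s in range(reps):
            counts[random_sort(pm, "D", seed=s).instance_ids[0]] += 1
        for c in counts.values():
            assert abs(c / reps - 0.2) <= 0.02


class TestReferenceAlgorithms:
    def test_appends_constant_columns(self, rng):
        pm = matrix_with_discordance(rng, 20, 3)
        aug = add_reference_algorithms(pm)
        assert aug.n_algorithms == pm.n_algorithms + 2
        at = aug.calls[:, aug.algorithm_index("AllTrue")]
        af = aug.calls[:, aug.algorithm_index("AllFalse")]
        assert at.sum() == aug.n_instances and af.sum() == 0

    def test_name_collision_rejected(self, rng):
        pm = matrix_with_discordance(rng, 10, 3)
        with pytest.raises(ValueError, match="AllTrue"):
            add_reference_algorithms(add_reference_algorithms(pm))

    def test_every_mixed_or_partial_row_becomes_discordant(self, rng):
        pm = random_matrix(rng, 40, 3)
        aug = add_reference_algorithms(pm)
        # after augmentation every single instance disagrees between AllTrue
        # and AllFalse, hence D is the full instance set
        assert discordant_set(aug) == set(aug.instance_ids)
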