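import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxdce import defaults
from vaxdce.design_space import (
    AttributeSpec,
    ChoiceTask,
    Profile,
    assign_blocks,
    block_balance_test,
    chain,
    code_profile,
    coded_columns,
    count_unique_pairs,
    d_optimal_select,
    design_from_frame,
    design_to_frame,
    enumerate_full_factorial,
    information_matrix,
    is_dominant_pair,
    johnson_orme_min_n,
    sample_candidate_pairs,
)


def make_attrs(level_counts):
    return [
        AttributeSpec(name=f"a{i}", levels=tuple(f"l{i}_{j}" for j in range(k)))
        for i, k in enumerate(level_counts)
    ]


# ---------------------------------------------------------------------------
# enumeration


class TestFullFactorial:
    def test_study_grid_yields_2592_profiles(self, attrs):
        assert len(enumerate_full_factorial(attrs)) == 2592

    def test_single_two_level_attribute(self):
        assert len(enumerate_full_factorial(make_attrs([2]))) == 2

    def test_matches_nested_loop_listing(self):
        attrs = make_attrs([2, 3])
        got = enumerate_full_factorial(attrs)
        expected = [
            Profile({"a0": x, "a1": y})
            for x in attrs[0].levels
            for y in attrs[1].levels
        ]
        assert got == expected

    def test_profiles_are_distinct(self):
        profs = enumerate_full_factorial(make_attrs([3, 2, 2]))
        assert len(set(profs)) == len(profs)

    def test_empty_attribute_list_raises(self):
        with pytest.raises(ValueError):
            enumerate_full_factorial([])

    def test_single_level_attribute_rejected(self):
        with pytest.raises(ValueError):
            AttributeSpec(name="bad", levels=("only",))

    @given(st.lists(st.integers(min_value=2, max_value=4), min_size=1, max_size=4))
    @settings(max_examples=25, deadline=None)
    def test_count_is_product_of_level_counts(self, level_counts):
        got = enumerate_full_factorial(make_attrs(level_counts))
        assert len(got) == math.prod(level_counts)


class TestCountUniquePairs:
    def test_study_profile_count(self):
        assert count_unique_pairs(2592) == 3_357_936

    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3)])
    def test_small_cases(self, n, expected):
        assert count_unique_pairs(n) == expected

    def test_rejects_fewer_than_two(self):
        with pytest.raises(ValueError):
            count_unique_pairs(1)

    @given(st.integers(min_value=2, max_value=200))
    @settings(max_examples=30, deadline=None)
    def test_matches_explicit_enumeration(self, n):
        assert count_unique_pairs(n) == len(list(itertools.combinations(range(n), 2)))

    def test_sample_candidate_pairs_distinct_and_seeded(self):
        profs = enumerate_full_factorial(make_attrs([3, 3, 2]))
        tasks = sample_candidate_pairs(profs, 40, seed=5)
        pairs = {(id(t.profile_a), id(t.profile_b)) for t in tasks}
        assert len(tasks) == 40 and len(pairs) == 40
        again = sample_candidate_pairs(profs, 40, seed=5)
        assert [(t.profile_a, t.profile_b) for t in tasks] == [
            (t.profile_a, t.profile_b) for t in again
        ]


# ---------------------------------------------------------------------------
# information matrix


def random_tasks(attrs, n, seed):
    profs = enumerate_full_factorial(attrs)
    return sample_candidate_pairs(profs, n, seed=seed)


class TestInformationMatrix:
    def test_identical_coded_rows_give_zero_matrix(self):
        # two distinct labels sharing one numeric value code identically
        attrs = [
            AttributeSpec(
                name="x",
                levels=("p", "q"),
                coding="continuous",
                numeric_values={"p": 1.0, "q": 1.0},
            )
        ]
        task = ChoiceTask(1, Profile({"x": "p"}), Profile({"x": "q"}))
        M = information_matrix([task], np.zeros(1), attrs)
        assert np.allclose(M, 0.0)

    def test_binary_difference_closed_form(self):
        attrs = make_attrs([2])
        a, b = enumerate_full_factorial(attrs)
        task = ChoiceTask(1, a, b)
        M = information_matrix([task], np.zeros(1), attrs)
        dx = code_profile(a, attrs) - code_profile(b, attrs)
        assert np.allclose(M, 0.25 * np.outer(dx, dx))

    def test_matches_numeric_hessian_of_expected_loglik(self):
        attrs = make_attrs([2, 3])
        tasks = random_tasks(attrs, 3, seed=2)
        k = len(coded_columns(attrs))
        beta0 = np.zeros(k)

        def expected_ll(beta):
            total = 0.0
            for t in tasks:
                X = np.vstack(
                    [code_profile(t.profile_a, attrs), code_profile(t.profile_b, attrs)]
                )
                p_true = np.full(2, 0.5)  # probabilities at beta0 = 0
                u = X @ beta
                logp = u - np.log(np.exp(u).sum())
                total += p_true @ logp
            return total

        h = 1e-5
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                ei, ej = np.eye(k)[i] * h, np.eye(k)[j] * h
                H[i, j] = (
                    expected_ll(beta0 + ei + ej)
                    - expected_ll(beta0 + ei - ej)
                    - expected_ll(beta0 - ei + ej)
                    + expected_ll(beta0 - ei - ej)
                ) / (4 * h * h)
        M = information_matrix(tasks, beta0, attrs)
        assert np.allclose(M, -H, atol=1e-5)

    def test_symmetric_psd(self, attrs):
        tasks = random_tasks(attrs, 8, seed=3)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=len(coded_columns(attrs))) * 0.2
        M = information_matrix(tasks, beta, attrs)
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() > -1e-10

    def test_adding_task_never_shrinks_eigenvalues(self, attrs):
        tasks = random_tasks(attrs, 6, seed=4)
        beta = np.zeros(len(coded_columns(attrs)))
        M = information_matrix(tasks[:5], beta, attrs)
        M2 = information_matrix(tasks, beta, attrs)
        ev, ev2 = np.linalg.eigvalsh(M), np.linalg.eigvalsh(M2)
        assert (ev2 >= ev - 1e-10).all()  # Weyl: adding a PSD term

    def test_dimension_mismatch_raises(self, attrs):
        tasks = random_tasks(attrs, 1, seed=0)
        with pytest.raises(ValueError):
            information_matrix(tasks, np.zeros(3), attrs)


# ---------------------------------------------------------------------------
# D-optimal exchange


class TestDOptimalSelect:
    def test_all_candidates_returned_when_n_sets_equals_pool(self):
        attrs = make_attrs([2, 2, 2])
        cands = random_tasks(attrs, 6, seed=1)
        d = d_optimal_select(cands, attrs, n_sets=6, seed=0)
        assert len(d.tasks) == 6
        M = information_matrix(cands, np.zeros(3), attrs)
        assert d.criterion_value == pytest.approx(np.linalg.slogdet(M)[1])

    def test_attains_exhaustive_optimum_on_toy_space(self):
        attrs = make_attrs([2, 2, 2])
        cands = random_tasks(attrs, 6, seed=8)
        beta0 = np.zeros(3)
        best = -np.inf
        for combo in itertools.combinations(range(6), 3):
            M = information_matrix([cands[i] for i in combo], beta0, attrs)
            sign, ld = np.linalg.slogdet(M)
            if sign > 0:
                best = max(best, ld)
        d = d_optimal_select(cands, attrs, n_sets=3, seed=0)
        assert d.criterion_value == pytest.approx(best, abs=1e-9)

    def test_criterion_history_non_decreasing(self, attrs):
        cands = random_tasks(attrs, 300, seed=2)
        d = d_optimal_select(cands, attrs, n_sets=25, seed=1)
        hist = d.criterion_history
        assert all(b >= a - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_beats_random_designs(self, attrs):
        cands = random_tasks(attrs, 600, seed=3)
        d = d_optimal_select(cands, attrs, n_sets=20, seed=1)
        beta0 = np.zeros(len(coded_columns(attrs)))
        rng = np.random.default_rng(0)
        for _ in range(50):
            pick = rng.choice(len(cands), size=20, replace=False)
            M = information_matrix([cands[i] for i in pick], beta0, attrs)
            sign, ld = np.linalg.slogdet(M)
            assert sign <= 0 or ld <= d.criterion_value + 1e-9

    def test_deterministic_given_seed(self, attrs):
        cands = random_tasks(attrs, 400, seed=5)
        d1 = d_optimal_select(cands, attrs, n_sets=15, seed=9, n_candidate_sample=200)
        d2 = d_optimal_select(cands, attrs, n_sets=15, seed=9, n_candidate_sample=200)
        assert [t.task_id for t in d1.tasks] == [t.task_id for t in d2.tasks]
        assert d1.criterion_value == d2.criterion_value

    def test_singular_pool_raises(self):
        attrs = make_attrs([2, 2])
        a, b = enumerate_full_factorial(attrs)[:2]
        cands = [ChoiceTask(i, a, b) for i in range(4)]  # rank-1 pool
        with pytest.raises(ValueError):
            d_optimal_select(cands, attrs, n_sets=2, seed=0)

    def test_n_sets_larger_than_pool_raises(self, attrs):
        cands = random_tasks(attrs, 5, seed=0)
        with pytest.raises(ValueError):
            d_optimal_select(cands, attrs, n_sets=6, seed=0)


# ---------------------------------------------------------------------------
# blocking


class TestAssignBlocks:
    def test_40_tasks_into_8_blocks_of_5(self, attrs):
        from vaxdce.design_space import Design

        tasks = random_tasks(attrs, 40, seed=0)
        d = assign_blocks(Design(tasks=tasks), n_blocks=8, seed=3)
        sizes = {}
        for t in d.nontrap_tasks:
            sizes[t.block_id] = sizes.get(t.block_id, 0) + 1
        assert sizes == {b: 5 for b in range(1, 9)}

    def test_singleton_blocks(self, attrs):
        from vaxdce.design_space import Design

        tasks = random_tasks(attrs, 5, seed=1)
        d = assign_blocks(Design(tasks=tasks), n_blocks=5, seed=0)
        assert sorted(t.block_id for t in d.nontrap_tasks) == [1, 2, 3, 4, 5]

    def test_same_seed_same_partition(self, attrs):
        from vaxdce.design_space import Design

        tasks = random_tasks(attrs, 12, seed=2)
        d1 = assign_blocks(Design(tasks=tasks), n_blocks=4, seed=11)
        d2 = assign_blocks(Design(tasks=tasks), n_blocks=4, seed=11)
        assert [t.block_id for t in d1.tasks] == [t.block_id for t in d2.tasks]

    def test_non_divisible_raises(self, attrs):
        from vaxdce.design_space import Design

        tasks = random_tasks(attrs, 10, seed=3)
        with pytest.raises(ValueError):
            assign_blocks(Design(tasks=tasks), n_blocks=3, seed=0)

    def test_trap_task_keeps_no_block(self, attrs):
        from vaxdce.design_space import Design

        tasks = random_tasks(attrs, 4, seed=4) + [defaults.study_trap_task(attrs)]
        d = assign_blocks(Design(tasks=tasks), n_blocks=2, seed=0)
        assert d.trap_tasks[0].block_id is None


class TestBlockBalance:
    def test_equal_counts_statistic_zero(self):
        stat, p = block_balance_test([5] * 8)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        stat, _ = block_balance_test([10, 20])  # E = 15 each
        assert stat == pytest.approx(10 / 3)

    @pytest.mark.parametrize("k", [1, 3, 17])
    def test_scale_invariance_of_zero_statistic(self, k):
        stat, _ = block_balance_test([5 * k] * 8)
        assert stat == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            block_balance_test([7])
        with pytest.raises(ValueError):
            block_balance_test([0, 0])


# ---------------------------------------------------------------------------
# dominance and sample size


class TestDominance:
    def test_trap_pair_a_dominates(self, attrs):
        t = defaults.study_trap_task(attrs)
        assert is_dominant_pair(t.profile_a, t.profile_b, attrs) == "a_dominates"

    def test_identical_profiles_none(self, attrs):
        p = enumerate_full_factorial(attrs)[0]
        assert is_dominant_pair(p, p, attrs) == "none"

    def test_trade_off_pair_none(self, attrs):
        t = defaults.study_trap_task(attrs)
        # a keeps the better effectiveness but b becomes free: a trade-off
        a = t.profile_a
        b_assign = dict(t.profile_b.assignment)
        b_assign["cost"] = "Free"
        a_assign = dict(a.assignment)
        a_assign["cost"] = "Rs. 2000"
        assert is_dominant_pair(Profile(a_assign), Profile(b_assign), attrs) == "none"

    def test_origin_difference_blocks_dominance(self, attrs):
        t = defaults.study_trap_task(attrs)
        b_like_a = dict(t.profile_a.assignment)
        b_like_a["origin"] = "Imported product"  # incomparable attribute differs
        assert is_dominant_pair(t.profile_a, Profile(b_like_a), attrs) == "none"

    def test_mirror_symmetry(self, attrs):
        profs = enumerate_full_factorial(attrs)
        rng = np.random.default_rng(1)
        for _ in range(100):
            i, j = rng.choice(len(profs), 2, replace=False)
            fwd = is_dominant_pair(profs[i], profs[j], attrs)
            rev = is_dominant_pair(profs[j], profs[i], attrs)
            mirror = {"a_dominates": "b_dominates", "b_dominates": "a_dominates", "none": "none"}
            assert rev == mirror[fwd]


class TestJohnsonOrme:
    @pytest.mark.parametrize(
        "c,t,a,expected", [(6, 5, 2, 300), (2, 5, 2, 100), (6, 6, 2, 250)]
    )
    def test_values(self, c, t, a, expected):
        assert johnson_orme_min_n(c, t, a) == expected

    def test_rounds_up(self):
        assert johnson_orme_min_n(3, 7, 2) == 108  # 1500/14 = 107.14...

    @pytest.mark.parametrize("bad", [(0, 5, 2), (6, 0, 2), (6, 5, -1)])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            johnson_orme_min_n(*bad)


# ---------------------------------------------------------------------------
# partial orders and CSV round trip


class TestAttributeSpec:
    def test_chain_is_transitively_closed(self):
        pairs = set(chain(["a", "b", "c"]))
        assert ("a", "c") in pairs

    def test_cyclic_preference_rejected(self):
        with pytest.raises(ValueError):
            AttributeSpec(
                name="x",
                levels=("a", "b"),
                preference_order=(("a", "b"), ("b", "a")),
            )

    def test_reference_must_be_a_level(self):
        with pytest.raises(ValueError):
            AttributeSpec(name="x", levels=("a", "b"), reference_level="z")

    def test_continuous_needs_numeric_values(self):
        with pytest.raises(ValueError):
            AttributeSpec(name="x", levels=("a", "b"), coding="continuous")


def test_design_csv_round_trip(design, attrs, tmp_path):
    frame = design_to_frame(design, attrs)
    back = design_from_frame(frame, attrs)
    assert len(back.tasks) == len(design.tasks)
    by_id = {t.task_id: t for t in design.tasks}
    for t in back.tasks:
        orig = by_id[t.task_id]
        assert t.profile_a == orig.profile_a
        assert t.profile_b == orig.profile_b
        assert t.is_trap == orig.is_trap
        assert t.block_id == orig.block_id
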