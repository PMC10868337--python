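import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_instance
from drcombo.optimize import (
    AnnealConfig,
    DegenerateSelectionError,
    MoleculeLibrary,
    ObjectiveConfig,
    Selection,
    accept_probability,
    anneal,
    exhaustive_oracle,
    f_corr,
    f_mole,
    objective,
    propose_neighbor,
)
from drcombo.signature import DRSignature


def make_sig(values):
    values = np.asarray(values, dtype=float)
    return DRSignature(0.0, [f"g{i}" for i in range(values.size)], values,
                       np.zeros(values.size))


def make_lib(columns):
    Y = np.asarray(columns, dtype=float).T
    return MoleculeLibrary([f"M{i}" for i in range(Y.shape[1])], Y)


class TestFMole:
    def test_within_budget_is_one(self):
        cfg = ObjectiveConfig(n=100, T=10, t=3)
        assert f_mole(5, cfg) == 1.0
        assert f_mole(10, cfg) == 1.0  # boundary of the branch

    def test_closed_form_beyond_budget(self):
        cfg = ObjectiveConfig(n=100, T=10, t=3)
        assert f_mole(12, cfg) == pytest.approx(math.exp(-16.0), rel=1e-15)

    @given(st.integers(1, 99))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_and_one_iff_small(self, k):
        cfg = ObjectiveConfig(n=100, T=10, t=3)
        assert f_mole(k, cfg) <= f_mole(max(k - 1, 1), cfg) + 1e-15
        assert (f_mole(k, cfg) == 1.0) == (k <= cfg.T)


class TestFCorr:
    def test_affine_match_is_one(self):
        lib = make_lib([[0, 1, 2, 3]])
        sig = make_sig([1, 2, 3, 4])
        assert f_corr(Selection(frozenset({0}), 1), lib, sig) == pytest.approx(1.0)

    def test_hand_computed_negative(self):
        lib = make_lib([[3, 1, 2, 0]])
        sig = make_sig([1, 2, 3, 4])
        assert f_corr(Selection(frozenset({0}), 1), lib, sig) == pytest.approx(-0.8)

    def test_constant_sum_degenerate(self):
        lib = make_lib([[1, 1, 1, 1]])
        with pytest.raises(DegenerateSelectionError):
            f_corr(Selection(frozenset({0}), 1), lib, make_sig([1, 2, 3, 4]))

    def test_sum_not_mean(self):
        # two identical molecules: the summed signature doubles, correlation unchanged
        lib = make_lib([[0, 1, 2, 3], [0, 1, 2, 3], [5, -1, 2, 2]])
        sig = make_sig([1, 2, 3, 4])
        assert f_corr(Selection(frozenset({0, 1}), 3), lib, sig) == pytest.approx(1.0)


class TestObjective:
    def test_perfect_match_attains_two(self):
        lib = make_lib([[0, 1, 2, 3]])
        cfg = ObjectiveConfig(n=1, T=1, t=3)
        f = objective(Selection(frozenset({0}), 1), lib, make_sig([1, 2, 3, 4]), cfg)
        assert f == pytest.approx(2.0, abs=1e-12)

    def test_component_sum(self):
        lib = make_lib([[3, 1, 2, 0]])
        cfg = ObjectiveConfig(n=1, T=1, t=3)
        f = objective(Selection(frozenset({0}), 1), lib, make_sig([1, 2, 3, 4]), cfg)
        assert f == pytest.approx(0.2)

    def test_bounded_by_two_on_random_instances(self):
        cfg = ObjectiveConfig(n=12, T=3, t=3)
        for seed in range(200):
            lib, sig = random_instance(seed, s=15, n=12)
            rng = np.random.default_rng(seed)
            k = int(rng.integers(1, 13))
            sel = Selection(frozenset(int(i) for i in rng.choice(12, k, replace=False)), 12)
            assert objective(sel, lib, sig, cfg) <= 2.0 + 1e-12


class TestProposeNeighbor:
    def test_forced_add_at_k_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = propose_neighbor(Selection(frozenset({1}), 4), rng)
            assert out.k == 2 and 1 in out.index_set

    def test_forced_remove_at_k_n(self):
        rng = np.random.default_rng(0)
        full = Selection(frozenset(range(4)), 4)
        for _ in range(20):
            assert propose_neighbor(full, rng).k == 3

    def test_hamming_distance_always_one(self):
        rng = np.random.default_rng(5)
        sel = Selection(frozenset({0, 2}), 6)
        for _ in range(200):
            nxt = propose_neighbor(sel, rng)
            assert int(np.abs(nxt.binary_vector - sel.binary_vector).sum()) == 1
            sel = nxt

    def test_no_neighborhood_for_single_molecule(self):
        with pytest.raises(ValueError):
            propose_neighbor(Selection(frozenset({0}), 1), np.random.default_rng(0))


class TestAcceptProbability:
    def test_improvement_certain(self):
        assert accept_probability(1.0, 1.5, iteration=10, n=100) == 1.0

    def test_equal_scores_certain(self):
        assert accept_probability(1.2, 1.2, iteration=999, n=100) == 1.0

    def test_worsening_closed_form(self):
        p = accept_probability(1.5, 1.4, iteration=100, n=100)
        assert p == pytest.approx(math.exp(-0.1), rel=1e-12)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.integers(1, 10**6), st.integers(1, 2000))
    @settings(max_examples=100, deadline=None)
    def test_valid_probability(self, fc, fp, it, n):
        assert 0.0 <= accept_probability(fc, fp, it, n) <= 1.0

    def test_monotone_non_increasing_in_iteration(self):
        ps = [accept_probability(1.5, 1.4, it, 100) for it in (1, 10, 100, 1000, 10000)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestExhaustiveOracle:
    def test_perfect_singleton(self):
        lib = make_lib([[0, 1, 2, 3], [3, 1, 2, 0], [1, 1, 2, 1]])
        sig = make_sig([1, 2, 3, 4])
        sel, f = exhaustive_oracle(lib, sig, ObjectiveConfig(n=3, T=3, t=3))
        assert sel.index_set == {0}
        assert f == pytest.approx(2.0, abs=1e-12)

    def test_tie_break_lexicographic(self):
        col = [0.0, 1.0, 2.0, 3.0]
        lib = make_lib([col, col, col])
        sig = make_sig([1, 2, 3, 4])
        sel, f = exhaustive_oracle(lib, sig, ObjectiveConfig(n=3, T=3, t=3))
        assert sel.index_set == {0}  # smallest bitmask among equal scorers

    def test_refuses_large_n(self):
        lib, sig = random_instance(0, s=5, n=12)
        with pytest.raises(ValueError, match="refusing"):
            exhaustive_oracle(lib, sig, ObjectiveConfig(n=12), max_n=10)

    def test_matches_plain_enumeration(self):
        """Cross-check the vectorized enumeration against a per-subset loop."""
        from itertools import combinations

        lib, sig = random_instance(123, s=8, n=6)
        cfg = ObjectiveConfig(n=6, T=2, t=3)
        best = max(
            (objective(Selection(frozenset(c), 6), lib, sig, cfg), sorted(c))
            for k in range(1, 7)
            for c in combinations(range(6), k)
        )
        sel, f = exhaustive_oracle(lib, sig, cfg)
        assert f == pytest.approx(best[0], abs=1e-12)


class TestAnneal:
    def test_single_molecule_library_rejected(self):
        lib = make_lib([[0, 1, 2, 3]])
        with pytest.raises(ValueError):
            anneal(lib, make_sig([1, 2, 3, 4]), ObjectiveConfig(n=1, T=1),
                   AnnealConfig(seed=0))

    def test_finds_planted_perfect_singleton(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=30)
        cols = [list(rng.normal(size=30)) for _ in range(11)] + [list(2.0 * z + 1.0)]
        lib = make_lib(cols)
        sig = make_sig(z)
        res = anneal(lib, sig, ObjectiveConfig(n=12, T=10, t=3),
                     AnnealConfig(seed=4, max_iterations=10_000, restarts=3))
        assert res.prediction_score == pytest.approx(2.0, abs=1e-9)
        assert 11 in res.best_selection.index_set

    def test_deterministic_given_seed(self):
        lib, sig = random_instance(5)
        cfg = ObjectiveConfig(n=12)
        a = AnnealConfig(seed=77, max_iterations=5000, restarts=2)
        r1 = anneal(lib, sig, cfg, a)
        r2 = anneal(lib, sig, cfg, a)
        assert r1.best_selection == r2.best_selection
        assert r1.prediction_score == r2.prediction_score
        np.testing.assert_array_equal(r1.trace, r2.trace)
        assert r1.accepted_moves == r2.accepted_moves

    def test_prediction_score_is_trace_max_and_at_least_initial(self):
        lib, sig = random_instance(8)
        res = anneal(lib, sig, ObjectiveConfig(n=12),
                     AnnealConfig(seed=1, max_iterations=3000))
        assert res.prediction_score == pytest.approx(res.trace[:, 2].max())
        assert res.prediction_score >= res.trace[0, 1] - 1e-12
        # best column is the running max of the current column
        np.testing.assert_allclose(res.trace[:, 2],
                                   np.maximum.accumulate(res.trace[:, 1]), atol=1e-9)

    def test_matches_oracle_on_seeded_instance(self):
        lib, sig = random_instance(0)
        cfg = ObjectiveConfig(n=12)
        _, fstar = exhaustive_oracle(lib, sig, cfg)
        res = anneal(lib, sig, cfg, AnnealConfig(seed=0, max_iterations=50_000, restarts=3))
        assert res.prediction_score == pytest.approx(fstar, abs=1e-12)

    def test_all_constant_library_degenerate(self):
        lib = make_lib([[1, 1, 1, 1], [2, 2, 2, 2]])
        with pytest.raises(DegenerateSelectionError):
            anneal(lib, make_sig([1, 2, 3, 4]), ObjectiveConfig(n=2, T=2),
                   AnnealConfig(seed=0, max_iterations=100))
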