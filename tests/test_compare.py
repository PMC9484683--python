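import itertools

import numpy as np
import pytest

from epsckit.compare import (
    assign_events,
    distance_matrix,
    match_event_sets,
    missed_rate,
    missed_rate_matrix,
)


def brute_force_assignment(cost):
    """Exhaustive max-cardinality / min-cost matching over feasible pairs.

    Independent oracle: enumerates every injective partial assignment of
    rows to columns and returns the best (cardinality, total cost).
    """
    n_a, n_b = cost.shape
    best = (0, 0.0)
    cols = range(n_b)
    for k in range(min(n_a, n_b), -1, -1):
        found = False
        best_cost = np.inf
        for rows in itertools.combinations(range(n_a), k):
            for perm in itertools.permutations(cols, k):
                c = 0.0
                ok = True
                for i, j in zip(rows, perm):
                    if not np.isfinite(cost[i, j]):
                        ok = False
                        break
                    c += cost[i, j]
                if ok:
                    found = True
                    best_cost = min(best_cost, c)
        if found:
            best = (k, best_cost)
            break
    return best


class TestDistanceMatrix:
    def test_identical_sets_zero_diagonal(self):
        t = np.array([0.1, 0.5, 0.9])
        C = distance_matrix(t, t, gamma=1e-3)
        np.testing.assert_array_equal(np.diag(C), 0.0)

    def test_far_pairs_unassignable(self):
        C = distance_matrix(np.array([0.0]), np.array([0.006]), gamma=2e-3)
        assert np.isinf(C[0, 0])

    def test_direct_substitution(self):
        C = distance_matrix(np.array([1.0]), np.array([1.0005]), gamma=1e-3)
        assert C[0, 0] == pytest.approx(0.0005)

    def test_empty_sets_valid(self):
        C = distance_matrix(np.array([]), np.array([1.0]), gamma=1e-3)
        assert C.shape == (0, 1)

    def test_bad_gamma_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(np.array([0.0]), np.array([0.0]), gamma=0.0)


class TestAssignment:
    def test_identical_sets_identity_matching(self):
        t = np.array([0.1, 0.2, 0.3])
        res = match_event_sets(t, t, gamma=1e-3)
        assert res.pairs == [(0, 0), (1, 1), (2, 2)]
        assert res.total_cost == 0.0

    def test_three_by_three_matches_permutation_minimum(self, rng):
        for _ in range(20):
            cost = rng.random((3, 3))
            res = assign_events(cost, gamma=np.inf)
            brute = min(
                sum(cost[i, p[i]] for i in range(3))
                for p in itertools.permutations(range(3))
            )
            assert res.total_cost == pytest.approx(brute)

    @pytest.mark.parametrize("trial", range(100))
    def test_oracle_equivalence_small_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_a = int(rng.integers(0, 7))
        n_b = int(rng.integers(0, 7))
        gamma = float(rng.uniform(0.002, 0.05))
        a = np.sort(rng.uniform(0, 0.2, n_a))
        b = np.sort(rng.uniform(0, 0.2, n_b))
        cost = distance_matrix(a, b, gamma)
        res = assign_events(cost, gamma)
        card, total = brute_force_assignment(cost)
        assert res.n_matched == card
        assert res.total_cost == pytest.approx(total, abs=1e-12)

    def test_transpose_symmetry(self, rng):
        a = np.sort(rng.uniform(0, 0.1, 5))
        b = np.sort(rng.uniform(0, 0.1, 7))
        res_ab = match_event_sets(a, b, gamma=5e-3)
        res_ba = match_event_sets(b, a, gamma=5e-3)
        assert res_ab.total_cost == pytest.approx(res_ba.total_cost)
        assert sorted((j, i) for i, j in res_ab.pairs) == sorted(res_ba.pairs)

    def test_matching_matrix_constraints(self, rng):
        a = np.sort(rng.uniform(0, 0.1, 6))
        b = np.sort(rng.uniform(0, 0.1, 4))
        res = match_event_sets(a, b, gamma=3e-3)
        assert res.X.sum(axis=0).max() <= 1
        assert res.X.sum(axis=1).max() <= 1
        for i, j in res.pairs:
            assert res.cost[i, j] <= res.gamma


class TestMissedRate:
    def test_identical_sets_zero(self):
        t = np.array([0.1, 0.2])
        assert missed_rate(t, t) == 0.0

    def test_empty_detector_misses_all(self):
        assert missed_rate(np.array([]), np.array([0.1, 0.2])) == 1.0

    def test_empty_reference_zero(self):
        assert missed_rate(np.array([0.1]), np.array([])) == 0.0

    def test_three_of_four_matched(self):
        reference = np.array([1.0, 2.0, 3.0, 4.0])
        a = np.array([1.0005, 2.0005, 3.0005])  # no partner for 4.0
        assert missed_rate(a, reference, gamma=2e-3) == pytest.approx(0.25)

    def test_non_increasing_in_gamma(self, rng):
        a = np.sort(rng.uniform(0, 1, 30))
        ref = np.sort(rng.uniform(0, 1, 25))
        rates = [missed_rate(a, ref, g) for g in (1e-3, 2e-3, 5e-3, 2e-2)]
        assert rates == sorted(rates, reverse=True)


class TestMissedRateMatrix:
    def test_identical_detectors_zero_offdiagonal(self):
        t = np.array([0.1, 0.2, 0.3])
        mat = missed_rate_matrix({"x": t, "y": t.copy()})
        assert mat.loc["x", "y"] == 0.0
        assert mat.loc["y", "x"] == 0.0

    def test_superset_asymmetry(self):
        sub = np.array([0.1, 0.3])
        sup = np.array([0.1, 0.2, 0.3, 0.4])
        mat = missed_rate_matrix({"sub": sub, "sup": sup})
        assert mat.loc["sup", "sub"] == 0.0      # superset misses nothing
        assert mat.loc["sub", "sup"] == pytest.approx(0.5)

    def test_entries_in_unit_interval(self, rng):
        sets = {f"d{i}": np.sort(rng.uniform(0, 1, 10 + i)) for i in range(3)}
        mat = missed_rate_matrix(sets)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()
        assert np.diag(mat.values).tolist() == [0.0, 0.0, 0.0]

    def test_single_detector_rejected(self):
        with pytest.raises(ValueError):
            missed_rate_matrix({"only": np.array([0.1])})
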