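"""Packing, nestedness temperature, modularity, runs test and BH."""

import igraph as ig
import numpy as np
import pytest

import gapmine as gm
from _oracles import exact_runs_lower_tail_p, temperature_oracle


# ----------------------------------------------------------------- packing
class TestPackMatrix:
    def test_staircase_already_packed(self):
        P = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=bool)
        packed = gm.pack_matrix(P)
        assert np.array_equal(packed.row_order, [0, 1, 2])
        assert np.array_equal(packed.col_order, [0, 1, 2])
        assert packed.fill == pytest.approx(6 / 9)

    def test_reversed_staircase_reverses(self):
        P = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=bool)
        rev = P[::-1, ::-1]
        packed = gm.pack_matrix(rev)
        assert np.array_equal(packed.row_order, [2, 1, 0])
        assert np.array_equal(packed.col_order, [2, 1, 0])

    def test_tied_marginals_deterministic(self):
        # rows 0 and 2 tie on count and on the opposite-margin sum; the
        # lexicographic pattern key in packed column order breaks the tie
        P = np.array([[1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=bool)
        packed = gm.pack_matrix(P)
        assert list(packed.row_order) == [1, 0, 2]
        assert list(packed.col_order) == [2, 0, 1]
        again = gm.pack_matrix(P)
        assert np.array_equal(packed.row_order, again.row_order)
        assert np.array_equal(packed.col_order, again.col_order)

    def test_marginals_non_increasing_after_packing(self, rng):
        P = rng.random((8, 6)) < 0.5
        P[0, 0] = True
        packed = gm.pack_matrix(P)
        Pp = P[np.ix_(packed.row_order, packed.col_order)]
        assert (np.diff(Pp.sum(axis=1)) <= 0).all()
        assert (np.diff(Pp.sum(axis=0)) <= 0).all()

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            gm.pack_matrix(np.zeros((3, 3), dtype=bool))


# ------------------------------------------------------------- temperature
class TestTemperature:
    def test_fully_observed_is_zero(self):
        assert gm.nestedness_temperature(np.ones((4, 5), bool)).T == 0.0

    def test_perfect_staircase_is_zero(self):
        P = gm.nested_mask(12, 10, 0.5)
        assert gm.nestedness_temperature(P).T == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_matches_frozen_oracle_value(self):
        # frozen from the independent geometric oracle in tests/_oracles.py
        cb = np.indices((4, 4)).sum(axis=0) % 2 == 0
        assert gm.nestedness_temperature(cb).T == pytest.approx(
            75.91559442433991, abs=1e-9
        )

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(20):
            m, n = rng.integers(4, 9, size=2)
            P = rng.random((m, n)) < rng.uniform(0.25, 0.75)
            if P.all() or not P.any():
                continue
            packed = gm.pack_matrix(P)
            Pp = P[np.ix_(packed.row_order, packed.col_order)]
            assert gm.nestedness_temperature(P).T == pytest.approx(
                temperature_oracle(Pp), abs=1e-9
            )

    def test_invariant_under_permutation(self, rng):
        P = rng.random((7, 6)) < 0.5
        P[0, 0] = True
        T = gm.nestedness_temperature(P).T
        for _ in range(5):
            pr, pc = rng.permutation(7), rng.permutation(6)
            assert gm.nestedness_temperature(P[np.ix_(pr, pc)]).T == pytest.approx(
                T, abs=1e-9
            )

    def test_single_swap_heats_a_nested_matrix(self):
        P = gm.nested_mask(6, 6, 0.5)
        assert gm.nestedness_temperature(P).T == pytest.approx(0.0, abs=1e-12)
        swapped = P.copy()
        # swap a deep presence with a far absence
        swapped[0, 0] = False
        swapped[-1, -1] = True
        assert gm.nestedness_temperature(swapped).T > 0.0

    def test_range_and_degenerate_input(self, rng):
        for _ in range(10):
            P = rng.random((5, 5)) < rng.random()
            if not P.any() or P.all():
                continue
            T = gm.nestedness_temperature(P).T
            assert 0.0 <= T <= 100.0
        with pytest.raises(ValueError):
            gm.nestedness_temperature(np.ones((1, 5), bool))


# -------------------------------------------------------------- modularity
class TestModularity:
    def test_single_community_is_zero(self):
        g = ig.Graph.Famous("Zachary")
        assert gm.modularity(g, [0] * g.vcount()) == pytest.approx(0.0)

    def test_two_disconnected_cliques_half(self):
        g = ig.Graph.Full(5) + ig.Graph.Full(5)
        g.es["weight"] = [1.0] * g.ecount()
        mem = [0] * 5 + [1] * 5
        assert gm.modularity(g, mem) == pytest.approx(0.5)

    def test_agrees_with_igraph(self, rng):
        g = ig.Graph.Erdos_Renyi(n=40, p=0.2)
        g.es["weight"] = rng.random(g.ecount()).tolist()
        mem = rng.integers(0, 4, size=40).tolist()
        assert gm.modularity(g, mem) == pytest.approx(
            g.modularity(mem, weights="weight"), abs=1e-12
        )

    def test_random_partition_near_zero(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            g = ig.Graph.Erdos_Renyi(n=60, p=0.3)
            mem = r.permutation(np.repeat([0, 1], 30)).tolist()
            assert abs(gm.modularity(g, mem)) < 0.2

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            gm.modularity(ig.Graph(3), [0, 0, 0])


# --------------------------------------------------------------- runs test
class TestRunsPermutationTest:
    def test_all_identical_labels(self):
        res = gm.runs_permutation_test(["A"] * 10, n_perm=200, seed=1)
        assert res.observed_runs == 1 and res.p_empirical == 1.0

    def test_aabb_exact_reference(self):
        # exhaustive: 6 distinct arrangements of AABB, 2 with runs <= 2
        assert exact_runs_lower_tail_p(list("AABB")) == pytest.approx(1 / 3)
        res = gm.runs_permutation_test(list("AABB"), n_perm=5000, seed=3)
        se = np.sqrt((1 / 3) * (2 / 3) / 5001)
        assert abs(res.p_empirical - 1 / 3) < 3 * se

    def test_three_blocks_hit_floor(self):
        labels = ["a"] * 100 + ["b"] * 100 + ["c"] * 100
        res = gm.runs_permutation_test(labels, n_perm=5000, seed=5)
        assert res.observed_runs == 3
        assert res.p_empirical == pytest.approx(1 / 5001)

    def test_deterministic_given_seed(self):
        labels = list("AABBABABAB")
        a = gm.runs_permutation_test(labels, n_perm=500, seed=9)
        b = gm.runs_permutation_test(labels, n_perm=500, seed=9)
        assert a.p_empirical == b.p_empirical

    def test_single_element_raises(self):
        with pytest.raises(ValueError):
            gm.runs_permutation_test(["A"], seed=0)


# ---------------------------------------------------------------------- BH
class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert gm.bh_adjust([0.04]) == [pytest.approx(0.04)]

    def test_all_equal_unchanged(self):
        assert gm.bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_closed_form_floor_case(self):
        # six permutation floors among eight tests adjust to 8/(6*5001)
        p = [1 / 5001] * 6 + [0.0077, 0.161]
        adj = gm.bh_adjust(p)
        assert adj[:6] == pytest.approx([8 / (6 * 5001)] * 6)
        assert f"{adj[0]:.2g}" == "0.00027"
        assert adj[6] == pytest.approx(0.0077 * 8 / 7)
        assert adj[7] == pytest.approx(0.161)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(1e-6, 1.0, size=20)
        adj = np.asarray(gm.bh_adjust(p))
        assert (adj <= 1.0).all() and (adj >= p).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            gm.bh_adjust([0.0, 0.5])


def test_significance_codes():
    assert gm.significance_code(0.00027) == "***"
    assert gm.significance_code(0.0103) == "*"
    assert gm.significance_code(0.215) == "ns"
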