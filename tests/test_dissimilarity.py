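"""The weighted Jensen-Shannon dissimilarity and its weight contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import traceclust as tc
from traceclust.errors import ConfigurationError, NoCoactiveWeeksError

from conftest import make_process
from oracles import eq1_dissimilarity_oracle, js_distance_oracle


def random_processes(rng, n_actors, T, M=3, p_active=0.8):
    procs = []
    for i in range(n_actors):
        C = np.where(rng.random(T) < p_active, rng.integers(25, 200, size=T), 0)
        P = rng.dirichlet(np.ones(M), size=T)
        procs.append(
            make_process(f"a{i:02d}", [(2019, w + 1) for w in range(T)], P, C)
        )
    return procs


class TestJsDistance:
    def test_identity_of_indiscernibles(self):
        p = np.array([0.2, 0.3, 0.5])
        assert tc.js_distance(p, p) == 0.0

    def test_disjoint_support_attains_one(self):
        assert tc.js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        p, q = [0.5, 0.5], [0.25, 0.75]
        assert tc.js_distance(p, q) == pytest.approx(
            js_distance_oracle(p, q), abs=1e-12
        )

    def test_divergence_without_root(self):
        p, q = [0.5, 0.5], [0.25, 0.75]
        assert tc.js_distance(p, q, sqrt=False) == pytest.approx(
            js_distance_oracle(p, q) ** 2, abs=1e-12
        )

    def test_natural_log_base_rescales(self):
        p, q = [0.9, 0.1], [0.1, 0.9]
        d2 = tc.js_distance(p, q, base=2.0)
        de = tc.js_distance(p, q, base=np.e)
        assert de == pytest.approx(d2 * np.sqrt(np.log(2)), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.js_distance([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ConfigurationError):
            tc.js_distance([-0.1, 1.1], [0.5, 0.5])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 10.0), min_size=3, max_size=3),
        st.lists(st.floats(0.01, 10.0), min_size=3, max_size=3),
        st.lists(st.floats(0.01, 10.0), min_size=3, max_size=3),
    )
    def test_metric_axioms(self, a, b, c):
        p = np.array(a) / np.sum(a)
        q = np.array(b) / np.sum(b)
        r = np.array(c) / np.sum(c)
        dpq = tc.js_distance(p, q)
        assert 0.0 <= dpq <= 1.0
        assert dpq == pytest.approx(tc.js_distance(q, p), abs=1e-12)
        assert tc.js_distance(p, q) + tc.js_distance(q, r) >= tc.js_distance(p, r) - 1e-12


class TestPairWeights:
    def test_single_overlapping_week(self):
        w = tc.pair_weights([10, 0, 5], [2, 7, 0])
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])

    def test_symmetric_counts(self):
        np.testing.assert_allclose(tc.pair_weights([1, 1], [1, 1]), [0.5, 0.5])

    def test_direct_arithmetic(self):
        np.testing.assert_allclose(
            tc.pair_weights([3, 4], [5, 2]), [15 / 23, 8 / 23], atol=1e-15
        )

    def test_no_coactive_week_signalled(self):
        with pytest.raises(NoCoactiveWeeksError):
            tc.pair_weights([1, 0], [0, 1])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            C_i = rng.integers(0, 100, size=12)
            C_j = rng.integers(0, 100, size=12)
            if (C_i * C_j).sum() == 0:
                continue
            w = tc.pair_weights(C_i, C_j)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w[(C_i == 0) | (C_j == 0)] == 0)


class TestPairwiseDissimilarity:
    def test_identical_processes_distance_zero(self, toy_window):
        P = [[0.4, 0.6]] * 4
        pa = make_process("a", toy_window, P, [10, 20, 0, 5])
        pb = make_process("b", toy_window, P, [3, 9, 7, 0])
        m = tc.pairwise_dissimilarity([pa, pb])
        assert m.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_coactive_week_equals_that_js(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [0, 0, 0, 10])
        pb = make_process("b", toy_window, [[0.5, 0.5]] * 4, [5, 0, 0, 10])
        m = tc.pairwise_dissimilarity([pa, pb])
        assert m.D[0, 1] == pytest.approx(
            tc.js_distance([1.0, 0.0], [0.5, 0.5]), abs=1e-12
        )

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            procs = random_processes(rng, n_actors=6, T=15)
            m = tc.pairwise_dissimilarity(procs)
            for i in range(6):
                for j in range(i + 1, 6):
                    expected = eq1_dissimilarity_oracle(
                        procs[i].P, procs[j].P, procs[i].C, procs[j].C
                    )
                    assert m.D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal_in_unit_interval(self):
        rng = np.random.default_rng(7)
        procs = random_processes(rng, n_actors=8, T=10)
        m = tc.pairwise_dissimilarity(procs)
        np.testing.assert_array_equal(m.D, m.D.T)
        np.testing.assert_array_equal(np.diag(m.D), 0.0)
        assert np.all((m.D >= 0) & (m.D <= 1))

    def test_inactive_weeks_never_influence(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [10, 0, 0, 10])
        pb = make_process("b", toy_window, [[0.3, 0.7]] * 4, [10, 9, 0, 10])
        d1 = tc.pairwise_dissimilarity([pa, pb]).D[0, 1]
        # perturb P on weeks where either count is zero
        P2 = pa.P.copy()
        P2[1] = [0.0, 1.0]
        P2[2] = [0.5, 0.5]
        pa2 = tc.ThemeProcess("a", pa.weeks, P2, pa.C)
        d2 = tc.pairwise_dissimilarity([pa2, pb]).D[0, 1]
        assert d1 == d2

    def test_missing_pair_max_policy(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [10, 0, 0, 0])
        pb = make_process("b", toy_window, [[1.0, 0.0]] * 4, [0, 10, 0, 0])
        m = tc.pairwise_dissimilarity([pa, pb], missing_pair="max")
        assert m.D[0, 1] == 1.0
        assert m.undefined_pairs == [("a", "b")]

    def test_missing_pair_drop_policy(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [10, 0, 0, 0])
        pb = make_process("b", toy_window, [[1.0, 0.0]] * 4, [0, 10, 0, 0])
        pc = make_process("c", toy_window, [[1.0, 0.0]] * 4, [10, 10, 0, 0])
        m = tc.pairwise_dissimilarity([pa, pb, pc], missing_pair="drop")
        assert len(m.actor_ids) == 2 and "c" in m.actor_ids

    def test_fewer_than_two_processes_rejected(self, toy_window):
        pa = make_process("a", toy_window, [[1.0, 0.0]] * 4, [10, 0, 0, 0])
        with pytest.raises(ConfigurationError):
            tc.pairwise_dissimilarity([pa])

    def test_triangle_inequality_can_fail(self):
        """The pair-specific weights break the metric property.

        Actors a and c are deterministic opposites; b agrees with each of
        them on the week where their joint activity concentrates, so both
        d(a,b) and d(b,c) are tiny while d(a,c) = 1.
        """
        window = [(2019, 1), (2019, 2)]
        pa = make_process("a", window, [[1.0, 0.0], [1.0, 0.0]], [100, 1])
        pb = make_process("b", window, [[1.0, 0.0], [0.0, 1.0]], [10, 10])
        pc = make_process("c", window, [[0.0, 1.0], [0.0, 1.0]], [1, 100])
        m = tc.pairwise_dissimilarity([pa, pb, pc])
        d_ab, d_bc, d_ac = m.D[0, 1], m.D[1, 2], m.D[0, 2]
        assert d_ac > d_ab + d_bc

    def test_csv_round_trip(self, toy_window, tmp_path):
        rng = np.random.default_rng(1)
        procs = random_processes(rng, 4, 4)
        m = tc.pairwise_dissimilarity(procs)
        m.to_csv(tmp_path / "D.csv")
        back = tc.DissimilarityMatrix.from_csv(tmp_path / "D.csv")
        assert back.actor_ids == m.actor_ids
        np.testing.assert_allclose(back.D, m.D, atol=1e-12)
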