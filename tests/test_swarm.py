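"""Swarm operations and the full optimizer on small oracle graphs."""

import numpy as np
import pytest

from udpso import (
    Partition,
    UPSOConfig,
    modularity,
    run_pso,
    run_upso,
    run_upso_fixed_k,
)
from udpso.swarm import (
    centroid_update,
    decode_position,
    fitness,
    inertia_weight,
    regulate,
    update_velocity_position,
)
from udpso.swarm import _batch_fitness

from conftest import brute_force_max_modularity, random_weighted_graph

SMALL_CFG = UPSOConfig(n_pop=20, t_max=50, s_subspaces=2, q0=11, seed=0)


class _PinnedRng:
    """Stub RNG returning a fixed uniform value."""

    def __init__(self, value):
        self.value = value

    def random(self, shape=()):
        return np.full(shape, self.value) if shape else self.value


class TestDecode:
    def test_hand_computed_distances(self, two_edge_graph):
        position = np.concatenate([[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]])
        part = decode_position(position, two_edge_graph, 2)
        assert part.labels.tolist() == [0, 0, 1, 1]

    def test_exact_centroid_rows(self, two_edge_graph):
        rows = two_edge_graph.adjacency
        position = np.concatenate([rows[0], rows[2]])
        part = decode_position(position, two_edge_graph, 2)
        assert part.labels[0] == 0 and part.labels[2] == 1

    def test_tie_goes_to_lowest_community(self, two_edge_graph):
        position = np.concatenate([[0.3, 0.3, 0.3, 0.3]] * 3)
        part = decode_position(position, two_edge_graph, 3)
        assert np.all(part.labels == 0)

    def test_length_mismatch(self, two_edge_graph):
        with pytest.raises(ValueError):
            decode_position(np.zeros(7), two_edge_graph, 2)


class TestFitness:
    def test_optimal_position(self, two_edge_graph):
        position = np.concatenate([[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]])
        q, part = fitness(position, two_edge_graph, 2)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert part.effective_k == 2

    def test_k1_is_zero(self, two_edge_graph):
        q, _ = fitness(np.random.default_rng(0).random(4), two_edge_graph, 1)
        assert q == pytest.approx(0.0, abs=1e-15)

    def test_matches_public_modularity(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            g = random_weighted_graph(seed, 7)
            pos = rng.random(3 * g.n)
            q, part = fitness(pos, g, 3)
            assert q == pytest.approx(modularity(g, part), abs=1e-12)

    def test_batch_agrees_with_scalar(self):
        g = random_weighted_graph(3, 6)
        rng = np.random.default_rng(9)
        batch = rng.random((8, 2 * g.n))
        qs, labels = _batch_fitness(batch, g, 2)
        for i in range(8):
            q, part = fitness(batch[i], g, 2)
            assert qs[i] == pytest.approx(q, abs=1e-12)
            assert np.array_equal(labels[i], part.labels)


class TestCentroidUpdate:
    def test_single_member(self, two_edge_graph):
        part = Partition(np.array([0, 1, 1, 1]), 2)
        cents = centroid_update(part, two_edge_graph)
        assert np.array_equal(cents[0], two_edge_graph.adjacency[0])

    def test_pair_mean(self, two_edge_graph):
        part = Partition(np.array([0, 0, 1, 1]), 2)
        cents = centroid_update(part, two_edge_graph)
        assert np.allclose(cents[0], [0.5, 0.5, 0, 0])
        assert np.allclose(cents[1], [0, 0, 0.5, 0.5])

    def test_empty_community_keeps_previous(self, two_edge_graph):
        part = Partition(np.array([0, 0, 0, 0]), 2)
        prev = np.arange(8, dtype=float).reshape(2, 4) / 10
        cents = centroid_update(part, two_edge_graph, previous=prev)
        assert np.array_equal(cents[1], prev[1])


class TestRegulate:
    def test_accept_if_strictly_better(self, two_edge_graph):
        bad = np.concatenate([[1, 0, 0, 1], [0, 1, 1, 0]]).astype(float)
        q0, part0 = fitness(bad, two_edge_graph, 2)
        _, q1, _, _ = regulate(bad, q0, part0, two_edge_graph, 2)
        assert q1 >= q0

    def test_fixed_point_unchanged(self, two_edge_graph):
        opt = np.concatenate([[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]])
        q, part = fitness(opt, two_edge_graph, 2)
        pos1, q1, _, kc = regulate(opt, q, part, two_edge_graph, 2)
        # equal fitness must NOT be accepted (strict >)
        assert np.array_equal(pos1, opt)
        assert q1 == q
        assert np.allclose(kc, opt)


class TestVelocityUpdate:
    def test_fixed_point(self):
        x = np.full(4, 0.4)
        x2, s2 = update_velocity_position(x, np.zeros(4), x, x, x, 0.5, 2, 2, 2, _PinnedRng(0.5))
        assert np.array_equal(x2, x)
        assert np.array_equal(s2, np.zeros(4))

    def test_pure_inertia(self):
        x = np.full(3, 0.5)
        s = np.full(3, 0.1)
        _, s2 = update_velocity_position(x, s, x, x, x, 1.0, 0, 0, 0, _PinnedRng(0.5))
        assert np.allclose(s2, s)

    def test_hand_computed_step(self):
        # s' = 0.5*0 + 2*0.5*(0.4-0.2) + 2*0.5*(0.6-0.2) + 2*0.5*(0.2-0.2) = 0.6
        x2, s2 = update_velocity_position(
            np.array([0.2]), np.array([0.0]), np.array([0.4]), np.array([0.6]),
            np.array([0.2]), 0.5, 2, 2, 2, _PinnedRng(0.5),
        )
        assert s2[0] == pytest.approx(0.6, abs=1e-12)
        assert x2[0] == pytest.approx(0.8, abs=1e-12)

    def test_clamping(self):
        x2, s2 = update_velocity_position(
            np.array([0.9]), np.array([0.0]), np.array([0.9]), np.array([0.9]),
            np.array([0.9]), 1.0, 2, 2, 2, _PinnedRng(1.0), vector_r=False,
        )
        assert -1.0 <= s2[0] <= 1.0
        assert 0.0 <= x2[0] <= 1.0


class TestInertiaWeight:
    @pytest.mark.parametrize("t,expected", [(0, 1.0), (50, 0.55), (100, 0.1)])
    def test_linear_schedule(self, t, expected):
        assert inertia_weight(t, 100, 0.1, 1.0) == pytest.approx(expected)

    def test_zero_tmax_rejected(self):
        with pytest.raises(ValueError):
            inertia_weight(0, 0, 0.1, 1.0)


class TestFixedKRun:
    def test_two_edge_optimum(self, two_edge_graph):
        res = run_upso_fixed_k(two_edge_graph, 2, SMALL_CFG)
        assert res.best_q == pytest.approx(0.5, abs=1e-9)
        assert res.partition.effective_k == 2

    def test_trace_nondecreasing(self, two_triangles):
        res = run_upso_fixed_k(two_triangles, 3, SMALL_CFG)
        assert np.all(np.diff(res.trace) >= -1e-15)

    def test_seeded_determinism(self, two_triangles):
        a = run_upso_fixed_k(two_triangles, 2, SMALL_CFG, rng=np.random.default_rng(7))
        b = run_upso_fixed_k(two_triangles, 2, SMALL_CFG, rng=np.random.default_rng(7))
        assert a.best_q == b.best_q
        assert np.array_equal(a.partition.labels, b.partition.labels)
        assert np.array_equal(a.trace, b.trace)

    def test_invalid_k(self, two_edge_graph):
        with pytest.raises(ValueError):
            run_upso_fixed_k(two_edge_graph, 0, SMALL_CFG)
        with pytest.raises(ValueError):
            run_upso_fixed_k(two_edge_graph, 5, SMALL_CFG)

    def test_termination_cause(self, two_edge_graph):
        res = run_upso_fixed_k(two_edge_graph, 2, SMALL_CFG)
        assert res.termination in ("t_max", "stall")
        if res.termination == "stall":
            assert res.n_iterations < SMALL_CFG.t_max


class TestKSweep:
    def test_two_triangles_matches_oracle(self, two_triangles):
        cfg = UPSOConfig(n_pop=20, t_max=50, s_subspaces=2, q0=11, seed=1, k_min=1, k_max=6)
        res = run_upso(two_triangles, cfg)
        oracle_q, _ = brute_force_max_modularity(two_triangles)
        assert res.best_q == pytest.approx(oracle_q, abs=1e-9)
        assert res.chosen_k == 2
        assert len(res.per_k_history) == 6
        assert res.best_q == pytest.approx(max(res.per_k_history.values()))

    def test_k1_only(self, two_edge_graph):
        cfg = UPSOConfig(n_pop=10, t_max=10, s_subspaces=2, q0=11, seed=0, k_min=1, k_max=1)
        res = run_upso(two_edge_graph, cfg)
        assert res.best_q == pytest.approx(0.0, abs=1e-15)
        assert res.chosen_k == 1

    def test_positions_bounded_via_partition_validity(self, two_triangles):
        cfg = UPSOConfig(n_pop=15, t_max=20, s_subspaces=2, q0=11, seed=3, k_min=2, k_max=3)
        res = run_upso(two_triangles, cfg)
        assert res.best_partition.labels.min() >= 0
        assert res.best_partition.labels.max() < res.best_partition.k

    def test_kmax_validation(self, two_edge_graph):
        with pytest.raises(ValueError, match="k_max"):
            run_upso(two_edge_graph, UPSOConfig(n_pop=10, s_subspaces=2, q0=11, k_min=3, k_max=2))


class TestPSOAblation:
    def test_reaches_easy_optimum(self, two_edge_graph):
        cfg = UPSOConfig(n_pop=30, t_max=50, s_subspaces=4, q0=11, seed=2, k_min=2, k_max=2)
        res = run_pso(two_edge_graph, cfg)
        assert res.best_q == pytest.approx(0.5, abs=1e-9)
        assert res.method == "pso"

    def test_seeded_determinism(self, two_triangles):
        cfg = UPSOConfig(n_pop=15, t_max=30, s_subspaces=2, q0=11, seed=11, k_min=2, k_max=3)
        a = run_pso(two_triangles, cfg)
        b = run_pso(two_triangles, cfg)
        assert a.best_q == b.best_q
        assert np.array_equal(a.best_partition.labels, b.best_partition.labels)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="power of two"):
            UPSOConfig(s_subspaces=3).validate()
        with pytest.raises(ValueError, match="Q0 and Q1"):
            UPSOConfig(q0=9).validate()
        with pytest.raises(ValueError, match="S\\*Q0"):
            UPSOConfig(n_pop=100, s_subspaces=2, q0=31).validate()
        UPSOConfig().validate()
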