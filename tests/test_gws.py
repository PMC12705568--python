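"""Glowworm swarm optimization: phase rules, hand-checked iteration, search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neurofuse import (
    GlowwormSwarm,
    SwarmConfig,
    concave_quadratic,
    gws_optimize,
    luciferin_update,
    move,
    neighbor_set,
    range_update,
    select_neighbor,
)
from neurofuse.image import InvalidParameterError, NeurofuseError


class TestLuciferinUpdate:
    def test_hand_value(self):
        assert luciferin_update(5.0, 10.0, rho=0.4, z=0.6) == pytest.approx(9.0)

    def test_full_decay_limit(self):
        assert luciferin_update(123.0, 10.0, rho=1 - 1e-13, z=0.6) == pytest.approx(6.0, abs=1e-9)

    def test_invalid_rho(self):
        for rho in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidParameterError):
                luciferin_update(1.0, 1.0, rho=rho, z=0.6)

    @pytest.mark.parametrize("rho", [0.4, 0.5, 0.6])
    def test_constant_fitness_fixed_point(self, rho):
        z, fitness = 0.6, 3.0
        k_star = z * fitness / rho
        k = 0.0
        for _ in range(100):
            k = luciferin_update(k, fitness, rho, z)
        assert abs(k - k_star) < 1e-6


def _swarm(positions, luciferin, cfg=None, ranges=None):
    cfg = cfg or SwarmConfig(population=len(positions))
    pos = np.asarray(positions, dtype=float).reshape(len(positions), -1)
    lo = np.full(pos.shape[1], -10.0)
    return GlowwormSwarm(pos, cfg, (lo, -lo), luciferin=np.asarray(luciferin, float),
                         ranges=ranges)


class TestNeighborSet:
    def test_brightest_has_no_neighbors(self):
        sw = _swarm([[0.0], [0.1], [0.2]], [1.0, 2.0, 3.0])
        assert neighbor_set(sw, 2).size == 0

    def test_dimmer_sees_brighter_within_range(self):
        sw = _swarm([[0.0], [0.5]], [1.0, 2.0])
        assert list(neighbor_set(sw, 0)) == [1]
        assert neighbor_set(sw, 1).size == 0

    def test_boundary_distance_excluded(self):
        sw = _swarm([[0.0], [1.0]], [1.0, 2.0])  # range exactly 1.0
        assert neighbor_set(sw, 0).size == 0


class TestSelectNeighbor:
    def test_single_neighbor_certain(self):
        sw = _swarm([[0.0], [0.5]], [1.0, 2.0])
        rng = np.random.default_rng(0)
        assert select_neighbor(sw, 0, np.array([1]), rng) == 1

    def test_empty_neighbors_is_contract_violation(self):
        sw = _swarm([[0.0], [0.5]], [1.0, 2.0])
        with pytest.raises(NeurofuseError):
            select_neighbor(sw, 0, np.array([], dtype=int), np.random.default_rng(0))

    def test_excess_proportional_probabilities(self):
        # excesses 1 and 3 -> selection frequencies 0.25 / 0.75
        sw = _swarm([[0.0], [0.1], [0.2]], [1.0, 2.0, 4.0])
        rng = np.random.default_rng(42)
        draws = np.array([select_neighbor(sw, 0, np.array([1, 2]), rng)
                          for _ in range(10_000)])
        assert np.isclose((draws == 1).mean(), 0.25, atol=0.02)
        assert np.isclose((draws == 2).mean(), 0.75, atol=0.02)

    def test_equal_excess_uniform(self):
        sw = _swarm([[0.0], [0.1], [0.2]], [1.0, 3.0, 3.0])
        rng = np.random.default_rng(7)
        draws = np.array([select_neighbor(sw, 0, np.array([1, 2]), rng)
                          for _ in range(10_000)])
        counts = [(draws == 1).sum(), (draws == 2).sum()]
        assert stats.chisquare(counts).pvalue > 0.01


class TestMove:
    def test_unit_vector_step(self):
        assert np.allclose(move(np.zeros(2), np.array([3.0, 4.0]), 1.0), [0.6, 0.8])

    def test_zero_distance_guard(self):
        p = np.array([1.0, 2.0])
        assert np.array_equal(move(p, p.copy(), 0.05), p)

    def test_full_distance_lands_on_neighbor(self):
        a, b = np.array([1.0, 1.0]), np.array([4.0, 5.0])
        assert np.allclose(move(a, b, 5.0), b)


class TestRangeUpdate:
    def test_hand_value(self):
        assert range_update(2.0, 3, beta=0.08, m_s=5, q_t=5.0, range_min=0.0) == pytest.approx(2.16)

    def test_clamps(self):
        assert range_update(0.1, 1000, 0.08, 5, 5.0, 0.0) == 0.0
        r = 4.9
        for _ in range(10):
            r = range_update(r, 0, 0.08, 5, 5.0, 0.0)
        assert r == 5.0

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 5), st.integers(0, 50), st.floats(0.01, 0.5))
    def test_result_always_within_clamps(self, r, n, beta):
        out = range_update(r, n, beta, 5, 5.0, 0.0)
        assert 0.0 <= out <= 5.0


class TestHandIteration:
    """One synchronous 3-worm iteration against a fully hand-evaluated update."""

    def test_matches_hand_computation(self):
        cfg = SwarmConfig(population=3, rho=0.4, z=0.6, step=0.1, beta=0.08,
                          m_s=5, q0=1.0, q_t=5.0, range_min=0.0, seed=0)
        sw = _swarm([[0.0], [0.4], [1.0]], [1.0, 2.0, 3.0], cfg)
        sw.iterate(lambda p: float(p[0]))  # fitness = position
        # luciferin: 0.6*k + 0.6*I -> (0.6, 1.44, 2.4)
        assert np.allclose(sw.luciferin, [0.6, 1.44, 2.4], atol=1e-12)
        # neighbor sets: N0={1} (worm 2 at distance exactly 1.0 is excluded),
        # N1={2}, N2={} -> deterministic follower moves of step 0.1
        assert sw.positions[0, 0] == pytest.approx(0.1, abs=1e-12)
        assert sw.positions[1, 0] == pytest.approx(0.5, abs=1e-12)
        # brightest worm falls back to a bounded random step
        assert abs(sw.positions[2, 0] - 1.0) <= cfg.step + 1e-12
        # ranges: 1 + 0.08*(5 - (1,1,0)) = (1.32, 1.32, 1.4)
        assert np.allclose(sw.ranges, [1.32, 1.32, 1.4], atol=1e-12)
        assert sw.best_fitness == pytest.approx(1.0)
        assert sw.best_position[0] == pytest.approx(1.0)


class TestOptimize:
    def test_quadratic_recovery(self):
        center = np.array([0.3, -0.2])
        best, fit, trace = gws_optimize(concave_quadratic(center), 2, (-1.0, 1.0),
                                        SwarmConfig(seed=1))
        assert np.linalg.norm(best - center) < 0.05
        assert len(trace.best_fitness) == 150

    def test_constant_objective_random_search_stays_in_bounds(self):
        cfg = SwarmConfig(population=10, iterations=50, seed=3)
        best, fit, _ = gws_optimize(lambda p: 1.5, 1, (-0.5, 0.5), cfg)
        assert fit == 1.5
        sw = GlowwormSwarm.initialize(1, (np.array([-0.5]), np.array([0.5])), cfg)
        for _ in range(50):
            sw.iterate(lambda p: 1.5)
            assert np.all(sw.positions >= -0.5) and np.all(sw.positions <= 0.5)

    def test_best_fitness_trace_non_decreasing(self):
        _, _, trace = gws_optimize(concave_quadratic(np.zeros(2)), 2, (-1, 1),
                                   SwarmConfig(iterations=60, seed=5))
        assert np.all(np.diff(trace.best_fitness) >= 0)

    def test_seeded_determinism_bitwise(self):
        cfg = SwarmConfig(population=15, iterations=40, seed=9)
        obj = concave_quadratic(np.array([0.1, 0.2]))
        b1, f1, t1 = gws_optimize(obj, 2, (-1, 1), cfg)
        b2, f2, t2 = gws_optimize(obj, 2, (-1, 1), cfg)
        assert np.array_equal(b1, b2) and f1 == f2
        assert np.array_equal(np.array(t1.best_fitness), np.array(t2.best_fitness))
        assert np.array_equal(np.array(t1.mean_luciferin), np.array(t2.mean_luciferin))

    def test_nan_objective_raises_with_position(self):
        with pytest.raises(NeurofuseError, match="position"):
            gws_optimize(lambda p: float("nan"), 1, (-1, 1), SwarmConfig(iterations=2))

    def test_luciferin_nonnegative_under_nonnegative_fitness(self):
        cfg = SwarmConfig(population=8, iterations=30, seed=2)
        sw = GlowwormSwarm.initialize(2, (np.full(2, -1.0), np.full(2, 1.0)), cfg)
        for _ in range(30):
            sw.iterate(lambda p: float(np.abs(p).sum()))
            assert np.all(sw.luciferin >= 0)
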