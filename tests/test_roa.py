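import math

import numpy as np
import pytest

from roacnn import roa


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestSearchSpace:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            roa.SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_zero_dimension_rejected(self):
        with pytest.raises(ValueError):
            roa.SearchSpace.box(0)

    def test_default_box_matches_reference_bounds(self):
        space = roa.SearchSpace.box(3)
        assert np.all(space.lower == -10.0)
        assert np.all(space.upper == 10.0)


class TestInitializePopulation:
    def test_all_coordinates_within_bounds(self):
        space = roa.SearchSpace.box(3, 1.0, 5.0)
        swarm = roa.initialize_population(space, roa.ROAConfig(population=50, seed=3))
        pts = np.array([s.position for s in swarm])
        assert pts.shape == (50, 3)
        assert np.all((pts >= 1.0) & (pts <= 5.0))

    def test_same_seed_identical_population(self):
        space = roa.SearchSpace.box(4)
        cfg = roa.ROAConfig(population=10, seed=7)
        a = roa.initialize_population(space, cfg)
        b = roa.initialize_population(space, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.position, sb.position)
            assert sa.host_flag == sb.host_flag

    def test_prev_position_starts_equal(self):
        swarm = roa.initialize_population(roa.SearchSpace.box(2), roa.ROAConfig(population=5, seed=0))
        for s in swarm:
            np.testing.assert_array_equal(s.position, s.prev_position)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            roa.ROAConfig(population=0)


class TestInertiaWeight:
    def test_flat_before_switch(self):
        cfg = roa.ROAConfig(max_iter=100, inertia_switch=0.5)
        for t in range(0, 50):
            assert roa.inertia_weight(t, cfg) == 0.9

    def test_sigmoid_tail_value(self):
        # frozen from 1 / (1 + exp(10*100/100 - 2)) = 1 / (1 + e^8)
        cfg = roa.ROAConfig(max_iter=100)
        assert roa.inertia_weight(100, cfg) == pytest.approx(1.0 / (1.0 + math.exp(8.0)), abs=1e-15)
        assert roa.inertia_weight(100, cfg) == pytest.approx(3.3535013e-4, rel=1e-6)

    def test_non_increasing_and_bounded(self):
        cfg = roa.ROAConfig(max_iter=100)
        values = [roa.inertia_weight(t, cfg) for t in range(101)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0.0 < v <= 0.9 for v in values)

    def test_out_of_range_rejected(self):
        cfg = roa.ROAConfig(max_iter=10)
        with pytest.raises(ValueError):
            roa.inertia_weight(11, cfg)
        with pytest.raises(ValueError):
            roa.inertia_weight(-1, cfg)


class TestMoves:
    def test_sfo_zero_fixed_point(self):
        out = roa.sfo_move(np.zeros(2), np.zeros(2), 0.37)
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_sfo_direct_evaluation(self):
        # r_best - (u*(r_best + r_rand)/2 - r_rand) with u=1: 2 - (1 - 0) = 1
        out = roa.sfo_move(np.array([2.0]), np.array([0.0]), 1.0)
        np.testing.assert_allclose(out, [1.0])

    def test_sfo_shape_mismatch(self):
        with pytest.raises(ValueError):
            roa.sfo_move(np.zeros(2), np.zeros(3), 0.5)

    def test_experience_attack_zero_step(self):
        r = np.array([1.5, -2.0])
        np.testing.assert_array_equal(roa.experience_attack(r, r, 1.7), r)

    def test_experience_attack_direct(self):
        out = roa.experience_attack(np.array([1.0]), np.array([0.0]), 0.5)
        np.testing.assert_allclose(out, [1.5])

    def test_experience_attack_zero_draw(self):
        out = roa.experience_attack(np.array([3.0, 4.0]), np.array([1.0, 1.0]), 0.0)
        np.testing.assert_array_equal(out, [3.0, 4.0])

    def test_woa_zero_distance(self):
        r = np.array([1.0, 2.0])
        np.testing.assert_allclose(roa.woa_move(r, r, 5, 10, 0.3), r)

    def test_woa_scale_endpoints(self):
        assert roa.woa_scale(0, 100) == -1.0
        assert roa.woa_scale(100, 100) == -2.0

    def test_woa_zero_draw_direct(self):
        # u=0 -> alpha=1 -> step is d * e * cos(2*pi) = d * e
        r_i = np.array([0.0])
        r_best = np.array([2.0])
        out = roa.woa_move(r_i, r_best, 0, 100, 0.0)
        np.testing.assert_allclose(out, [2.0 * math.e])

    def test_host_volume_endpoints(self):
        assert roa.host_volume(0, 100) == 2.0
        assert roa.host_volume(100, 100) == 0.0

    def test_host_feeding_final_iteration_no_move(self):
        cfg = roa.ROAConfig(max_iter=10)
        r = np.array([3.0, -1.0])
        np.testing.assert_allclose(roa.host_feeding_move(r, np.zeros(2), 10, cfg, 0.9), r)

    def test_host_feeding_midpoint_draw_no_move(self):
        cfg = roa.ROAConfig(max_iter=10)
        r = np.array([3.0, -1.0])
        np.testing.assert_allclose(roa.host_feeding_move(r, np.ones(2), 4, cfg, 0.5), r)

    def test_host_feeding_direct(self):
        # t=0, u=1: V=2, B=2 -> step = w(0)*2*(r - 0.1*r_best)
        cfg = roa.ROAConfig(max_iter=10, remora_factor=0.1)
        r = np.array([1.0])
        r_best = np.array([2.0])
        out = roa.host_feeding_move(r, r_best, 0, cfg, 1.0)
        expected = 1.0 + 0.9 * 2.0 * (1.0 - 0.1 * 2.0)
        np.testing.assert_allclose(out, [expected])


class TestSchedules:
    def test_full_schedule_ranges(self):
        cfg = roa.ROAConfig(max_iter=100)
        for t in range(101):
            a = roa.woa_scale(t, cfg.max_iter)
            V = roa.host_volume(t, cfg.max_iter)
            w = roa.inertia_weight(t, cfg)
            assert -2.0 <= a <= -1.0
            assert 0.0 <= V <= 2.0
            assert 0.0 < w <= 0.9
            for u in (0.0, 0.25, 0.5, 0.75, 1.0):
                B = 2.0 * V * u - V
                assert -V <= B <= V


class TestClip:
    def test_clip_basic(self):
        space = roa.SearchSpace.box(2)
        np.testing.assert_array_equal(
            roa.clip_to_bounds(np.array([12.0, -12.0]), space), [10.0, -10.0]
        )

    def test_clip_identity_in_bounds(self):
        space = roa.SearchSpace.box(2)
        p = np.array([1.0, -9.9])
        np.testing.assert_array_equal(roa.clip_to_bounds(p, space), p)

    def test_clip_random_positions_feasible(self, rng):
        space = roa.SearchSpace(np.array([-3.0, 0.0, 5.0]), np.array([-1.0, 2.0, 6.0]))
        for _ in range(200):
            p = rng.normal(scale=20, size=3)
            out = roa.clip_to_bounds(p, space)
            assert np.all((out >= space.lower) & (out <= space.upper))


class TestOptimize:
    def test_sphere_elitist_trace_non_increasing(self):
        trace = roa.optimize(sphere, roa.SearchSpace.box(2), roa.ROAConfig(seed=0))
        assert len(trace.best_fitness) == 101
        assert np.all(np.diff(trace.best_fitness) <= 0)

    def test_sphere_converges(self):
        finals = []
        for seed in range(20):
            trace = roa.optimize(sphere, roa.SearchSpace.box(2), roa.ROAConfig(seed=seed))
            finals.append(trace.best_fitness[-1])
        assert np.median(finals) <= 1e-2

    def test_constant_objective(self):
        trace = roa.optimize(lambda x: 5.0, roa.SearchSpace.box(2), roa.ROAConfig(population=5, max_iter=10, seed=1))
        np.testing.assert_array_equal(trace.best_fitness, np.full(11, 5.0))

    def test_same_seed_bit_identical(self):
        cfg = roa.ROAConfig(population=8, max_iter=20, seed=42)
        a = roa.optimize(sphere, roa.SearchSpace.box(3), cfg)
        b = roa.optimize(sphere, roa.SearchSpace.box(3), cfg)
        np.testing.assert_array_equal(a.best_fitness, b.best_fitness)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.evaluations == b.evaluations

    def test_visited_positions_feasible(self):
        space = roa.SearchSpace.box(3, -2.0, 2.0)
        seen = []

        def watcher(x):
            seen.append(np.array(x))
            return sphere(x)

        roa.optimize(watcher, space, roa.ROAConfig(population=6, max_iter=15, seed=9))
        pts = np.array(seen)
        assert np.all((pts >= -2.0) & (pts <= 2.0))

    def test_non_finite_objective_reports_position(self):
        def bad(x):
            return math.nan

        with pytest.raises(ValueError, match="non-finite"):
            roa.optimize(bad, roa.SearchSpace.box(2), roa.ROAConfig(population=2, max_iter=2, seed=0))

    def test_single_agent_single_iteration_matches_step_oracle(self):
        """Replay the documented draw protocol by hand for N=1, Tmax=1."""
        space = roa.SearchSpace.box(2, -4.0, 4.0)
        cfg = roa.ROAConfig(population=1, max_iter=1, seed=11)

        rng = np.random.default_rng(cfg.seed)
        pos = rng.uniform(space.lower, space.upper)
        host = int(rng.integers(0, 2))
        fit = sphere(pos)
        best_pos, best_fit = pos.copy(), fit

        u_move = float(rng.uniform())
        if host == 0:
            moved = roa.woa_move(pos, best_pos, 1, 1, u_move)
        else:
            mate = int(rng.integers(0, 1))
            moved = roa.sfo_move(best_pos, pos, u_move)
        moved = np.clip(moved, space.lower, space.upper)
        probe = np.clip(roa.experience_attack(moved, pos, float(rng.standard_normal())), space.lower, space.upper)
        probe_fit = sphere(probe)
        if probe_fit < fit:
            new_pos, new_fit = probe, probe_fit
            rng.integers(0, 2)
        else:
            fed = roa.host_feeding_move(moved, best_pos, 1, cfg, float(rng.uniform()))
            new_pos = np.clip(fed, space.lower, space.upper)
            new_fit = sphere(new_pos)
        expected_best = min(best_fit, new_fit)

        trace = roa.optimize(sphere, space, cfg)
        assert trace.best_fitness[0] == pytest.approx(best_fit)
        assert trace.best_fitness[1] == pytest.approx(expected_best)

    def test_initial_positions_override(self):
        space = roa.SearchSpace.box(2)
        cfg = roa.ROAConfig(population=3, max_iter=1, seed=5)
        start = np.array([[0.0, 0.0]])
        trace = roa.optimize(sphere, space, cfg, initial_positions=start)
        assert trace.best_fitness[0] == 0.0  # seeded agent sits at the optimum

    def test_trace_json_roundtrip(self):
        import json

        trace = roa.optimize(sphere, roa.SearchSpace.box(2), roa.ROAConfig(population=4, max_iter=5, seed=2))
        payload = json.loads(trace.to_json())
        assert payload["seed"] == 2
        assert len(payload["best_fitness"]) == 6
        assert payload["config"]["population"] == 4
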