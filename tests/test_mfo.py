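"""Moth-flame optimizer: update rules, elitism, convergence, determinism."""

import math

import numpy as np
import pytest

from mfocnn.exceptions import ConfigurationError
from mfocnn.mfo import (
    FlameSet,
    MFOConfig,
    MothPopulation,
    flame_count,
    init_population,
    round_half_away,
    run_mfo,
    spiral_update,
    update_flames,
)


class TestFlameCount:
    @pytest.mark.parametrize(
        "t, T, N, expected",
        [
            (30, 30, 20, 1),  # last iteration: single flame
            (1, 30, 20, 19),  # round(20 - 19/30) = round(19.367)
            (10, 30, 20, 14),  # round(20 - 190/30) = round(13.667)
        ],
    )
    def test_schedule_values(self, t, T, N, expected):
        assert flame_count(t, T, N) == expected

    def test_monotone_nonincreasing_and_endpoints(self):
        counts = [flame_count(t, 30, 20) for t in range(1, 31)]
        assert counts[0] <= 20
        assert counts[-1] == 1
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert all(c >= 1 for c in counts)

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            flame_count(31, 30, 20)

    def test_half_away_from_zero_rounding(self):
        # np.round would give 2 at 2.5; the schedule requires 3
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.4) == 2


class TestSpiralUpdate:
    def test_zero_distance_fixed_point(self):
        flame = np.array([0.3, -1.2, 4.0])
        for t in (-1.0, -0.5, 0.0, 0.7, 1.0):
            np.testing.assert_allclose(spiral_update(flame, flame, 1.0, t), flame)

    def test_hand_evaluated_points(self):
        # D=1, t=0: 1*e^0*cos(0) + 0 = 1
        np.testing.assert_allclose(spiral_update([1.0], [0.0], 1.0, 0.0), [1.0])
        # t=-1: e^-1 * cos(-2pi) = 0.36788
        np.testing.assert_allclose(
            spiral_update([1.0], [0.0], 1.0, -1.0), [math.exp(-1)], rtol=1e-12
        )

    def test_signed_distance_variant_differs(self):
        sym = spiral_update([-1.0], [0.0], 1.0, 0.25)
        signed = spiral_update([-1.0], [0.0], 1.0, 0.25, signed_distance=True)
        assert sym[0] == pytest.approx(-signed[0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            spiral_update([1.0, 2.0], [0.0], 1.0, 0.0)


class TestUpdateFlames:
    def test_first_iteration_is_sorted_moths(self):
        moths = MothPopulation(
            positions=np.arange(8.0).reshape(4, 2),
            fitness=np.array([3.0, 1.0, 2.0, 0.5]),
        )
        flames = update_flames(moths, None, 4)
        np.testing.assert_array_equal(flames.fitness, [0.5, 1.0, 2.0, 3.0])
        np.testing.assert_array_equal(flames.positions[0], [6.0, 7.0])

    def test_elitism_keeps_previous_best(self):
        moths = MothPopulation(
            positions=np.ones((3, 1)), fitness=np.array([0.5, 0.9, 0.7])
        )
        previous = FlameSet(positions=np.zeros((1, 1)), fitness=np.array([0.1]))
        flames = update_flames(moths, previous, 3)
        assert flames.fitness[0] == 0.1

    def test_matches_exhaustive_sort(self, rng):
        moth_fit = rng.uniform(size=5)
        flame_fit = rng.uniform(size=5)
        moths = MothPopulation(positions=rng.normal(size=(5, 3)), fitness=moth_fit)
        previous = FlameSet(positions=rng.normal(size=(5, 3)), fitness=np.sort(flame_fit))
        flames = update_flames(moths, previous, 3)
        expected = np.sort(np.concatenate([moth_fit, flame_fit]))[:3]
        np.testing.assert_allclose(flames.fitness, expected)

    def test_invalid_flame_count_rejected(self):
        moths = MothPopulation(positions=np.ones((2, 1)), fitness=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            update_flames(moths, None, 0)


class TestInitPopulation:
    def test_seeded_reproducibility(self):
        cfg = MFOConfig(bounds=[(0, 1), (0, 1)], n_moths=3, seed=42)
        a = init_population(cfg).positions
        b = init_population(cfg).positions
        np.testing.assert_array_equal(a, b)

    def test_bound_containment_narrow_interval(self):
        cfg = MFOConfig(bounds=[(5.0, 5.0001)], n_moths=50, seed=0)
        pos = init_population(cfg).positions
        assert (pos >= 5.0).all() and (pos <= 5.0001).all()

    def test_six_dim_search_space_shape(self):
        from mfocnn.search_space import default_space

        cfg = MFOConfig(bounds=default_space().bounds, n_moths=20, seed=1)
        pos = init_population(cfg).positions
        assert pos.shape == (20, 6)
        assert (pos[:, 0] >= 40).all() and (pos[:, 0] <= 100).all()

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            MFOConfig(bounds=[(1.0, 1.0)])


class TestRunMFO:
    def test_constant_objective(self):
        cfg = MFOConfig(bounds=[(-1, 1)] * 2, n_moths=4, max_iter=3, seed=0)
        res = run_mfo(lambda x: 7.5, cfg)
        assert res.best_fitness == 7.5
        assert res.trace["best_fitness"].iloc[0] == 7.5

    def test_single_moth_single_iteration(self):
        cfg = MFOConfig(bounds=[(0, 1)], n_moths=1, max_iter=1, seed=3)
        pop = init_population(cfg)
        res = run_mfo(lambda x: float(x[0]), cfg)
        assert res.best_fitness == pytest.approx(float(pop.positions[0, 0]))

    def test_trace_best_fitness_nonincreasing(self):
        cfg = MFOConfig(bounds=[(-5, 5)] * 2, n_moths=10, max_iter=30, seed=5)
        res = run_mfo(lambda x: float(np.sum(x**2)), cfg)
        best = res.trace["best_fitness"].to_numpy()
        assert (np.diff(best) <= 0).all()
        assert len(res.trace) == 30

    def test_positions_respect_bounds(self):
        seen = []
        cfg = MFOConfig(bounds=[(-2, 3), (0, 1)], n_moths=8, max_iter=20, seed=9)

        def objective(x):
            seen.append(x.copy())
            return float(np.sum(x**2))

        run_mfo(objective, cfg)
        arr = np.array(seen)
        assert (arr[:, 0] >= -2).all() and (arr[:, 0] <= 3).all()
        assert (arr[:, 1] >= 0).all() and (arr[:, 1] <= 1).all()

    def test_seeded_determinism_bit_identical(self):
        cfg = MFOConfig(bounds=[(-5, 5)] * 3, n_moths=6, max_iter=15, seed=21)
        obj = lambda x: float(np.sum(x**2))
        r1, r2 = run_mfo(obj, cfg), run_mfo(obj, cfg)
        assert r1.trace.equals(r2.trace)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_nonfinite_objective_survives(self):
        cfg = MFOConfig(bounds=[(-1, 1)], n_moths=4, max_iter=5, seed=2)

        def objective(x):
            return np.nan if x[0] > 0 else float(x[0] ** 2)

        res = run_mfo(objective, cfg)
        assert np.isfinite(res.best_fitness)

    def test_sphere_convergence_over_seeds(self):
        obj = lambda x: float(np.sum(x**2))
        finals, earlies = [], []
        for seed in range(5):
            cfg = MFOConfig(bounds=[(-5, 5)] * 2, n_moths=20, max_iter=100, seed=seed)
            res = run_mfo(obj, cfg)
            finals.append(res.best_fitness)
            earlies.append(res.trace["best_fitness"].iloc[9])
        assert np.median(finals) < 1e-2
        assert np.median(finals) <= np.median(earlies)
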