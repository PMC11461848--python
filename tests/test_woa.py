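import numpy as np
import pytest

from volfuse.selection import (FitnessSpec, OptimizerConfig, binarize,
                               woa_optimize, woa_select)
from volfuse.selection._woa import woa_step


def sphere(x):
    return float((x ** 2).sum())


class TestWoaStep:
    """Update-rule identities with pinned random draws."""

    dim = 4

    def _draws(self, value=0.3):
        return (np.full(self.dim, value), np.full(self.dim, value))

    def test_encircling_branch_matches_formula(self):
        rng = np.random.default_rng(0)
        pos = rng.random(self.dim)
        best = rng.random(self.dim)
        partner = rng.random(self.dim)
        a = 0.8
        s_a = np.full(self.dim, 0.6)   # A = 2*0.8*0.6 - 0.8 = 0.16, |A| < 1
        s_c = np.full(self.dim, 0.4)   # C = 0.8
        p = np.zeros(self.dim)         # p < 0.5 everywhere
        out = woa_step(pos, best, partner, a, 1.0, s_a, s_c, p, k=0.1,
                       lower=-10, upper=10)
        coeff_a = 2 * a * 0.6 - a
        expected = best - coeff_a * np.abs(0.8 * best - pos)
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_exploration_branch_targets_partner(self):
        rng = np.random.default_rng(1)
        pos = rng.random(self.dim)
        best = rng.random(self.dim)
        partner = rng.random(self.dim)
        a = 2.0
        s_a = np.ones(self.dim)        # A = 2*2*1 - 2 = 2, |A| >= 1
        s_c = np.full(self.dim, 0.5)   # C = 1
        p = np.zeros(self.dim)
        out = woa_step(pos, best, partner, a, 1.0, s_a, s_c, p, k=0.0,
                       lower=-10, upper=10)
        expected = partner - 2.0 * np.abs(partner - pos)
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_terminal_iteration_collapses_to_best(self):
        # a = 0 => A = 0 and the encircling update returns Z* exactly
        rng = np.random.default_rng(2)
        pos = rng.random(self.dim)
        best = rng.random(self.dim)
        partner = rng.random(self.dim)
        s_a, s_c = rng.random(self.dim), rng.random(self.dim)
        p = np.zeros(self.dim)
        out = woa_step(pos, best, partner, 0.0, 1.0, s_a, s_c, p, k=0.5,
                       lower=0, upper=1)
        np.testing.assert_array_equal(out, np.clip(best, 0, 1))

    def test_spiral_identity_at_k_zero(self):
        # k = 0: e^0 cos(0) = 1, so Z' = |Z* - Z| + Z*
        rng = np.random.default_rng(3)
        pos = rng.random(self.dim)
        best = rng.random(self.dim)
        p = np.ones(self.dim)  # spiral branch everywhere
        out = woa_step(pos, best, pos, 1.0, 1.0, *self._draws(), p, k=0.0,
                       lower=-10, upper=10)
        np.testing.assert_allclose(out, np.abs(best - pos) + best, atol=1e-14)

    def test_positions_clipped_to_bounds(self):
        pos = np.full(self.dim, 0.9)
        best = np.full(self.dim, 1.0)
        p = np.ones(self.dim)
        out = woa_step(pos, best, pos, 1.0, 1.0, *self._draws(), p, k=1.0,
                       lower=0.0, upper=1.0)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestWoaOptimize:
    def test_sphere_convergence(self):
        cfg = OptimizerConfig(algorithm="woa", population=30, iterations=200,
                              lower=-100, upper=100, independent_runs=1)
        _, best_fit, curve = woa_optimize(sphere, 10, cfg, seed=0)
        assert best_fit <= 1e-4
        assert len(curve) == 200

    def test_curve_non_increasing(self):
        cfg = OptimizerConfig(algorithm="woa", population=10, iterations=50,
                              lower=-5, upper=5, independent_runs=1)
        for seed in range(5):
            _, _, curve = woa_optimize(sphere, 6, cfg, seed=seed)
            assert np.all(np.diff(curve) <= 1e-15)

    def test_deterministic(self):
        cfg = OptimizerConfig(algorithm="woa", population=10, iterations=30,
                              lower=-5, upper=5)
        r1 = woa_optimize(sphere, 4, cfg, seed=7)
        r2 = woa_optimize(sphere, 4, cfg, seed=7)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1] == r2[1]


class TestWoaSelect:
    def test_selects_planted_features(self, planted_problem):
        cfg = OptimizerConfig(algorithm="woa", population=20, iterations=30,
                              independent_runs=2, seed=0)
        res = woa_select(planted_problem.X, planted_problem.y, cfg,
                         FitnessSpec(split_seed=0))
        informative = set(planted_problem.informative_set.tolist())
        assert len(set(res.selected_indices) & informative) >= 4
        assert res.selection_size < 30
        assert len(res.per_run) == 2
        assert len(res.convergence) == 30
        for run in res.per_run:
            assert np.all(np.diff(run["convergence"]) <= 1e-15)

    def test_fitness_recomputable_from_mask(self, planted_problem):
        from volfuse.selection._fitness import FitnessCache
        spec = FitnessSpec(split_seed=5)
        cfg = OptimizerConfig(algorithm="woa", population=10, iterations=10,
                              independent_runs=1, seed=5)
        res = woa_select(planted_problem.X, planted_problem.y, cfg, spec)
        cache = FitnessCache(planted_problem.X, planted_problem.y, spec)
        assert cache(res.mask) == pytest.approx(res.fitness, abs=1e-12)

    def test_determinism(self, planted_problem):
        cfg = OptimizerConfig(algorithm="woa", population=10, iterations=10,
                              independent_runs=2, seed=9)
        spec = FitnessSpec(split_seed=9)
        r1 = woa_select(planted_problem.X, planted_problem.y, cfg, spec)
        r2 = woa_select(planted_problem.X, planted_problem.y, cfg, spec)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r1.fitness == r2.fitness

    def test_requires_woa_algorithm(self, planted_problem):
        cfg = OptimizerConfig(algorithm="pso")
        with pytest.raises(ValueError, match="woa"):
            woa_select(planted_problem.X, planted_problem.y, cfg,
                       FitnessSpec())

    def test_result_serializes(self, planted_problem):
        import json
        cfg = OptimizerConfig(algorithm="woa", population=5, iterations=5,
                              independent_runs=1, seed=1)
        res = woa_select(planted_problem.X, planted_problem.y, cfg,
                         FitnessSpec(split_seed=1))
        doc = json.loads(json.dumps(res.to_dict()))
        assert doc["algorithm"] == "woa"
        assert len(doc["mask"]) == planted_problem.X.shape[1]


class TestOptimizerConfig:
    def test_defaults_per_algorithm(self):
        assert OptimizerConfig(algorithm="woa").params["b"] == 1.0
        pso = OptimizerConfig(algorithm="pso").params
        assert (pso["c1"], pso["c2"], pso["w"]) == (2.0, 2.0, 0.9)
        gsa = OptimizerConfig(algorithm="gsa").params
        assert (gsa["G0"], gsa["alpha"]) == (100.0, 20.0)
        ga = OptimizerConfig(algorithm="ga").params
        assert (ga["CR"], ga["MR"], ga["Ts"]) == (0.8, 0.01, 3)
        aco = OptimizerConfig(algorithm="aco").params
        assert (aco["tau"], aco["eta"], aco["alpha"], aco["beta"],
                aco["rho"]) == (1.0, 1.0, 1.0, 0.1, 0.2)

    def test_search_setting_defaults(self):
        cfg = OptimizerConfig()
        assert cfg.population == 100
        assert cfg.iterations == 200
        assert (cfg.lower, cfg.upper) == (0.0, 1.0)
        assert cfg.independent_runs == 20
        assert cfg.threshold == 0.5

    def test_validation(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            OptimizerConfig(algorithm="sa")
        with pytest.raises(ValueError):
            OptimizerConfig(population=1)
        with pytest.raises(ValueError):
            OptimizerConfig(iterations=0)
        with pytest.raises(ValueError):
            OptimizerConfig(lower=1.0, upper=0.0)
        with pytest.raises(ValueError):
            OptimizerConfig(threshold=0.0)
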