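"""Whale optimization: continuous core and binary wrapper feature selection.

Per agent and iteration the update draws one scalar ``k`` (spiral
parameter in [-1, 1]), one random partner index, and per-dimension
uniforms for the branch choice ``p`` and the ``A`` and ``C`` coefficient
vectors; each dimension then follows

* ``p >= 0.5``  bubble-net spiral:   ``Z' = e^(b k) cos(2 pi k) |Z* - Z| + Z*``
* ``p < 0.5``, ``|A| < 1``  encircle: ``Z' = Z* - A |C Z* - Z|``
* ``p < 0.5``, ``|A| >= 1`` explore:  ``Z' = Z_r - A |C Z_r - Z|``

with ``A = 2 a s - a``, ``C = 2 s'``, and ``a`` decreasing linearly from 2
to exactly 0 over the iteration budget (so the final encircling step
collapses onto the best agent). The distance term follows the canonical
formulation ``|C Z_ref - Z|`` — the coefficient weights the reference
point, not the difference — which keeps a non-zero perturbation even at
population consensus. Agents are updated and evaluated sequentially and
the best-so-far solution is refreshed immediately (steady-state elitism);
positions are clipped to the bounds after every update.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from ._fitness import FitnessCache, FitnessSpec, binarize

__all__ = ["OptimizerConfig", "SelectionResult", "woa_optimize", "woa_select"]

ALGORITHMS = ("woa", "pso", "ga", "gsa", "aco")

_DEFAULT_PARAMS = {
    "woa": {"b": 1.0},
    "pso": {"c1": 2.0, "c2": 2.0, "w": 0.9},
    "gsa": {"G0": 100.0, "alpha": 20.0},
    "ga": {"CR": 0.8, "MR": 0.01, "Ts": 3},
    "aco": {"tau": 1.0, "eta": 1.0, "alpha": 1.0, "beta": 0.1, "rho": 0.2},
}


@dataclass
class OptimizerConfig:
    algorithm: str = "woa"
    population: int = 100
    iterations: int = 200
    lower: float = 0.0
    upper: float = 1.0
    independent_runs: int = 20
    threshold: float = 0.5
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.lower >= self.upper:
            raise ValueError("bounds must be ordered")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.independent_runs < 1:
            raise ValueError("independent_runs must be >= 1")
        merged = dict(_DEFAULT_PARAMS[self.algorithm])
        merged.update(self.params)
        self.params = merged


@dataclass
class SelectionResult:
    mask: np.ndarray
    fitness: float
    convergence: np.ndarray          # best-so-far per iteration, best run
    per_run: list[dict]              # one entry per independent run
    selection_size: int
    algorithm: str
    elapsed_s: float
    config: dict = field(default_factory=dict)

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "mask": self.mask.astype(int).tolist(),
            "selected_indices": self.selected_indices.tolist(),
            "fitness": self.fitness,
            "selection_size": self.selection_size,
            "convergence": np.asarray(self.convergence).tolist(),
            "elapsed_s": self.elapsed_s,
            "config": self.config,
        }


def woa_step(position: np.ndarray, best: np.ndarray, partner: np.ndarray,
             a: float, b: float, s_a: np.ndarray, s_c: np.ndarray,
             p: np.ndarray, k: float, lower: float, upper: float
             ) -> np.ndarray:
    """One deterministic whale update given all random draws.

    ``s_a``, ``s_c``, ``p``: per-dimension uniforms in [0,1); ``k``: the
    per-agent spiral scalar in [-1, 1]. Exposed separately so the update
    rules can be unit-tested with pinned draws.
    """
    coeff_a = 2.0 * a * s_a - a
    coeff_c = 2.0 * s_c

    encircle = best - coeff_a * np.abs(coeff_c * best - position)
    explore = partner - coeff_a * np.abs(coeff_c * partner - position)
    shrink_or_explore = np.where(np.abs(coeff_a) < 1.0, encircle, explore)

    spiral = (np.exp(b * k) * np.cos(2.0 * np.pi * k)
              * np.abs(best - position) + best)

    new = np.where(np.asarray(p) >= 0.5, spiral, shrink_or_explore)
    return np.clip(new, lower, upper)


def woa_optimize(objective, dim: int, cfg: OptimizerConfig, seed: int
                 ) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over ``[lower, upper]^dim``.

    Returns (best position, best fitness, best-so-far curve of length
    ``cfg.iterations``).
    """
    rng = np.random.default_rng(seed)
    pop, t_max = cfg.population, cfg.iterations
    b = float(cfg.params.get("b", 1.0))
    positions = rng.uniform(cfg.lower, cfg.upper, size=(pop, dim))
    fitness = np.array([objective(x) for x in positions])
    best_i = int(fitness.argmin())
    best = positions[best_i].copy()
    best_fit = float(fitness[best_i])
    curve = np.empty(t_max)
    for u in range(t_max):
        a = 2.0 * (1.0 - u / (t_max - 1)) if t_max > 1 else 0.0
        for i in range(pop):
            s_a = rng.random(dim)
            s_c = rng.random(dim)
            p = rng.random(dim)
            k = rng.uniform(-1.0, 1.0)
            partner = positions[int(rng.integers(0, pop))]
            positions[i] = woa_step(positions[i], best, partner, a, b,
                                    s_a, s_c, p, k, cfg.lower, cfg.upper)
            f = float(objective(positions[i]))
            if f < best_fit:  # steady-state elitism
                best_fit = f
                best = positions[i].copy()
        curve[u] = best_fit
    return best, best_fit, curve


def run_seeds(cfg: OptimizerConfig) -> list[int]:
    """Derived per-run seeds, one per independent run."""
    ss = np.random.SeedSequence(cfg.seed)
    return [int(child.generate_state(1)[0]) for child
            in ss.spawn(cfg.independent_runs)]


def woa_select(X, y, cfg: OptimizerConfig, spec: FitnessSpec
               ) -> SelectionResult:
    """Binary wrapper feature selection with WOA over [lower, upper]^N."""
    if cfg.algorithm != "woa":
        raise ValueError(f"woa_select requires algorithm='woa', got {cfg.algorithm!r}")
    x = np.asarray(getattr(X, "values", X), dtype=np.float64)
    dim = x.shape[1]
    t0 = time.time()
    per_run = []
    # one cache for all runs: the frozen splits make fitness values
    # comparable across independent runs and memoization carries over
    cache = FitnessCache(x, y, spec)

    def objective(pos):
        return cache(binarize(pos, cfg.threshold))

    for run_i, seed in enumerate(run_seeds(cfg)):
        evals_before = cache.n_evaluations
        pos, fit, curve = woa_optimize(objective, dim, cfg, seed)
        mask = binarize(pos, cfg.threshold)
        per_run.append({"run": run_i, "seed": seed, "fitness": fit,
                        "mask": mask, "convergence": curve,
                        "selection_size": int(mask.sum()),
                        "n_evaluations": cache.n_evaluations - evals_before})
    best_run = min(per_run, key=lambda r: r["fitness"])
    return SelectionResult(
        mask=best_run["mask"], fitness=best_run["fitness"],
        convergence=best_run["convergence"], per_run=per_run,
        selection_size=int(best_run["mask"].sum()), algorithm="woa",
        elapsed_s=time.time() - t0,
        config={"population": cfg.population, "iterations": cfg.iterations,
                "independent_runs": cfg.independent_runs,
                "threshold": cfg.threshold, "seed": cfg.seed,
                "params": cfg.params, "alpha": spec.alpha,
                "knn_k": spec.knn_k})
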