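"""Comparison optimizers: PSO, GSA (continuous), GA, ACO (native binary).

All four run under the exact same fitness, binarization rule, population,
iteration and independent-run budget as the whale optimizer so the
comparison is apples-to-apples. Best-so-far curves are recorded
elitistically (monotone non-increasing) for every algorithm.
"""

from __future__ import annotations

import time

import numpy as np

from ._fitness import FitnessCache, FitnessSpec, binarize
from ._woa import OptimizerConfig, SelectionResult, run_seeds

__all__ = ["baseline_select"]


def _pso_run(objective, dim, cfg, seed):
    rng = np.random.default_rng(seed)
    pop, t_max = cfg.population, cfg.iterations
    c1 = cfg.params["c1"]
    c2 = cfg.params["c2"]
    w = cfg.params["w"]
    span = cfg.upper - cfg.lower
    x = rng.uniform(cfg.lower, cfg.upper, (pop, dim))
    v = np.zeros((pop, dim))
    fit = np.array([objective(p) for p in x])
    pbest, pbest_fit = x.copy(), fit.copy()
    gi = int(fit.argmin())
    gbest, gbest_fit = x[gi].copy(), float(fit[gi])
    curve = np.empty(t_max)
    vmax = 0.2 * span
    for u in range(t_max):
        r1 = rng.random((pop, dim))
        r2 = rng.random((pop, dim))
        v = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest[None] - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, cfg.lower, cfg.upper)
        fit = np.array([objective(p) for p in x])
        improved = fit < pbest_fit
        pbest[improved] = x[improved]
        pbest_fit[improved] = fit[improved]
        gi = int(pbest_fit.argmin())
        if pbest_fit[gi] < gbest_fit:
            gbest, gbest_fit = pbest[gi].copy(), float(pbest_fit[gi])
        curve[u] = gbest_fit
    return gbest, gbest_fit, curve


def _gsa_run(objective, dim, cfg, seed):
    rng = np.random.default_rng(seed)
    pop, t_max = cfg.population, cfg.iterations
    g0 = cfg.params["G0"]
    alpha = cfg.params["alpha"]
    x = rng.uniform(cfg.lower, cfg.upper, (pop, dim))
    v = np.zeros((pop, dim))
    best, best_fit = None, np.inf
    curve = np.empty(t_max)
    eps = 1e-12
    for u in range(t_max):
        fit = np.array([objective(p) for p in x])
        i_best = int(fit.argmin())
        if fit[i_best] < best_fit:
            best, best_fit = x[i_best].copy(), float(fit[i_best])
        worst, bst = fit.max(), fit.min()
        m = ((fit - worst) / (bst - worst - eps)) if bst < worst else np.ones(pop)
        mass = m / max(m.sum(), eps)
        g = g0 * np.exp(-alpha * u / t_max)
        k_best = max(1, int(round(pop * (1.0 - u / t_max))))
        elite = np.argsort(fit)[:k_best]
        force = np.zeros((pop, dim))
        for j in elite:
            diff = x[j][None] - x
            dist = np.linalg.norm(diff, axis=1)[:, None]
            contrib = g * (mass[:, None] * mass[j]) * diff / (dist + eps)
            contrib[j] = 0.0
            force += rng.random((pop, 1)) * contrib
        acc = force / (mass[:, None] + eps)
        v = rng.random((pop, 1)) * v + acc
        x = np.clip(x + v, cfg.lower, cfg.upper)
        curve[u] = best_fit
    # account for final positions
    fit = np.array([objective(p) for p in x])
    i_best = int(fit.argmin())
    if fit[i_best] < best_fit:
        best, best_fit = x[i_best].copy(), float(fit[i_best])
        curve[-1] = best_fit
    return best, best_fit, curve


def _ga_run(objective_bits, dim, cfg, seed):
    rng = np.random.default_rng(seed)
    pop, t_max = cfg.population, cfg.iterations
    cr = cfg.params["CR"]
    mr = cfg.params["MR"]
    ts = int(cfg.params["Ts"])
    bits = (rng.random((pop, dim)) < 0.5).astype(np.int8)
    fit = np.array([objective_bits(b) for b in bits])
    gi = int(fit.argmin())
    best, best_fit = bits[gi].copy(), float(fit[gi])
    curve = np.empty(t_max)

    def tournament():
        idx = rng.integers(0, pop, ts)
        return bits[idx[np.argmin(fit[idx])]]

    for u in range(t_max):
        children = np.empty_like(bits)
        for i in range(0, pop, 2):
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < cr:  # uniform crossover
                swap = rng.random(dim) < 0.5
                p1[swap], p2[swap] = p2[swap], p1[swap].copy()
            children[i] = p1
            if i + 1 < pop:
                children[i + 1] = p2
        flip = rng.random((pop, dim)) < mr
        children = np.where(flip, 1 - children, children).astype(np.int8)
        children[0] = best  # elitism: keep the incumbent
        bits = children
        fit = np.array([objective_bits(b) for b in bits])
        gi = int(fit.argmin())
        if fit[gi] < best_fit:
            best, best_fit = bits[gi].copy(), float(fit[gi])
        curve[u] = best_fit
    return best, best_fit, curve


def _aco_run(objective_bits, dim, cfg, seed):
    rng = np.random.default_rng(seed)
    pop, t_max = cfg.population, cfg.iterations
    tau0 = np.full(dim, cfg.params["tau"])
    tau1 = np.full(dim, cfg.params["tau"])
    eta = cfg.params["eta"]
    al = cfg.params["alpha"]
    be = cfg.params["beta"]
    rho = cfg.params["rho"]
    best, best_fit = None, np.inf
    curve = np.empty(t_max)
    for u in range(t_max):
        w1 = tau1 ** al * eta ** be
        w0 = tau0 ** al * eta ** be
        p_sel = w1 / (w1 + w0)
        ants = (rng.random((pop, dim)) < p_sel[None]).astype(np.int8)
        fit = np.array([objective_bits(a) for a in ants])
        gi = int(fit.argmin())
        if fit[gi] < best_fit:
            best, best_fit = ants[gi].copy(), float(fit[gi])
        tau1 *= (1.0 - rho)
        tau0 *= (1.0 - rho)
        deposit = 1.0 / (0.01 + best_fit)
        tau1[best == 1] += rho * deposit
        tau0[best == 0] += rho * deposit
        np.clip(tau1, 0.01, 10.0, out=tau1)
        np.clip(tau0, 0.01, 10.0, out=tau0)
        curve[u] = best_fit
    return best, best_fit, curve


def baseline_select(X, y, cfg: OptimizerConfig, spec: FitnessSpec
                    ) -> SelectionResult:
    """Run one of the comparison algorithms as a wrapper feature selector."""
    if cfg.algorithm not in ("pso", "ga", "gsa", "aco"):
        raise ValueError(
            f"unknown baseline algorithm {cfg.algorithm!r}; "
            "expected one of ('pso', 'ga', 'gsa', 'aco')")
    x = np.asarray(getattr(X, "values", X), dtype=np.float64)
    dim = x.shape[1]
    t0 = time.time()
    per_run = []
    cache = FitnessCache(x, y, spec)  # shared: splits are frozen per call
    for run_i, seed in enumerate(run_seeds(cfg)):
        evals_before = cache.n_evaluations
        if cfg.algorithm in ("pso", "gsa"):
            def objective(pos):
                return cache(binarize(pos, cfg.threshold))
            runner = _pso_run if cfg.algorithm == "pso" else _gsa_run
            sol, fit, curve = runner(objective, dim, cfg, seed)
            mask = binarize(sol, cfg.threshold)
        else:
            def objective_bits(bits):
                return cache(np.asarray(bits, dtype=np.int8))
            runner = _ga_run if cfg.algorithm == "ga" else _aco_run
            sol, fit, curve = runner(objective_bits, dim, cfg, seed)
            mask = np.asarray(sol, dtype=np.int8)
        per_run.append({"run": run_i, "seed": seed, "fitness": fit,
                        "mask": mask, "convergence": curve,
                        "selection_size": int(mask.sum()),
                        "n_evaluations": cache.n_evaluations - evals_before})
    best_run = min(per_run, key=lambda r: r["fitness"])
    return SelectionResult(
        mask=best_run["mask"], fitness=best_run["fitness"],
        convergence=best_run["convergence"], per_run=per_run,
        selection_size=int(best_run["mask"].sum()), algorithm=cfg.algorithm,
        elapsed_s=time.time() - t0,
        config={"population": cfg.population, "iterations": cfg.iterations,
                "independent_runs": cfg.independent_runs,
                "threshold": cfg.threshold, "seed": cfg.seed,
                "params": cfg.params, "alpha": spec.alpha,
                "knn_k": spec.knn_k})
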