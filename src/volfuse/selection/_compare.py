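"""Side-by-side benchmarking of the five wrapper-selection optimizers."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._baselines import baseline_select
from ._fitness import FitnessCache, FitnessSpec
from ._woa import OptimizerConfig, SelectionResult, woa_select

__all__ = ["compare_optimizers"]

METRIC_COLUMNS = ["accuracy", "mean_fitness", "best_fitness",
                  "mean_selection_size", "time_s"]


def compare_optimizers(X, y, algorithms: list[str], cfg: OptimizerConfig,
                       spec: FitnessSpec
                       ) -> tuple[pd.DataFrame, dict[str, np.ndarray],
                                  dict[str, SelectionResult]]:
    """Run each algorithm under an identical fitness and budget.

    Returns ``(table, mean_curves, results)`` where the table has one row
    per algorithm with columns: validation accuracy of the best mask, mean
    and best fitness over the independent runs, mean selection size, and
    elapsed wall time.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    rows = []
    curves: dict[str, np.ndarray] = {}
    results: dict[str, SelectionResult] = {}
    for algo in algorithms:
        acfg = replace(cfg, algorithm=algo, params={})
        if algo == "woa":
            res = woa_select(X, y, acfg, spec)
        else:
            res = baseline_select(X, y, acfg, spec)
        cache = FitnessCache(X, y, spec)
        rows.append({
            "algorithm": algo,
            "accuracy": cache.holdout_accuracy(res.mask),
            "mean_fitness": float(np.mean([r["fitness"] for r in res.per_run])),
            "best_fitness": res.fitness,
            "mean_selection_size": float(np.mean(
                [r["selection_size"] for r in res.per_run])),
            "time_s": res.elapsed_s,
        })
        curves[algo] = np.mean(
            np.stack([r["convergence"] for r in res.per_run]), axis=0)
        results[algo] = res
    table = pd.DataFrame(rows, columns=["algorithm"] + METRIC_COLUMNS)
    return table, curves, results


def plot_comparison(table: pd.DataFrame, curves: dict[str, np.ndarray],
                    out_prefix: str) -> list[str]:
    """Write metric-bar and convergence-curve figures; returns file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, axes = plt.subplots(1, len(METRIC_COLUMNS), figsize=(4 * 5, 3.5))
    for ax, metric in zip(np.atleast_1d(axes), METRIC_COLUMNS):
        ax.bar(table["algorithm"], table[metric])
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    p = f"{out_prefix}_metrics.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for algo, curve in curves.items():
        ax.plot(curve, label=algo)
    ax.set_xlabel("iteration")
    ax.set_ylabel("best-so-far fitness (mean over runs)")
    ax.legend()
    fig.tight_layout()
    p = f"{out_prefix}_convergence.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
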