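"""Wrapper feature-selection fitness: KNN validation error + subset size.

``fitness(mask) = alpha * error_rate(KNN on masked features) +
(1 - alpha) * |R| / N`` — lower is better. The error rate is averaged over
a small set of stratified train/validation splits that are fixed per
optimizer run, which keeps the fitness landscape static across iterations
while taming single-split variance; an empty mask scores the worst
possible value (1.0) by convention so optimizers stay total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

__all__ = ["FitnessSpec", "binarize", "evaluate_fitness", "FitnessCache"]


@dataclass
class FitnessSpec:
    alpha: float = 0.99
    knn_k: int = 5
    val_fraction: float = 0.2
    n_splits: int = 5
    split_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.knn_k < 1 or self.n_splits < 1:
            raise ValueError("knn_k and n_splits must be >= 1")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Continuous position -> inclusion mask; ties at the threshold select."""
    return (np.asarray(position) >= threshold).astype(np.int8)


def _splits(y: np.ndarray, spec: FitnessSpec) -> list:
    # a handful of fixed stratified splits, averaged, to tame the variance
    # of a single small validation set while keeping the landscape static
    idx = np.arange(len(y))
    return [train_test_split(idx, test_size=spec.val_fraction,
                             random_state=spec.split_seed + j, stratify=y)
            for j in range(spec.n_splits)]


def _knn_error(x, y, mask_idx, splits, k: int) -> float:
    errs = []
    for tr, va in splits:
        clf = KNeighborsClassifier(n_neighbors=min(k, len(tr)))
        clf.fit(x[np.ix_(tr, mask_idx)], y[tr])
        errs.append(1.0 - clf.score(x[np.ix_(va, mask_idx)], y[va]))
    return float(np.mean(errs))


def evaluate_fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray,
                     spec: FitnessSpec, splits: list | None = None) -> float:
    """Fitness of one binary mask; see module docstring."""
    x = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(y)
    mask = np.asarray(mask).astype(bool)
    if mask.shape[0] != x.shape[1]:
        raise ValueError(
            f"mask length {mask.shape[0]} != n_features {x.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    n_total = mask.shape[0]
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 1.0
    if splits is None:
        splits = _splits(y, spec)
    gamma = _knn_error(x, y, np.flatnonzero(mask), splits, spec.knn_k)
    return spec.alpha * gamma + spec.beta * n_sel / n_total


class FitnessCache:
    """Memoized per-run fitness with frozen stratified splits."""

    def __init__(self, X, y, spec: FitnessSpec):
        self.x = np.asarray(getattr(X, "values", X), dtype=np.float64)
        self.y = np.asarray(y)
        self.spec = spec
        self.splits = _splits(self.y, spec)
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = evaluate_fitness(mask, self.x, self.y, self.spec, self.splits)
        self._cache[key] = val
        self.n_evaluations += 1
        return val

    def holdout_accuracy(self, mask: np.ndarray) -> float:
        """Mean validation-split KNN accuracy (1 - error term)."""
        mask = np.asarray(mask).astype(bool)
        if mask.sum() == 0:
            return 0.0
        return 1.0 - _knn_error(self.x, self.y, np.flatnonzero(mask),
                                self.splits, self.spec.knn_k)
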