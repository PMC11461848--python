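"""Synthetic generators: volumetric phantoms, dual-view correlated feature
matrices and planted-subset feature-selection problems.

Every generator is a pure function of its config (all randomness flows from
a single integer seed per call), so identical configs reproduce identical
data bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import VolumeSample

__all__ = [
    "PhantomConfig",
    "DualViewConfig",
    "PlantedSelectionProblem",
    "gen_volumes",
    "gen_dual_view_features",
    "gen_planted_selection",
]


@dataclass
class PhantomConfig:
    """Three-class volumetric phantoms differing in a localized nucleus.

    Classes differ by the mean intensity (and optionally the radii) of an
    ellipsoidal nucleus region placed in an otherwise homogeneous volume,
    mimicking a localized subcortical signal change rather than a global
    intensity shift.
    """

    n_samples: int
    n_classes: int = 3
    shape: tuple[int, int, int] = (56, 56, 56)
    nucleus_center: tuple[int, int, int] | None = None
    nucleus_radii: tuple[float, float, float] | None = None
    class_intensity_deltas: tuple[float, ...] | None = None
    class_radius_deltas: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    jitter_voxels: int = 0
    background: float = 0.2
    nucleus_base: float = 0.6
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError(f"invalid phantom shape {self.shape}")
        if self.n_samples < self.n_classes:
            raise ValueError("n_samples must be >= n_classes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.jitter_voxels < 0:
            raise ValueError("jitter_voxels must be nonnegative")
        if self.nucleus_center is None:
            self.nucleus_center = tuple(s // 2 for s in self.shape)
        if self.nucleus_radii is None:
            self.nucleus_radii = tuple(max(2.0, s / 7) for s in self.shape)
        if self.class_intensity_deltas is None:
            self.class_intensity_deltas = tuple(
                0.3 * k for k in range(self.n_classes))
        if len(self.class_intensity_deltas) != self.n_classes:
            raise ValueError("need one intensity delta per class")
        if self.class_radius_deltas is None:
            self.class_radius_deltas = (0.0,) * self.n_classes
        if len(self.class_radius_deltas) != self.n_classes:
            raise ValueError("need one radius delta per class")


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """0..k-1 repeated; counts balanced to within 1."""
    return np.arange(n) % k


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def gen_volumes(cfg: PhantomConfig) -> list[VolumeSample]:
    """Generate labeled phantom volumes with class-dependent nucleus signal."""
    rng = np.random.default_rng(cfg.seed)
    labels = _balanced_labels(cfg.n_samples, cfg.n_classes)
    out = []
    for i, label in enumerate(labels):
        center = np.array(cfg.nucleus_center, dtype=float)
        if cfg.jitter_voxels > 0:
            center = center + rng.integers(-cfg.jitter_voxels,
                                           cfg.jitter_voxels + 1, size=3)
        radii = np.array(cfg.nucleus_radii, dtype=float) \
            + cfg.class_radius_deltas[label]
        vox = np.full(cfg.shape, cfg.background, dtype=np.float64)
        mask = _ellipsoid_mask(cfg.shape, center, radii)
        vox[mask] = cfg.nucleus_base + cfg.class_intensity_deltas[label]
        if cfg.noise_sd > 0:
            vox = vox + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
        out.append(VolumeSample(
            voxels=vox, spacing=(1.0, 1.0, 1.0),
            subject_id=f"phantom-{i:04d}", label=int(label),
            provenance={"generator": "phantom", "seed": cfg.seed, "index": i}))
    return out


@dataclass
class DualViewConfig:
    """Two observed views driven by a shared latent factor.

    Per sample: ``a = L_A z + e_A`` and ``b = L_B z + e_B`` with latent
    ``z ~ N(0, I_d)``, orthonormal loading directions scaled per component,
    and isotropic view noise. With equal per-component scale ``s`` in both
    views the population canonical correlation of component ``i`` is
    ``s_i^2 / (s_i^2 + noise_sd^2)``, which the generator returns alongside
    the data for use as a closed-form oracle.
    """

    n: int
    p: int
    q: int
    d_latent: int
    loading_scale: float | tuple[float, ...] = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.d_latent > min(self.p, self.q):
            raise ValueError("d_latent must be <= min(p, q)")
        if self.d_latent < 0 or self.n < 1:
            raise ValueError("invalid dual-view config")
        if np.isscalar(self.loading_scale):
            self.loading_scale = (float(self.loading_scale),) * self.d_latent
        if len(self.loading_scale) != self.d_latent:
            raise ValueError("need one loading scale per latent component")


def _random_orthonormal(p: int, d: int, rng) -> np.ndarray:
    m = rng.standard_normal((p, max(d, 1)))
    q_mat, _ = np.linalg.qr(m)
    return q_mat[:, :d]


def gen_dual_view_features(cfg: DualViewConfig):
    """Returns (A, B, theoretical_correlations).

    ``theoretical_correlations`` has length ``min(p, q)``: the first
    ``d_latent`` entries are the population canonical correlations implied
    by the loadings and noise (sorted non-increasing), the rest are zero.
    """
    from .extractors import FeatureMatrix

    rng = np.random.default_rng(cfg.seed)
    scales = np.asarray(cfg.loading_scale, dtype=float)
    u_a = _random_orthonormal(cfg.p, cfg.d_latent, rng)
    u_b = _random_orthonormal(cfg.q, cfg.d_latent, rng)
    z = rng.standard_normal((cfg.n, cfg.d_latent))
    a = z @ (u_a * scales).T
    b = z @ (u_b * scales).T
    if cfg.noise_sd > 0:
        a = a + rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.p))
        b = b + rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.q))
    rho = np.zeros(min(cfg.p, cfg.q))
    if cfg.d_latent:
        lead = scales ** 2 / (scales ** 2 + cfg.noise_sd ** 2)
        rho[: cfg.d_latent] = np.sort(lead)[::-1]
    ids = [f"s{i:05d}" for i in range(cfg.n)]
    fm_a = FeatureMatrix(a, [("synthetic", "viewA")] * cfg.p, ids)
    fm_b = FeatureMatrix(b, [("synthetic", "viewB")] * cfg.q, ids)
    return fm_a, fm_b, rho


@dataclass
class PlantedSelectionProblem:
    """Feature-selection benchmark with a known informative subset."""

    X: "np.ndarray"
    y: np.ndarray
    informative_set: np.ndarray
    effect_size: float
    seed: int
    n_classes: int = 3
    manifest: dict = field(default_factory=dict)

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"informative_set": self.informative_set.tolist(),
             "effect_size": self.effect_size, "seed": self.seed,
             "n_classes": self.n_classes, **self.manifest}, indent=2))


def gen_planted_selection(n: int, N: int, k_informative: int,
                          effect_size: float, seed: int,
                          n_classes: int = 3,
                          distractor_sd: float = 1.5
                          ) -> PlantedSelectionProblem:
    """Gaussian features; labels depend only on a planted subset.

    Labels are balanced to within 1 by construction; the informative
    features (unit within-class variance) receive class-conditional mean
    shifts of magnitude ``effect_size / sqrt(k_informative)`` per feature
    with the per-feature class spread equalized, so every planted feature
    is equally informative and the total class separation scales with
    ``effect_size`` independently of the subset size. Equal-covariance
    Gaussian classes make the label posterior exactly a softmax-linear
    (multinomial logistic) rule in the informative features, so labels
    depend on the planted subset and nothing else; at ``effect_size = 0``
    they are independent of every feature. Distractor features are pure
    ``N(0, distractor_sd^2)`` noise — the larger variance makes their
    inclusion measurably dilute nearest-neighbour distances, as irrelevant
    deep features do in practice.
    """
    if k_informative >= N:
        raise ValueError("k_informative must be < N")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, N)) * distractor_sd
    informative = np.sort(rng.choice(N, size=k_informative, replace=False))
    x[:, informative] /= distractor_sd
    y = rng.permutation(np.arange(n) % n_classes).astype(np.int64)
    centers = rng.standard_normal((n_classes, k_informative))
    centers -= centers.mean(axis=0)
    centers /= np.sqrt((centers ** 2).mean(axis=0))
    x[:, informative] += (effect_size / np.sqrt(k_informative)) * centers[y]
    return PlantedSelectionProblem(
        X=x, y=y, informative_set=informative, effect_size=effect_size,
        seed=seed, n_classes=n_classes,
        manifest={"n": n, "N": N, "k_informative": k_informative})
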