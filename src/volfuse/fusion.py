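"""Canonical correlation analysis feature fusion.

Two feature views A (n x p) and B (n x q) are projected onto paired
canonical directions maximizing their cross-view correlation subject to
unit-variance variates. The directions solve the coupled eigenproblems

    S_AA^-1 S_AB S_BB^-1 S_BA w_A = rho^2 w_A
    S_BB^-1 S_BA S_AA^-1 S_AB w_B = rho^2 w_B

with the within-view covariances optionally shrunk towards a scaled
identity (``S + lam * tr(S)/p * I``) — required in the wide-data regime
(p, q >> n) where the plain covariances are singular. An optional PCA
pre-reduction of each view to rank <= n-1 is applied in that regime and
folded back into the returned transformation matrices, so callers always
work in the original feature coordinates.

Fused outputs: ``Z1`` stacks the paired variates column-wise (width 2d),
``Z2`` sums them (width d).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .extractors import FeatureMatrix

__all__ = ["CCAModel", "FusedFeatures", "fit_cca", "fuse"]


@dataclass
class CCAModel:
    W_A: np.ndarray            # p x d
    W_B: np.ndarray            # q x d
    correlations: np.ndarray   # length d, non-increasing, in [0, 1]
    mean_A: np.ndarray
    mean_B: np.ndarray
    regularization: float
    d: int
    training_variates: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {"regularization": self.regularization, "d": self.d}
        with zipfile.ZipFile(path, "w") as zf:
            for name, arr in [("W_A", self.W_A), ("W_B", self.W_B),
                              ("correlations", self.correlations),
                              ("mean_A", self.mean_A), ("mean_B", self.mean_B)]:
                with zf.open(name + ".npy", "w") as f:
                    np.save(f, arr)
            zf.writestr("meta.json", json.dumps(meta))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CCAModel":
        with zipfile.ZipFile(path) as zf:
            arrays = {n: np.load(zf.open(n + ".npy"))
                      for n in ("W_A", "W_B", "correlations", "mean_A", "mean_B")}
            meta = json.loads(zf.read("meta.json"))
        return cls(W_A=arrays["W_A"], W_B=arrays["W_B"],
                   correlations=arrays["correlations"],
                   mean_A=arrays["mean_A"], mean_B=arrays["mean_B"],
                   regularization=meta["regularization"], d=meta["d"])


@dataclass
class FusedFeatures:
    mode: str
    values: np.ndarray
    source: CCAModel = field(repr=False)


def _as_array(m) -> np.ndarray:
    if isinstance(m, FeatureMatrix):
        return m.values
    return np.asarray(m, dtype=np.float64)


def _fix_signs(w: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip column signs so the first non-negligible loading is positive."""
    w = w.copy()
    for j in range(w.shape[1]):
        col = w[:, j]
        nz = np.flatnonzero(np.abs(col) > tol * max(1.0, np.abs(col).max()))
        if nz.size and col[nz[0]] < 0:
            w[:, j] = -col
    return w


def _pca_reduce(xc: np.ndarray, max_rank: int) -> np.ndarray:
    """Orthonormal basis (columns) spanning the top principal directions."""
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = min(max_rank, int((s > s[0] * 1e-10).sum()) if s.size else 0)
    return vt[:keep].T


def fit_cca(A, B, lam: float = 1e-3, d: int | None = None,
            pca_rank: int | None = None) -> CCAModel:
    """Fit CCA between two views with shrinkage regularization.

    Parameters
    ----------
    A, B : FeatureMatrix or array, shape (n, p) and (n, q)
    lam : shrinkage strength; each within-view covariance S becomes
        ``S + lam * tr(S)/dim * I``.
    d : number of components to retain; default = number of canonical
        correlations exceeding 1e-6.
    pca_rank : optional per-view PCA pre-reduction rank. Defaults to
        ``n - 1`` whenever a view is wider than ``n - 1``.
    """
    a = _as_array(A)
    b = _as_array(B)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("views must be 2-D")
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"views must have equal sample counts, got {a.shape[0]} != {b.shape[0]}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to fit CCA")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite input")

    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    ac = a - mean_a
    bc = b - mean_b

    p_basis = q_basis = None
    if pca_rank is None and max(a.shape[1], b.shape[1]) > n - 1:
        pca_rank = n - 1
    if pca_rank is not None:
        p_basis = _pca_reduce(ac, pca_rank)
        q_basis = _pca_reduce(bc, pca_rank)
        ac = ac @ p_basis
        bc = bc @ q_basis

    p, q = ac.shape[1], bc.shape[1]
    s_aa = (ac.T @ ac) / (n - 1)
    s_bb = (bc.T @ bc) / (n - 1)
    s_ab = (ac.T @ bc) / (n - 1)
    if lam:
        s_aa = s_aa + lam * (np.trace(s_aa) / p) * np.eye(p)
        s_bb = s_bb + lam * (np.trace(s_bb) / q) * np.eye(q)

    # coupled eigenproblem for the A-side directions
    m = scipy.linalg.solve(s_aa, s_ab, assume_a="pos") \
        @ scipy.linalg.solve(s_bb, s_ab.T, assume_a="pos")
    eigvals, eigvecs = scipy.linalg.eig(m)
    eigvals = eigvals.real
    eigvecs = eigvecs.real
    order = np.argsort(eigvals)[::-1]
    n_comp = min(p, q)
    order = order[:n_comp]
    rho = np.sqrt(np.clip(eigvals[order], 0.0, 1.0))
    w_a = eigvecs[:, order]
    # B-side directions follow from the A-side ones: w_B ∝ S_BB^-1 S_BA w_A
    w_b = scipy.linalg.solve(s_bb, s_ab.T @ w_a, assume_a="pos")

    # normalize to unit-variance variates: w' S w = 1
    for w, s in ((w_a, s_aa), (w_b, s_bb)):
        norms = np.sqrt(np.einsum("ij,jk,ki->i", w.T, s, w))
        norms[norms < 1e-300] = 1.0
        w /= norms

    if d is None:
        d = max(1, int((rho > 1e-6).sum()))
    d = min(d, n_comp)
    w_a, w_b, rho = w_a[:, :d], w_b[:, :d], rho[:d]

    # align B-side sign with the A-side variate (positive correlation),
    # then apply the deterministic first-nonzero-positive convention jointly
    va = ac @ w_a
    vb = bc @ w_b
    cross = np.einsum("ij,ij->j", va, vb)
    flip = np.sign(cross)
    flip[flip == 0] = 1.0
    w_b = w_b * flip
    w_a_fixed = _fix_signs(w_a)
    joint_flip = np.where(np.einsum("ij,ij->j", w_a, w_a_fixed) < 0, -1.0, 1.0)
    w_a = w_a_fixed
    w_b = w_b * joint_flip

    if p_basis is not None:
        w_a = p_basis @ w_a
        w_b = q_basis @ w_b

    model = CCAModel(W_A=w_a, W_B=w_b, correlations=rho,
                     mean_A=mean_a, mean_B=mean_b,
                     regularization=float(lam), d=int(d))
    model.training_variates = ((a - mean_a) @ w_a, (b - mean_b) @ w_b)
    return model


def fuse(model: CCAModel, A, B, mode: str = "Z1_concat") -> FusedFeatures:
    """Project both views through the fitted model and fuse the variates."""
    a = _as_array(A)
    b = _as_array(B)
    if a.shape[1] != model.W_A.shape[0] or b.shape[1] != model.W_B.shape[0]:
        raise ValueError(
            f"view widths ({a.shape[1]}, {b.shape[1]}) do not match fitted "
            f"model ({model.W_A.shape[0]}, {model.W_B.shape[0]})")
    va = (a - model.mean_A) @ model.W_A
    vb = (b - model.mean_B) @ model.W_B
    if mode == "Z1_concat":
        values = np.concatenate([va, vb], axis=1)
    elif mode == "Z2_sum":
        values = va + vb
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return FusedFeatures(mode=mode, values=values, source=model)
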