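import numpy as np
import pytest
import scipy.linalg

from volfuse.fusion import CCAModel, fit_cca, fuse
from volfuse.synthetic import DualViewConfig, gen_dual_view_features


def whitening_svd_oracle(a, b):
    """Independent CCA implementation: whiten each view, SVD the
    cross-covariance of the whitened views. Written against the textbook
    definition, deliberately sharing no code with the fitted path."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    n = a.shape[0]
    saa = a.T @ a / (n - 1)
    sbb = b.T @ b / (n - 1)
    sab = a.T @ b / (n - 1)
    saa_isqrt = scipy.linalg.fractional_matrix_power(saa, -0.5).real
    sbb_isqrt = scipy.linalg.fractional_matrix_power(sbb, -0.5).real
    u, s, vt = np.linalg.svd(saa_isqrt @ sab @ sbb_isqrt)
    return np.clip(s, 0, 1), saa_isqrt @ u, sbb_isqrt @ vt.T


class TestFitCCA:
    def test_identical_views_all_correlations_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((50, 5))
        model = fit_cca(a, a, lam=0.0)
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-6)

    def test_one_dimensional_equals_abs_pearson(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((80, 1))
        b = -0.7 * a + rng.standard_normal((80, 1))
        model = fit_cca(a, b, lam=0.0)
        expected = abs(np.corrcoef(a[:, 0], b[:, 0])[0, 1])
        assert model.correlations[0] == pytest.approx(expected, abs=1e-10)

    def test_matches_whitening_svd_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((500, 3))
        a = z @ rng.standard_normal((3, 10)) + rng.standard_normal((500, 10))
        b = z @ rng.standard_normal((3, 10)) + rng.standard_normal((500, 10))
        model = fit_cca(a, b, lam=0.0)
        rho_oracle, _, _ = whitening_svd_oracle(a, b)
        np.testing.assert_allclose(model.correlations, rho_oracle, atol=1e-8)

    def test_recovers_generator_theoretical_correlations(self):
        cfg = DualViewConfig(n=2000, p=5, q=5, d_latent=2,
                             loading_scale=(3.0, 1.5), noise_sd=1.0, seed=3)
        a, b, rho = gen_dual_view_features(cfg)
        model = fit_cca(a, b, lam=0.0)
        np.testing.assert_allclose(model.correlations[:2], rho[:2], atol=0.05)

    def test_unit_variance_variates_and_stored_correlation(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((200, 6))
        b = 0.5 * a[:, :4] @ rng.standard_normal((4, 5)) \
            + rng.standard_normal((200, 5))
        model = fit_cca(a, b, lam=0.0)
        va, vb = model.training_variates
        np.testing.assert_allclose(va.std(axis=0, ddof=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(vb.std(axis=0, ddof=1), 1.0, atol=1e-6)
        for j in range(model.d):
            r = np.corrcoef(va[:, j], vb[:, j])[0, 1]
            assert r == pytest.approx(model.correlations[j], abs=1e-6)

    def test_components_uncorrelated_within_view(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((300, 6))
        b = rng.standard_normal((300, 6)) + 0.3 * a
        model = fit_cca(a, b, lam=0.0)
        va, _ = model.training_variates
        gram = np.corrcoef(va.T)
        np.testing.assert_allclose(gram - np.eye(model.d), 0.0, atol=1e-6)

    def test_correlations_sorted_in_unit_interval(self):
        rng = np.random.default_rng(6)
        model = fit_cca(rng.standard_normal((60, 8)),
                        rng.standard_normal((60, 4)), lam=1e-3)
        rho = model.correlations
        assert np.all(np.diff(rho) <= 1e-12)
        assert np.all((rho >= 0) & (rho <= 1 + 1e-12))

    def test_noise_never_increases_leading_correlation(self):
        # statistical monotonicity over 10 seeds
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((400, 2))
            a = z @ rng.standard_normal((2, 5)) + 0.1 * rng.standard_normal((400, 5))
            b = z @ rng.standard_normal((2, 5)) + 0.1 * rng.standard_normal((400, 5))
            r_clean = fit_cca(a, b, lam=0.0).correlations[0]
            b_noisy = b + 2.0 * rng.standard_normal(b.shape)
            r_noisy = fit_cca(a, b_noisy, lam=0.0).correlations[0]
            wins += r_noisy <= r_clean + 1e-9
        assert wins == 10

    def test_wide_views_use_pca_prereduction(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((40, 2))
        a = z @ rng.standard_normal((2, 100)) + 0.5 * rng.standard_normal((40, 100))
        b = z @ rng.standard_normal((2, 100)) + 0.5 * rng.standard_normal((40, 100))
        model = fit_cca(a, b, lam=1e-3)
        assert model.W_A.shape[0] == 100  # folded back to original space
        assert model.d <= 39
        assert model.correlations[0] > 0.8

    def test_errors(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="equal sample counts"):
            fit_cca(rng.standard_normal((10, 3)), rng.standard_normal((11, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            fit_cca(rng.standard_normal((2, 3)), rng.standard_normal((2, 3)))
        bad = rng.standard_normal((10, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_cca(bad, rng.standard_normal((10, 3)))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((100, 4))
        b = rng.standard_normal((100, 4)) + 0.5 * a
        m1 = fit_cca(a, b, lam=0.0)
        m2 = fit_cca(a, b, lam=0.0)
        np.testing.assert_array_equal(m1.W_A, m2.W_A)
        for j in range(m1.d):
            col = m1.W_A[:, j]
            first = col[np.flatnonzero(np.abs(col) > 1e-12)[0]]
            assert first > 0


class TestFuse:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((120, 8))
        b = rng.standard_normal((120, 6)) + 0.4 * a[:, :6]
        return a, b, fit_cca(a, b, lam=0.0, d=4)

    def test_z1_concat_width_2d(self, fitted):
        a, b, model = fitted
        out = fuse(model, a, b, mode="Z1_concat")
        assert out.values.shape == (120, 8)

    def test_z2_sum_width_d(self, fitted):
        a, b, model = fitted
        out = fuse(model, a, b, mode="Z2_sum")
        assert out.values.shape == (120, 4)
        z1 = fuse(model, a, b, mode="Z1_concat").values
        np.testing.assert_allclose(out.values, z1[:, :4] + z1[:, 4:], atol=1e-12)

    def test_training_data_reproduces_stored_variates(self, fitted):
        a, b, model = fitted
        z1 = fuse(model, a, b, mode="Z1_concat").values
        va, vb = model.training_variates
        np.testing.assert_allclose(z1[:, :4], va, atol=1e-10)
        np.testing.assert_allclose(z1[:, 4:], vb, atol=1e-10)

    def test_dimension_mismatch(self, fitted):
        a, b, model = fitted
        with pytest.raises(ValueError, match="do not match"):
            fuse(model, a[:, :5], b)

    def test_unknown_mode(self, fitted):
        a, b, model = fitted
        with pytest.raises(ValueError, match="unknown fusion mode"):
            fuse(model, a, b, mode="Z3")

    def test_save_load_roundtrip(self, fitted, tmp_path):
        a, b, model = fitted
        model.save(tmp_path / "cca.zip")
        back = CCAModel.load(tmp_path / "cca.zip")
        np.testing.assert_array_equal(back.W_A, model.W_A)
        np.testing.assert_array_equal(back.correlations, model.correlations)
        out1 = fuse(model, a, b).values
        out2 = fuse(back, a, b).values
        np.testing.assert_array_equal(out1, out2)
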