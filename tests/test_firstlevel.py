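"""Motion QC, residualization, CompCor, smoothing, and GLM fitting."""

import numpy as np
import pytest

from stressglm.firstlevel import (Mask3D, NuisanceSet, Volume4D, compcor,
                                  dvars, fit_glm, framewise_displacement,
                                  residualize, smooth_gaussian, t_contrast)
from stressglm.paradigm import DesignMatrix, Regressor, assemble_design


def _vol(data, tr=2.0, vox=2.0):
    aff = np.diag([vox, vox, vox, 1.0])
    return Volume4D(np.asarray(data, dtype=np.float64), aff, tr)


def _full_mask(shape, vox=2.0):
    return Mask3D(np.ones(shape, dtype=bool), np.diag([vox, vox, vox, 1.0]))


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        out = framewise_displacement(np.zeros((100, 6)))
        assert not out.fd.any() and not out.excluded

    def test_translation_step(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 1.0
        out = framewise_displacement(m)
        assert out.fd[5] == pytest.approx(1.0)
        assert out.fd[4] == 0.0 and out.fd[6] == 0.0

    def test_rotation_scaled_by_radius(self):
        m = np.zeros((10, 6))
        m[5:, 3] = 0.01
        out = framewise_displacement(m, radius=50.0)
        assert out.fd[5] == pytest.approx(0.5)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="6"):
            framewise_displacement(np.zeros((10, 5)))

    def test_exclusion_threshold(self):
        m = np.cumsum(np.full((50, 6), 0.5), axis=0)   # huge drift
        assert framewise_displacement(m).excluded


class TestDvars:
    def test_constant_volume_is_zero(self):
        v = _vol(np.full((4, 4, 4, 20), 50.0))
        out = dvars(v, _full_mask((4, 4, 4)))
        assert np.allclose(out.series, 0.0) and not out.spike_flags.any()

    def test_corrupted_frame_flagged(self, rng):
        data = 100 + rng.normal(0, 1, size=(5, 5, 5, 40))
        data[..., 17] *= 1.10
        out = dvars(_vol(data), _full_mask((5, 5, 5)))
        flagged = np.flatnonzero(out.spike_flags)
        assert 17 in flagged and 18 in flagged   # jump in and out

    def test_spike_count_monotone_in_threshold(self, rng):
        data = 100 + rng.normal(0, 1, size=(5, 5, 5, 60))
        v = _vol(data)
        m = _full_mask((5, 5, 5))
        counts = [dvars(v, m, spike_iqr_factor=f).spike_flags.sum()
                  for f in (0.5, 1.5, 3.0)]
        assert counts[0] >= counts[1] >= counts[2]


class TestResidualize:
    def test_linear_trend_removed(self):
        trend = np.linspace(0, 10, 50)
        data = np.tile(trend, (3, 3, 3, 1)) + 100.0
        out = residualize(_vol(data), NuisanceSet())
        np.testing.assert_allclose(out.data, 105.0, atol=1e-8)

    def test_motion_copy_removed(self, rng):
        motion = rng.normal(0, 1, size=(60, 6))
        data = np.zeros((2, 2, 2, 60))
        data[..., :] = 100 + 5 * motion[:, 0]
        nuis = NuisanceSet(motion=motion)
        out = residualize(_vol(data), nuis)
        resid = out.data[0, 0, 0] - out.data[0, 0, 0].mean()
        assert np.abs(np.corrcoef(resid + rng.normal(0, 1e-12, 60),
                                  motion[:, 0])[0, 1]) < 1e-6 or \
            np.allclose(resid, 0, atol=1e-8)

    def test_orthogonal_signal_untouched(self, rng):
        n = 120
        motion = rng.normal(0, 1, size=(n, 6))
        sig = np.sin(2 * np.pi * np.arange(n) / 10)
        # orthogonalize the signal against the nuisance space first
        X = np.column_stack([np.ones(n), np.linspace(-1, 1, n), motion])
        sig_o = sig - X @ np.linalg.lstsq(X, sig, rcond=None)[0]
        data = np.zeros((2, 2, 2, n)) + 100 + sig_o
        out = residualize(_vol(data), NuisanceSet(motion=motion))
        resid = out.data[0, 0, 0] - 100.0
        c = np.corrcoef(resid, sig_o)[0, 1]
        assert c > 0.999

    def test_spikes_zero_centered_residual(self, rng):
        n = 50
        data = 100 + rng.normal(0, 1, size=(3, 3, 3, n))
        flags = np.zeros(n, dtype=bool)
        flags[[7, 23]] = True
        out = residualize(_vol(data), NuisanceSet(spike_flags=flags))
        centered = out.data - out.data.mean(axis=-1, keepdims=True)
        assert np.abs(centered[..., 7]).max() < 1e-8
        assert np.abs(centered[..., 23]).max() < 1e-8


class TestCompCor:
    def test_embedded_sinusoid_recovered(self, rng):
        n, nvox = 100, 200
        sine = np.sin(2 * np.pi * np.arange(n) / 12)
        data = (np.outer(sine, rng.uniform(0.5, 1.5, nvox))
                + rng.normal(0, 0.3, size=(n, nvox)))
        vol = _vol(data.T.reshape(10, 20, 1, n) + 100)
        comps = compcor(vol, _full_mask((10, 20, 1)), n_components=5)
        assert comps.shape == (n, 5)
        assert abs(np.corrcoef(comps[:, 0], sine)[0, 1]) > 0.95

    def test_components_orthonormal(self, rng):
        data = 100 + rng.normal(0, 1, size=(6, 6, 2, 80))
        comps = compcor(_vol(data), _full_mask((6, 6, 2)), 5)
        gram = comps.T @ comps
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_too_few_voxels_rejected(self, rng):
        data = 100 + rng.normal(0, 1, size=(1, 1, 3, 40))
        with pytest.raises(ValueError, match="voxels"):
            compcor(_vol(data), _full_mask((1, 1, 3)), 5)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        v = _vol(rng.normal(size=(8, 8, 8, 3)))
        assert smooth_gaussian(v, 0.0) is v

    def test_delta_half_maximum_at_fwhm_over_two(self):
        data = np.zeros((25, 25, 25, 1))
        data[12, 12, 12, 0] = 1.0
        out = smooth_gaussian(_vol(data, vox=2.0), 6.0)
        prof = out.data[:, 12, 12, 0]
        peak = prof[12]
        # half maximum 3 mm = 1.5 voxels from the peak
        half_at = np.interp(peak / 2, prof[12:18][::-1],
                            np.arange(12, 18)[::-1]) - 12
        assert half_at * 2.0 == pytest.approx(3.0, abs=0.3)

    def test_constant_unchanged(self):
        v = _vol(np.full((8, 8, 8, 2), 7.0))
        out = smooth_gaussian(v, 6.0)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-10)

    def test_global_mean_conserved(self, rng):
        v = _vol(rng.normal(100, 10, size=(10, 10, 10, 2)))
        out = smooth_gaussian(v, 6.0)
        for t in range(2):
            assert out.data[..., t].mean() == pytest.approx(
                v.data[..., t].mean(), rel=1e-10)


def _design_from_matrix(M, tr=2.0):
    regs = [Regressor(f"x{j}", M[:, j], "task") for j in range(M.shape[1])]
    return assemble_design(regs, tr=tr)


class TestFitGLM:
    def test_noiseless_exact_recovery(self):
        n = 40
        x = np.sin(np.arange(n))
        X = _design_from_matrix(x[:, None])
        y = (2.0 + 3.0 * x)[:, None]
        fit = fit_glm(y, X)
        assert fit.beta[0, 0] == pytest.approx(3.0, abs=1e-10)
        assert fit.beta[0, 1] == pytest.approx(2.0, abs=1e-10)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-16)

    def test_matches_statsmodels_on_random_designs(self, rng):
        """Independent oracle: statsmodels OLS on 50 random small problems."""
        import statsmodels.api as sm
        for _ in range(50):
            n, p = 20, 3
            M = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            X = _design_from_matrix(M)
            fit = fit_glm(y[:, None], X)
            ref = sm.OLS(y, X.matrix).fit()
            np.testing.assert_allclose(fit.beta[0], ref.params, atol=1e-8)
            np.testing.assert_allclose(fit.sigma2[0], ref.mse_resid, atol=1e-8)

    def test_sigma2_estimates_noise_variance(self, rng):
        n, nvox = 200, 1000
        M = rng.normal(size=(n, 4))
        X = _design_from_matrix(M)
        y = rng.normal(0, 2.0, size=(n, nvox))
        fit = fit_glm(y, X)
        assert fit.sigma2.mean() == pytest.approx(4.0, rel=0.05)
        assert np.all(fit.sigma2 >= 0)
        assert fit.dof == n - 5

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=30)
        M = np.column_stack([x, 2 * x])
        X = _design_from_matrix(M)
        with pytest.raises(ValueError, match="x1"):
            fit_glm(rng.normal(size=(30, 1)), X)


class TestTContrast:
    def test_sign_flip_negates_t(self, rng):
        M = rng.normal(size=(50, 3))
        X = _design_from_matrix(M)
        fit = fit_glm(rng.normal(size=(50, 20)), X)
        c = np.array([0, 1.0, 0, 0])
        tp = t_contrast(fit, c).t
        tm = t_contrast(fit, -c).t
        np.testing.assert_allclose(tp, -tm)

    def test_matches_closed_form_simple_regression(self):
        """Textbook oracle: slope t-statistic in simple linear regression."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        X = _design_from_matrix(x[:, None])
        fit = fit_glm(y[:, None], X)
        t = t_contrast(fit, np.array([1.0, 0.0])).t[0]
        # closed form
        b = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        a = y.mean() - b * x.mean()
        rss = ((y - a - b * x) ** 2).sum()
        se = np.sqrt(rss / 3 / ((x - x.mean()) ** 2).sum())
        assert t == pytest.approx(b / se, abs=1e-10)

    def test_zero_contrast_rejected(self, rng):
        X = _design_from_matrix(rng.normal(size=(20, 2)))
        fit = fit_glm(rng.normal(size=(20, 2)), X)
        with pytest.raises(ValueError):
            t_contrast(fit, np.zeros(3))

    def test_wrong_length_rejected(self, rng):
        X = _design_from_matrix(rng.normal(size=(20, 2)))
        fit = fit_glm(rng.normal(size=(20, 2)), X)
        with pytest.raises(ValueError, match="length"):
            t_contrast(fit, np.array([1.0]))


class TestResidualizeThenFit:
    def test_equals_joint_model_when_orthogonalized(self, rng):
        """Two-stage nuisance removal equals the joint fit for task betas
        when the task regressor is orthogonal to the stage-1 space."""
        n = 80
        motion = rng.normal(size=(n, 6))
        stage1 = np.column_stack([np.ones(n), np.linspace(-1, 1, n), motion])
        task = rng.normal(size=n)
        task -= stage1 @ np.linalg.lstsq(stage1, task, rcond=None)[0]
        betas_true = rng.normal(size=8)
        y = 100 + 0.7 * task + stage1 @ betas_true + rng.normal(0, 0.5, n)
        # joint fit
        Xj = _design_from_matrix(np.column_stack([task, stage1[:, 1:]]))
        joint_beta = fit_glm(y[:, None], Xj).beta[0, 0]
        # two-stage: residualize against stage 1, then fit task alone
        data = np.zeros((1, 1, 1, n)) + y
        out = residualize(_vol(data), NuisanceSet(motion=motion))
        X2 = _design_from_matrix(task[:, None])
        twostage_beta = fit_glm(out.data.reshape(1, n).T, X2).beta[0, 0]
        assert twostage_beta == pytest.approx(joint_beta, abs=1e-6)
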