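import numpy as np
import pytest
from scipy import stats
from scipy.linalg import toeplitz

from somatomap.er_glm import (
    GLMFit,
    NoiseModel,
    contrast_ttest,
    deconvolved_curves,
    estimate_noise_acf,
    estimate_subject_timing,
    fit_deconvolution,
    fit_gls,
    fit_ols,
)
from somatomap.hrf_design import (HRFTiming, build_canonical_design,
                                  build_fir_design, double_gamma,
                                  orthogonalized_derivative)
from somatomap.phase_encoding import FingertipROI
from somatomap.synthetic_data import (NoiseSpec, make_er_paradigm,
                                      make_somatotopic_phantom, simulate_bold)
from somatomap.timeseries_prep import BoldRun


def white_noise_run(rng, shape, n_time):
    return BoldRun(rng.standard_normal(shape + (n_time,)), 2.0,
                   units="percent", mask=np.ones(shape, bool))


@pytest.fixture(scope="module")
def paradigm():
    return make_er_paradigm(1, seed=5)[0]


@pytest.fixture(scope="module")
def design(paradigm):
    return build_canonical_design(paradigm, HRFTiming())


class TestFitOLS:
    def test_noiseless_exact_recovery(self, paradigm, design):
        ph = make_somatotopic_phantom()
        run = simulate_bold(ph, paradigm,
                            NoiseSpec(0.0, 0.0, 0.0, 128.0, 0),
                            amplitude_percent=2.0)
        fit = fit_ols(design, run)
        i = int(round(ph.band_centers_mm[0] / 1.5))
        assert fit.coef(1, "magnitude")[i, 10, 2] == pytest.approx(
            2.0 * ph.tuning[i, 10, 2, 0], abs=1e-9)

    def test_null_t_statistics_follow_student_t(self, design, paradigm, rng):
        n_vol = design.n_time
        run = white_noise_run(rng, (40, 40, 1), n_vol)
        fit = fit_ols(design, run)
        t, _ = contrast_ttest(fit, 3)
        ks = stats.kstest(t.ravel(), stats.t(fit.dof).cdf)
        assert ks.pvalue > 0.01

    def test_duplicate_column_raises(self, design, paradigm, rng):
        bad = build_canonical_design(paradigm, HRFTiming())
        bad.matrix[:, 1] = 2.0 * bad.matrix[:, 0]
        run = white_noise_run(rng, (2, 2, 1), bad.n_time)
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(bad, run)

    def test_dof(self, design, rng):
        run = white_noise_run(rng, (2, 2, 1), design.n_time)
        fit = fit_ols(design, run)
        assert fit.dof == design.n_time - 11      # 10 task + intercept


def _fake_fit(design, betas_by_finger, shape=(2, 2, 1)):
    """GLMFit with constant betas per labeled column."""
    p = len(design.labels) + 1
    beta = np.zeros(shape + (p,))
    for (f, comp), val in betas_by_finger.items():
        beta[..., design.labels.index((f, comp))] = val
    return GLMFit(design=design, x_full=np.zeros((design.n_time, p)),
                  column_labels=design.labels + [(0, "intercept_0")],
                  beta=beta, stderr=np.ones_like(beta), dof=100,
                  valid=np.ones(shape, bool))


def _one_voxel_roi(finger, shape=(2, 2, 1)):
    vox = np.zeros(shape, bool)
    vox[0, 0, 0] = True
    return FingertipROI(finger, vox)


class TestSubjectTiming:
    def test_zero_derivative_returns_timing0(self, design):
        timing0 = HRFTiming()
        fit = _fake_fit(design, {(f, "magnitude"): 1.0 for f in range(1, 6)})
        rois = [_one_voxel_roi(f) for f in range(1, 6)]
        est = estimate_subject_timing(fit, rois, timing0)
        assert est.t_peak_pos_s == pytest.approx(6.0, abs=0.02)
        assert est.t_peak_neg_s == pytest.approx(16.0, abs=0.05)

    def test_derivative_shifts_peak_earlier(self, design):
        """Fine-grid argmax oracle on the closed-form combination."""
        timing0 = HRFTiming()
        betas = {(f, "magnitude"): 1.0 for f in range(1, 6)}
        betas.update({(f, "derivative"): 0.3 for f in range(1, 6)})
        fit = _fake_fit(design, betas)
        rois = [_one_voxel_roi(f) for f in range(1, 6)]
        est = estimate_subject_timing(fit, rois, timing0,
                                      invert_to_parameters=False)
        # oracle: numeric argmax of 1*h + 0.3*(dh - mix*h) on a 0.01 s grid
        h = double_gamma(HRFTiming(dt_s=0.01), 40.0)
        dh = orthogonalized_derivative(h, 0.01)
        mix = design.deriv_mix[1]
        comb = h + 0.3 * (dh - mix * h)
        expected = np.argmax(comb) * 0.01
        assert est.t_peak_pos_s == pytest.approx(expected, abs=0.011)
        assert expected < 6.0

    def test_across_roi_average(self, design):
        betas = {(f, "magnitude"): 1.0 for f in range(1, 6)}
        betas[(1, "derivative")] = 0.3
        betas[(2, "derivative")] = -0.3
        fit = _fake_fit(design, betas)
        rois = [_one_voxel_roi(1), _one_voxel_roi(2)]
        est = estimate_subject_timing(fit, rois, HRFTiming(),
                                      invert_to_parameters=False)
        singles = []
        for roi in rois:
            singles.append(estimate_subject_timing(
                fit, [roi], HRFTiming(), invert_to_parameters=False))
        assert est.t_peak_pos_s == pytest.approx(
            np.mean([s.t_peak_pos_s for s in singles]), abs=1e-9)

    def test_empty_rois_raise(self, design):
        fit = _fake_fit(design, {(1, "magnitude"): 1.0})
        empty = FingertipROI(1, np.zeros((2, 2, 1), bool))
        with pytest.raises(ValueError):
            estimate_subject_timing(fit, [empty], HRFTiming())

    def test_negative_hrf_roi_excluded_with_warning(self, design):
        # undershoot 0 makes -h non-positive everywhere -> ROI flagged
        timing0 = HRFTiming(undershoot_ratio=0.0)
        betas = {(f, "magnitude"): 1.0 for f in range(1, 6)}
        betas[(1, "magnitude")] = -1.0
        fit = _fake_fit(design, betas)
        rois = [_one_voxel_roi(f) for f in range(1, 6)]
        with pytest.warns(RuntimeWarning):
            est = estimate_subject_timing(fit, rois, timing0,
                                          invert_to_parameters=False)
        assert est.t_peak_pos_s == pytest.approx(6.0, abs=0.05)


class TestNoiseACF:
    def test_white_noise_acf_small(self, rng):
        resid = rng.standard_normal((20, 20, 1, 2000))
        model = estimate_noise_acf(resid, np.ones((20, 20, 1), bool))
        assert np.all(np.abs(model.acf[:, 1:]) < 3.0 / np.sqrt(2000))

    def test_ar1_acf_lag1(self, rng):
        rho, n_time = 0.5, 10000
        eps = rng.standard_normal((20, 20, 1, n_time))
        ar = np.empty_like(eps)
        ar[..., 0] = eps[..., 0]
        for t in range(1, n_time):
            ar[..., t] = rho * ar[..., t - 1] + np.sqrt(1 - rho ** 2) * eps[..., t]
        model = estimate_noise_acf(ar, np.ones((20, 20, 1), bool))
        assert model.raw_acf[0][1] == pytest.approx(0.5, abs=0.02)

    def test_taper_zero_at_m(self, rng):
        resid = rng.standard_normal((4, 4, 1, 500))
        model = estimate_noise_acf(resid, np.ones((4, 4, 1), bool), taper_m=10)
        assert np.all(model.acf[:, 10:] == 0.0)
        assert np.all(model.acf[:, 0] == 1.0)

    def test_empty_tile_inherits_neighbor(self, rng):
        resid = rng.standard_normal((40, 20, 1, 300))
        mask = np.zeros((40, 20, 1), bool)
        mask[:20] = True                      # second tile has no brain voxels
        model = estimate_noise_acf(resid, mask)
        assert np.allclose(model.acf[1], model.acf[0])

    def test_mean_series_method(self, rng):
        resid = rng.standard_normal((20, 20, 1, 1000))
        model = estimate_noise_acf(resid, np.ones((20, 20, 1), bool),
                                   method="mean-series")
        assert abs(model.raw_acf[0][1]) < 0.1


class TestFitGLS:
    def test_identity_noise_equals_ols(self, design, rng):
        run = white_noise_run(rng, (4, 4, 1), design.n_time)
        acf = np.zeros((1, design.n_time))
        acf[0, 0] = 1.0
        noise = NoiseModel(acf=acf, tile_index=np.zeros((4, 4, 1), int))
        gls = fit_gls(design, run, noise)
        ols = fit_ols(design, run)
        assert np.allclose(gls.beta, ols.beta, atol=1e-10)
        assert np.allclose(gls.stderr, ols.stderr, atol=1e-10)

    def test_known_ar1_stderr_closed_form(self, design, rng):
        """stderr matches sqrt(diag((X' V^-1 X)^-1) sigma^2)."""
        rho, n_time = 0.5, design.n_time
        n_vox = 4000
        v = toeplitz(rho ** np.arange(n_time))
        chol = np.linalg.cholesky(v)
        data = (chol @ rng.standard_normal((n_time, n_vox))).T
        run = BoldRun(data.reshape(n_vox, 1, 1, n_time), 2.0, units="percent",
                      mask=np.ones((n_vox, 1, 1), bool))
        acf = np.zeros((1, n_time))
        acf[0, : n_time] = rho ** np.arange(n_time)
        noise = NoiseModel(acf=acf, tile_index=np.zeros((n_vox, 1, 1), int))
        fit = fit_gls(design, run, noise)
        x = fit.x_full
        vinv = np.linalg.inv(v)
        closed = np.sqrt(np.diag(np.linalg.inv(x.T @ vinv @ x)))
        mean_se = np.sqrt((fit.stderr ** 2).mean(axis=(0, 1, 2)))
        assert np.allclose(mean_se, closed, rtol=0.05)

    def test_gls_calibrated_ols_inflated(self, rng):
        """MC calibration: GLS FPR in the binomial CI at alpha=0.05."""
        pars = make_er_paradigm(2, seed=5)
        lengths = [int(p.run_duration_s / 2) for p in pars]
        n_time = sum(lengths)
        shape = (100, 100, 1)
        rho = 0.4
        eps = rng.standard_normal(shape + (n_time,))
        ar = np.empty_like(eps)
        ar[..., 0] = eps[..., 0]
        for t in range(1, n_time):
            ar[..., t] = rho * ar[..., t - 1] + np.sqrt(1 - rho ** 2) * eps[..., t]
        run = BoldRun(ar, 2.0, units="percent", mask=np.ones(shape, bool))
        des = build_canonical_design(pars, HRFTiming())
        ols = fit_ols(des, run, run_lengths=lengths)
        noise = estimate_noise_acf(ols.residuals, np.ones(shape, bool),
                                   x_model=ols.x_full)
        gls = fit_gls(des, run, noise, run_lengths=lengths)
        n = shape[0] * shape[1]
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n)
        fpr_gls = float((contrast_ttest(gls, 1)[1] < 0.05).mean())
        fpr_ols = float((contrast_ttest(ols, 1)[1] < 0.05).mean())
        assert abs(fpr_gls - 0.05) < ci + 0.005
        assert fpr_ols > 0.05 + ci


class TestContrastTTest:
    def test_zero_beta_gives_half(self, design):
        fit = _fake_fit(design, {})
        t, p = contrast_ttest(fit, 1)
        assert np.all(t == 0.0)
        assert np.all(p == 0.5)

    def test_null_p_uniform(self, design, rng):
        run = white_noise_run(rng, (50, 50, 1), design.n_time)
        fit = fit_ols(design, run)
        _, p = contrast_ttest(fit, 2)
        ks = stats.kstest(p.ravel(), "uniform")
        assert ks.pvalue > 0.01

    def test_large_effect_tiny_p(self, paradigm, design):
        ph = make_somatotopic_phantom()
        run = simulate_bold(ph, paradigm, NoiseSpec(0.2, 0.0, 0.0, 128.0, 3),
                            amplitude_percent=2.0)
        run = BoldRun(run.data - 100.0, 2.0, units="percent",
                      mask=ph.brain_mask)
        fit = fit_ols(design, run)
        _, p = contrast_ttest(fit, 3)
        strong = ph.tuning[..., 2] > 0.99
        assert np.all(p[strong] < 1e-6)

    def test_bad_side(self, design):
        with pytest.raises(ValueError):
            contrast_ttest(_fake_fit(design, {}), 1, side="both")


class TestDeconvolution:
    def _noiseless_run(self, paradigm, amp=1.5, hrf_duration=24.0):
        ph = make_somatotopic_phantom()
        run = simulate_bold(ph, paradigm, NoiseSpec(0.0, 0.0, 0.0, 128.0, 0),
                            amplitude_percent=amp, hrf_duration_s=hrf_duration)
        return ph, run

    def test_noiseless_exact_recovery(self, paradigm):
        """True single-trial response (support <= 13 lags) recovered exactly."""
        ph, run = self._noiseless_run(paradigm)
        design = build_fir_design(paradigm)
        fit = fit_deconvolution(design, run)
        curves = deconvolved_curves(fit)
        # oracle: independently convolved single-trial response at TRs
        timing = HRFTiming()
        h = double_gamma(timing, 24.0)
        trial = np.zeros_like(h)
        trial[: int(1.0 / timing.dt_s)] = 1.0
        resp = np.convolve(trial, h)
        resp = 1.5 * resp / resp.max()
        expected = np.array([resp[int(k * 2.0 / timing.dt_s)]
                             if int(k * 2.0 / timing.dt_s) < resp.size else 0.0
                             for k in range(13)])
        i = int(round(ph.band_centers_mm[2] / 1.5))
        assert np.allclose(curves[i, 10, 2, 2], expected, atol=1e-10)

    def test_zero_tuning_voxel_near_zero(self, paradigm):
        ph, run = self._noiseless_run(paradigm)
        design = build_fir_design(paradigm)
        fit = fit_deconvolution(design, run)
        curves = deconvolved_curves(fit)
        assert np.max(np.abs(curves[0, 0, 0])) < 1e-10   # non-gray voxel

    def test_linearity_in_amplitude(self, paradigm):
        ph, run1 = self._noiseless_run(paradigm, amp=1.0)
        _, run2 = self._noiseless_run(paradigm, amp=2.0)
        design = build_fir_design(paradigm)
        c1 = deconvolved_curves(fit_deconvolution(design, run1))
        c2 = deconvolved_curves(fit_deconvolution(design, run2))
        assert np.allclose(c2[ph.gray_mask], 2.0 * c1[ph.gray_mask],
                           atol=1e-9)
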