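import numpy as np
import pytest

from somatomap.hrf_design import HRFTiming, double_gamma
from somatomap.synthetic_data import (
    COMPARTMENT_ANTERIOR,
    COMPARTMENT_POSTERIOR,
    NoiseSpec,
    ParadigmER,
    ParadigmPE,
    make_er_paradigm,
    make_pe_paradigm,
    make_somatotopic_phantom,
    make_vein_phantom,
    simulate_bold,
)

ITI_SET = {4.0, 6.0, 8.0, 10.0, 12.0}


def validate_er_run(par):
    """Independent validator for the ER paradigm invariants."""
    fingers = [f for _, f in par.events]
    onsets = [o for o, _ in par.events]
    assert len(par.events) == 30
    for f in range(1, 6):
        assert fingers.count(f) == 6
    for o in onsets:
        assert o % par.tr_s == 0
    assert set(np.diff(onsets).tolist()) <= ITI_SET
    for b in range(6):
        assert sorted(fingers[5 * b: 5 * b + 5]) == [1, 2, 3, 4, 5]


class TestSomatotopicPhantom:
    def test_band_center_tuning_is_one(self, phantom):
        # finger-3 band center at 21 mm sits exactly on lattice index 14
        i = int(round(phantom.band_centers_mm[2] / phantom.voxel_size_mm[0]))
        v = phantom.tuning[i, 10, 2]
        assert v[2] == pytest.approx(1.0)
        assert np.all(v[2] >= v)
        assert phantom.preferred_finger[i, 10, 2] == 3

    def test_equal_sigmas_give_identical_compartment_tuning(self):
        ph = make_somatotopic_phantom(sigma_tuning_anterior_mm=3.0,
                                      sigma_tuning_posterior_mm=3.0,
                                      far_posterior_fraction=0.0)
        ant = ph.tuning[ph.compartment == COMPARTMENT_ANTERIOR]
        post = ph.tuning[ph.compartment == COMPARTMENT_POSTERIOR]
        # same x-profile on both sides: compare sorted flattened values
        assert np.allclose(np.sort(ant, axis=None)[:: ant.size // 50],
                           np.sort(post, axis=None)[:: post.size // 50])

    def test_adjacent_finger_tuning_higher_posteriorly(self):
        """Closed-form Gaussian oracle at the 5.5 mm band spacing."""
        sig_a, sig_p = 2.0, 4.0
        ph = make_somatotopic_phantom(sigma_tuning_anterior_mm=sig_a,
                                      sigma_tuning_posterior_mm=sig_p,
                                      far_posterior_fraction=0.0)
        i = int(round(ph.band_centers_mm[2] / ph.voxel_size_mm[0]))
        ant = ph.tuning[i][ph.compartment[i] == COMPARTMENT_ANTERIOR]
        post = ph.tuning[i][ph.compartment[i] == COMPARTMENT_POSTERIOR]
        d = 21.0 - ph.band_centers_mm[1]           # distance to finger-2 band
        expect_a = np.exp(-d ** 2 / (2 * sig_a ** 2))
        expect_p = np.exp(-d ** 2 / (2 * sig_p ** 2))
        assert ant[:, 1] == pytest.approx(expect_a)
        assert post[:, 1] == pytest.approx(expect_p)
        assert post[:, 1].mean() > ant[:, 1].mean()

    def test_invariants(self, phantom):
        assert phantom.tuning.min() >= 0 and phantom.tuning.max() <= 1
        assert np.all(phantom.brain_mask[phantom.gray_mask])
        # anterior tuning strictly narrower: mean cross-finger spread lower
        ant = phantom.tuning[phantom.compartment == COMPARTMENT_ANTERIOR]
        post = phantom.tuning[phantom.compartment == COMPARTMENT_POSTERIOR]
        assert ant.sum(axis=1).mean() < post.sum(axis=1).mean()

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            make_somatotopic_phantom(sigma_tuning_anterior_mm=-1.0)
        with pytest.raises(ValueError):
            make_somatotopic_phantom(grid_shape=(0, 4, 4))


class TestERParadigm:
    def test_event_counts(self):
        run = make_er_paradigm(1, seed=0)[0]
        assert len(run.events) == 30
        for f in range(1, 6):
            assert sum(1 for _, g in run.events if g == f) == 6

    def test_first_block_is_permutation(self):
        run = make_er_paradigm(1, seed=1)[0]
        assert sorted(f for _, f in run.events[:5]) == [1, 2, 3, 4, 5]

    @pytest.mark.parametrize("seed", range(0, 1000, 100))
    def test_validator_over_seeds(self, seed):
        for run in make_er_paradigm(2, seed=seed):
            validate_er_run(run)

    def test_itis_over_many_seeds(self):
        itis = set()
        for seed in range(1000):
            run = make_er_paradigm(1, seed=seed)[0]
            itis |= set(np.diff([o for o, _ in run.events]).tolist())
        assert itis == ITI_SET

    def test_runs_differ_across_subseeds(self):
        a, b = make_er_paradigm(2, seed=0)
        assert a.events != b.events

    def test_n_runs_positive(self):
        with pytest.raises(ValueError):
            make_er_paradigm(0)


class TestPEParadigm:
    def test_forward_schedule(self):
        par = make_pe_paradigm(40.0, 8, "forward")
        assert par.run_duration_s == 320.0
        assert par.stim_freq_cycles_per_run == 8
        epochs = par.finger_epochs()
        assert epochs[0] == (0.0, 8.0, 1)

    def test_reverse_is_mirror(self):
        par = make_pe_paradigm(40.0, 8, "reverse")
        assert par.finger_epochs()[0][2] == 5
        fwd = make_pe_paradigm(40.0, 8, "forward").stimulus_trains(0.1)
        rev = par.stimulus_trains(0.1)
        # time-mirror within each cycle
        n_cycle = int(40.0 / 0.1)
        assert np.array_equal(rev[:, :n_cycle], fwd[:, :n_cycle][:, ::-1])

    def test_non_divisible_period_raises(self):
        with pytest.raises(ValueError):
            make_pe_paradigm(37.0, 8)


class TestSimulateBold:
    def test_single_event_unit_tuning_equals_scaled_hrf(self, phantom):
        par = ParadigmER(events=[(10.0, 3)], run_duration_s=60.0)
        noise = NoiseSpec(sigma=0.0, ar1_rho=0.0, drift_amplitude=0.0, seed=0)
        amp = 2.0
        run = simulate_bold(phantom, par, noise, amplitude_percent=amp)
        i = int(round(phantom.band_centers_mm[2] / 1.5))
        series = run.data[i, 10, 2] - 100.0
        # oracle: convolve the 1 s boxcar with the HRF independently
        timing = HRFTiming()
        h = double_gamma(timing, 32.0)
        dt = timing.dt_s
        trial = np.zeros_like(h)
        trial[: int(1.0 / dt)] = 1.0
        resp = np.convolve(trial, h)
        resp = amp * resp / resp.max()
        expected = np.zeros(30)
        onset_vol = 5
        for k in range(30 - onset_vol):
            idx = int(k * 2.0 / dt)
            expected[onset_vol + k] = resp[idx] if idx < resp.size else 0.0
        assert series == pytest.approx(expected, abs=1e-10)

    def test_zero_tuning_constant_baseline(self):
        ph = make_somatotopic_phantom(grid_shape=(4, 4, 2))  # all non-gray rim
        ph.tuning[:] = 0.0
        par = ParadigmER(events=[(0.0, 1)], run_duration_s=20.0)
        noise = NoiseSpec(sigma=0.0, ar1_rho=0.0, drift_amplitude=0.0, seed=0)
        run = simulate_bold(ph, par, noise)
        assert np.allclose(run.data, 100.0)

    def test_ar1_autocorrelation(self):
        ph = make_somatotopic_phantom(grid_shape=(3, 3, 1))
        ph.tuning[:] = 0.0
        par = ParadigmER(events=[], run_duration_s=20000.0)
        noise = NoiseSpec(sigma=1.0, ar1_rho=0.5, drift_amplitude=0.0, seed=4)
        run = simulate_bold(ph, par, noise)
        x = run.data.reshape(9, -1) - 100.0
        x = x - x.mean(axis=-1, keepdims=True)
        rho1 = float((x[:, :-1] * x[:, 1:]).sum() / (x * x).sum())
        assert rho1 == pytest.approx(0.5, abs=0.02)
        assert np.std(x) == pytest.approx(1.0, rel=0.05)

    def test_deterministic_for_fixed_seed(self, phantom, er_paradigms):
        noise = NoiseSpec(seed=9)
        a = simulate_bold(phantom, er_paradigms[0], noise)
        b = simulate_bold(phantom, er_paradigms[0], noise)
        assert np.array_equal(a.data, b.data)

    def test_noiseless_regression_recovers_tuning(self, phantom, er_paradigms):
        """sigma=0: OLS on the true design returns amplitude*tuning exactly."""
        from somatomap.er_glm import fit_ols
        from somatomap.hrf_design import build_canonical_design

        par = er_paradigms[0]
        noise = NoiseSpec(sigma=0.0, ar1_rho=0.0, drift_amplitude=0.0, seed=0)
        amp = 1.5
        run = simulate_bold(phantom, par, noise, amplitude_percent=amp)
        design = build_canonical_design(par, HRFTiming())
        fit = fit_ols(design, run)
        i = int(round(phantom.band_centers_mm[2] / 1.5))
        for f in range(1, 6):
            expected = amp * phantom.tuning[i, 10, 2, f - 1]
            assert fit.coef(f, "magnitude")[i, 10, 2] == pytest.approx(
                expected, abs=1e-9)
        assert np.nanmax(np.abs(fit.residuals[phantom.gray_mask])) < 1e-9


class TestVeinPhantom:
    def test_zero_veins_zero_gradient(self):
        vp = make_vein_phantom(grid_shape=(8, 8, 4), n_veins=0,
                               background_gradient_rad=0.0, seed=0)
        assert np.allclose(vp.phase_volume, 0.0)
        assert not vp.true_vein_mask.any()

    def test_ramp_wrap_count(self):
        """A 4*pi ramp wraps exactly twice along the ramp axis."""
        vp = make_vein_phantom(grid_shape=(64, 8, 4), n_veins=0,
                               background_gradient_rad=4.0 * np.pi, seed=0)
        jumps = np.abs(np.diff(vp.phase_volume, axis=0)) > np.pi
        assert np.all(jumps.sum(axis=0) == 2)

    def test_phase_range(self):
        vp = make_vein_phantom(seed=2)
        assert vp.phase_volume.min() > -np.pi - 1e-12
        assert vp.phase_volume.max() <= np.pi + 1e-12

    def test_vein_voxels_pass_highpass_threshold(self):
        """Vein deviations survive the high-pass filter above background."""
        from somatomap.vein_mapping import highpass_phase, unwrap_phase

        vp = make_vein_phantom(seed=5)
        filtered = highpass_phase(unwrap_phase(vp.phase_volume), 10.0,
                                  vp.voxel_size_mm)
        background = np.abs(filtered[~vp.true_vein_mask])
        vein_core = np.abs(filtered[vp.true_vein_mask])
        assert np.median(vein_core) > np.percentile(background, 95)

    def test_n_veins_nonnegative(self):
        with pytest.raises(ValueError):
            make_vein_phantom(n_veins=-1)


def test_noise_spec_requires_stationary_rho():
    with pytest.raises(ValueError):
        NoiseSpec(ar1_rho=1.0)


def test_paradigm_er_validate_rejects_bad_runs():
    good = make_er_paradigm(1, seed=0)[0]
    bad = ParadigmER(events=good.events[:-1] + [(good.events[-1][0], 1)],
                     run_duration_s=good.run_duration_s)
    with pytest.raises(ValueError):
        bad.validate()


def test_paradigm_pe_direction_checked():
    with pytest.raises(ValueError):
        ParadigmPE(40.0, 8, direction="sideways")
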