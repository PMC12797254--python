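"""Outlier flagging, design construction, OLS and smoothing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gamma as gamma_dist

from taskoverlap.firstlevel import (
    arithmetic_contrast,
    build_design_matrix,
    compute_contrast,
    concatenate_designs,
    condition_vs_fixation,
    fit_glm,
    fit_glm_multirun,
    flag_outlier_volumes,
    framewise_displacement,
    smooth_volume,
)
from taskoverlap.hrf import convolve_events, hrf_kernel
from taskoverlap.synthetic import AcquisitionSpec, BlockDesign, Event, make_block_design


# ---------------------------------------------------------------------------
# outlier flagging
# ---------------------------------------------------------------------------


class TestFlagOutliers:
    def test_constant_motion_no_flags(self):
        motion = np.ones((244, 6)) * 0.3
        signal = np.full(244, 500.0)
        report = flag_outlier_volumes(motion, signal)
        assert report.flagged_volumes == ()
        assert not report.run_excluded
        assert report.fraction_flagged == 0.0

    def test_fd_hand_oracle_three_volumes(self):
        """FD = sum |diff translations| + 50 * sum |diff rotations|."""
        motion = np.array(
            [
                [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                [1.0, -0.5, 0.2, 0.01, 0.0, 0.0],
                [1.0, -0.5, 0.2, 0.01, 0.0, 0.0],
            ]
        )
        fd = framewise_displacement(motion)
        # volume 1: |1| + |-0.5| + |0.2| + 50*0.01 = 2.2; volume 2: 0
        np.testing.assert_allclose(fd, [0.0, 2.2, 0.0])

    def test_single_2mm_jump_flags_exactly_that_volume(self):
        motion = np.zeros((244, 6))
        motion[100:, 0] += 2.0  # step: FD spikes only at the transition
        signal = np.full(244, 500.0)
        report = flag_outlier_volumes(motion, signal)
        assert report.flagged_volumes == (100,)
        assert report.reasons[100] == "displacement"
        assert not report.run_excluded

    def test_signal_outlier_flagged(self):
        motion = np.zeros((244, 6))
        rng = np.random.default_rng(0)
        signal = rng.normal(500.0, 1.0, 244)
        signal[42] += 30.0
        report = flag_outlier_volumes(motion, signal)
        assert 42 in report.flagged_volumes
        assert report.reasons[42] == "signal"

    def test_49_of_244_triggers_exclusion(self):
        """49/244 = 0.2008 >= 0.20 -> run excluded."""
        motion = np.zeros((244, 6))
        for i, v in enumerate(range(4, 4 + 49 * 4, 4)):
            motion[v:, 0] += 2.0 * (-1) ** i
        signal = np.full(244, 500.0)
        report = flag_outlier_volumes(motion, signal)
        assert len(report.flagged_volumes) == 49
        assert report.fraction_flagged == pytest.approx(49 / 244)
        assert report.run_excluded

    def test_48_of_244_not_excluded(self):
        motion = np.zeros((244, 6))
        for i, v in enumerate(range(4, 4 + 48 * 4, 4)):
            motion[v:, 0] += 2.0 * (-1) ** i
        report = flag_outlier_volumes(motion, np.full(244, 500.0))
        assert len(report.flagged_volumes) == 48
        assert not report.run_excluded

    def test_non_finite_motion_rejected(self):
        motion = np.zeros((10, 6))
        motion[3, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            flag_outlier_volumes(motion, np.ones(10))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


class TestBuildDesignMatrix:
    def test_column_count_no_flags_all_correct(self, small_spec, arithmetic_design):
        motion = np.random.default_rng(0).normal(size=(244, 6)).cumsum(axis=0)
        dm = build_design_matrix(arithmetic_design, small_spec, motion, None)
        # 3 conditions + 6 motion + drift + intercept
        assert dm.n_regressors == 3 + 6 + 2
        assert dm.omitted_conditions == []

    def test_missing_condition_omitted_and_recorded(self, small_spec):
        events = [Event("Small", 10.0, 3.5), Event("Large", 20.0, 3.5)]
        design = BlockDesign(task="arithmetic", events=events)
        dm = build_design_matrix(design, small_spec)
        assert "PlusOne" not in dm.column_labels
        assert dm.omitted_conditions == ["PlusOne"]

    def test_incorrect_trials_regressor(self, small_spec):
        events = [
            Event("Small", 10.0, 3.5, correct=True),
            Event("Large", 20.0, 3.5, correct=False),
        ]
        design = BlockDesign(task="arithmetic", events=events)
        dm = build_design_matrix(design, small_spec)
        assert "incorrect" in dm.column_labels
        # Large had only an incorrect trial -> no Large condition column
        assert "Large" not in dm.column_labels

    def test_spike_columns(self, small_spec, arithmetic_design):
        motion = np.zeros((244, 6))
        motion[50:, 0] += 2.0
        report = flag_outlier_volumes(motion, np.full(244, 500.0))
        dm = build_design_matrix(arithmetic_design, small_spec, None, report)
        assert "spike_50" in dm.column_labels
        col = dm.matrix[:, dm.column_index("spike_50")]
        assert col[50] == 1.0 and col.sum() == 1.0

    def test_convolved_block_regressor_shape(self, small_spec):
        """Rises after onset, plateaus, returns toward 0 ~30 s after offset."""
        events = [Event("Small", 30.0 + 5.5 * k, 3.5) for k in range(6)]
        design = BlockDesign(task="arithmetic", events=events)
        dm = build_design_matrix(design, small_spec)
        reg = dm.matrix[:, dm.column_index("Small")]
        assert np.all(np.abs(reg[:30]) < 1e-8)  # nothing before onset
        assert reg[45] > 0.5 * reg.max()  # rising/plateau mid-block
        offset = 30.0 + 5 * 5.5 + 3.5  # last trial ends ~61 s
        assert abs(reg[int(offset) + 32]) < 0.05 * reg.max()  # decayed

    def test_convolution_matches_direct_oracle(self, small_spec):
        """Independent brute-force convolution with the double-gamma kernel."""
        onsets, durations = np.array([12.0, 40.0]), np.array([3.5, 3.5])
        tr, n_vol, dt = 1.0, 80, 0.1
        fine_t = np.arange(0, n_vol * tr + dt, dt)
        box = np.zeros_like(fine_t)
        for o, d in zip(onsets, durations):
            box[(fine_t >= o) & (fine_t < o + d)] = 1.0
        h = gamma_dist.pdf(fine_t, 6.0) - gamma_dist.pdf(fine_t, 16.0) / 6.0
        h = h / h.max()
        oracle = np.array(
            [
                np.sum(box * np.where(i * tr - fine_t >= 0,
                                      np.interp(i * tr - fine_t, fine_t, h), 0.0)) * dt
                for i in range(n_vol)
            ]
        )
        reg = convolve_events(onsets, durations, n_vol, tr, oversampling=10)
        np.testing.assert_allclose(reg, oracle, atol=5e-3)

    def test_events_beyond_run_rejected(self, small_spec):
        events = [Event("Small", 243.0, 3.5)]
        design = BlockDesign(task="arithmetic", events=events)
        with pytest.raises(ValueError, match="beyond the run duration"):
            build_design_matrix(design, small_spec)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def _toy_design():
    x = np.array(
        [
            [1.0, 0.2],
            [1.0, 0.8],
            [1.0, -0.3],
            [1.0, 1.1],
            [1.0, 0.5],
            [1.0, -0.9],
        ]
    )
    from taskoverlap.firstlevel import DesignMatrix

    return DesignMatrix(matrix=x, column_labels=["intercept", "reg"],
                        condition_labels=["reg"])


class TestFitGlm:
    def test_normal_equations_oracle_single_voxel(self):
        """Brute-force (X'X)^-1 X'y on a hand-sized design."""
        dm = _toy_design()
        y = np.array([1.0, 2.0, 0.5, 2.5, 1.5, -0.5]).reshape(-1, 1, 1, 1)
        fit = fit_glm(y, dm)
        x = dm.matrix
        beta_oracle = np.linalg.inv(x.T @ x) @ x.T @ y.ravel()
        np.testing.assert_allclose(fit.flat_betas().ravel(), beta_oracle, atol=1e-12)
        resid = y.ravel() - x @ beta_oracle
        sigma2 = resid @ resid / (6 - 2)
        assert fit.sigma2.ravel()[0] == pytest.approx(sigma2)
        assert fit.dof == 4

    def test_contrast_t_matches_bruteforce(self):
        dm = _toy_design()
        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 1, 1, 1))
        fit = fit_glm(y, dm)
        cmap = compute_contrast(fit, {"reg": 1.0})
        x = dm.matrix
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y.ravel()
        resid = y.ravel() - x @ beta
        s2 = resid @ resid / 4
        t_oracle = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
        assert cmap.t.ravel()[0] == pytest.approx(t_oracle, abs=1e-10)

    def test_rank_deficient_names_columns(self):
        from taskoverlap.firstlevel import DesignMatrix

        x = np.ones((10, 2))
        dm = DesignMatrix(matrix=x, column_labels=["intercept", "dup"])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_glm(np.zeros((10, 1, 1, 1)), dm)

    def test_residuals_orthogonal_to_design(self, small_spec, arithmetic_design):
        rng = np.random.default_rng(7)
        dm = build_design_matrix(arithmetic_design, small_spec)
        y = rng.normal(size=(244, 4, 4, 4))
        fit = fit_glm(y, dm)
        inner = dm.matrix.T @ fit.flat_residuals()
        scale = np.abs(dm.matrix).max() * np.abs(y).max()
        assert np.abs(inner).max() <= 1e-6 * scale

    def test_null_type_one_error_calibrated(self):
        """Pure-noise voxels: p < 0.001 rate within 3 SE of nominal at 1e5 tests."""
        from scipy import stats

        dm = _toy_design()
        rng = np.random.default_rng(11)
        n_vox = 100_000
        y = rng.normal(size=(6, n_vox, 1, 1))
        fit = fit_glm(y, dm)
        cmap = compute_contrast(fit, {"reg": 1.0})
        p = stats.t.sf(cmap.t.ravel(), fit.dof)
        rate = float((p < 0.001).mean())
        se = np.sqrt(0.001 * 0.999 / n_vox)
        assert abs(rate - 0.001) <= 3 * se

    def test_multirun_concatenation_run_specific_nuisances(self, small_spec):
        d1 = make_block_design("arithmetic", small_spec, seed=1)
        d2 = make_block_design("arithmetic", small_spec, seed=2)
        dm1 = build_design_matrix(d1, small_spec)
        dm2 = build_design_matrix(d2, small_spec)
        combined = concatenate_designs([dm1, dm2])
        assert combined.n_volumes == 488
        assert combined.condition_labels == ["Small", "Large", "PlusOne"]
        assert "intercept|run1" in combined.column_labels
        assert "intercept|run2" in combined.column_labels
        assert "drift|run2" in combined.column_labels

    def test_multirun_noiseless_recovery(self, small_spec):
        from conftest import single_roi_truth
        from taskoverlap.synthetic import generate_run, simulate_pattern_set

        truth = single_roi_truth(noise_sd=0.0)
        pats = {"roi": simulate_pattern_set(truth, "roi", seed=3)}
        runs, dms = [], []
        for seed in (1, 2):
            d = make_block_design("arithmetic", small_spec, seed=seed)
            run = generate_run(d, truth, small_spec, seed=seed, patterns=pats)
            runs.append(run)
            dms.append(build_design_matrix(d, small_spec, run.motion, None))
        fit = fit_glm_multirun(runs, dms)
        idx = np.flatnonzero(truth.roi_masks["roi"].ravel())
        betas = fit.flat_betas()[fit.design.column_index("Small")][idx]
        np.testing.assert_allclose(betas, 2.0 * pats["roi"]["Small"], atol=1e-8)


class TestContrasts:
    def test_zero_weights_rejected(self, small_spec, arithmetic_design):
        dm = build_design_matrix(arithmetic_design, small_spec)
        fit = fit_glm(np.zeros((244, 2, 2, 2)), dm)
        with pytest.raises(ValueError, match="all zero"):
            compute_contrast(fit, np.zeros(dm.n_regressors))

    def test_weight_on_omitted_condition_raises(self, small_spec):
        events = [Event("Small", 10.0, 3.5), Event("Large", 20.0, 3.5)]
        design = BlockDesign(task="arithmetic", events=events)
        dm = build_design_matrix(design, small_spec)
        fit = fit_glm(np.random.default_rng(0).normal(size=(244, 2, 2, 2)), dm)
        with pytest.raises(KeyError, match="omitted"):
            arithmetic_contrast(fit)

    def test_condition_vs_fixation_is_beta(self, small_spec, arithmetic_design):
        rng = np.random.default_rng(5)
        dm = build_design_matrix(arithmetic_design, small_spec)
        fit = fit_glm(rng.normal(size=(244, 3, 3, 3)), dm)
        cmap = condition_vs_fixation(fit, "Small")
        np.testing.assert_array_equal(cmap.effect, fit.beta_map("Small"))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


class TestSmoothVolume:
    def test_fwhm_zero_identity(self):
        vol = np.random.default_rng(0).normal(size=(8, 8, 8))
        np.testing.assert_array_equal(smooth_volume(vol, 0.0, 2.5), vol)

    def test_interior_delta_mass_conserved(self):
        vol = np.zeros((24, 24, 24))
        vol[12, 12, 12] = 1.0
        out = smooth_volume(vol, 6.0, 2.5)
        assert out.max() < 1.0  # peak attenuated
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        # discrete-kernel oracle for the peak value
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 2.5
        from scipy.ndimage import gaussian_filter1d

        d = np.zeros(25)
        d[12] = 1.0
        k = gaussian_filter1d(d, sigma)
        assert out[12, 12, 12] == pytest.approx(k[12] ** 3, rel=1e-6)

    def test_constant_image_unchanged(self):
        vol = np.full((10, 10, 10), 3.7)
        out = smooth_volume(vol, 6.0, 2.5, mode="nearest")
        np.testing.assert_allclose(out, vol, atol=1e-10)

    @given(scale=st.floats(min_value=-5, max_value=5).filter(lambda s: abs(s) > 1e-3))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_scaling(self, scale):
        vol = np.random.default_rng(1).normal(size=(6, 6, 6))
        a = smooth_volume(scale * vol, 6.0, 2.5)
        b = scale * smooth_volume(vol, 6.0, 2.5)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((5, 5, 5)), -1.0, 2.5)


def test_hrf_kernel_shape():
    k = hrf_kernel(0.1)
    assert k.max() == pytest.approx(1.0)
    t_peak = np.argmax(k) * 0.1
    assert 4.5 <= t_peak <= 6.5  # gamma(6,1) mode: peak at 5 s, SPM convention
    assert k[int(16 / 0.1)] < 0  # undershoot around 16 s
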