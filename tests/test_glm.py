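"""Design matrix, motion censoring, OLS fitting and voxel selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flashmvpa.glm import (DesignMatrix, ExperimentSchedule, build_design,
                           censor_trs, contrast_t, convolved_boxcar,
                           double_gamma_hrf, fit_glm, select_voxels,
                           SELECTION_CONTRAST)
from flashmvpa.synth import SyntheticConfig, build_schedule, small_config


def _manual_design(X, tr=2.0):
    """Wrap a raw matrix as a single-run DesignMatrix for oracle tests."""
    p = X.shape[1]
    return DesignMatrix(X=X, names=[f"c{i}" for i in range(p)],
                        condition_cols={}, n_runs=1, n_trs_per_run=X.shape[0],
                        tr=tr)


class TestCensoring:
    def test_constant_motion_censors_nothing(self):
        m = np.ones((50, 6)) * 0.7
        assert not censor_trs(m, [50]).any()

    def test_spike_censors_tr_and_predecessor(self):
        m = np.zeros((30, 6))
        m[10:, 0] = 0.4                       # permanent step at TR 10
        censored = censor_trs(m, [30])
        assert set(np.flatnonzero(censored)) == {9, 10}

    def test_threshold_is_strict(self):
        m = np.zeros((30, 6))
        m[10:, 0] = 0.3                       # derivative exactly at threshold
        assert not censor_trs(m, [30]).any()
        m[10:, 0] = 0.3 + 1e-9
        assert censor_trs(m, [30]).any()

    def test_between_run_shifts_are_ignored(self):
        m = np.zeros((40, 6))
        m[20:, 2] = 5.0                       # huge shift at the run boundary
        assert not censor_trs(m, [20, 20]).any()

    def test_adding_a_spike_never_shrinks_the_censored_set(self):
        rng = np.random.default_rng(0)
        m = np.cumsum(rng.normal(0, 0.05, size=(60, 6)), axis=0)
        base = censor_trs(m, [60])
        m2 = m.copy()
        m2[40:, 3] += 1.0
        extra = censor_trs(m2, [60])
        assert np.all(extra[base])            # superset

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            censor_trs(np.zeros((10, 6)), [10], threshold=0.0)
        with pytest.raises(ValueError):
            censor_trs(np.zeros((10, 6)), [8])


class TestDesign:
    def test_default_session_has_52_columns(self):
        cfg = SyntheticConfig()
        schedule = build_schedule(cfg, 0)
        motion = np.zeros((schedule.total_trs, 6))
        d = build_design(schedule, motion)
        assert d.X.shape == (1840, 6 + 4 * 10 + 6)

    def test_single_run_without_motion_has_10_columns(self):
        schedule = build_schedule(small_config(n_runs=1), 0)
        d = build_design(schedule)
        assert d.X.shape[1] == 10
        assert np.linalg.matrix_rank(d.X) == 10

    def test_all_fixation_schedule_is_rank_deficient(self):
        cfg = small_config(n_runs=1, n_trs_per_run=4,
                           reps={c: 0 for c in ["CLW-M", "CCW-M", "CLW-S",
                                                "CCW-S", "M", "F"]})
        d = build_design(build_schedule(cfg, 0))
        for cond in ("CLW-M", "CCW-M", "CLW-S", "CCW-S", "M"):
            assert np.all(d.X[:, d.condition_cols[cond]] == 0)
        assert np.linalg.matrix_rank(d.X) < d.n_params

    def test_overlapping_blocks_rejected(self):
        blocks = pd.DataFrame([
            {"run": 0, "onset_s": 0.0, "duration_s": 12.0, "condition": "CLW-M"},
            {"run": 0, "onset_s": 6.0, "duration_s": 12.0, "condition": "CCW-M"},
        ])
        with pytest.raises(ValueError, match="overlap"):
            ExperimentSchedule(tr=2.0, n_runs=1, n_trs_per_run=20, blocks=blocks)

    def test_motion_params_must_cover_all_trs(self):
        schedule = build_schedule(small_config(n_runs=1), 0)
        with pytest.raises(ValueError):
            build_design(schedule, np.zeros((10, 6)))

    def test_hrf_peaks_at_five_seconds(self):
        h = double_gamma_hrf(0.1)
        assert h.max() == pytest.approx(1.0)
        assert np.argmax(h) * 0.1 == pytest.approx(5.0, abs=0.2)

    def test_boxcar_plateau_is_unit(self):
        y = convolved_boxcar(0.0, 60.0, 40, 2.0)
        assert y[14:28].mean() == pytest.approx(1.0, abs=0.01)


class TestOLS:
    @pytest.mark.parametrize("n_trs,n_params,n_vox", [(12, 4, 2), (20, 6, 3)])
    def test_matches_normal_equations_oracle(self, n_trs, n_params, n_vox):
        """OLS betas, residual variance and t equal the explicit pseudo-inverse
        solution on small systems, to 1e-8."""
        rng = np.random.default_rng(n_trs)
        X = rng.normal(size=(n_trs, n_params))
        Y = rng.normal(size=(n_vox, n_trs))
        res = fit_glm(Y, _manual_design(X))
        w = rng.normal(size=n_params)
        # independent oracle: explicit normal equations
        xtx_inv = np.linalg.inv(X.T @ X)
        b0 = xtx_inv @ X.T @ Y.T
        resid = Y.T - X @ b0
        s2 = (resid ** 2).sum(axis=0) / (n_trs - n_params)
        t0 = (b0.T @ w) / np.sqrt(s2 * (w @ xtx_inv @ w))
        assert np.allclose(res.betas, b0.T, atol=1e-8)
        assert np.allclose(res.sigma2, s2, atol=1e-8)
        assert np.allclose(contrast_t(res, w), t0, atol=1e-8)

    def test_exact_data_recovers_betas(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(18, 5))
        b0 = rng.normal(size=(3, 5))
        res = fit_glm(b0 @ X.T, _manual_design(X))
        assert np.allclose(res.betas, b0, atol=1e-10)
        assert np.allclose(res.sigma2, 0.0, atol=1e-18)

    def test_censored_fit_equals_row_deletion(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(4, 20))
        censored = np.zeros(20, bool)
        censored[[3, 4, 11]] = True
        a = fit_glm(Y, _manual_design(X), censored=censored)
        b = fit_glm(Y[:, ~censored], _manual_design(X[~censored]))
        assert np.allclose(a.betas, b.betas)
        assert np.allclose(a.sigma2, b.sigma2)
        assert a.df == b.df

    def test_rejects_nans_and_length_mismatch(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            fit_glm(np.full((2, 10), np.nan), _manual_design(X))
        with pytest.raises(ValueError):
            fit_glm(np.zeros((2, 9)), _manual_design(X))

    def test_white_noise_type_one_calibration(self):
        """On pure noise the contrast t follows its nominal t distribution."""
        rng = np.random.default_rng(3)
        schedule = build_schedule(small_config(n_runs=1), rng)
        d = build_design(schedule)
        Y = rng.normal(size=(2000, schedule.total_trs))
        res = fit_glm(Y, d)
        t = contrast_t(res, SELECTION_CONTRAST)
        p = stats.t.sf(t, res.df)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.02)


class TestContrast:
    def test_zero_contrast_gives_zero_t(self):
        rng = np.random.default_rng(0)
        res = fit_glm(rng.normal(size=(3, 15)),
                      _manual_design(rng.normal(size=(15, 4))))
        assert np.all(contrast_t(res, np.zeros(4)) == 0)

    def test_noiseless_effect_flags_infinite_t(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        b0 = np.array([[1.0, 0.0, 0.0, 0.0]])
        res = fit_glm(b0 @ X.T, _manual_design(X))
        t = contrast_t(res, np.array([1.0, 0.0, 0.0, 0.0]))
        assert np.isinf(t[0]) and t[0] > 0

    def test_t_invariant_to_joint_positive_rescaling(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 4))
        Y = rng.normal(size=(3, 16))
        w = rng.normal(size=4)
        t1 = contrast_t(fit_glm(Y, _manual_design(X)), w)
        t2 = contrast_t(fit_glm(3.7 * Y, _manual_design(X)), 2.5 * w)
        assert np.allclose(t1, t2)


class TestSelection:
    def test_thresholding_keeps_voxels_above_critical_t(self):
        rng = np.random.default_rng(0)
        res = fit_glm(rng.normal(size=(3, 15)),
                      _manual_design(rng.normal(size=(15, 4))))
        alpha, n = 0.01, 100
        t_star = stats.t.isf(alpha / n, res.df)
        t_map = np.array([t_star + 1, t_star - 1, t_star + 2])
        sel, frac = select_voxels(res, np.arange(3), alpha, n, t_map=t_map)
        assert set(sel) == {0, 2}
        assert frac == pytest.approx(2 / 3)

    def test_empty_roi_raises(self):
        rng = np.random.default_rng(0)
        res = fit_glm(rng.normal(size=(3, 15)),
                      _manual_design(rng.normal(size=(15, 4))))
        with pytest.raises(ValueError):
            select_voxels(res, np.array([]), t_map=np.zeros(3))

    def test_all_noise_retention_matches_alpha(self):
        """Without correction, the retained fraction calibrates to alpha."""
        rng = np.random.default_rng(7)
        schedule = build_schedule(small_config(n_runs=1), rng)
        d = build_design(schedule)
        Y = rng.normal(size=(3000, schedule.total_trs))
        res = fit_glm(Y, d)
        _, frac = select_voxels(res, np.arange(3000), alpha=0.05, correction_n=1)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_default_synthetic_retention_in_reported_range(self, small_dataset):
        """With the default generator the Bonferroni selection keeps roughly
        half the ROI voxels, the regime reported for early visual areas."""
        from flashmvpa.controls import participant_glm

        corr_n = sum(len(v) for v in small_dataset.roi_voxels.values())
        fracs = []
        for p in small_dataset.participants[:3]:
            res, _ = participant_glm(p)
            for vox in small_dataset.roi_voxels.values():
                _, f = select_voxels(res, vox, 0.01, corr_n)
                fracs.append(f)
        assert 0.3 <= np.mean(fracs) <= 0.6
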