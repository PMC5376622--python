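"""Random-cluster, confound, split-half and effect-size controls."""

import numpy as np
import pytest

from flashmvpa.controls import (ClusterNullResult, ROIMask,
                                cluster_specificity_null, confound_correlation,
                                dataset_maps, debiased_mad_ratio,
                                effect_size_estimate, expected_mad_ratio,
                                random_cluster, split_half_validation)
from flashmvpa.mvpa import fisher_z
from flashmvpa.synth import (ROISpec, build_schedule, generate_betas,
                             generate_dataset, place_rois, small_config)


class TestRandomCluster:
    GRID = (13, 13, 13)

    def test_single_voxel_cluster_is_the_seed(self):
        mask = np.ones(np.prod(self.GRID), bool)
        cl = random_cluster(mask, self.GRID, 1, rng=0)
        assert cl.voxels.size == 1
        assert cl.source == "random-cluster"

    def test_seven_voxels_are_seed_plus_face_neighbors(self):
        # rng seed 2 draws an interior seed voxel on the full 13^3 lattice
        mask = np.ones(np.prod(self.GRID), bool)
        cl = random_cluster(mask, self.GRID, 7, rng=2)
        coords = np.indices(self.GRID).reshape(3, -1).T[cl.voxels]
        center = coords[np.argmin(np.linalg.norm(coords - coords.mean(0), axis=1))]
        d = np.linalg.norm(coords - center, axis=1)
        assert sorted(d.round(6)) == [0.0] + [1.0] * 6

    def test_fixed_seed_reproduces_cluster(self):
        mask = np.ones(np.prod(self.GRID), bool)
        a = random_cluster(mask, self.GRID, 25, rng=5)
        b = random_cluster(mask, self.GRID, 25, rng=5)
        assert np.array_equal(a.voxels, b.voxels)

    def test_exact_size_within_mask_and_disjoint_from_excluded(self):
        rng = np.random.default_rng(0)
        mask = rng.random(np.prod(self.GRID)) < 0.6
        exclude = np.flatnonzero(mask)[:200]
        for seed in range(5):
            cl = random_cluster(mask, self.GRID, 40, rng=seed, exclude=exclude)
            assert cl.voxels.size == 40
            assert mask[cl.voxels].all()
            assert len(np.intersect1d(cl.voxels, exclude)) == 0

    def test_unreachable_target_raises(self):
        mask = np.zeros(np.prod(self.GRID), bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="target_n"):
            random_cluster(mask, self.GRID, 10, rng=0)

    def test_mask_validation(self):
        with pytest.raises(ValueError):
            ROIMask("x", np.array([]))
        with pytest.raises(ValueError):
            ROIMask("x", np.array([1]), source="atlas")


class TestClusterSpecificity:
    def test_null_effect_target_sits_inside_the_null(self):
        """kappa = 0 everywhere: the ROI mean is just another cluster mean,
        so its exceedance p stays away from both tails on average."""
        ps = []
        for s in range(6):
            cfg = small_config(n_participants=5, roi_specs=(
                ROISpec("V1", 40, 0.0), ROISpec("hMT", 40, 0.0)))
            ds = generate_dataset(cfg, seed=100 + s)
            maps = dataset_maps(ds)
            vox = ds.roi_voxels["V1"]
            zs = [fisher_z(float(np.corrcoef(m["dm"][vox], m["ds"][vox])[0, 1]))
                  for m in maps]
            res = cluster_specificity_null(ds, float(np.mean(zs)), target_n=40,
                                           n_clusters=60, rng=s, maps=maps)
            ps.append(res.p)
        assert 0.2 < np.mean(ps) < 0.9

    def test_selection_mode_drops_invalid_clusters(self, small_dataset):
        """With voxel selection inside each cluster, clusters with too few
        surviving voxels in too many participants are excluded."""
        maps = dataset_maps(small_dataset)
        res = cluster_specificity_null(
            small_dataset, target_mean_z=0.4, target_n=30, n_clusters=40,
            mode="matched-size-with-selection", rng=0, alpha=0.01, maps=maps)
        assert isinstance(res, ClusterNullResult)
        assert 1 <= res.n_valid <= res.n_clusters

    def test_planted_effect_beats_the_cluster_null(self, small_dataset,
                                                   small_fit):
        fits, _ = small_fit
        maps = [{"dm": f.result.condition_betas("CLW-M")
                 - f.result.condition_betas("CCW-M"),
                 "ds": f.result.condition_betas("CLW-S")
                 - f.result.condition_betas("CCW-S"),
                 "sel_p": f.sel_p} for f in fits]
        target = float(np.mean([f.corr["V1"].z for f in fits]))
        res = cluster_specificity_null(small_dataset, target, target_n=16,
                                       n_clusters=100, rng=3, maps=maps)
        assert res.p <= 0.02

    def test_unknown_mode_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            cluster_specificity_null(small_dataset, 0.0, 10, mode="nearest",
                                     maps=[])


class TestConfoundCorrelation:
    def test_metric_equal_to_z_gives_unit_r_and_saturated_p(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(7, 5))
        cc = confound_correlation(z.copy(), z, n_shuffles=400, rng=1)
        assert cc.r == pytest.approx(1.0)
        assert cc.p_lower > 0.95          # nearly all shuffled are lower
        assert cc.p_greater < 0.05

    def test_constant_metric_is_flagged_undefined(self):
        z = np.random.default_rng(0).normal(size=(7, 5))
        cc = confound_correlation(np.ones((7, 5)), z, n_shuffles=50, rng=0)
        assert not cc.valid and np.isnan(cc.r)

    def test_planted_confound_is_recovered(self):
        rng = np.random.default_rng(2)
        metric = rng.normal(size=(7, 5))
        z = 0.8 * metric + rng.normal(0, 0.5, size=(7, 5))
        cc = confound_correlation(metric, z, n_shuffles=500, rng=3)
        assert cc.r > 0.5
        assert cc.p_greater < 0.05

    def test_shuffle_p_uniform_under_exchangeability(self):
        """Independent metric and z: the upper-tail shuffle p rejects at its
        nominal rate."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 120
        for _ in range(n_rep):
            metric = rng.normal(size=(7, 5))
            z = rng.normal(size=(7, 5))
            cc = confound_correlation(metric, z, n_shuffles=100, rng=rng)
            rejections += cc.p_greater < 0.1
        # binomial 99% band around 0.1 of 120
        assert 3 <= rejections <= 23

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            confound_correlation(np.ones((3, 2)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            confound_correlation(np.ones((3, 1)), np.ones((3, 1)))


class TestSplitHalf:
    def test_noiseless_halves_overlap_completely(self):
        cfg = small_config(n_participants=4, noise_sd=0.0, drift_sd=0.0,
                           motion_coupling_sd=0.0, motion_spike_rate=0.0)
        ds = generate_dataset(cfg, seed=0)
        res = split_half_validation(ds, "V1")
        assert res.overlap == pytest.approx(1.0)

    def test_default_small_dataset_behaves_sanely(self, small_dataset):
        res = split_half_validation(small_dataset, "V1")
        assert 0.0 < res.overlap <= 1.0
        assert 2 <= len(res.z_full) <= len(small_dataset.participants)
        assert len(res.z_full) == len(res.z_from_odd_selection)
        assert np.isfinite([res.t_odd, res.t_even]).all()

    def test_single_run_rejected(self):
        cfg = small_config(n_participants=4, n_runs=1)
        ds = generate_dataset(cfg, seed=1)
        with pytest.raises(ValueError, match="2 runs"):
            split_half_validation(ds, "V1")


class TestEffectSize:
    def test_identical_maps_give_full_ratio(self):
        x = np.array([0.5, -1.0, 2.0])
        e = effect_size_estimate(x, x, matched_shift_deg=12.0)
        assert e.ratio == pytest.approx(1.0)
        assert e.degrees == pytest.approx(12.0)

    def test_zero_motion_map_gives_zero(self):
        e = effect_size_estimate(np.zeros(5), np.ones(5), 10.0)
        assert e.ratio == 0.0 and e.degrees == 0.0

    def test_half_scale_map(self):
        ds = np.array([1.0, -2.0, 3.0, -4.0])
        e = effect_size_estimate(0.5 * ds, ds, matched_shift_deg=12.0)
        assert e.ratio == pytest.approx(0.5)
        assert e.degrees == pytest.approx(6.0)

    def test_degenerate_physical_map_rejected(self):
        with pytest.raises(ValueError):
            effect_size_estimate(np.ones(4), np.zeros(4), 10.0)
        with pytest.raises(ValueError):
            effect_size_estimate(np.ones(4), np.ones(4), 0.0)

    def test_positive_bias_at_zero_encoding_matches_closed_form(self):
        """kappa = 0: pattern noise alone drives the MAD ratio to
        sd(eta)/sd(P), not zero — the documented positive bias."""
        cfg = small_config(roi_specs=(ROISpec("V1", 200, 0.0),),
                           grid_shape=(7, 7, 7), pattern_noise_sd=0.3)
        vox = place_rois(cfg)["V1"]
        ratios = []
        for s in range(40):
            betas, truth = generate_betas(cfg, s)
            e = effect_size_estimate(truth.motion_pattern[vox],
                                     truth.pattern[vox], 10.0)
            ratios.append(e.ratio)
        expected = expected_mad_ratio(0.0, cfg.pattern_sd, cfg.pattern_noise_sd)
        assert expected == pytest.approx(0.3)
        assert np.mean(ratios) == pytest.approx(expected, abs=0.02)

    def test_debiasing_recovers_kappa_through_the_pipeline(self):
        """Fitting noisy time series inflates both MADs; removing the
        estimated measurement noise recovers kappa without material bias."""
        from conftest import simulate_participant
        from flashmvpa.glm import build_design, fit_glm

        cfg = small_config(pattern_noise_sd=0.0)
        vox = place_rois(cfg)["V1"]
        rng = np.random.default_rng(12)
        ratios = []
        for _ in range(40):
            schedule, Y, _, _, _ = simulate_participant(cfg, rng)
            d = build_design(schedule)
            res = fit_glm(Y[vox], d)
            dm = res.condition_betas("CLW-M") - res.condition_betas("CCW-M")
            ds_ = res.condition_betas("CLW-S") - res.condition_betas("CCW-S")
            wd = d.condition_weights({"CLW-M": 1.0, "CCW-M": -1.0})
            ws = d.condition_weights({"CLW-S": 1.0, "CCW-S": -1.0})
            s2 = float(np.mean(res.sigma2))
            se_m = np.sqrt(s2 * (wd @ res.xtx_pinv @ wd))
            se_s = np.sqrt(s2 * (ws @ res.xtx_pinv @ ws))
            ratios.append(debiased_mad_ratio(np.mean(np.abs(dm)),
                                             np.mean(np.abs(ds_)), se_m, se_s))
        assert np.mean(ratios) == pytest.approx(0.2, abs=0.03)
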