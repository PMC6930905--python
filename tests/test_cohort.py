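"""Synthetic-cohort generator: construction, planted effects, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

from smnet import (
    CohortConfig,
    EffectSpec,
    build_ground_truth,
    default_effects,
    default_ground_truth,
    generate_cohort,
    simulate_nuisance,
    simulate_session,
    simulate_voxel_rois,
)
from smnet.atlas import LEFT_PCL_ROI
from smnet.cohort import session_covariance
from smnet.netbuild import correlation_matrix, extract_all_rois, threshold_by_sparsity


class TestGroundTruth:
    def test_single_module_zero_correlation_is_identity(self):
        gt = build_ground_truth(n_nodes=29, modules=[0] * 29, within_r=0.0, between_r=0.0)
        assert np.array_equal(gt.covariance, np.eye(29))

    def test_two_module_block_values(self):
        modules = [0] * 3 + [1] * 3
        gt = build_ground_truth(6, modules, within_r=0.5, between_r=0.1)
        cov = gt.covariance
        assert cov[0, 1] == cov[4, 5] == 0.5
        assert cov[0, 3] == cov[2, 5] == 0.1
        assert np.allclose(np.diag(cov), 1.0)

    def test_hub_elevates_cross_module_coupling(self):
        modules = [0] * 3 + [1] * 3
        gt = build_ground_truth(6, modules, 0.5, 0.1, hub_spec={0: 0.3})
        assert np.allclose(gt.covariance[0, 3:], 0.3)
        assert gt.covariance[1, 3] == 0.1

    def test_default_is_positive_semidefinite(self, ground_truth):
        assert np.linalg.eigvalsh(ground_truth.covariance).min() >= -1e-8

    def test_invalid_contrast_rejected(self):
        with pytest.raises(ValueError):
            build_ground_truth(6, [0] * 6, within_r=0.2, between_r=0.5)


class TestEffectSpec:
    def test_sham_must_be_identity(self):
        with pytest.raises(ValueError):
            EffectSpec("SHAM", None, connectivity_attenuation=0.5)

    def test_responsiveness_keeps_factors_in_unit_interval(self):
        eff = default_effects()["LF"]
        for expo in (0.5, 1.0, 1.5):
            mod = eff.with_responsiveness(expo)
            assert 0 < mod.connectivity_attenuation <= 1
            assert 0 < mod.amplitude_attenuation <= 1


class TestSimulateSession:
    def test_sham_pre_post_same_distributional_parameters(self, ground_truth):
        eff = EffectSpec("SHAM", None)
        cov_pre, sc_pre = session_covariance(ground_truth, eff, "pre")
        cov_post, sc_post = session_covariance(ground_truth, eff, "post")
        assert np.array_equal(cov_pre, cov_post)
        assert np.array_equal(sc_pre, sc_post)

    def test_full_attenuation_decorrelates_target(self, ground_truth):
        eff = EffectSpec("LF", LEFT_PCL_ROI - 1, connectivity_attenuation=0.0)
        cov, _ = session_covariance(ground_truth, eff, "post")
        t = eff.target_node
        assert np.allclose(np.delete(cov[t], t), 0.0)
        # sample correlations shrink toward 0 with many timepoints
        cfg = CohortConfig(n_volumes=2000, noise_sd=0.0, seed=5)
        sess = simulate_session(ground_truth, eff, "post", cfg, 0)
        r = np.corrcoef(sess.data, rowvar=False)[t]
        assert np.abs(np.delete(r, t)).mean() < 0.12

    def test_half_attenuation_halves_target_correlations(self, ground_truth):
        """With amplitude untouched, the mean sample correlation of the
        target's edges post vs pre is the attenuation factor (common
        noise dilution cancels in the ratio)."""
        t = LEFT_PCL_ROI - 1
        eff = EffectSpec("LF", t, connectivity_attenuation=0.5, amplitude_attenuation=1.0)
        cfg = CohortConfig(seed=77)
        pre, post = [], []
        for k in range(50):
            sp = simulate_session(ground_truth, eff, "pre", cfg, (1, k))
            so = simulate_session(ground_truth, eff, "post", cfg, (1, k))
            pre.append(np.delete(np.corrcoef(sp.data, rowvar=False)[t], t).mean())
            post.append(np.delete(np.corrcoef(so.data, rowvar=False)[t], t).mean())
        assert np.mean(post) / np.mean(pre) == pytest.approx(0.5, abs=0.08)

    def test_deterministic_given_seeds(self, ground_truth):
        cfg = CohortConfig(seed=9)
        a = simulate_session(ground_truth, None, "pre", cfg, (2, 3))
        b = simulate_session(ground_truth, None, "pre", cfg, (2, 3))
        assert np.array_equal(a.data, b.data)

    def test_band_limited_variance_fraction(self, ground_truth):
        cfg = CohortConfig(seed=4, noise_sd=0.0)
        sess = simulate_session(ground_truth, None, "pre", cfg, 0)
        f, P = periodogram(sess.data, fs=1.0 / cfg.tr_seconds, axis=0)
        mask = (f >= cfg.passband[0]) & (f <= cfg.passband[1])
        frac = P[mask].sum(axis=0) / P.sum(axis=0)
        assert frac.min() >= 0.8


class TestVoxelSimulation:
    def test_noise_free_weighted_extraction_is_exact(self, ground_truth):
        cfg = CohortConfig(n_volumes=64, seed=1)
        sess = simulate_session(ground_truth, None, "pre", cfg, 0)
        voxels, weights = simulate_voxel_rois(sess, voxels_per_roi=5, voxel_noise_sd=0.0, seed=2)
        rec = extract_all_rois(voxels, weights)
        assert np.allclose(rec, sess.data, atol=1e-10)

    def test_noisy_extraction_recovers_signal(self, ground_truth):
        cfg = CohortConfig(n_volumes=240, seed=1)
        sess = simulate_session(ground_truth, None, "pre", cfg, 0)
        sd = sess.data.std(axis=0).mean()
        voxels, weights = simulate_voxel_rois(
            sess, voxels_per_roi=50, voxel_noise_sd=0.3 * sd, seed=3
        )
        rec = extract_all_rois(voxels, weights)
        for j in range(sess.n_nodes):
            assert np.corrcoef(rec[:, j], sess.data[:, j])[0, 1] > 0.9

    def test_empty_roi_rejected(self, ground_truth):
        cfg = CohortConfig(n_volumes=64, seed=1)
        sess = simulate_session(ground_truth, None, "pre", cfg, 0)
        with pytest.raises(ValueError):
            simulate_voxel_rois(sess, voxels_per_roi=0)


class TestNuisance:
    def test_shapes_and_determinism(self):
        cfg = CohortConfig(seed=8)
        a = simulate_nuisance(cfg, 1)
        b = simulate_nuisance(cfg, 1)
        assert a.motion6.shape == (cfg.n_volumes, 6)
        assert a.wm.shape == a.csf.shape == (cfg.n_volumes,)
        assert np.array_equal(a.motion6, b.motion6)
        assert np.array_equal(a.wm, b.wm)

    def test_motion_step_scale(self):
        cfg = CohortConfig(seed=8)
        nuis = simulate_nuisance(cfg, 2, motion_step_sd=0.02)
        steps = np.diff(nuis.motion6, axis=0)
        assert steps.std() == pytest.approx(0.02, rel=0.2)


class TestCohort:
    def test_bit_reproducible(self):
        cfg = CohortConfig(n_per_group=2, seed=21)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a.sessions, b.sessions):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.data, sb.data)

    def test_layout(self, small_cohort):
        assert len(small_cohort.sessions) == 3 * 4 * 2
        groups = {s.group for s in small_cohort.sessions}
        assert groups == {"HF", "LF", "SHAM"}

    def test_effect_monotonicity_in_degree(self, ground_truth):
        """Mean post-session sample degree of the LF target (sparsity
        0.2) decreases monotonically as connectivity attenuation
        decreases over {1.0, 0.7, 0.4}, averaged across cohorts."""
        t = LEFT_PCL_ROI - 1
        means = []
        for att in (1.0, 0.7, 0.4):
            degs = []
            for c in range(20):
                cfg = CohortConfig(n_per_group=3, seed=300 + c, response_jitter=0.0)
                eff = EffectSpec("LF", t, connectivity_attenuation=att)
                cohort = generate_cohort(
                    cfg, ground_truth, {"LF": eff}, groups=("LF",), with_nuisance=False
                )
                for s in cohort.sessions:
                    if s.session == "post":
                        C = correlation_matrix(s.data)
                        degs.append(threshold_by_sparsity(C, 0.2).adjacency[t].sum())
            means.append(np.mean(degs))
        assert means[0] > means[1] > means[2]

    def test_write_and_read_round_trip(self, small_cohort, tmp_path):
        from smnet import write_cohort
        from smnet.cohort import read_session

        out = write_cohort(small_cohort, tmp_path / "cohort")
        assert (out / "manifest.csv").exists()
        assert (out / "ground_truth.json").exists()
        sess = small_cohort.sessions[0]
        back = read_session(
            out / f"{sess.subject_id}_{sess.session}.tsv",
            sess.subject_id, sess.group, sess.session,
        )
        assert np.allclose(back.data, sess.data, atol=1e-5)
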