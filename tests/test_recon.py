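"""Rigid-body fitting, pose smoothing and the reconstruction chain."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wristsim.geometry import rotation_angle_deg
from wristsim.recon import (
    DegenerateMarkersError,
    PoseSeries,
    fit_rigid_transform,
    fit_rigid_transforms_batch,
    reconstruct_trial,
    smooth_pose_series,
)
from wristsim.wrist import generate_motion_path, make_trial_bundle
from conftest import random_rotation

TRIAD = np.array([[0.0, 0.0, 0.0], [20.0, 5.0, 0.0], [5.0, 18.0, 7.0]])


class TestProcrustes:
    def test_identity_and_pure_translation(self):
        tf, res = fit_rigid_transform(TRIAD, TRIAD)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(res, 0.0)
        tf, _ = fit_rigid_transform(TRIAD, TRIAD + [5.0, 0.0, 0.0])
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, [5.0, 0.0, 0.0], atol=1e-12)

    def test_recovery_under_noise_monte_carlo(self):
        rot_errs, trans_errs = [], []
        for seed in range(100):
            r = np.random.default_rng(seed)
            R = random_rotation(r)
            t = r.normal(size=3) * 20
            obs = TRIAD @ R.T + t + r.normal(scale=0.05, size=TRIAD.shape)
            tf, _ = fit_rigid_transform(TRIAD, obs)
            rot_errs.append(rotation_angle_deg(tf.rotation @ R.T))
            trans_errs.append(np.linalg.norm(tf.translation - t))
        assert np.mean(rot_errs) < 0.3
        assert np.mean(trans_errs) < 0.1

    def test_agrees_with_scipy_align_vectors(self, rng):
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.normal(size=3)
            obs = TRIAD @ R.T + t + rng.normal(scale=0.1, size=TRIAD.shape)
            tf, _ = fit_rigid_transform(TRIAD, obs)
            rot, _ = Rotation.align_vectors(
                obs - obs.mean(axis=0), TRIAD - TRIAD.mean(axis=0)
            )
            assert rotation_angle_deg(tf.rotation @ rot.as_matrix().T) < 1e-5

    def test_agrees_with_angle_grid_search_oracle(self):
        """For a known-axis rotation, an exhaustive 1-deg grid (then refined)
        over the angle agrees with the closed-form fit."""
        axis = np.array([0.0, 0.0, 1.0])
        true_angle = 37.3
        R = Rotation.from_rotvec(np.radians(true_angle) * axis).as_matrix()
        obs = TRIAD @ R.T
        tf, _ = fit_rigid_transform(TRIAD, obs)

        def cost(angle_deg):
            Rg = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
            c = (obs - obs.mean(0)) - (TRIAD - TRIAD.mean(0)) @ Rg.T
            return np.sum(c**2)

        coarse = min(range(360), key=cost)
        fine = min(np.linspace(coarse - 1, coarse + 1, 2001), key=cost)
        est = rotation_angle_deg(tf.rotation)
        assert est == pytest.approx(fine, abs=1e-3)
        assert est == pytest.approx(true_angle, abs=1e-9)

    def test_reflection_is_never_returned(self, rng):
        for _ in range(50):
            obs = TRIAD @ random_rotation(rng).T + rng.normal(scale=2.0, size=TRIAD.shape)
            tf, _ = fit_rigid_transform(TRIAD, obs)
            assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(tf.rotation.T @ tf.rotation, np.eye(3), atol=1e-9)

    def test_degenerate_marker_sets_rejected(self):
        with pytest.raises(DegenerateMarkersError):
            fit_rigid_transform(TRIAD[:2], TRIAD[:2])
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateMarkersError):
            fit_rigid_transform(line, line)

    def test_batch_fit_matches_single_frame_fit(self, rng):
        obs = np.stack([TRIAD @ random_rotation(rng).T + rng.normal(size=3)
                        for _ in range(10)])
        Rs, ts, rms = fit_rigid_transforms_batch(TRIAD, obs)
        for k in range(10):
            tf, _ = fit_rigid_transform(TRIAD, obs[k])
            assert np.allclose(Rs[k], tf.rotation, atol=1e-9)
            assert np.allclose(ts[k], tf.translation, atol=1e-9)


def _sinusoid_series(freq_hz, amp_deg, fps=50.0, n=400):
    t = np.arange(n) / fps
    angles = amp_deg * np.sin(2 * np.pi * freq_hz * t)
    Rs = Rotation.from_euler("Y", angles[:, None], degrees=True).as_matrix()
    return PoseSeries(Rs, np.zeros((n, 3)), fps=fps), angles


class TestSmoothing:
    def test_constant_series_passes_through(self):
        Rs = np.broadcast_to(np.eye(3), (50, 3, 3)).copy()
        ts = np.broadcast_to([1.0, 2.0, 3.0], (50, 3)).copy()
        out = smooth_pose_series(PoseSeries(Rs, ts, fps=50.0))
        assert np.allclose(out.rotations, Rs, atol=1e-9)
        assert np.allclose(out.translations, ts, atol=1e-9)

    def test_slow_motion_attenuated_below_three_percent(self):
        series, angles = _sinusoid_series(0.5, 30.0)
        out = smooth_pose_series(series, cutoff_hz=2.0)
        got = Rotation.from_matrix(out.rotations).as_euler("YZX", degrees=True)[:, 0]
        mid = slice(100, 300)  # away from the padded edges
        atten = 1 - np.max(np.abs(got[mid])) / np.max(np.abs(angles[mid]))
        assert abs(atten) < 0.03

    def test_fast_jitter_suppressed(self):
        series, _ = _sinusoid_series(10.0, 1.0)
        out = smooth_pose_series(series, cutoff_hz=2.0)
        got = Rotation.from_matrix(out.rotations).as_euler("YZX", degrees=True)[:, 0]
        assert np.max(np.abs(got[100:300])) < 0.05

    def test_double_smoothing_is_nearly_idempotent_on_bandlimited_signal(self):
        # 0.1 Hz signal is deep in the 2 Hz passband: a second pass changes
        # the output by less than 1e-3 deg
        series, _ = _sinusoid_series(0.1, 10.0, n=1000)
        once = smooth_pose_series(series)
        twice = smooth_pose_series(once)
        a1 = Rotation.from_matrix(once.rotations).as_euler("YZX", degrees=True)
        a2 = Rotation.from_matrix(twice.rotations).as_euler("YZX", degrees=True)
        assert np.max(np.abs(a1[300:700] - a2[300:700])) < 1e-3

    def test_output_rotations_remain_orthonormal(self):
        series, _ = _sinusoid_series(1.0, 45.0)
        out = smooth_pose_series(series)
        RtR = np.einsum("nji,njk->nik", out.rotations, out.rotations)
        assert np.allclose(RtR, np.eye(3), atol=1e-9)

    def test_short_series_raises_with_minimum_length(self):
        Rs = np.broadcast_to(np.eye(3), (5, 3, 3)).copy()
        with pytest.raises(ValueError, match="at least"):
            smooth_pose_series(PoseSeries(Rs, np.zeros((5, 3)), fps=50.0))

    def test_undersampled_cutoff_rejected(self):
        Rs = np.broadcast_to(np.eye(3), (50, 3, 3)).copy()
        with pytest.raises(ValueError):
            smooth_pose_series(PoseSeries(Rs, np.zeros((50, 3)), fps=3.0), cutoff_hz=2.0)


class TestReconstructTrial:
    def _bundle(self, left_model, rig, sigma, n=80):
        spec = {"motion": "flexion", "amplitude_deg": 50.0, "n_frames": n}
        trials, static = make_trial_bundle(
            left_model, spec, cameras=rig, n_trials=1,
            noise_sigma_mm=sigma, trial_jitter_deg=0.0, seed=5,
        )
        return trials[0]

    def test_noiseless_chain_recovers_truth_to_numerical_precision(
        self, left_model, rig, marker_sets
    ):
        bundle = self._bundle(left_model, rig, 0.0)
        poses = reconstruct_trial(bundle, rig, marker_sets, smooth=False)
        truth = generate_motion_path("flexion", 50.0, 80)
        Rs_truth = truth.matrices()
        mc = poses["MCIII"]
        for k in range(len(mc)):
            assert rotation_angle_deg(mc.rotations[k] @ Rs_truth[k].T) < 1e-6
        # translation of the commanded rotation about the joint center
        jc = left_model.joint_center
        t_truth = jc - np.einsum("nij,j->ni", Rs_truth, jc)
        assert np.abs(mc.translations - t_truth).max() < 1e-6

    def test_bead_noise_keeps_pose_errors_submillimetre_subdegree(
        self, left_model, rig, marker_sets
    ):
        bundle = self._bundle(left_model, rig, 0.1, n=120)
        poses = reconstruct_trial(bundle, rig, marker_sets, smooth=False)
        truth = generate_motion_path("flexion", 50.0, 120).matrices()
        mc = poses["MCIII"]
        rot_err = [rotation_angle_deg(mc.rotations[k] @ truth[k].T)
                   for k in range(len(mc))]
        jc = left_model.joint_center
        t_truth = jc - np.einsum("nij,j->ni", truth, jc)
        trans_err = np.linalg.norm(mc.translations - t_truth, axis=1)
        assert np.sqrt(np.mean(np.square(rot_err))) < 1.0
        assert np.sqrt(np.mean(trans_err**2)) < 1.0

    def test_static_bone_pose_is_near_constant_under_noise(
        self, left_model, rig, marker_sets
    ):
        sigma = 0.1
        bundle = self._bundle(left_model, rig, sigma, n=120)
        poses = reconstruct_trial(bundle, rig, marker_sets, smooth=False)
        radius = poses["radius"]
        drift = np.linalg.norm(
            radius.translations - radius.translations.mean(axis=0), axis=1
        )
        assert drift.max() < 3 * sigma * 3  # generous 3-sigma-style bound

    def test_missing_marker_leaves_explicit_gap(self, left_model, rig, marker_sets):
        bundle = self._bundle(left_model, rig, 0.0)
        for cam in bundle.image_points:
            bundle.image_points[cam]["MCIII"][10, 1] = np.nan
        poses = reconstruct_trial(bundle, rig, marker_sets, smooth=False)
        assert not poses["MCIII"].valid[10]
        assert poses["MCIII"].valid[11]
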