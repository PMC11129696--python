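"""Virtual wrist model, motion paths, excursions and trial bundles."""

import numpy as np
import pytest

from wristsim.geometry import RigidTransform, cardan_to_matrix
from wristsim.wrist import (
    ActuatorTravelError,
    JointAngles,
    MarkerSet,
    build_default_wrist,
    default_marker_sets,
    generate_motion_path,
    make_trial_bundle,
    markers_from_motion,
    record_excursion_profile,
    tendon_lengths,
)


class TestBuildDefaultWrist:
    def test_left_arm_axis_map_matches_mounting_table(self, left_model):
        assert left_model.axis_map == {"ECRL": 1, "ECRB": 2, "ECU": 3, "FCR": 5, "FCU": 4}
        assert left_model.axis_map["FCU"] == 4

    def test_right_arm_axis_map_is_mirror_mounting(self):
        right = build_default_wrist("right")
        assert right.axis_map == {"ECRL": 3, "ECRB": 2, "ECU": 1, "FCR": 4, "FCU": 5}
        assert right.axis_map["ECU"] == 1

    def test_right_model_mirrors_left_across_sagittal_plane(self, left_model):
        right = build_default_wrist("right")
        for lt, rt in zip(left_model.tendons, right.tendons):
            assert lt.name == rt.name
            # radioulnar (y) coordinates negated, all else equal
            assert rt.insertion_point[1] == pytest.approx(-lt.insertion_point[1])
            assert rt.insertion_point[[0, 2]] == pytest.approx(lt.insertion_point[[0, 2]])
            assert rt.origin_point[1] == pytest.approx(-lt.origin_point[1])

    def test_flexors_volar_extensors_dorsal(self, left_model):
        for t in left_model.tendons:
            if t.name in ("FCR", "FCU"):
                assert t.insertion_point[2] < 0
            else:
                assert t.insertion_point[2] > 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_default_wrist("ambidextrous")
        with pytest.raises(ValueError):
            build_default_wrist("left", {"proximal_length": 0.0})
        with pytest.raises(ValueError):
            build_default_wrist("left", {"bogus_key": 1.0})


class TestTendonLengths:
    def test_neutral_pose_gives_direct_distances(self, left_model):
        lengths = tendon_lengths(left_model, (0.0, 0.0, 0.0))
        for t in left_model.tendons:
            expected = np.linalg.norm(t.insertion_point - t.origin_point)
            assert lengths[t.name] == pytest.approx(expected, abs=1e-12)

    def test_small_angle_excursion_approaches_moment_arm(self):
        # insertion at radius r purely volar, origin far proximal on the
        # same line: flexion excursion -> r * theta(rad) as theta -> 0
        r = 12.0
        model = build_default_wrist("left")
        t = model.tendon("FCU")
        t.insertion_point = np.array([0.0, 0.0, -r])
        t.origin_point = np.array([-500.0, 0.0, -r])
        t.rest_length = None
        model.__post_init__()
        theta = 5.0
        l0 = tendon_lengths(model, (0, 0, 0))["FCU"]
        l1 = tendon_lengths(model, (0, theta, 0))["FCU"]
        excursion = l0 - l1
        closed_form = r * np.radians(theta)
        assert excursion == pytest.approx(closed_form, rel=0.02)

    def test_flexion_excursion_antisymmetric_for_symmetric_insertion(self, left_model):
        # FCU insertion mirrored across the FE axis under +-theta: the
        # excursions are equal and opposite (brute-force at both poses)
        theta = 20.0
        l0 = tendon_lengths(left_model, (0, 0, 0))
        lp = tendon_lengths(left_model, (0, theta, 0))
        lm = tendon_lengths(left_model, (0, -theta, 0))
        # FCU (volar) and its dorsal mirror ECU share |y|; FCU shortens in
        # flexion exactly as much as it lengthens in extension only if the
        # origin is symmetric too -- true for the default geometry of ECU/FCU
        exc_flex = l0["FCU"] - lp["FCU"]
        exc_ext = l0["FCU"] - lm["FCU"]
        assert exc_flex > 0 and exc_ext < 0

    def test_pose_beyond_gimbal_range_rejected(self, left_model):
        with pytest.raises(ValueError):
            tendon_lengths(left_model, (0.0, 95.0, 0.0))


class TestGenerateMotionPath:
    def test_flexion_is_pure_planar_with_exact_peak(self):
        path = generate_motion_path("flexion", 50.0, 100)
        assert path.fe_deg.max() == pytest.approx(50.0, abs=1e-12)
        assert np.all(path.rud_deg == 0)
        assert np.all(path.prosup_deg == 0)
        assert path.fe_deg[0] == 0 and path.fe_deg[-1] == pytest.approx(0, abs=1e-12)

    def test_extension_and_deviations_carry_their_signs(self):
        assert generate_motion_path("extension", 30, 50).fe_deg.min() == pytest.approx(-30)
        assert generate_motion_path("RD", 20, 50).rud_deg.min() == pytest.approx(-20)
        assert generate_motion_path("UD", 20, 50).rud_deg.max() == pytest.approx(20)

    def test_uf_path_lies_exactly_in_dart_throwers_plane(self):
        path = generate_motion_path("UF", 30.0, 100, dtm_angle_deg=25.0)
        assert np.allclose(path.rud_deg, path.fe_deg * np.tan(np.radians(25.0)))
        assert np.all(path.fe_deg >= 0) and np.all(path.rud_deg >= 0)

    def test_circumduction_satisfies_implicit_ellipse_equation(self):
        path = generate_motion_path("circumduction", n_frames=200,
                                    ellipse_axes=(50.0, 25.0))
        val = (path.fe_deg / 50.0) ** 2 + (path.rud_deg / 25.0) ** 2
        assert np.allclose(val, 1.0, atol=1e-9)
        # starts and ends at the extension configuration
        assert path.fe_deg[0] == pytest.approx(-50.0)
        assert path.fe_deg[-1] == pytest.approx(-50.0)

    def test_invalid_motion_requests_rejected(self):
        with pytest.raises(ValueError):
            generate_motion_path("wiggle", 10, 100)
        with pytest.raises(ValueError):
            generate_motion_path("flexion", 95.0, 100)
        with pytest.raises(ValueError):
            generate_motion_path("UF", 30.0, 100)  # missing plane angle
        with pytest.raises(ValueError):
            generate_motion_path("circumduction", n_frames=100)  # missing axes


class TestExcursionProfiles:
    def test_neutral_path_gives_all_zero_profiles(self, left_model):
        still = JointAngles.from_array(np.zeros((20, 3)))
        assert np.allclose(record_excursion_profile(left_model, still), 0.0)

    def test_flexion_shortens_flexors_and_lengthens_extensors(self, left_model):
        path = generate_motion_path("flexion", 50.0, 100)
        profile = record_excursion_profile(left_model, path)
        peak = np.argmax(path.fe_deg)
        for name in ("FCR", "FCU"):
            assert profile[peak, left_model.axis_map[name] - 1] > 0
        for name in ("ECRL", "ECRB", "ECU"):
            assert profile[peak, left_model.axis_map[name] - 1] < 0

    def test_travel_violation_raises(self):
        model = build_default_wrist(
            "left", {"insertion_radius": 120.0, "origin_radius": 240.0}
        )
        path = generate_motion_path("flexion", 60.0, 50)
        with pytest.raises(ActuatorTravelError):
            record_excursion_profile(model, path)


class TestMarkers:
    def test_marker_set_invariants(self):
        with pytest.raises(ValueError):
            MarkerSet("radius", np.array([[0, 0, 0], [10, 0, 0]]))
        with pytest.raises(ValueError):
            MarkerSet("radius", np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]]))
        with pytest.raises(ValueError):
            MarkerSet("radius", np.array([[0, 0, 0], [1, 0.5, 0], [0, 0, 5]]))

    def test_static_path_gives_constant_trajectories(self, left_model, marker_sets):
        still = JointAngles.from_array(np.zeros((10, 3)))
        trajs = markers_from_motion(left_model, still, marker_sets)
        for bone, arr in trajs.items():
            assert np.allclose(arr, arr[0], atol=1e-12)

    def test_within_bone_distances_are_frame_invariant(self, left_model, marker_sets):
        path = generate_motion_path("flexion", 50.0, 80)
        trajs = markers_from_motion(left_model, path, marker_sets)
        for arr in trajs.values():
            d = np.linalg.norm(arr[:, :, None] - arr[:, None, :], axis=-1)
            assert np.abs(d - d[0]).max() < 1e-9

    def test_distal_markers_follow_the_commanded_transform(self, left_model, marker_sets):
        path = generate_motion_path("flexion", 40.0, 60)
        trajs = markers_from_motion(left_model, path, marker_sets)
        k = 30
        R = cardan_to_matrix(*path.frame(k))
        tf = RigidTransform.about_point(R, left_model.joint_center)
        expected = tf.apply(marker_sets["MCIII"].reference_positions)
        assert np.allclose(trajs["MCIII"][k], expected, atol=1e-9)
        assert np.allclose(trajs["radius"][k], marker_sets["radius"].reference_positions)


class TestTrialBundles:
    SPEC = {"motion": "flexion", "amplitude_deg": 40.0, "n_frames": 60}

    def test_noiseless_trials_equal_ground_truth(self, left_model, rig):
        trials, static = make_trial_bundle(
            left_model, self.SPEC, cameras=rig, n_trials=5,
            noise_sigma_mm=0.0, trial_jitter_deg=0.0, seed=3,
        )
        assert len(trials) == 5
        base = generate_motion_path("flexion", 40.0, 60)
        for t in trials:
            assert np.allclose(t.angles_truth.as_array(), base.as_array())
        assert static.is_static and np.allclose(static.angles_truth.as_array(), 0.0)

    def test_identical_seeds_give_bit_identical_bundles(self, left_model, rig):
        kw = dict(cameras=rig, n_trials=3, noise_sigma_mm=0.1,
                  trial_jitter_deg=0.5, seed=11)
        a, _ = make_trial_bundle(left_model, self.SPEC, **kw)
        b, _ = make_trial_bundle(left_model, self.SPEC, **kw)
        for ta, tb in zip(a, b):
            for bone in ta.marker_3d:
                assert np.array_equal(ta.marker_3d[bone], tb.marker_3d[bone])
            for cam in ta.image_points:
                for bone in ta.image_points[cam]:
                    assert np.array_equal(
                        ta.image_points[cam][bone], tb.image_points[cam][bone]
                    )

    def test_marker_noise_has_the_requested_sigma(self, left_model):
        spec = {"motion": "flexion", "amplitude_deg": 40.0, "n_frames": 300}
        trials, _ = make_trial_bundle(
            left_model, spec, cameras=None, n_trials=5,
            noise_sigma_mm=0.1, trial_jitter_deg=0.0, seed=7,
        )
        truth = markers_from_motion(
            left_model, generate_motion_path("flexion", 40.0, 300),
            default_marker_sets(),
        )
        devs = np.concatenate([
            (t.marker_3d[bone] - truth[bone]).ravel()
            for t in trials for bone in truth
        ])
        assert devs.size >= 3 * 10_000
        assert np.std(devs) == pytest.approx(0.1, rel=0.10)
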