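"""Trial averaging, ROM, dart thrower's plane, ellipse fit, repeatability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristsim.metrics import (
    ANGLE_CHANNELS,
    CircumductionPathError,
    average_trials,
    extract_rom,
    fit_circumduction_ellipse,
    fit_dtm_plane,
    inter_specimen_rmse,
    inter_trial_rmse,
    join_circumduction,
    resample_profile,
    truncate_to_max,
)


def _angles(fe, rud, pro=None):
    fe = np.asarray(fe, float)
    rud = np.asarray(rud, float)
    pro = np.zeros_like(fe) if pro is None else np.asarray(pro, float)
    return np.column_stack([pro, fe, rud])


class TestAveraging:
    def test_mean_of_two_trials(self):
        trials = [_angles([1, 2, 3], [0, 0, 0]), _angles([3, 4, 5], [0, 0, 0])]
        prof = average_trials(trials, "flexion")
        assert np.allclose(prof.channel("fe_deg"), [2, 3, 4])
        assert prof.n_trials == 2

    def test_truncates_to_shortest_trial(self):
        trials = [_angles(np.zeros(n), np.zeros(n)) for n in (100, 98, 99)]
        assert len(average_trials(trials, "flexion")) == 98

    def test_identical_trials_average_to_themselves(self):
        t = _angles(np.linspace(0, 50, 30), np.zeros(30))
        prof = average_trials([t] * 5, "flexion")
        assert np.allclose(prof.data, t)

    def test_single_trial_is_an_error(self):
        with pytest.raises(ValueError, match="single trial"):
            average_trials([_angles([1], [1])], "flexion")


class TestTruncation:
    def test_flexion_cut_at_fe_peak(self):
        fe = np.concatenate([np.linspace(0, 50, 81), np.linspace(50, 0, 19)[1:]])
        prof = average_trials([_angles(fe, np.zeros(99))] * 2, "flexion")
        out = truncate_to_max(prof, "flexion")
        assert len(out) == 81
        assert out.channel("fe_deg")[-1] == pytest.approx(50.0)

    def test_dtm_cut_uses_combined_magnitude(self):
        # combined peak at sample 60 even though |fe| alone peaks later
        n = 101
        fe = np.linspace(0, 30, n)
        rud = np.zeros(n)
        rud[:61] = np.linspace(0, 40, 61)
        rud[61:] = np.linspace(40, 0, n - 61)
        prof = average_trials([_angles(fe, rud)] * 2, "UF")
        out = truncate_to_max(prof, "UF")
        combined = np.hypot(fe, rud)
        assert len(out) == int(np.argmax(combined)) + 1
        assert len(out) < n
        assert np.argmax(np.abs(fe)) == n - 1  # fe alone would not truncate

    def test_monotone_profile_is_unchanged(self):
        fe = np.linspace(0, 40, 50)
        prof = average_trials([_angles(fe, np.zeros(50))] * 2, "flexion")
        assert len(truncate_to_max(prof, "flexion")) == 50

    def test_circumduction_passes_through_with_notice(self):
        prof = average_trials([_angles(np.ones(30), np.ones(30))] * 2, "circumduction")
        with pytest.warns(UserWarning, match="not truncated"):
            out = truncate_to_max(prof, "circumduction")
        assert len(out) == 30

    def test_never_lengthens(self):
        for motion in ("flexion", "extension", "RD", "UD", "RE", "UF"):
            fe = np.sin(np.linspace(0, np.pi, 40)) * 30
            prof = average_trials([_angles(fe, 0.5 * fe)] * 2, motion)
            assert len(truncate_to_max(prof, motion)) <= len(prof)


class TestROM:
    def test_pure_flexion(self):
        fe = np.sin(np.linspace(0, np.pi / 2, 50)) * 50
        prof = average_trials([_angles(fe, np.zeros(50))] * 2, "flexion")
        rom = extract_rom(prof, "flexion")
        assert rom == {"in_plane_max_deg": pytest.approx(50.0),
                       "out_of_plane_at_max_deg": pytest.approx(0.0)}

    def test_coupled_ulnar_drift_read_at_flexion_peak(self):
        fe = np.linspace(0, 50, 60)
        prof = average_trials([_angles(fe, 0.16 * fe)] * 2, "flexion")
        rom = extract_rom(prof, "flexion")
        assert rom["in_plane_max_deg"] == pytest.approx(50.0)
        assert rom["out_of_plane_at_max_deg"] == pytest.approx(8.0)

    def test_extension_reported_negative(self):
        fe = -np.linspace(0, 57, 40)
        prof = average_trials([_angles(fe, np.zeros(40))] * 2, "extension")
        assert extract_rom(prof, "extension")["in_plane_max_deg"] == pytest.approx(-57.0)

    def test_deviation_motions_use_rud_axis(self):
        rud = np.linspace(0, -21, 40)
        prof = average_trials([_angles(0.1 * rud, rud)] * 2, "RD")
        rom = extract_rom(prof, "RD")
        assert rom["in_plane_max_deg"] == pytest.approx(-21.0)
        assert rom["out_of_plane_at_max_deg"] == pytest.approx(-2.1)


class TestDTM:
    def test_perfect_45_degree_plane(self):
        rud = np.linspace(-20, 20, 50)
        prof = average_trials([_angles(-rud, rud)] * 2, "UF")
        fit = fit_dtm_plane(prof)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.plane_angle_deg == pytest.approx(45.0)
        assert fit.fit_rmse_deg == pytest.approx(0.0, abs=1e-9)
        assert not fit.excluded

    @pytest.mark.parametrize("angle", [5.0, 10.0, 25.0, 45.0, 60.0])
    def test_generator_round_trip_is_unbiased(self, angle):
        from wristsim.wrist import generate_motion_path

        path = generate_motion_path("UF", 30.0, 100, dtm_angle_deg=angle)
        prof = average_trials([path.as_array()] * 2, "UF",
                              channels=ANGLE_CHANNELS)
        fit = fit_dtm_plane(prof)
        assert fit.plane_angle_deg == pytest.approx(angle, abs=0.1)
        assert not fit.excluded

    def test_isotropic_cloud_is_excluded(self):
        r = np.random.default_rng(0)
        prof = average_trials(
            [_angles(r.normal(size=200), r.normal(size=200))] * 2, "UF"
        )
        fit = fit_dtm_plane(prof)
        assert fit.r_squared < 0.7
        assert fit.excluded

    def test_too_short_or_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_dtm_plane(average_trials([_angles([1, 2], [1, 2])] * 2, "UF"))
        fe = np.linspace(0, 30, 50)
        fit = fit_dtm_plane(average_trials([_angles(fe, np.zeros(50))] * 2, "UF"))
        assert fit.plane_angle_deg == 0.0 and not fit.excluded


def _ellipse_path(a_fe, b_rud, tilt_deg=0.0, n=200, noise=0.0, seed=0,
                  center=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rud = b_rud * np.cos(phi)
    fe = a_fe * np.sin(phi)
    if tilt_deg:
        c, s = np.cos(np.radians(tilt_deg)), np.sin(np.radians(tilt_deg))
        rud, fe = c * rud - s * fe, s * rud + c * fe
    if noise:
        r = np.hypot(rud, fe)
        scale = 1.0 + noise * rng.normal(size=n) / r
        rud, fe = rud * scale, fe * scale
    return np.column_stack([rud + center[0], fe + center[1]])


class TestEllipse:
    def test_circle_recovered_exactly(self):
        fit = fit_circumduction_ellipse(_ellipse_path(10.0, 10.0))
        assert fit.semi_major_deg == pytest.approx(10.0, abs=1e-9)
        assert fit.semi_minor_deg == pytest.approx(10.0, abs=1e-9)
        assert fit.area_deg2 == pytest.approx(100 * np.pi, abs=1e-6)
        assert fit.rmse_deg == pytest.approx(0.0, abs=1e-9)

    def test_axis_aligned_ellipse_orientation_zero_from_sagittal(self):
        fit = fit_circumduction_ellipse(_ellipse_path(50.0, 25.0))
        assert fit.semi_major_deg == pytest.approx(50.0, abs=1e-9)
        assert fit.semi_minor_deg == pytest.approx(25.0, abs=1e-9)
        assert fit.orientation_deg == pytest.approx(0.0, abs=1e-9)
        assert fit.area_deg2 == pytest.approx(1250 * np.pi, rel=1e-9)

    def test_tilted_noisy_ellipse_recovered_over_seeds(self):
        areas, orients = [], []
        for seed in range(20):
            fit = fit_circumduction_ellipse(
                _ellipse_path(50.0, 25.0, tilt_deg=12.0, noise=0.5, seed=seed)
            )
            areas.append(fit.area_deg2)
            orients.append(fit.orientation_deg)
        assert np.mean(areas) == pytest.approx(1250 * np.pi, rel=0.02)
        assert np.mean(orients) == pytest.approx(12.0, abs=1.0)

    def test_area_identity_holds(self):
        fit = fit_circumduction_ellipse(_ellipse_path(40.0, 20.0, tilt_deg=30.0))
        assert fit.area_deg2 == pytest.approx(
            np.pi * fit.semi_major_deg * fit.semi_minor_deg, abs=1e-9
        )

    def test_open_path_rejected(self):
        arc = _ellipse_path(30.0, 20.0)[:80]  # a bit over half the loop
        with pytest.raises(CircumductionPathError):
            fit_circumduction_ellipse(arc)

    def test_sparse_path_rejected(self):
        with pytest.raises(CircumductionPathError):
            fit_circumduction_ellipse(_ellipse_path(30.0, 20.0, n=10))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(20, 60), ratio=st.floats(0.3, 1.0), tilt=st.floats(-45, 45))
    def test_noiseless_recovery_property(self, a, ratio, tilt):
        b = a * ratio
        fit = fit_circumduction_ellipse(_ellipse_path(a, b, tilt_deg=tilt))
        assert fit.area_deg2 == pytest.approx(np.pi * a * b, rel=1e-6)


class TestJoin:
    def test_exact_halves_rejoin_to_closed_loop(self):
        full = _ellipse_path(50.0, 25.0, n=200)
        a, b = full[:101], full[100:]
        joined = join_circumduction(a, b)
        assert len(joined) == len(a) + len(b) - 1
        assert np.allclose(joined, full)

    def test_junction_gap_reported(self):
        full = _ellipse_path(50.0, 25.0, n=200)
        a, b = full[:101], full[100:] + 5.0
        with pytest.raises(CircumductionPathError, match="7.0"):
            join_circumduction(a, b)

    def test_split_then_join_matches_unsplit_fit(self):
        full = _ellipse_path(50.0, 25.0, n=200, noise=0.3, seed=4)
        joined = join_circumduction(full[:101], full[100:])
        f1 = fit_circumduction_ellipse(full)
        f2 = fit_circumduction_ellipse(joined)
        assert f1.area_deg2 == pytest.approx(f2.area_deg2, abs=1e-6)
        assert f1.orientation_deg == pytest.approx(f2.orientation_deg, abs=1e-6)
        assert f1.rmse_deg == pytest.approx(f2.rmse_deg, abs=1e-6)


class TestInterTrial:
    def test_identical_trials_give_zero(self):
        t = _angles(np.linspace(0, 50, 40), np.zeros(40))
        res = inter_trial_rmse([[t] * 5], ANGLE_CHANNELS)
        assert res.mean == 0.0
        assert all(w.value == 0.0 for w in res.per_specimen_worst)

    def test_single_offset_trial_hand_computed(self):
        base = _angles(np.zeros(50), np.zeros(50))
        off = base.copy()
        off[:, 1] += 1.0  # +1 deg on fe
        res = inter_trial_rmse([[off, base, base, base, base]], ANGLE_CHANNELS)
        # mean fe profile is 0.2; offset trial deviates 0.8, others 0.2
        rmse = res.per_trial_rmse[0][:, 1]
        assert rmse[0] == pytest.approx(0.8)
        assert np.allclose(rmse[1:], 0.2)
        assert res.per_specimen_worst[0].value == pytest.approx(0.8)
        assert res.per_specimen_worst[0].channel == "fe_deg"

    def test_gaussian_noise_matches_sampling_theory(self):
        """iid N(0, 0.5 deg) noise on n=5 trials: each trial's RMSE against
        the trial mean estimates 0.5*sqrt(4/5) ~ 0.447 deg."""
        rng = np.random.default_rng(99)
        sigma, n_trials, length = 0.5, 5, 200
        vals = []
        for _ in range(200):
            trials = [
                _angles(rng.normal(scale=sigma, size=length), np.zeros(length))
                for _ in range(n_trials)
            ]
            res = inter_trial_rmse([trials], ANGLE_CHANNELS)
            vals.append(res.per_trial_rmse[0][:, 1].mean())
        expected = sigma * np.sqrt((n_trials - 1) / n_trials)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            inter_trial_rmse([[_angles([1], [1])]], ANGLE_CHANNELS)


class TestInterSpecimen:
    def test_identical_specimens_give_zero(self):
        p = _angles(np.linspace(0, 50, 60), np.zeros(60))
        res = inter_specimen_rmse([p, p, p], "flexion", ANGLE_CHANNELS)
        assert res.mean == 0.0

    def test_two_constant_specimens_hand_computed(self):
        a = _angles(np.full(60, 10.0), np.zeros(60))
        b = _angles(np.full(80, 20.0), np.zeros(80))
        res = inter_specimen_rmse([a, b], "flexion", ANGLE_CHANNELS)
        assert res.mean == pytest.approx(5.0)
        assert res.sd == pytest.approx(0.0)
        assert res.worst_channel == "fe_deg"

    def test_interpolation_counts_are_100_and_200(self):
        a = _angles(np.linspace(0, 1, 90), np.zeros(90))
        b = _angles(np.linspace(0, 1, 110), np.zeros(110))
        res = inter_specimen_rmse([a, b], "flexion", ANGLE_CHANNELS)
        assert res.n_points == 100
        res = inter_specimen_rmse([a, b], "circumduction", ANGLE_CHANNELS)
        assert res.n_points == 200
        assert resample_profile(a, 100).shape == (100, 3)

    def test_requires_two_specimens(self):
        with pytest.raises(ValueError):
            inter_specimen_rmse([_angles([1], [1])], "flexion", ANGLE_CHANNELS)
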