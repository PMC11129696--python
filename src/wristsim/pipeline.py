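"""End-to-end study pipeline: simulate -> reconstruct -> analyze.

``simulate_run`` generates a full synthetic study (specimens x motions x
trials) with the tendon-driven control twin producing force/displacement
logs and the virtual wrist producing bead trajectories and biplanar image
observations.  ``reconstruct_run`` replays the marker-based reconstruction
chain from the written files alone (DLT calibration from the bead cube,
triangulation, rigid-body fits, 2 Hz smoothing).  ``analyze_run`` turns the
reconstructed poses into wrist angles (static-trial neutral correction),
motion summaries (ROM, dart thrower's plane, circumduction ellipse) and
repeatability tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as wio
from .cameras import calibrate_dlt, make_biplanar_rig, make_calibration_cube
from .control import ForceCaps, WristSimulator
from .kinematics import (
    angles_from_poses,
    build_mcs,
    build_rcs,
    default_landmarks,
    neutral_correct,
)
from .metrics import (
    ANGLE_CHANNELS,
    average_trials,
    extract_rom,
    fit_circumduction_ellipse,
    fit_dtm_plane,
    inter_specimen_rmse,
    inter_trial_rmse,
    join_circumduction,
    truncate_to_max,
)
from .recon import reconstruct_trial
from .wrist import (
    DEFAULT_GEOMETRY,
    JointAngles,
    TENDON_NAMES,
    TrialBundle,
    build_default_wrist,
    default_marker_sets,
    make_trial_bundle,
    record_excursion_profile,
)

__version__ = "0.1.0"

FORCE_CHANNELS = tuple(f"F_{n}" for n in TENDON_NAMES)
DISPLACEMENT_CHANNELS = tuple(f"d_axis{i}" for i in range(1, 6))


def _specimen_dirname(i: int) -> str:
    return f"spec{i + 1:02d}"


def _smooth_channel_noise(rng: np.random.Generator, n: int, k: int,
                          sigma: float) -> np.ndarray:
    """Band-limited observation noise with per-sample sd ~ sigma."""
    if sigma == 0.0:
        return np.zeros((n, k))
    raw = rng.normal(size=(n, k))
    kernel = np.hanning(9)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, raw)
    sm /= np.sqrt(np.sum(kernel**2))  # restore unit variance away from edges
    return sigma * sm


@dataclass
class SpecimenParams:
    """Per-specimen draw of the protocol: anatomy scale, mounting, scaling."""

    index: int
    geometry: dict
    mount_offset_deg: tuple[float, float, float]
    motion_specs: list[dict] = field(default_factory=list)


def _draw_specimen_params(config: wio.RunConfig, rng: np.random.Generator,
                          index: int) -> SpecimenParams:
    geo = dict(DEFAULT_GEOMETRY)
    geo.update(config.wrist_geometry)
    scale = float(np.clip(1.0 + rng.normal(scale=config.geometry_scale_sd), 0.8, 1.2))
    geo["insertion_radius"] *= scale
    geo["origin_radius"] *= scale
    mount = tuple(
        float(b + rng.normal(scale=config.mount_offset_sd_deg))
        for b in config.mount_offset_deg
    )
    specs = []
    for m in config.motions:
        spec = {"motion": m["name"], "n_frames": int(m["n_frames"]),
                "fps": float(m["fps"])}
        if m["name"] == "circumduction":
            a, b = m["ellipse_axes"]
            sa, sb = m.get("ellipse_axes_sd", [0.0, 0.0])
            spec["ellipse_axes"] = (
                float(np.clip(a + rng.normal(scale=sa), 20.0, 80.0)),
                float(np.clip(b + rng.normal(scale=sb), 6.0, 40.0)),
            )
            tilt = m.get("ellipse_tilt_deg", 0.0)
            spec["ellipse_tilt_deg"] = float(
                tilt + rng.normal(scale=m.get("ellipse_tilt_sd_deg", 0.0))
            )
        else:
            amp = m["amplitude_deg"]
            spec["amplitude_deg"] = float(
                np.clip(amp + rng.normal(scale=m.get("amplitude_sd_deg", 0.0)), 5.0, 85.0)
            )
            if m["name"] in ("RE", "UF"):
                ang = m["dtm_angle_deg"]
                spec["dtm_angle_deg"] = float(
                    np.clip(ang + rng.normal(scale=m.get("dtm_angle_sd_deg", 0.0)),
                            5.0, 55.0)
                )
            else:
                spec["coupling"] = float(m.get("coupling", 0.0))
        specs.append(spec)
    return SpecimenParams(index, geo, mount, specs)


def _split_bundle(bundle: TrialBundle) -> tuple[TrialBundle, TrialBundle]:
    """Split a circumduction trial into its two half-profiles.

    The first half runs extension -> UD -> flexion, the second
    flexion -> RD -> extension; the junction sample appears in both halves
    and is dropped again when the halves are rejoined during analysis.
    """
    n = bundle.n_frames
    mid = n // 2

    def cut(sl: slice) -> TrialBundle:
        return TrialBundle(
            motion=bundle.motion,
            angles_truth=JointAngles.from_array(
                bundle.angles_truth.as_array()[sl], fps=bundle.fps
            ),
            marker_3d={b: a[sl] for b, a in bundle.marker_3d.items()},
            image_points={
                cam: {b: a[sl] for b, a in per.items()}
                for cam, per in bundle.image_points.items()
            },
            fps=bundle.fps,
            noise_sigma_mm=bundle.noise_sigma_mm,
            seed=bundle.seed,
            is_static=False,
        )

    return cut(slice(0, mid + 1)), cut(slice(mid, n))


def _write_trial_files(outdir: Path, stem: str, bundle: TrialBundle,
                       manifest: wio.Manifest, root: Path) -> None:
    rows = wio.write_markers3d_csv(bundle.marker_3d, outdir / f"{stem}_markers3d.csv")
    manifest.add_file(root, outdir / f"{stem}_markers3d.csv", rows)
    rows = wio.write_angles_csv(bundle.angles_truth, outdir / f"{stem}_truth_angles.csv")
    manifest.add_file(root, outdir / f"{stem}_truth_angles.csv", rows)
    for cam, per_bone in bundle.image_points.items():
        p = outdir / f"{stem}_{cam}_2d.csv"
        rows = wio.write_points2d_csv(per_bone, p)
        manifest.add_file(root, p, rows)


def simulate_run(config: wio.RunConfig, outdir: str | Path) -> wio.Manifest:
    """Generate the full synthetic study under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = wio.Manifest(
        run_id=f"sim-{config.seed}", config_hash=config.digest(),
        software_version=__version__,
    )
    wio.save_config(config, outdir / "config_used.yaml")
    manifest.add_file(outdir, outdir / "config_used.yaml")

    landmarks = default_landmarks()
    wio.write_landmarks_json(landmarks, outdir / "landmarks.json")
    manifest.add_file(outdir, outdir / "landmarks.json")

    cameras = make_biplanar_rig(
        source_to_object_mm=config.source_to_object_mm,
        source_to_image_mm=config.source_to_image_mm,
        px_per_mm=config.px_per_mm,
        image_size=tuple(config.image_size),
    )
    cube = make_calibration_cube()
    cal_pts = {name: cam.project(cube) for name, cam in cameras.items()}
    for p in wio.write_calibration_csv(cube, cal_pts, outdir / "calibration"):
        manifest.add_file(outdir, p)

    marker_sets = default_marker_sets()
    for s in range(config.n_specimens):
        params = _draw_specimen_params(config, rng, s)
        model = build_default_wrist(config.handedness, params.geometry)
        sim = WristSimulator(model, joint_stiffness=config.joint_stiffness,
                             caps=ForceCaps())
        sim.set_initial_forces(rng.uniform(0.5, 5.0, size=5))
        sim.equalize_forces(config.target_force_n, tol_n=config.equalize_tol_n)
        sdir = outdir / _specimen_dirname(s)
        for spec in params.motion_specs:
            motion = spec["motion"]
            mdir = sdir / motion
            mdir.mkdir(parents=True, exist_ok=True)
            fps = spec["fps"]
            path_kwargs = {k: v for k, v in spec.items() if k != "motion"}
            from .wrist import generate_motion_path

            path = generate_motion_path(motion, **path_kwargs)
            profile = record_excursion_profile(model, path)
            log, _ = sim.track_profile(profile, fps=fps)
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trials, static = make_trial_bundle(
                model,
                spec,
                cameras=cameras,
                marker_sets=marker_sets,
                n_trials=config.n_trials,
                noise_sigma_mm=config.marker_sigma_mm,
                trial_jitter_deg=config.trial_jitter_deg,
                mount_offset_deg=params.mount_offset_deg,
                n_static_frames=config.n_static_frames,
                seed=trial_seed,
                trial_length_jitter=config.trial_length_jitter,
            )
            # actuator profiles: circumduction is exported as two halves
            if motion == "circumduction":
                mid = len(profile) // 2
                for tag, sl in (("a", slice(0, mid + 1)), ("b", slice(mid, None))):
                    p = mdir / f"profile_{tag}.csv"
                    rows = wio.write_profile_csv(profile[sl], p)
                    manifest.add_file(outdir, p, rows)
            else:
                rows = wio.write_profile_csv(profile, mdir / "profile.csv")
                manifest.add_file(outdir, mdir / "profile.csv", rows)
            for t, bundle in enumerate(trials, start=1):
                n = bundle.n_frames
                force_obs = log.forces_n[:n] + _smooth_channel_noise(
                    rng, n, 5, config.force_sigma_n
                )
                force_obs = np.maximum(force_obs, 0.0)
                disp_obs = log.displacements_mm[:n] + _smooth_channel_noise(
                    rng, n, 5, config.displacement_sigma_mm
                )
                p = mdir / f"trial{t}_log.csv"
                rows = wio.write_log_csv(np.arange(n) / fps, force_obs, disp_obs, p)
                manifest.add_file(outdir, p, rows)
                if motion == "circumduction":
                    half_a, half_b = _split_bundle(bundle)
                    _write_trial_files(mdir, f"trial{t}a", half_a, manifest, outdir)
                    _write_trial_files(mdir, f"trial{t}b", half_b, manifest, outdir)
                else:
                    _write_trial_files(mdir, f"trial{t}", bundle, manifest, outdir)
            _write_trial_files(mdir, "static", static, manifest, outdir)
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# reconstruction stage


def _trial_stems(mdir: Path) -> list[str]:
    stems = sorted(
        p.name.replace("_markers3d.csv", "")
        for p in mdir.glob("trial*_markers3d.csv")
    )
    return stems


def reconstruct_run(sim_dir: str | Path, outdir: str | Path,
                    smooth: bool = True) -> wio.Manifest:
    """Reconstruct bone poses for every trial found under ``sim_dir``."""
    sim_dir = Path(sim_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cal_dir = sim_dir / "calibration"
    if not cal_dir.exists():
        raise wio.DataError(f"missing calibration directory: {cal_dir}")
    try:
        config = wio.load_config(sim_dir / "config_used.yaml")
    except FileNotFoundError:
        raise wio.DataError(
            f"missing config file: {sim_dir / 'config_used.yaml'}"
        ) from None
    beads, cam_pts = wio.read_calibration_csv(cal_dir)
    cameras = {}
    residuals = {}
    for cam_name, pts in cam_pts.items():
        cameras[cam_name], residuals[cam_name] = calibrate_dlt(
            beads, pts, image_size=tuple(config.image_size)
        )
    marker_sets = default_marker_sets()
    manifest = wio.Manifest(
        run_id=f"recon-{config.seed}", config_hash=config.digest(),
        software_version=__version__,
    )
    summary = {"calibration_rms_px": {k: float(v) for k, v in residuals.items()},
               "trials": {}}
    for sdir in sorted(sim_dir.glob("spec*")):
        for mdir in sorted(p for p in sdir.iterdir() if p.is_dir()):
            motion = mdir.name
            fps = next(
                (float(m["fps"]) for m in config.motions if m["name"] == motion), 50.0
            )
            rdir = outdir / sdir.name / motion
            rdir.mkdir(parents=True, exist_ok=True)
            for stem in _trial_stems(mdir) + ["static"]:
                image_points = {}
                for cam_name in cameras:
                    p = mdir / f"{stem}_{cam_name}_2d.csv"
                    image_points[cam_name] = wio.read_points2d_csv(p)
                any_bone = next(iter(image_points[next(iter(cameras))]))
                n = len(image_points[next(iter(cameras))][any_bone])
                bundle = TrialBundle(
                    motion=motion,
                    angles_truth=JointAngles.from_array(np.zeros((n, 3)), fps=fps),
                    marker_3d={},
                    image_points=image_points,
                    fps=fps,
                    noise_sigma_mm=config.marker_sigma_mm,
                    seed=config.seed,
                    is_static=stem == "static",
                )
                do_smooth = smooth and not bundle.is_static
                poses = reconstruct_trial(
                    bundle, cameras, marker_sets, smooth=do_smooth,
                    cutoff_hz=config.filter_cutoff_hz,
                )
                out_path = rdir / f"{stem}_poses.csv"
                rows = wio.write_poses_csv(poses, out_path)
                manifest.add_file(outdir, out_path, rows)
                res = [
                    float(np.nanmean(series.residual_rms))
                    for series in poses.values()
                    if series.residual_rms is not None
                ]
                summary["trials"][f"{sdir.name}/{motion}/{stem}"] = {
                    "mean_marker_residual_mm": float(np.mean(res)) if res else None
                }
    (outdir / "recon_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    manifest.add_file(outdir, outdir / "recon_summary.json")
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# analysis stage


def _corrected_trial_angles(
    rdir: Path, mdir_name: str, fps: float, landmarks: dict
) -> tuple[list[np.ndarray], JointAngles]:
    """Per-trial neutral-corrected angle arrays (n, 3) plus the static series."""
    rcs = build_rcs(landmarks["radius"])
    mcs = build_mcs(landmarks["metacarpals"])
    static_path = rdir / "static_poses.csv"
    if not static_path.exists():
        raise wio.DataError(
            f"missing static trial for {mdir_name}: expected {static_path}"
        )
    static_poses = wio.read_poses_csv(static_path, fps=fps)
    static_angles = angles_from_poses(
        rcs, mcs, static_poses["radius"], static_poses["MCIII"]
    )

    def corrected(stem: str) -> np.ndarray:
        poses = wio.read_poses_csv(rdir / f"{stem}_poses.csv", fps=fps)
        raw = angles_from_poses(rcs, mcs, poses["radius"], poses["MCIII"])
        return neutral_correct(raw, static_angles).as_array()

    stems = sorted(
        p.name.replace("_poses.csv", "")
        for p in rdir.glob("trial*_poses.csv")
    )
    if any(s.endswith("a") or s.endswith("b") for s in stems):
        # circumduction halves: join trialNa + trialNb
        trials = []
        n_trials = len({s[:-1] for s in stems})
        for t in range(1, n_trials + 1):
            a = corrected(f"trial{t}a")
            b = corrected(f"trial{t}b")
            trials.append(join_circumduction(a, b, tol_deg=5.0))
    else:
        trials = [corrected(s) for s in stems]
    return trials, static_angles


def analyze_run(recon_dir: str | Path, sim_dir: str | Path,
                outdir: str | Path) -> dict:
    """Motion summaries and repeatability tables from reconstructed poses."""
    recon_dir = Path(recon_dir)
    sim_dir = Path(sim_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = wio.load_config(sim_dir / "config_used.yaml")
    landmarks = wio.read_landmarks_json(sim_dir / "landmarks.json")

    per_specimen: dict[str, dict] = {}
    angle_trials: dict[str, list[list[np.ndarray]]] = {}
    force_trials: dict[str, list[list[np.ndarray]]] = {}
    disp_trials: dict[str, list[list[np.ndarray]]] = {}
    mean_profiles: dict[str, list[np.ndarray]] = {}
    mean_forces: dict[str, list[np.ndarray]] = {}
    mean_disps: dict[str, list[np.ndarray]] = {}

    for sdir in sorted(recon_dir.glob("spec*")):
        spec_report: dict[str, dict] = {}
        for rdir in sorted(p for p in sdir.iterdir() if p.is_dir()):
            motion = rdir.name
            fps = next(
                (float(m["fps"]) for m in config.motions if m["name"] == motion), 50.0
            )
            trials, _ = _corrected_trial_angles(rdir, motion, fps, landmarks)
            # matching force/displacement logs from the simulation stage
            log_dir = sim_dir / sdir.name / motion
            f_list, d_list = [], []
            for p in sorted(log_dir.glob("trial*_log.csv")):
                _, forces, disp = wio.read_log_csv(p)
                f_list.append(forces)
                d_list.append(disp)
            angle_trials.setdefault(motion, []).append(trials)
            force_trials.setdefault(motion, []).append(f_list)
            disp_trials.setdefault(motion, []).append(d_list)

            profile = average_trials(trials, motion, channels=ANGLE_CHANNELS, fps=fps)
            mean_profiles.setdefault(motion, []).append(profile.data)
            mean_forces.setdefault(motion, []).append(
                average_trials(f_list, motion, channels=FORCE_CHANNELS, fps=fps).data
            )
            mean_disps.setdefault(motion, []).append(
                average_trials(d_list, motion, channels=DISPLACEMENT_CHANNELS,
                               fps=fps).data
            )
            entry: dict = {"n_trials": len(trials)}
            if motion == "circumduction":
                envelope = np.column_stack(
                    [profile.channel("rud_deg"), profile.channel("fe_deg")]
                )
                fit = fit_circumduction_ellipse(envelope)
                entry["ellipse"] = {
                    "area_deg2": fit.area_deg2,
                    "orientation_deg": fit.orientation_deg,
                    "semi_major_deg": fit.semi_major_deg,
                    "semi_minor_deg": fit.semi_minor_deg,
                    "rmse_deg": fit.rmse_deg,
                    "center_rud_fe_deg": list(fit.center),
                }
            else:
                trunc = truncate_to_max(profile, motion)
                if motion in ("RE", "UF"):
                    fit = fit_dtm_plane(trunc)
                    entry["dtm"] = {
                        "plane_angle_deg": fit.plane_angle_deg,
                        "r_squared": fit.r_squared,
                        "fit_rmse_deg": fit.fit_rmse_deg,
                        "excluded": fit.excluded,
                    }
                else:
                    entry["rom"] = extract_rom(trunc, motion)
            spec_report[motion] = entry
        per_specimen[sdir.name] = spec_report

    summary: dict = {"rom": {}, "dtm": {}, "circumduction": {},
                     "repeatability": {"inter_trial": {}, "inter_specimen": {}}}
    specs = sorted(per_specimen)
    for motion in angle_trials:
        if motion in ("flexion", "extension", "RD", "UD"):
            in_plane = [per_specimen[s][motion]["rom"]["in_plane_max_deg"]
                        for s in specs if motion in per_specimen[s]]
            out_plane = [per_specimen[s][motion]["rom"]["out_of_plane_at_max_deg"]
                         for s in specs if motion in per_specimen[s]]
            summary["rom"][motion] = {
                "in_plane_mean_deg": float(np.mean(in_plane)),
                "in_plane_sd_deg": float(np.std(in_plane, ddof=1)) if len(in_plane) > 1 else 0.0,
                "out_of_plane_mean_deg": float(np.mean(out_plane)),
                "out_of_plane_sd_deg": float(np.std(out_plane, ddof=1)) if len(out_plane) > 1 else 0.0,
            }
        elif motion in ("RE", "UF"):
            fits = [per_specimen[s][motion]["dtm"] for s in specs
                    if motion in per_specimen[s]]
            kept = [f for f in fits if not f["excluded"]]
            summary["dtm"][motion] = {
                "plane_angle_mean_deg": float(np.mean([f["plane_angle_deg"] for f in kept]))
                if kept else None,
                "plane_angle_sd_deg": float(np.std([f["plane_angle_deg"] for f in kept], ddof=1))
                if len(kept) > 1 else 0.0,
                "fit_rmse_mean_deg": float(np.mean([f["fit_rmse_deg"] for f in kept]))
                if kept else None,
                "n_excluded": sum(f["excluded"] for f in fits),
            }
        else:
            fits = [per_specimen[s][motion]["ellipse"] for s in specs
                    if motion in per_specimen[s]]
            summary["circumduction"] = {
                "area_mean_deg2": float(np.mean([f["area_deg2"] for f in fits])),
                "area_sd_deg2": float(np.std([f["area_deg2"] for f in fits], ddof=1))
                if len(fits) > 1 else 0.0,
                "orientation_mean_deg": float(np.mean([f["orientation_deg"] for f in fits])),
                "orientation_sd_deg": float(np.std([f["orientation_deg"] for f in fits], ddof=1))
                if len(fits) > 1 else 0.0,
                "rmse_mean_deg": float(np.mean([f["rmse_deg"] for f in fits])),
            }
        # repeatability
        it = {}
        for label, data, channels in (
            ("angles", angle_trials[motion], ANGLE_CHANNELS),
            ("forces", force_trials[motion], FORCE_CHANNELS),
            ("displacements", disp_trials[motion], DISPLACEMENT_CHANNELS),
        ):
            res = inter_trial_rmse(data, channels)
            it[label] = {"mean": res.mean, "sd": res.sd,
                         "worst_channels": [w.channel for w in res.per_specimen_worst]}
        summary["repeatability"]["inter_trial"][motion] = it
        if len(specs) >= 2:
            isr = {}
            for label, data, channels in (
                ("angles", mean_profiles[motion], ANGLE_CHANNELS),
                ("forces", mean_forces[motion], FORCE_CHANNELS),
                ("displacements", mean_disps[motion], DISPLACEMENT_CHANNELS),
            ):
                res = inter_specimen_rmse(data, motion, channels)
                isr[label] = {"mean": res.mean, "sd": res.sd,
                              "worst_channel": res.worst_channel,
                              "n_points": res.n_points}
            summary["repeatability"]["inter_specimen"][motion] = isr

    report = {"config_hash": config.digest(), "per_specimen": per_specimen,
              "summary": summary}
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    _write_tables(report, outdir)
    return report


def _write_tables(report: dict, outdir: Path) -> None:
    import pandas as pd

    summary = report["summary"]
    rows = [
        {"motion": m, **vals} for m, vals in summary["rom"].items()
    ]
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "rom_table.csv", index=False,
                                  lineterminator="\n")
    it_rows = []
    for motion, per in summary["repeatability"]["inter_trial"].items():
        row = {"motion": motion}
        for label in ("angles", "forces", "displacements"):
            row[f"{label}_mean"] = per[label]["mean"]
            row[f"{label}_sd"] = per[label]["sd"]
        it_rows.append(row)
    pd.DataFrame(it_rows).to_csv(outdir / "inter_trial_rmse.csv", index=False,
                                 lineterminator="\n")
    is_rows = []
    for motion, per in summary["repeatability"]["inter_specimen"].items():
        row = {"motion": motion}
        for label in ("angles", "forces", "displacements"):
            row[f"{label}_mean"] = per[label]["mean"]
            row[f"{label}_sd"] = per[label]["sd"]
        is_rows.append(row)
    if is_rows:
        pd.DataFrame(is_rows).to_csv(outdir / "inter_specimen_rmse.csv", index=False,
                                     lineterminator="\n")


def compare_reports(report_a: dict, report_b: dict) -> "pd.DataFrame":
    """Paired per-motion comparison of two analysis reports (two conditions)."""
    import pandas as pd

    rows = []
    sa, sb = report_a["summary"], report_b["summary"]
    for motion in sorted(set(sa["rom"]) | set(sb["rom"])):
        rows.append({
            "motion": motion, "metric": "in_plane_max_deg",
            "condition_a": sa["rom"].get(motion, {}).get("in_plane_mean_deg"),
            "condition_b": sb["rom"].get(motion, {}).get("in_plane_mean_deg"),
        })
    for motion in sorted(set(sa["dtm"]) | set(sb["dtm"])):
        rows.append({
            "motion": motion, "metric": "dtm_plane_angle_deg",
            "condition_a": sa["dtm"].get(motion, {}).get("plane_angle_mean_deg"),
            "condition_b": sb["dtm"].get(motion, {}).get("plane_angle_mean_deg"),
        })
    if sa.get("circumduction") or sb.get("circumduction"):
        rows.append({
            "motion": "circumduction", "metric": "ellipse_area_deg2",
            "condition_a": sa.get("circumduction", {}).get("area_mean_deg2"),
            "condition_b": sb.get("circumduction", {}).get("area_mean_deg2"),
        })
    return pd.DataFrame(rows)
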