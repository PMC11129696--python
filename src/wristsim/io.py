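"""Configuration, interchange formats and the run manifest.

All interchange files are plain text: CSV with mandatory header rows and
full double precision ('.' decimal, no thousands separators), JSON for
landmarks/reports/manifest, YAML for run configuration.  Every writer/reader
pair round-trips bit-identically, and all randomness in a run flows from the
single config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recon import PoseSeries
from .wrist import BONES, JointAngles, TENDON_NAMES


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


class DataError(ValueError):
    """Malformed interchange file."""


# ---------------------------------------------------------------------------
# configuration

_TABLE2_COUPLING = {
    # out-of-plane / in-plane ratios of the anatomical-wrist maxima
    "flexion": 8.2 / 50.5,
    "extension": (-1.4) / (-57.2),
    "RD": 5.8 / (-20.9),
    "UD": (-2.4) / 29.2,
}

DEFAULT_MOTIONS = [
    {"name": "flexion", "amplitude_deg": 50.5, "amplitude_sd_deg": 6.3,
     "coupling": _TABLE2_COUPLING["flexion"], "n_frames": 200, "fps": 50.0},
    {"name": "extension", "amplitude_deg": 57.2, "amplitude_sd_deg": 7.9,
     "coupling": _TABLE2_COUPLING["extension"], "n_frames": 200, "fps": 50.0},
    {"name": "RD", "amplitude_deg": 20.9, "amplitude_sd_deg": 8.3,
     "coupling": _TABLE2_COUPLING["RD"], "n_frames": 200, "fps": 50.0},
    {"name": "UD", "amplitude_deg": 29.2, "amplitude_sd_deg": 4.6,
     "coupling": _TABLE2_COUPLING["UD"], "n_frames": 200, "fps": 50.0},
    {"name": "RE", "amplitude_deg": 30.0, "amplitude_sd_deg": 4.0,
     "dtm_angle_deg": 20.4, "dtm_angle_sd_deg": 6.1, "n_frames": 200, "fps": 50.0},
    {"name": "UF", "amplitude_deg": 30.0, "amplitude_sd_deg": 4.0,
     "dtm_angle_deg": 26.2, "dtm_angle_sd_deg": 8.1, "n_frames": 200, "fps": 50.0},
    {"name": "circumduction", "ellipse_axes": [53.0, 15.66],
     "ellipse_axes_sd": [5.0, 3.0], "ellipse_tilt_deg": 4.2,
     "ellipse_tilt_sd_deg": 2.8, "n_frames": 360, "fps": 30.0},
]


@dataclass
class RunConfig:
    """Everything a simulated study needs, with study-condition defaults."""

    seed: int
    handedness: str = "left"
    n_specimens: int = 6
    n_trials: int = 5
    wrist_geometry: dict = field(default_factory=dict)
    joint_stiffness: float = 0.01          # N*mm/deg^2 passive regularizer
    motions: list = field(default_factory=lambda: [dict(m) for m in DEFAULT_MOTIONS])
    # noise / variability (study conditions)
    marker_sigma_mm: float = 0.05
    trial_jitter_deg: float = 0.5
    force_sigma_n: float = 0.4
    displacement_sigma_mm: float = 0.05
    trial_length_jitter: int = 4
    mount_offset_deg: list = field(default_factory=lambda: [1.0, 2.0, -1.5])
    mount_offset_sd_deg: float = 2.0
    geometry_scale_sd: float = 0.05
    # camera rig
    source_to_image_mm: float = 1100.0
    source_to_object_mm: float = 760.0
    px_per_mm: float = 2.56
    image_size: list = field(default_factory=lambda: [1024, 1024])
    # control
    target_force_n: float = 2.0
    equalize_tol_n: float = 0.01
    # reconstruction
    filter_cutoff_hz: float = 2.0
    n_static_frames: int = 50

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.seed = int(self.seed)
        if self.handedness not in ("left", "right"):
            raise ConfigError(f"handedness must be left|right, got {self.handedness!r}")
        if self.n_trials < 1 or self.n_specimens < 1:
            raise ConfigError("n_trials and n_specimens must be >= 1")
        from .wrist import MOTIONS

        for m in self.motions:
            if m.get("name") not in MOTIONS:
                raise ConfigError(f"unknown motion name in protocol: {m.get('name')!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        if "seed" not in data:
            raise ConfigError("seed is mandatory")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.canonical_yaml())


# ---------------------------------------------------------------------------
# CSV formats

def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, lineterminator="\n")
    return len(df)


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise DataError(f"missing file: {path}") from None
    except Exception as exc:  # malformed rows
        raise DataError(f"{path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def write_angles_csv(angles: JointAngles, path: str | Path) -> int:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(angles)),
            "prosup_deg": angles.prosup_deg,
            "fe_deg": angles.fe_deg,
            "rud_deg": angles.rud_deg,
        }
    )
    return _write_csv(df, Path(path))


def read_angles_csv(path: str | Path, fps: float = 50.0) -> JointAngles:
    df = _read_csv(Path(path), ["frame", "prosup_deg", "fe_deg", "rud_deg"])
    return JointAngles(
        df["prosup_deg"].to_numpy(), df["fe_deg"].to_numpy(),
        df["rud_deg"].to_numpy(), fps=fps,
    )


def write_markers3d_csv(markers: dict[str, np.ndarray], path: str | Path) -> int:
    rows = []
    for bone in BONES:
        if bone not in markers:
            continue
        arr = markers[bone]
        n, m, _ = arr.shape
        for k in range(m):
            rows.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(n),
                        "bone": bone,
                        "marker": k,
                        "X": arr[:, k, 0],
                        "Y": arr[:, k, 1],
                        "Z": arr[:, k, 2],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True).sort_values(
        ["frame", "bone", "marker"], kind="stable"
    )
    return _write_csv(df.reset_index(drop=True), Path(path))


def read_markers3d_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = _read_csv(Path(path), ["frame", "bone", "marker", "X", "Y", "Z"])
    out = {}
    for bone, grp in df.groupby("bone", sort=False):
        n = grp["frame"].max() + 1
        m = grp["marker"].max() + 1
        arr = np.full((n, m, 3), np.nan)
        arr[grp["frame"], grp["marker"]] = grp[["X", "Y", "Z"]].to_numpy()
        out[bone] = arr
    return out


def write_points2d_csv(points: dict[str, np.ndarray], path: str | Path) -> int:
    """XMAlab-style wide table: frame, then <bone>_m<k>_u/_v columns."""
    cols = {"frame": None}
    n = None
    for bone in BONES:
        if bone not in points:
            continue
        arr = points[bone]
        n = len(arr)
        for k in range(arr.shape[1]):
            cols[f"{bone}_m{k}_u"] = arr[:, k, 0]
            cols[f"{bone}_m{k}_v"] = arr[:, k, 1]
    cols["frame"] = np.arange(n)
    return _write_csv(pd.DataFrame(cols), Path(path))


def read_points2d_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = _read_csv(Path(path), ["frame"])
    out: dict[str, np.ndarray] = {}
    for bone in BONES:
        us = sorted(
            (c for c in df.columns if c.startswith(f"{bone}_m") and c.endswith("_u")),
            key=lambda c: int(c.split("_m")[1].split("_")[0]),
        )
        if not us:
            continue
        arr = np.stack(
            [df[[u, u[:-2] + "_v"]].to_numpy() for u in us], axis=1
        )
        out[bone] = arr
    return out


def write_profile_csv(profile: np.ndarray, path: str | Path) -> int:
    profile = np.atleast_2d(np.asarray(profile, dtype=float))
    df = pd.DataFrame(profile, columns=[f"axis{i}" for i in range(1, 6)])
    df.insert(0, "frame", np.arange(len(df)))
    return _write_csv(df, Path(path))


def read_profile_csv(path: str | Path) -> np.ndarray:
    df = _read_csv(Path(path), ["frame"] + [f"axis{i}" for i in range(1, 6)])
    return df[[f"axis{i}" for i in range(1, 6)]].to_numpy()


def write_log_csv(time_s, forces_n, displacements_mm, path: str | Path) -> int:
    data = {"time_s": np.asarray(time_s, dtype=float)}
    for j, name in enumerate(TENDON_NAMES):
        data[f"F_{name}"] = forces_n[:, j]
    for i in range(5):
        data[f"d_axis{i + 1}"] = displacements_mm[:, i]
    return _write_csv(pd.DataFrame(data), Path(path))


def read_log_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = ["time_s"] + [f"F_{n}" for n in TENDON_NAMES] + [f"d_axis{i}" for i in range(1, 6)]
    df = _read_csv(Path(path), cols)
    forces = df[[f"F_{n}" for n in TENDON_NAMES]].to_numpy()
    disp = df[[f"d_axis{i}" for i in range(1, 6)]].to_numpy()
    return df["time_s"].to_numpy(), forces, disp


def write_poses_csv(poses: dict[str, PoseSeries], path: str | Path) -> int:
    rows = []
    rcols = [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]
    for bone in BONES:
        if bone not in poses:
            continue
        series = poses[bone]
        flat = series.rotations.reshape(len(series), 9)
        df = pd.DataFrame(flat, columns=rcols)
        df.insert(0, "bone", bone)
        df.insert(0, "frame", np.arange(len(series)))
        df[["tx", "ty", "tz"]] = series.translations
        rows.append(df)
    df = pd.concat(rows, ignore_index=True)
    return _write_csv(df, Path(path))


def read_poses_csv(path: str | Path, fps: float = 50.0) -> dict[str, PoseSeries]:
    rcols = [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]
    df = _read_csv(Path(path), ["frame", "bone"] + rcols + ["tx", "ty", "tz"])
    out = {}
    for bone, grp in df.groupby("bone", sort=False):
        grp = grp.sort_values("frame")
        R = grp[rcols].to_numpy().reshape(-1, 3, 3)
        t = grp[["tx", "ty", "tz"]].to_numpy()
        out[bone] = PoseSeries(R, t, fps=fps)
    return out


def write_calibration_csv(
    beads_3d: np.ndarray, image_points: dict[str, np.ndarray], directory: str | Path
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    df = pd.DataFrame(beads_3d, columns=["X", "Y", "Z"])
    df.insert(0, "bead_id", np.arange(len(df)))
    p = directory / "cube_beads_3d.csv"
    _write_csv(df, p)
    paths.append(p)
    for cam, pts in sorted(image_points.items()):
        df = pd.DataFrame(pts, columns=["u", "v"])
        df.insert(0, "bead_id", np.arange(len(df)))
        p = directory / f"{cam}_cube_2d.csv"
        _write_csv(df, p)
        paths.append(p)
    return paths


def read_calibration_csv(directory: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    directory = Path(directory)
    cube = _read_csv(directory / "cube_beads_3d.csv", ["bead_id", "X", "Y", "Z"])
    beads = cube[["X", "Y", "Z"]].to_numpy()
    cams = {}
    for p in sorted(directory.glob("*_cube_2d.csv")):
        cam = p.name.replace("_cube_2d.csv", "")
        df = _read_csv(p, ["bead_id", "u", "v"])
        cams[cam] = df[["u", "v"]].to_numpy()
    if not cams:
        raise DataError(f"no per-camera calibration files found in {directory}")
    return beads, cams


def write_landmarks_json(landmarks: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landmarks, indent=2, sort_keys=True) + "\n")


def read_landmarks_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise DataError(f"missing landmarks file: {path}") from None


# ---------------------------------------------------------------------------
# manifest


@dataclass
class Manifest:
    """Inventory of a pipeline stage's outputs; reproducible per config+seed."""

    run_id: str
    config_hash: str
    software_version: str
    files: dict[str, dict] = field(default_factory=dict)

    def add_file(self, root: Path, path: Path, rows: int | None = None) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entry = {"sha256": digest}
        if rows is not None:
            entry["rows"] = int(rows)
        self.files[str(path.relative_to(root))] = entry

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config_hash, "files": self.files}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, path: str | Path) -> None:
        data = {
            "run_id": self.run_id,
            "config_hash": self.config_hash,
            "software_version": self.software_version,
            "manifest_hash": self.digest(),
            "files": dict(sorted(self.files.items())),
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "Manifest":
        data = json.loads(Path(path).read_text())
        m = cls(
            run_id=data["run_id"],
            config_hash=data["config_hash"],
            software_version=data["software_version"],
            files=data["files"],
        )
        return m
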