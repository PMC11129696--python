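"""Virtual two-segment wrist and synthetic trial generator.

This module stands in for the cadaveric specimens: a universal-joint linkage
of a fixed proximal (forearm) segment and a moving distal (hand) segment,
with five straight-line "tendons" (ECRL, ECRB, ECU, FCR, FCU) running from
fixed proximal exit points to insertions at the base of the distal segment.
It produces ground-truth joint-angle paths for the seven motion patterns,
tendon length/excursion profiles, implanted-bead trajectories for four bones
(radius, ulna, MCII, MCIII; three beads each), and noisy biplanar image
observations bundled per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, cardan_to_matrix

TENDON_NAMES = ("ECRL", "ECRB", "ECU", "FCR", "FCU")
FLEXORS = ("FCR", "FCU")
EXTENSORS = ("ECRL", "ECRB", "ECU")
BONES = ("radius", "ulna", "MCII", "MCIII")
PROXIMAL_BONES = ("radius", "ulna")
DISTAL_BONES = ("MCII", "MCIII")

#: tendon -> actuator axis, left and right arms (mirror-image mounting)
AXIS_MAP_LEFT = {"ECRL": 1, "ECRB": 2, "ECU": 3, "FCR": 5, "FCU": 4}
AXIS_MAP_RIGHT = {"ECRL": 3, "ECRB": 2, "ECU": 1, "FCR": 4, "FCU": 5}

MOTIONS = ("flexion", "extension", "RD", "UD", "RE", "UF", "circumduction")

ACTUATOR_TRAVEL_MM = 80.0


class ActuatorTravelError(ValueError):
    """A tendon excursion exceeds the available actuator travel."""


@dataclass
class JointAngles:
    """Per-frame wrist angles in degrees: pronation(+), flexion(+), ulnar(+)."""

    prosup_deg: np.ndarray
    fe_deg: np.ndarray
    rud_deg: np.ndarray
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.prosup_deg = np.atleast_1d(np.asarray(self.prosup_deg, dtype=float))
        self.fe_deg = np.atleast_1d(np.asarray(self.fe_deg, dtype=float))
        self.rud_deg = np.atleast_1d(np.asarray(self.rud_deg, dtype=float))
        n = len(self.prosup_deg)
        if len(self.fe_deg) != n or len(self.rud_deg) != n:
            raise ValueError("angle channels must have equal length")
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("angles must be finite")

    def __len__(self) -> int:
        return len(self.fe_deg)

    def as_array(self) -> np.ndarray:
        """(n, 3) array in (prosup, fe, rud) order."""
        return np.column_stack([self.prosup_deg, self.fe_deg, self.rud_deg])

    @classmethod
    def from_array(cls, arr: np.ndarray, fps: float = 50.0) -> "JointAngles":
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], fps=fps)

    def frame(self, k: int) -> tuple[float, float, float]:
        return float(self.prosup_deg[k]), float(self.fe_deg[k]), float(self.rud_deg[k])

    def matrices(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices of the distal segment."""
        from scipy.spatial.transform import Rotation

        from .geometry import CARDAN_SEQUENCE

        euler = np.column_stack([self.fe_deg, self.rud_deg, self.prosup_deg])
        return Rotation.from_euler(CARDAN_SEQUENCE, euler, degrees=True).as_matrix()


@dataclass
class TendonSpec:
    name: str
    origin_point: np.ndarray      # fixed, lab frame (epicondyle exit), mm
    insertion_point: np.ndarray   # distal-segment frame at neutral, mm
    stiffness: float = 25.0       # series spring, N/mm
    rest_length: float | None = None  # neutral geometric length, mm

    def __post_init__(self) -> None:
        self.origin_point = np.asarray(self.origin_point, dtype=float).reshape(3)
        self.insertion_point = np.asarray(self.insertion_point, dtype=float).reshape(3)


@dataclass
class WristModel:
    """Two-rod universal-joint wrist with five tendons.

    The joint center is the universal joint; the distal segment (hand rod)
    rotates about it with the Cardan convention of :mod:`wristsim.geometry`.
    Flexor insertions lie on the volar (negative z) side, extensors dorsal.
    """

    proximal_length: float
    distal_length: float
    joint_center: np.ndarray
    tendons: list[TendonSpec]
    handedness: str = "left"
    axis_map: dict[str, int] = field(default_factory=lambda: dict(AXIS_MAP_LEFT))

    def __post_init__(self) -> None:
        self.joint_center = np.asarray(self.joint_center, dtype=float).reshape(3)
        if self.proximal_length <= 0 or self.distal_length <= 0:
            raise ValueError("segment lengths must be positive")
        names = [t.name for t in self.tendons]
        if sorted(names) != sorted(TENDON_NAMES):
            raise ValueError(f"expected tendons {TENDON_NAMES}, got {names}")
        pts = np.array([t.insertion_point for t in self.tendons])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(pts), 1)] < 1e-9):
            raise ValueError("insertion points must be distinct")
        for t in self.tendons:
            z = t.insertion_point[2] - self.joint_center[2]
            if t.name in FLEXORS and z >= 0:
                raise ValueError(f"flexor {t.name} must insert on the volar (-z) side")
            if t.name in EXTENSORS and z <= 0:
                raise ValueError(f"extensor {t.name} must insert on the dorsal (+z) side")
        expected = AXIS_MAP_LEFT if self.handedness == "left" else AXIS_MAP_RIGHT
        if self.axis_map != expected:
            raise ValueError(f"axis_map does not match the {self.handedness}-arm mounting")
        # resolve rest lengths at the neutral pose
        for t in self.tendons:
            if t.rest_length is None:
                t.rest_length = float(
                    np.linalg.norm(t.insertion_point - t.origin_point)
                )

    def tendon(self, name: str) -> TendonSpec:
        for t in self.tendons:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def tendon_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tendons)


# insertion/origin direction factors in the (y, z) cross-section of the rod:
# y ulnar(+), z dorsal(+); flexors volar (z < 0), ulnar tendons y > 0.
# The routing is balanced so that equal tendon forces produce zero net joint
# torque at the neutral pose -- the analogue of the model wrist's symmetric
# Kevlar routing.  The flexor volar depth is solved per geometry in
# :func:`_balanced_directions`; the two flexors sit deeper volar than each
# extensor, matching their larger moment arms.
_SQ2 = 0.7071067811865476
_EXTENSOR_DIRECTIONS = {
    "ECRL": (-_SQ2, _SQ2),
    "ECRB": (0.0, 1.0),
    "ECU": (_SQ2, _SQ2),
}


def _balanced_directions(geo: dict) -> dict[str, tuple[float, float]]:
    """Cross-section directions with the flexor depth chosen for torque balance.

    The neutral-pose moment arm of tendon i about the flexion (and deviation)
    axis is proportional to u_z/l_i (resp. u_y/l_i) with l_i the straight-line
    length; the y-sum vanishes by left-right symmetry and the flexor depth
    beta is solved so the z-sum vanishes too.
    """
    dx = geo["insertion_offset"] + geo["origin_offset"]
    dr = geo["origin_radius"] - geo["insertion_radius"]

    def length(u_norm: float) -> float:
        return float(np.hypot(dx, dr * u_norm))

    ext_sum = sum(uz / length(np.hypot(uy, uz))
                  for uy, uz in _EXTENSOR_DIRECTIONS.values())
    beta = 1.2
    for _ in range(20):  # fixed point converges in a few steps
        beta = ext_sum * length(np.hypot(_SQ2, beta)) / 2.0
    dirs = dict(_EXTENSOR_DIRECTIONS)
    dirs["FCR"] = (-_SQ2, -beta)
    dirs["FCU"] = (_SQ2, -beta)
    return dirs

DEFAULT_GEOMETRY = {
    "proximal_length": 250.0,   # forearm rod, mm
    "distal_length": 80.0,      # hand rod, mm
    "insertion_radius": 15.0,   # radial offset of insertions at the rod base, mm
    "insertion_offset": 15.0,   # distal offset of insertions past the joint, mm
    "origin_radius": 30.0,      # radial offset of the proximal exit points, mm
    "origin_offset": 180.0,     # proximal offset of the exit points, mm
    "stiffness": 25.0,          # series spring stiffness, N/mm
}


def build_default_wrist(handedness: str = "left", config: dict | None = None) -> WristModel:
    """Build the model wrist; the right-arm model mirrors the left.

    Mirroring negates the radioulnar (y) coordinates of origins and
    insertions and swaps the actuator axis map to the right-arm mounting.
    """
    if handedness not in ("left", "right"):
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    geo = dict(DEFAULT_GEOMETRY)
    if config:
        unknown = set(config) - set(geo)
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        geo.update(config)
    if geo["proximal_length"] <= 0 or geo["distal_length"] <= 0:
        raise ValueError("segment lengths must be positive")
    mirror = -1.0 if handedness == "right" else 1.0
    directions = _balanced_directions(geo)
    tendons = []
    for name in TENDON_NAMES:
        uy, uz = directions[name]
        ins = np.array(
            [geo["insertion_offset"], mirror * geo["insertion_radius"] * uy,
             geo["insertion_radius"] * uz]
        )
        org = np.array(
            [-geo["origin_offset"], mirror * geo["origin_radius"] * uy,
             geo["origin_radius"] * uz]
        )
        tendons.append(TendonSpec(name, org, ins, stiffness=geo["stiffness"]))
    axis_map = dict(AXIS_MAP_LEFT if handedness == "left" else AXIS_MAP_RIGHT)
    return WristModel(
        proximal_length=geo["proximal_length"],
        distal_length=geo["distal_length"],
        joint_center=np.zeros(3),
        tendons=tendons,
        handedness=handedness,
        axis_map=axis_map,
    )


def tendon_lengths(model: WristModel, pose) -> dict[str, float]:
    """Straight-line tendon lengths (mm) at a single pose.

    ``pose`` is a (prosup, fe, rud) degree triple or a one-frame JointAngles.
    """
    if isinstance(pose, JointAngles):
        pose = pose.frame(0)
    prosup, fe, rud = (float(v) for v in pose)
    for v in (prosup, fe, rud):
        if abs(v) >= 90.0:
            raise ValueError("pose beyond +-90 deg is outside the gimbal-safe range")
    R = cardan_to_matrix(prosup, fe, rud)
    jc = model.joint_center
    out = {}
    for t in model.tendons:
        world = jc + R @ (t.insertion_point - jc)
        out[t.name] = float(np.linalg.norm(world - t.origin_point))
    return out


def tendon_length_series(model: WristModel, angles: JointAngles) -> np.ndarray:
    """(n_frames, 5) tendon lengths along a path, tendon order as in model."""
    jc = model.joint_center
    ins = np.array([t.insertion_point - jc for t in model.tendons])  # (5, 3)
    org = np.array([t.origin_point for t in model.tendons])
    Rs = angles.matrices()                         # (n, 3, 3)
    world = jc + np.einsum("nij,tj->nti", Rs, ins)  # (n, 5, 3)
    return np.linalg.norm(world - org[None], axis=-1)


def generate_motion_path(
    motion: str,
    amplitude_deg: float | None = None,
    n_frames: int = 200,
    fps: float = 50.0,
    dtm_angle_deg: float | None = None,
    ellipse_axes: tuple[float, float] | None = None,
    ellipse_tilt_deg: float = 0.0,
    coupling: float = 0.0,
) -> JointAngles:
    """Ground-truth joint-angle path for one of the seven motion patterns.

    Planar motions (flexion, extension, RD, UD) ramp smoothly from neutral to
    the signed amplitude on their axis and back to neutral.  RE/UF follow the
    dart thrower's plane ``rud = fe * tan(dtm_angle_deg)``.  Circumduction
    traces a full ellipse with FE/RUD semi-axes ``ellipse_axes``, starting and
    ending at the extension configuration; ``ellipse_tilt_deg`` rotates the
    ellipse in the RUD-FE plane (positive toward ulnar-flexion).

    ``coupling`` adds a proportional out-of-plane component to planar motions
    (out_of_plane = coupling * in_plane), emulating the coupled motion a real
    wrist shows; it defaults to zero (pure planar paths).
    """
    if motion not in MOTIONS:
        raise ValueError(f"unknown motion {motion!r}; expected one of {MOTIONS}")
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    zeros = np.zeros(n_frames)
    s = np.linspace(0.0, 1.0, n_frames)

    if motion == "circumduction":
        if ellipse_axes is None:
            raise ValueError("circumduction requires ellipse_axes=(fe_semi, rud_semi)")
        a, b = (float(v) for v in ellipse_axes)
        if not (0 < a < 90 and 0 < b < 90):
            raise ValueError("ellipse semi-axes must be in (0, 90) deg")
        phi = np.pi - 2.0 * np.pi * s  # extension -> UD -> flexion -> RD -> extension
        fe = a * np.cos(phi)
        rud = b * np.sin(phi)
        if ellipse_tilt_deg:
            ct = np.cos(np.radians(ellipse_tilt_deg))
            st = np.sin(np.radians(ellipse_tilt_deg))
            # rotate in the (rud, fe) plot plane about the center
            rud, fe = ct * rud - st * fe, st * rud + ct * fe
        return JointAngles(zeros, fe, rud, fps=fps)

    if amplitude_deg is None or amplitude_deg <= 0:
        raise ValueError("amplitude_deg must be positive")
    if amplitude_deg >= 90:
        raise ValueError("amplitude must stay below 90 deg (gimbal-safe)")
    ramp = np.sin(np.pi * s) ** 2
    ramp = amplitude_deg * ramp / ramp.max()  # peak is exactly the amplitude

    if motion in ("flexion", "extension"):
        fe = ramp if motion == "flexion" else -ramp
        return JointAngles(zeros, fe, coupling * fe, fps=fps)
    if motion in ("RD", "UD"):
        rud = -ramp if motion == "RD" else ramp  # radial(-), ulnar(+)
        return JointAngles(zeros, coupling * rud, rud, fps=fps)
    # dart thrower's motions
    if dtm_angle_deg is None:
        raise ValueError(f"{motion} requires dtm_angle_deg (plane angle from sagittal)")
    fe = ramp if motion == "UF" else -ramp
    rud = fe * np.tan(np.radians(dtm_angle_deg))
    return JointAngles(zeros, fe, rud, fps=fps)


def record_excursion_profile(model: WristModel, angles: JointAngles) -> np.ndarray:
    """Per-actuator displacement profile (mm) for a joint-angle path.

    Column order is actuator axis 1..5 per the model's axis map.  Shortening
    of a tendon is a positive actuator displacement (the actuator reels in).
    Raises :class:`ActuatorTravelError` if any excursion exceeds the 80 mm
    actuator travel.
    """
    lengths = tendon_length_series(model, angles)  # (n, 5) in model tendon order
    rest = np.array([t.rest_length for t in model.tendons])
    excursion = rest[None, :] - lengths            # + = shortening from neutral
    # paths that start at neutral (all but circumduction) begin at 0 mm by
    # construction; circumduction starts at its extension configuration
    over = np.abs(excursion).max(axis=0) > ACTUATOR_TRAVEL_MM
    if np.any(over):
        bad = [model.tendons[i].name for i in np.flatnonzero(over)]
        raise ActuatorTravelError(
            f"excursion exceeds {ACTUATOR_TRAVEL_MM:.0f} mm actuator travel for {bad}"
        )
    profile = np.empty_like(excursion)
    for i, t in enumerate(model.tendons):
        profile[:, model.axis_map[t.name] - 1] = excursion[:, i]
    return profile


@dataclass
class MarkerSet:
    """Implanted bead centroids of one bone in its CT/reference frame (mm)."""

    bone_id: str
    reference_positions: np.ndarray  # (n_markers, 3)

    def __post_init__(self) -> None:
        if self.bone_id not in BONES:
            raise ValueError(f"unknown bone {self.bone_id!r}")
        self.reference_positions = np.asarray(
            self.reference_positions, dtype=float
        ).reshape(-1, 3)
        p = self.reference_positions
        if len(p) < 3:
            raise ValueError("at least 3 markers per bone are required")
        d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(p), 1)] <= 2.0):
            raise ValueError("marker pairwise distances must exceed 2 mm")
        centered = p - p.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if len(sv) < 2 or sv[1] <= 0.5:
            raise ValueError("markers are collinear (planar extent <= 0.5 mm)")

    @property
    def n_markers(self) -> int:
        return len(self.reference_positions)


def default_marker_sets() -> dict[str, MarkerSet]:
    """Three-bead triads per bone, placed on the dorsal aspects.

    Reference (CT) frames coincide with the lab frame at the neutral pose.
    """
    layout = {
        "radius": [(-62.0, -9.0, 3.0), (-40.0, 7.0, 17.0), (-19.0, -5.0, 2.0)],
        "ulna": [(-60.0, 11.0, 2.0), (-42.0, 25.0, 15.0), (-23.0, 13.0, 4.0)],
        "MCII": [(38.0, -20.0, 5.0), (52.0, -8.0, 17.0), (67.0, -17.0, 4.0)],
        "MCIII": [(38.0, -5.0, 5.0), (54.0, 9.0, 17.0), (70.0, -3.0, 4.0)],
    }
    return {b: MarkerSet(b, np.array(pts)) for b, pts in layout.items()}


def bone_pose(model: WristModel, pose_deg: tuple[float, float, float],
              bone: str, mounting: RigidTransform | None = None) -> RigidTransform:
    """Lab pose of a bone's reference frame at a wrist pose.

    Radius/ulna ride on the fixed proximal segment; MCII/MCIII on the distal
    segment, which rotates about the joint center.
    """
    mount = mounting if mounting is not None else RigidTransform.identity()
    if bone in PROXIMAL_BONES:
        return mount
    R = cardan_to_matrix(*pose_deg)
    seg = RigidTransform.about_point(R, model.joint_center)
    return seg.compose(mount)


def markers_from_motion(
    model: WristModel,
    angles: JointAngles,
    marker_sets: dict[str, MarkerSet],
    mounting: dict[str, RigidTransform] | None = None,
) -> dict[str, np.ndarray]:
    """Per-bone (n_frames, n_markers, 3) noiseless marker trajectories."""
    mounting = mounting or {}
    n = len(angles)
    Rs = angles.matrices()
    jc = model.joint_center
    out: dict[str, np.ndarray] = {}
    for bone, ms in marker_sets.items():
        mount = mounting.get(bone, RigidTransform.identity())
        ref_lab = ms.reference_positions @ mount.rotation.T + mount.translation
        if bone in PROXIMAL_BONES:
            out[bone] = np.broadcast_to(ref_lab, (n, ms.n_markers, 3)).copy()
        else:
            rel = ref_lab - jc
            out[bone] = jc + np.einsum("nij,mj->nmi", Rs, rel)
    return out


@dataclass
class TrialBundle:
    """One synthetic motion trial: truth, 3D beads, and biplanar observations."""

    motion: str
    angles_truth: JointAngles
    marker_3d: dict[str, np.ndarray]            # bone -> (n, m, 3) mm
    image_points: dict[str, dict[str, np.ndarray]]  # camera -> bone -> (n, m, 2) px
    fps: float
    noise_sigma_mm: float
    seed: int
    is_static: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.angles_truth)


def _smooth_jitter(rng: np.random.Generator, n: int, amplitude_deg: float) -> np.ndarray:
    """Low-frequency perturbation vanishing at both trial ends."""
    if amplitude_deg == 0.0 or n < 4:
        return np.zeros(n)
    s = np.linspace(0.0, 1.0, n)
    coeffs = rng.normal(size=3) / np.arange(1, 4)
    wave = sum(c * np.sin(np.pi * (k + 1) * s) for k, c in enumerate(coeffs))
    peak = np.abs(wave).max()
    if peak < 1e-12:
        return np.zeros(n)
    return amplitude_deg * rng.uniform(0.3, 1.0) * wave / peak


def make_trial_bundle(
    model: WristModel,
    motion_spec: dict,
    cameras: dict | None = None,
    marker_sets: dict[str, MarkerSet] | None = None,
    mounting: dict[str, RigidTransform] | None = None,
    n_trials: int = 5,
    noise_sigma_mm: float = 0.0,
    trial_jitter_deg: float = 0.0,
    mount_offset_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_static_frames: int = 50,
    seed: int = 0,
    trial_length_jitter: int = 0,
) -> tuple[list[TrialBundle], TrialBundle]:
    """Generate repeat trials plus the per-motion static trial.

    ``motion_spec`` holds the keyword arguments of :func:`generate_motion_path`
    plus the motion name.  Each trial adds an independent smooth angle
    perturbation (amplitude ``trial_jitter_deg``) and Gaussian 3D marker noise
    (sigma ``noise_sigma_mm``) before projection.  ``mount_offset_deg`` is the
    constant not-quite-neutral mounting pose of the specimen, shared by all
    trials and by the static trial; the static trial captures the wrist
    resting at that offset.  Identical seeds give bit-identical bundles.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    marker_sets = marker_sets or default_marker_sets()
    rng = np.random.default_rng(seed)
    spec = dict(motion_spec)
    motion = spec.pop("motion")
    base = generate_motion_path(motion, **spec)
    off = RigidTransform.about_point(cardan_to_matrix(*mount_offset_deg),
                                     model.joint_center)
    off_mat = cardan_to_matrix(*mount_offset_deg)

    def bundle_for(path: JointAngles, is_static: bool) -> TrialBundle:
        trial_seed = int(rng.integers(0, 2**31 - 1))
        # mount offset composes on the left: distal pose = R_off @ R_path
        arr = path.as_array()
        markers = markers_from_motion(model, path, marker_sets, mounting)
        n = len(path)
        for bone in markers:
            if bone in DISTAL_BONES:
                jc = model.joint_center
                markers[bone] = jc + (markers[bone] - jc) @ off_mat.T
        if noise_sigma_mm > 0:
            for bone in markers:
                markers[bone] = markers[bone] + rng.normal(
                    scale=noise_sigma_mm, size=markers[bone].shape
                )
        image_points: dict[str, dict[str, np.ndarray]] = {}
        if cameras:
            for cam_name, cam in cameras.items():
                image_points[cam_name] = {
                    bone: cam.project(pts.reshape(-1, 3)).reshape(n, -1, 2)
                    for bone, pts in markers.items()
                }
        return TrialBundle(
            motion=motion,
            angles_truth=JointAngles.from_array(arr, fps=path.fps),
            marker_3d=markers,
            image_points=image_points,
            fps=path.fps,
            noise_sigma_mm=noise_sigma_mm,
            seed=trial_seed,
            is_static=is_static,
        )

    trials = []
    for _ in range(n_trials):
        arr = base.as_array().copy()
        n = len(base)
        if trial_length_jitter > 0:
            n = n - int(rng.integers(0, trial_length_jitter + 1))
            arr = arr[:n]
        for col in range(3):
            arr[:, col] = arr[:, col] + _smooth_jitter(rng, n, trial_jitter_deg)
        trials.append(bundle_for(JointAngles.from_array(arr, fps=base.fps), False))
    static_path = JointAngles.from_array(
        np.zeros((n_static_frames, 3)), fps=base.fps
    )
    static = bundle_for(static_path, True)
    return trials, static
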