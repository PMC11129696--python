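"""Anatomical coordinate systems and wrist-angle extraction.

The radial coordinate system (RCS) has its x-axis along the distal radial
shaft, origin where that axis meets the distal articular surface, y-axis
through the sigmoid notch center and z = x cross y.  The third-metacarpal
system (MCS) has x along the MCIII diaphysis and y the best-fit line through
the MCII/MCIII/MCIV centroids.  Wrist motion is the rotation of the MCS
about the RCS; neutral is defined as the alignment of the two systems, and
each motion's static trial supplies the specimen's actual initial offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, matrix_to_cardan
from .recon import PoseSeries
from .wrist import JointAngles

RADIUS_LANDMARKS = (
    "shaft_proximal", "shaft_distal", "articular_surface_point", "sigmoid_notch_center"
)
METACARPAL_LANDMARKS = (
    "mcIII_diaphysis_proximal", "mcIII_diaphysis_distal",
    "centroid_MCII", "centroid_MCIII", "centroid_MCIV",
)


class DegenerateFrameError(ValueError):
    """Landmarks do not span a well-defined right-handed frame."""


@dataclass
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes, all in the bone's frame."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        R = self.rotation()
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise DegenerateFrameError("axes are left-handed")

    def rotation(self) -> np.ndarray:
        """3x3 matrix with the frame axes as columns (frame -> bone coords)."""
        return np.column_stack([self.x, self.y, self.z])


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateFrameError(f"{what} has zero length")
    return v / n


def _require(landmarks: dict, names: tuple[str, ...]) -> None:
    missing = [n for n in names if n not in landmarks]
    if missing:
        raise ValueError(f"missing landmarks: {missing}")


def build_rcs(landmarks: dict[str, np.ndarray]) -> AnatomicalFrame:
    """Radial coordinate system from radius landmarks (bone/CT frame, mm)."""
    _require(landmarks, RADIUS_LANDMARKS)
    lm = {k: np.asarray(v, dtype=float).reshape(3) for k, v in landmarks.items()}
    x = _unit(lm["shaft_distal"] - lm["shaft_proximal"], "radial shaft axis")
    origin = lm["articular_surface_point"]
    toward_notch = lm["sigmoid_notch_center"] - origin
    y = toward_notch - np.dot(toward_notch, x) * x
    if np.linalg.norm(y) < 1e-6:
        raise DegenerateFrameError("sigmoid notch center lies on the shaft axis")
    y = y / np.linalg.norm(y)
    return AnatomicalFrame(origin, x, y, np.cross(x, y))


def build_mcs(landmarks: dict[str, np.ndarray]) -> AnatomicalFrame:
    """Third-metacarpal coordinate system from metacarpal landmarks.

    y is the principal direction of the three metacarpal centroids,
    orthogonalized against the diaphysis axis, signed toward MCII.
    """
    _require(landmarks, METACARPAL_LANDMARKS)
    lm = {k: np.asarray(v, dtype=float).reshape(3) for k, v in landmarks.items()}
    x = _unit(lm["mcIII_diaphysis_distal"] - lm["mcIII_diaphysis_proximal"],
              "MCIII diaphysis axis")
    cents = np.array([lm["centroid_MCII"], lm["centroid_MCIII"], lm["centroid_MCIV"]])
    centered = cents - cents.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    d = Vt[0]
    if np.dot(d, lm["centroid_MCII"] - lm["centroid_MCIII"]) < 0:
        d = -d
    y = d - np.dot(d, x) * x
    if np.linalg.norm(y) < 1e-6:
        raise DegenerateFrameError("metacarpal centroids are collinear with the diaphysis")
    y = y / np.linalg.norm(y)
    origin = lm["centroid_MCIII"]
    return AnatomicalFrame(origin, x, y, np.cross(x, y))


def relative_rotation(
    rcs: AnatomicalFrame,
    mcs: AnatomicalFrame,
    radius_pose: RigidTransform,
    mc_pose: RigidTransform,
) -> np.ndarray:
    """Rotation of the MCS relative to the RCS at one capture frame.

    R_rel = (R_radius R_RCS)^T (R_mc R_MCS); identity when the two anatomical
    systems are aligned in the lab, so a shared whole-arm motion cancels.
    """
    R_r = radius_pose.rotation @ rcs.rotation()
    R_m = mc_pose.rotation @ mcs.rotation()
    return R_r.T @ R_m


def decompose_angles(R_rel: np.ndarray) -> tuple[float, float, float]:
    """(prosup, fe, rud) in degrees via the intrinsic y->z->x Cardan sequence."""
    return matrix_to_cardan(R_rel)


def angles_from_poses(
    rcs: AnatomicalFrame,
    mcs: AnatomicalFrame,
    radius_series: PoseSeries,
    mc_series: PoseSeries,
) -> JointAngles:
    """Per-frame wrist angles from reconstructed radius and MCIII poses."""
    if len(radius_series) != len(mc_series):
        raise ValueError("pose series lengths differ")
    Rr = np.einsum("nij,jk->nik", radius_series.rotations, rcs.rotation())
    Rm = np.einsum("nij,jk->nik", mc_series.rotations, mcs.rotation())
    rel = np.einsum("nji,njk->nik", Rr, Rm)
    return _angles_from_matrices(rel, fps=radius_series.fps)


def _angles_from_matrices(rel: np.ndarray, fps: float) -> JointAngles:
    from .geometry import CARDAN_SEQUENCE

    euler = Rotation.from_matrix(rel).as_euler(CARDAN_SEQUENCE, degrees=True)
    # columns: fe, rud, prosup
    return JointAngles(euler[:, 2], euler[:, 0], euler[:, 1], fps=fps)


def mean_rotation(angles: JointAngles) -> np.ndarray:
    """Chordal-mean rotation of an angle series (quaternion average)."""
    Rs = Rotation.from_matrix(angles.matrices())
    return Rs.mean().as_matrix()


def neutral_correct(angles: JointAngles, static_angles: JointAngles) -> JointAngles:
    """Re-express wrist angles relative to the static-trial neutral pose.

    Correction composes in rotation space, R_corrected = R_static^T R_raw,
    which is exact for large offsets and reduces to angle subtraction for
    small ones.  Idempotent once the static offset has been removed.
    """
    if static_angles is None or len(static_angles) == 0:
        raise ValueError("a static trial is required for neutral correction")
    R_s = mean_rotation(static_angles)
    rel = np.einsum("ji,njk->nik", R_s, angles.matrices())
    return _angles_from_matrices(rel, fps=angles.fps)


def mirror_right_to_left(markers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Mirror right-arm marker data about the lab sagittal (xz) plane.

    Right and left arms are mounted as mirror images; negating the
    radioulnar (y) coordinate maps right-arm data onto the left-arm sign
    convention so ulnar deviation stays positive for both.
    """
    return {bone: pts * np.array([1.0, -1.0, 1.0]) for bone, pts in markers.items()}


def default_landmarks() -> dict[str, dict[str, list[float]]]:
    """Landmark sets (bone CT frames, mm) aligned with the lab at neutral.

    Constructed so that RCS and MCS both coincide with the lab axes at the
    neutral pose: the sigmoid notch center and the MCII centroid sit on the
    +y side, making the two y-axes parallel (the neutral-alignment
    definition of zero wrist angle fixes this sign choice).
    """
    return {
        "radius": {
            "shaft_proximal": [-120.0, 0.0, 0.0],
            "shaft_distal": [-20.0, 0.0, 0.0],
            "articular_surface_point": [0.0, 0.0, 0.0],
            "sigmoid_notch_center": [0.0, 14.0, 0.0],
        },
        "metacarpals": {
            "mcIII_diaphysis_proximal": [25.0, 0.0, 0.0],
            "mcIII_diaphysis_distal": [75.0, 0.0, 0.0],
            "centroid_MCII": [50.0, 18.0, 0.0],
            "centroid_MCIII": [50.0, 0.0, 0.0],
            "centroid_MCIV": [50.0, -18.0, 0.0],
        },
    }
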