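"""Rigid transforms and the wrist Cardan angle convention.

The lab frame is right-handed with x pointing distally along the forearm
axis, y along the radioulnar axis (positive toward the sigmoid-notch /
ulnar side) and z = x cross y (dorsal).  Wrist rotations follow the radial
coordinate system convention: rotation about x is pronation(+)/supination(-),
about y flexion(+)/extension(-), about z ulnar(+)/radial(-) deviation.

Angles are decomposed with the intrinsic Cardan sequence y -> z -> x
(flexion, deviation, pronation), i.e. R = Ry(fe) @ Rz(rud) @ Rx(prosup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

#: scipy intrinsic Euler sequence matching R = Ry(fe) @ Rz(rud) @ Rx(prosup)
CARDAN_SEQUENCE = "YZX"

GIMBAL_GUARD_DEG = 89.0


class GimbalWarning(UserWarning):
    """Second Cardan angle is close enough to 90 deg to degrade the others."""


def cardan_to_matrix(prosup_deg: float, fe_deg: float, rud_deg: float) -> np.ndarray:
    """Rotation matrix for (pronation, flexion, ulnar deviation) in degrees."""
    return Rotation.from_euler(
        CARDAN_SEQUENCE, [fe_deg, rud_deg, prosup_deg], degrees=True
    ).as_matrix()


def matrix_to_cardan(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation into (prosup_deg, fe_deg, rud_deg).

    Composing the returned angles in the y->z->x sequence reproduces ``R``
    (exact away from gimbal lock).  A :class:`GimbalWarning` is issued when
    the deviation angle approaches +-90 deg.
    """
    R = np.asarray(R, dtype=float)
    _check_rotation(R)
    fe, rud, prosup = Rotation.from_matrix(R).as_euler(CARDAN_SEQUENCE, degrees=True)
    if abs(rud) > GIMBAL_GUARD_DEG:
        warnings.warn(
            f"deviation angle {rud:.2f} deg is within 1 deg of gimbal lock; "
            "flexion/pronation angles are ill-conditioned",
            GimbalWarning,
            stacklevel=2,
        )
    return float(prosup), float(fe), float(rud)


def _check_rotation(R: np.ndarray, tol: float = 1e-8) -> None:
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection (det < 0)")


@dataclass
class RigidTransform:
    """Rotation + translation mapping reference-frame points into lab points.

    ``apply`` computes ``R @ p + t`` (mm).  Rotation is proper orthonormal.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_point(cls, rotation: np.ndarray, center: np.ndarray) -> "RigidTransform":
        """Rotation about an arbitrary fixed point (e.g. the joint center)."""
        rotation = np.asarray(rotation, dtype=float)
        center = np.asarray(center, dtype=float)
        return cls(rotation, center - rotation @ center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix in degrees.

    Uses the quaternion magnitude, which stays accurate for very small
    angles where the trace/arccos formula loses precision.
    """
    return float(np.degrees(Rotation.from_matrix(np.asarray(R, float)).magnitude()))
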