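"""Biplanar X-ray camera models: 11-parameter DLT, calibration, triangulation.

Each image chain (X-ray source -> image intensifier -> video camera) is an
ideal pinhole described by the direct linear transform

    u = (L1 X + L2 Y + L3 Z + L4) / (L9 X + L10 Y + L11 Z + 1)
    v = (L5 X + L6 Y + L7 Z + L8) / (L9 X + L10 Y + L11 Z + 1)

with lab coordinates in mm and image coordinates in px.  Calibration solves
the 11 coefficients by linear least squares from a bead cube of known
spacing; triangulation intersects the two view rays, again linearly.
Image-intensifier undistortion is not modelled (the synthetic cameras are
ideal); ``CameraModel.undistort`` is a hook for pre-applying an external
correction to observed points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


class CalibrationError(ValueError):
    """Degenerate calibration geometry (e.g. coplanar control points)."""


class ConditioningWarning(UserWarning):
    """Near-parallel viewing rays make the triangulation ill-conditioned."""


@dataclass
class CameraModel:
    """11 DLT coefficients plus the image size in px."""

    dlt: np.ndarray
    image_size: tuple[int, int] = (1024, 1024)
    undistort: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.dlt = np.asarray(self.dlt, dtype=float).reshape(11)

    def projection_matrix(self) -> np.ndarray:
        """3x4 homogeneous projection matrix (last entry 1)."""
        return np.append(self.dlt, 1.0).reshape(3, 4)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) lab points (mm) to (n, 2) image points (px)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        P = self.projection_matrix()
        hom = np.hstack([points, np.ones((len(points), 1))]) @ P.T
        denom = hom[:, 2]
        if np.any(np.abs(denom) < 1e-12):
            raise ValueError("projection denominator vanishes inside the volume")
        return hom[:, :2] / denom[:, None]

    @classmethod
    def from_look_at(
        cls,
        source: np.ndarray,
        target: np.ndarray,
        focal_px: float,
        image_size: tuple[int, int] = (1024, 1024),
        up: np.ndarray = (0.0, 0.0, 1.0),
    ) -> "CameraModel":
        """Ideal pinhole at ``source`` looking at ``target``."""
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        w = target - source
        w = w / np.linalg.norm(w)              # optical axis
        up = np.asarray(up, dtype=float)
        u = np.cross(w, up)
        if np.linalg.norm(u) < 1e-9:
            raise ValueError("up vector is parallel to the viewing direction")
        u = u / np.linalg.norm(u)
        v = np.cross(w, u)
        R = np.stack([u, v, w])                # lab -> camera
        K = np.array(
            [
                [focal_px, 0.0, image_size[0] / 2.0],
                [0.0, focal_px, image_size[1] / 2.0],
                [0.0, 0.0, 1.0],
            ]
        )
        P = K @ np.hstack([R, (-R @ source)[:, None]])
        if abs(P[2, 3]) < 1e-12:
            raise ValueError("camera center too close to the lab origin plane")
        P = P / P[2, 3]
        return cls(P.reshape(12)[:11], image_size=image_size)


def make_biplanar_rig(
    source_to_object_mm: float = 760.0,
    source_to_image_mm: float = 1100.0,
    px_per_mm: float = 2.56,
    image_size: tuple[int, int] = (1024, 1024),
    object_center: np.ndarray = (0.0, 0.0, 0.0),
) -> dict[str, CameraModel]:
    """Two orthogonal X-ray views, each at ~45 deg to the specimen axis.

    The default geometry mirrors the capture setup: source-to-image distance
    110 cm, views orthogonal to one another, and the forearm (lab x axis)
    at 45 deg to both beams.
    """
    center = np.asarray(object_center, dtype=float)
    focal_px = source_to_image_mm * px_per_mm
    d1 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    d2 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    cams = {}
    for name, d in (("cam1", d1), ("cam2", d2)):
        src = center - source_to_object_mm * d
        cams[name] = CameraModel.from_look_at(
            src, center, focal_px=focal_px, image_size=image_size
        )
    return cams


def make_calibration_cube(
    n_side: int = 4, spacing_mm: float = 50.0, center: np.ndarray = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """(n_side**3, 3) bead grid of known spacing (default 64 beads)."""
    half = (n_side - 1) / 2.0
    axes = (np.arange(n_side) - half) * spacing_mm
    X, Y, Z = np.meshgrid(axes, axes, axes, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) + np.asarray(center, float)


def calibrate_dlt(
    points_3d: np.ndarray,
    points_2d: np.ndarray,
    image_size: tuple[int, int] = (1024, 1024),
) -> tuple[CameraModel, float]:
    """Least-squares DLT calibration from >= 6 non-coplanar control points.

    Returns the camera model and the RMS reprojection residual in px.
    Raises :class:`CalibrationError` for coplanar or rank-deficient sets.
    """
    P3 = np.asarray(points_3d, dtype=float).reshape(-1, 3)
    P2 = np.asarray(points_2d, dtype=float).reshape(-1, 2)
    if len(P3) != len(P2):
        raise ValueError("3D and 2D point counts differ")
    if len(P3) < 6:
        raise CalibrationError("at least 6 control points are required")
    centered = P3 - P3.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-6 * sv[0]:
        raise CalibrationError("control points are coplanar; DLT is rank-deficient")

    # normalize both point sets (Hartley-style) for numerical conditioning
    c3, s3 = P3.mean(axis=0), P3.std()
    c2, s2 = P2.mean(axis=0), P2.std()
    s3 = s3 if s3 > 0 else 1.0
    s2 = s2 if s2 > 0 else 1.0
    N3 = (P3 - c3) / s3
    N2 = (P2 - c2) / s2

    n = len(P3)
    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    X, Y, Z = N3[:, 0], N3[:, 1], N3[:, 2]
    u, v = N2[:, 0], N2[:, 1]
    A[0::2, 0:3] = N3
    A[0::2, 3] = 1.0
    A[0::2, 8] = -u * X
    A[0::2, 9] = -u * Y
    A[0::2, 10] = -u * Z
    A[1::2, 4:7] = N3
    A[1::2, 7] = 1.0
    A[1::2, 8] = -v * X
    A[1::2, 9] = -v * Y
    A[1::2, 10] = -v * Z
    b[0::2] = u
    b[1::2] = v
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 11:
        raise CalibrationError("calibration system is rank-deficient")
    # denormalize: P = T2^-1 @ Pn @ T3 in homogeneous form
    Pn = np.append(coeffs, 1.0).reshape(3, 4)
    T3 = np.eye(4)
    T3[:3, :3] /= s3
    T3[:3, 3] = -c3 / s3
    T2inv = np.array([[s2, 0.0, c2[0]], [0.0, s2, c2[1]], [0.0, 0.0, 1.0]])
    P = T2inv @ Pn @ T3
    if abs(P[2, 3]) < 1e-12:
        raise CalibrationError("degenerate projection normalization")
    P = P / P[2, 3]
    cam = CameraModel(P.reshape(12)[:11], image_size=image_size)
    resid = cam.project(P3) - P2
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return cam, rms


def _triangulation_system(cams: list[CameraModel], pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows_A, rows_b = [], []
    for cam, uv in zip(cams, pts):
        L = cam.dlt
        u, v = uv
        rows_A.append([L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]])
        rows_A.append([L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]])
        rows_b.append(u - L[3])
        rows_b.append(v - L[7])
    return np.array(rows_A), np.array(rows_b)


def triangulate(
    cam_a: CameraModel,
    cam_b: CameraModel,
    pt_a: np.ndarray,
    pt_b: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Intersect two view rays; returns the 3D point (mm) and the RMS
    reprojection residual (px).

    Inconsistent observations yield a large residual, not an exception; a
    :class:`ConditioningWarning` is raised for near-parallel ray geometry.
    """
    pt_a = np.asarray(pt_a, dtype=float).reshape(2)
    pt_b = np.asarray(pt_b, dtype=float).reshape(2)
    if cam_a.undistort is not None:
        pt_a = np.asarray(cam_a.undistort(pt_a[None]), dtype=float).reshape(2)
    if cam_b.undistort is not None:
        pt_b = np.asarray(cam_b.undistort(pt_b[None]), dtype=float).reshape(2)
    A, b = _triangulation_system([cam_a, cam_b], [pt_a, pt_b])
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        warnings.warn(
            "viewing rays are near-parallel; triangulation is ill-conditioned",
            ConditioningWarning,
            stacklevel=2,
        )
    point, *_ = np.linalg.lstsq(A, b, rcond=None)
    ra = cam_a.project(point[None])[0] - pt_a
    rb = cam_b.project(point[None])[0] - pt_b
    rms = float(np.sqrt(np.mean(np.concatenate([ra, rb]) ** 2)))
    return point, rms


def triangulate_points(
    cam_a: CameraModel,
    cam_b: CameraModel,
    pts_a: np.ndarray,
    pts_b: np.ndarray,
) -> np.ndarray:
    """Vectorized two-view triangulation of (n, 2) point arrays -> (n, 3) mm.

    Rows with any non-finite observation yield NaN points (missing markers).
    """
    pts_a = np.atleast_2d(np.asarray(pts_a, dtype=float))
    pts_b = np.atleast_2d(np.asarray(pts_b, dtype=float))
    n = len(pts_a)
    La, Lb = cam_a.dlt, cam_b.dlt
    A = np.empty((n, 4, 3))
    b = np.empty((n, 4))
    for i, (L, pts) in enumerate(((La, pts_a), (Lb, pts_b))):
        u, v = pts[:, 0], pts[:, 1]
        A[:, 2 * i, :] = L[0:3][None] - u[:, None] * L[8:11][None]
        A[:, 2 * i + 1, :] = L[4:7][None] - v[:, None] * L[8:11][None]
        b[:, 2 * i] = u - L[3]
        b[:, 2 * i + 1] = v - L[7]
    good = np.isfinite(b).all(axis=1)
    out = np.full((n, 3), np.nan)
    if np.any(good):
        Ag, bg = A[good], b[good]
        AtA = np.einsum("nij,nik->njk", Ag, Ag)
        Atb = np.einsum("nij,ni->nj", Ag, bg)
        out[good] = np.linalg.solve(AtA, Atb[..., None])[..., 0]
    return out
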