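"""Marker-based reconstruction: rigid-body fitting and pose smoothing.

Bead centroids triangulated from the two views are grouped by bone and
aligned to their CT-frame reference positions with a closed-form orthogonal
Procrustes (Kabsch) fit, giving a rigid body transform per bone per frame.
Pose series are then low-pass filtered (zero-phase second-order Butterworth,
2 Hz cut-off by default) in quaternion + translation space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .cameras import CameraModel, triangulate_points
from .geometry import RigidTransform
from .wrist import MarkerSet, TrialBundle


class DegenerateMarkersError(ValueError):
    """Fewer than 3 usable markers, or a collinear marker set."""


def fit_rigid_transform(
    reference: np.ndarray, observed: np.ndarray
) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares rigid fit mapping reference points onto observed points.

    Minimizes sum ||R p_i + t - q_i||^2 over proper rotations (reflections
    are excluded by a sign correction on the smallest singular vector).
    Returns the transform and the per-marker residual norms (mm).
    """
    P = np.asarray(reference, dtype=float).reshape(-1, 3)
    Q = np.asarray(observed, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError("reference and observed point sets differ in shape")
    if len(P) < 3:
        raise DegenerateMarkersError("at least 3 matched markers are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateMarkersError("reference markers are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    residuals = np.linalg.norm(P @ R.T + t - Q, axis=1)
    return RigidTransform(R, t), residuals


def fit_rigid_transforms_batch(
    reference: np.ndarray, observed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kabsch fit per frame: reference (m, 3) vs observed (n, m, 3).

    Returns rotations (n, 3, 3), translations (n, 3) and per-frame RMS
    residuals (mm).  Frames with non-finite observations come back NaN.
    """
    P = np.asarray(reference, dtype=float).reshape(-1, 3)
    Q = np.asarray(observed, dtype=float)
    n = len(Q)
    Rs = np.full((n, 3, 3), np.nan)
    ts = np.full((n, 3), np.nan)
    rms = np.full(n, np.nan)
    good = np.isfinite(Q).all(axis=(1, 2))
    if not np.any(good):
        return Rs, ts, rms
    pc = P.mean(axis=0)
    P0 = P - pc
    Qg = Q[good]
    qc = Qg.mean(axis=1)
    Q0 = Qg - qc[:, None, :]
    H = np.einsum("mi,nmj->nij", P0, Q0)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,nkj->nik", Vt.transpose(0, 2, 1), U))
    D = np.broadcast_to(np.eye(3), (len(Qg), 3, 3)).copy()
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("nji,njk,nlk->nil", Vt, D, U)
    t = qc - np.einsum("nij,j->ni", R, pc)
    fitted = np.einsum("nij,mj->nmi", R, P) + t[:, None, :]
    rms_good = np.sqrt(np.mean(np.sum((fitted - Qg) ** 2, axis=-1), axis=-1))
    Rs[good], ts[good], rms[good] = R, t, rms_good
    return Rs, ts, rms


@dataclass
class PoseSeries:
    """Per-frame rigid transform of one bone, at a stated frame rate."""

    rotations: np.ndarray     # (n, 3, 3)
    translations: np.ndarray  # (n, 3) mm
    fps: float = 50.0
    residual_rms: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if len(self.rotations) != len(self.translations):
            raise ValueError("rotation and translation counts differ")

    def __len__(self) -> int:
        return len(self.rotations)

    def transform(self, k: int) -> RigidTransform:
        return RigidTransform(self.rotations[k], self.translations[k])

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of frames with a fitted pose (no flagged gap)."""
        return np.isfinite(self.rotations).all(axis=(1, 2))


def smooth_pose_series(series: PoseSeries, cutoff_hz: float = 2.0,
                       fps: float | None = None) -> PoseSeries:
    """Zero-phase low-pass Butterworth smoothing of a pose series.

    Translations and hemisphere-aligned quaternion components are filtered
    forward-backward with a second-order Butterworth filter (even-reflection
    padding), and the quaternions renormalized, so every output pose is a
    valid rigid transform with no phase lag.
    """
    fps = fps if fps is not None else series.fps
    if fps <= 2.0 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cut-off frequency")
    n = len(series)
    order = 2
    min_len = 3 * (order + 1) + 1
    if n < min_len:
        raise ValueError(
            f"series of length {n} is too short to filter; need at least {min_len} frames"
        )
    if not np.all(series.valid):
        raise ValueError("cannot smooth a series with flagged gaps")
    quats = Rotation.from_matrix(series.rotations).as_quat()
    for k in range(1, n):  # hemisphere continuity
        if np.dot(quats[k], quats[k - 1]) < 0:
            quats[k] = -quats[k]
    b, a = butter(order, cutoff_hz / (fps / 2.0))
    sm_q = filtfilt(b, a, quats, axis=0, padtype="even")
    sm_q /= np.linalg.norm(sm_q, axis=1, keepdims=True)
    sm_t = filtfilt(b, a, series.translations, axis=0, padtype="even")
    return PoseSeries(
        Rotation.from_quat(sm_q).as_matrix(), sm_t, fps=fps,
        residual_rms=series.residual_rms,
    )


def reconstruct_trial(
    bundle: TrialBundle,
    cameras: dict[str, CameraModel],
    marker_sets: dict[str, MarkerSet],
    smooth: bool = True,
    cutoff_hz: float = 2.0,
) -> dict[str, PoseSeries]:
    """Full reconstruction chain for one trial.

    Triangulates every bead per frame from the two views, groups beads by
    bone, fits a rigid transform per bone per frame, and (optionally)
    smooths the pose series.  A bone-frame with fewer than 3 finite beads is
    left as an explicit NaN gap, never interpolated.
    """
    if len(cameras) != 2:
        raise ValueError("exactly two calibrated cameras are required")
    (name_a, cam_a), (name_b, cam_b) = sorted(cameras.items())
    out: dict[str, PoseSeries] = {}
    for bone, ms in marker_sets.items():
        obs_a = bundle.image_points[name_a][bone]  # (n, m, 2)
        obs_b = bundle.image_points[name_b][bone]
        n, m = obs_a.shape[:2]
        pts3 = triangulate_points(
            cam_a, cam_b, obs_a.reshape(-1, 2), obs_b.reshape(-1, 2)
        ).reshape(n, m, 3)
        Rs, ts, rms = fit_rigid_transforms_batch(ms.reference_positions, pts3)
        # frames with a missing bead but >= 3 visible ones: fit the subset;
        # fewer than 3 visible stays an explicit gap
        finite = np.isfinite(pts3).all(axis=2)  # (n, m)
        partial = np.flatnonzero((~finite.all(axis=1)) & (finite.sum(axis=1) >= 3))
        for k in partial:
            sel = finite[k]
            tf, res = fit_rigid_transform(ms.reference_positions[sel], pts3[k, sel])
            Rs[k], ts[k] = tf.rotation, tf.translation
            rms[k] = float(np.sqrt(np.mean(res**2)))
        series = PoseSeries(Rs, ts, fps=bundle.fps, residual_rms=rms)
        if smooth and np.all(series.valid):
            series = smooth_pose_series(series, cutoff_hz=cutoff_hz)
        out[bone] = series
    return out
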