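"""Derived wrist-motion statistics.

Implements the analysis applied to the reconstructed angle series: trial
averaging with truncation to the shortest trial, further truncation at the
maximum joint rotation, in-/out-of-plane range of motion, the dart
thrower's motion (DTM) plane regression with the R^2 >= 0.7 inclusion rule,
direct least-squares ellipse fitting of the circumduction envelope with its
100-vector RMSE, and the inter-trial / inter-specimen repeatability RMSEs
(specimen profiles interpolated to 100 points, 200 for circumduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

R2_EXCLUSION_THRESHOLD = 0.7
INTERP_POINTS = 100
INTERP_POINTS_CIRCUMDUCTION = 200

ANGLE_CHANNELS = ("prosup_deg", "fe_deg", "rud_deg")

_FE_MOTIONS = ("flexion", "extension")
_RUD_MOTIONS = ("RD", "UD")
_DTM_MOTIONS = ("RE", "UF")


class CircumductionPathError(ValueError):
    """The envelope is open, too sparse, or otherwise unfit for ellipse fitting."""


# ---------------------------------------------------------------------------
# trial averaging and truncation


@dataclass
class MeanMotionProfile:
    """Mean profile over repeat trials, truncated to the shortest trial."""

    motion: str
    data: np.ndarray               # (n_samples, n_channels)
    channels: tuple[str, ...]
    n_trials: int
    fps: float = 50.0
    truncation_index: int | None = None

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]


def average_trials(
    trials: list[np.ndarray],
    motion: str,
    channels: tuple[str, ...] = ANGLE_CHANNELS,
    fps: float = 50.0,
) -> MeanMotionProfile:
    """Per-sample mean over trials, all truncated to the shortest trial.

    ``trials`` are (n_i, n_channels) arrays (angle, force or displacement
    channels alike).  At least two trials are required; for a single trial
    pass it through directly instead of averaging.
    """
    if len(trials) < 2:
        raise ValueError("averaging needs >= 2 trials; pass a single trial through")
    arrs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    ncols = {a.shape[1] for a in arrs}
    if len(ncols) != 1 or ncols.pop() != len(channels):
        raise ValueError("trials must share the channel layout")
    n = min(len(a) for a in arrs)
    mean = np.mean([a[:n] for a in arrs], axis=0)
    return MeanMotionProfile(motion, mean, tuple(channels), len(arrs), fps=fps)


def _combined_magnitude(profile: MeanMotionProfile) -> np.ndarray:
    fe = profile.channel("fe_deg")
    rud = profile.channel("rud_deg")
    return np.hypot(fe, rud)


def truncate_to_max(profile: MeanMotionProfile, motion: str | None = None) -> MeanMotionProfile:
    """Truncate a mean profile to end at the maximum joint rotation.

    Flexion/extension use |fe|, RD/UD |rud|, RE/UF the combined magnitude
    sqrt(fe^2 + rud^2).  Circumduction is exempt and passes through with a
    notice.  The cut is inclusive of the extremal sample.
    """
    motion = motion or profile.motion
    if motion == "circumduction":
        warnings.warn("circumduction profiles are not truncated", stacklevel=2)
        return profile
    if motion in _FE_MOTIONS:
        score = np.abs(profile.channel("fe_deg"))
    elif motion in _RUD_MOTIONS:
        score = np.abs(profile.channel("rud_deg"))
    elif motion in _DTM_MOTIONS:
        score = _combined_magnitude(profile)
    else:
        raise ValueError(f"unknown motion {motion!r}")
    end = int(np.argmax(score))
    return MeanMotionProfile(
        profile.motion, profile.data[: end + 1].copy(), profile.channels,
        profile.n_trials, fps=profile.fps, truncation_index=end,
    )


def extract_rom(profile: MeanMotionProfile, motion: str | None = None) -> dict[str, float]:
    """In-plane signed extremum and the out-of-plane angle at that sample.

    For flexion/extension the in-plane axis is FE and out-of-plane RUD; for
    RD/UD the reverse.  Sign conventions: flexion(+)/extension(-),
    ulnar(+)/radial(-), so extension and RD report negative maxima.
    """
    motion = motion or profile.motion
    if motion in _FE_MOTIONS:
        axis, other = "fe_deg", "rud_deg"
    elif motion in _RUD_MOTIONS:
        axis, other = "rud_deg", "fe_deg"
    else:
        raise ValueError(f"ROM extraction applies to planar motions, not {motion!r}")
    vals = profile.channel(axis)
    k = int(np.argmax(np.abs(vals)))
    return {
        "in_plane_max_deg": float(vals[k]),
        "out_of_plane_at_max_deg": float(profile.channel(other)[k]),
    }


# ---------------------------------------------------------------------------
# dart thrower's motion


@dataclass
class DTMFit:
    """Linear fit of a dart thrower's plane in the RUD-FE plot."""

    slope: float                  # d(FE)/d(RUD)
    intercept: float              # deg
    r_squared: float
    plane_angle_deg: float        # from the sagittal (pure-FE) axis
    fit_rmse_deg: float           # RMS of FE residuals
    excluded: bool                # True iff r_squared < 0.7


def fit_dtm_plane(profile: MeanMotionProfile) -> DTMFit:
    """Regress FE on RUD and report the plane angle from the sagittal axis.

    Ordinary least squares of FE (y) on RUD (x); the plane angle is the
    acute angle of the regression line from the pure-FE direction,
    arctan(|dRUD/dFE|) = arctan(1/|slope|).  Fits with R^2 < 0.7 are
    flagged ``excluded``.  A degenerate (vertical in FE) scatter falls back
    to the swapped regression, which is equivalent for the plane angle.
    """
    fe = profile.channel("fe_deg")
    rud = profile.channel("rud_deg")
    if len(fe) < 10:
        raise ValueError("DTM regression needs >= 10 samples")
    if np.ptp(fe) < 1e-12:
        raise ValueError("FE variance is zero; no dart thrower's plane to fit")
    if np.ptp(rud) < 1e-12:
        # pure-FE path: plane angle 0 from the sagittal axis, perfect fit
        return DTMFit(np.inf, 0.0, 1.0, 0.0, 0.0, False)
    res = stats.linregress(rud, fe)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    pred = slope * rud + intercept
    rmse = float(np.sqrt(np.mean((fe - pred) ** 2)))
    if abs(slope) < 1e-12:
        angle = 90.0
    else:
        angle = float(np.degrees(np.arctan(1.0 / abs(slope))))
    return DTMFit(slope, intercept, r2, angle, rmse, r2 < R2_EXCLUSION_THRESHOLD)


# ---------------------------------------------------------------------------
# circumduction


def join_circumduction(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    tol_deg: float = 2.0,
) -> np.ndarray:
    """Join the two circumduction half-profiles into one closed envelope.

    ``profile_a`` runs extension -> UD -> flexion and ``profile_b``
    flexion -> RD -> extension, as (n, 2) arrays of (rud, fe) deg.  The
    duplicate junction sample is dropped.  A junction gap larger than
    ``tol_deg`` raises with the measured gap.
    """
    a = np.atleast_2d(np.asarray(profile_a, dtype=float))
    b = np.atleast_2d(np.asarray(profile_b, dtype=float))
    gap = float(np.linalg.norm(a[-1] - b[0]))
    if gap > tol_deg:
        raise CircumductionPathError(
            f"junction gap {gap:.2f} deg exceeds tolerance {tol_deg:.2f} deg"
        )
    return np.vstack([a, b[1:]])


@dataclass
class EllipseFit:
    """Direct least-squares ellipse fit of a circumduction envelope."""

    center: tuple[float, float]    # (rud, fe) deg
    semi_major_deg: float          # a >= b
    semi_minor_deg: float
    orientation_deg: float         # acute angle of the major axis from the FE axis
    rmse_deg: float = np.nan       # over 100 rays from the ellipse center
    conic: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def area_deg2(self) -> float:
        return float(np.pi * self.semi_major_deg * self.semi_minor_deg)


def _fit_ellipse_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Halir-Flusser numerically stable direct ellipse fit.

    Returns conic coefficients (A, B, C, D, E, F) of
    A x^2 + B x y + C y^2 + D x + E y + F = 0 with 4AC - B^2 > 0 guaranteed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    D1 = np.column_stack([x**2, x * y, y**2])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    a1 = eigvec[:, np.flatnonzero(cond > 0)[0]]
    return np.concatenate([a1, T @ a1])


def _conic_to_geometry(c: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray]:
    if c[0] < 0:  # overall conic sign is arbitrary; fix A > 0
        c = -c
    A, B, C, D, E, F = c
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    center = np.linalg.solve(2.0 * M, -np.array([D, E]))
    # constant after translating to the center
    Fc = F + 0.5 * (D * center[0] + E * center[1])
    if Fc >= 0:
        raise CircumductionPathError("conic fit is not a real ellipse")
    Mn = M / (-Fc)  # x^T Mn x = 1 about the center
    w, V = np.linalg.eigh(Mn)
    if np.any(w <= 0):
        raise CircumductionPathError("conic fit is not an ellipse")
    axes = 1.0 / np.sqrt(w)          # descending axis = smallest eigenvalue
    order = np.argsort(axes)[::-1]   # major first
    return center, float(axes[order[0]]), float(axes[order[1]]), V[:, order]


def _envelope_radius_interp(path: np.ndarray, center: np.ndarray,
                            phis: np.ndarray) -> np.ndarray:
    rel = path - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    rad = np.linalg.norm(rel, axis=1)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    # wrap for periodic interpolation
    ang_ext = np.concatenate([ang - 2 * np.pi, ang, ang + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad, rad])
    return np.interp(phis, ang_ext, rad_ext)


def fit_circumduction_ellipse(envelope: np.ndarray, n_rays: int = 100) -> EllipseFit:
    """Fit an ellipse to a closed circumduction envelope.

    ``envelope`` is the joined closed path as an (n, 2) array of (rud, fe)
    deg.  The constrained algebraic (direct least-squares) conic fit cannot
    return a hyperbola.  The fit RMSE compares the magnitudes of ``n_rays``
    vectors from the ellipse center to the ellipse against the corresponding
    vectors to the envelope (radius linearly interpolated in polar angle).
    Orientation is the acute angle of the major axis from the FE (sagittal)
    axis; area is pi * a * b.
    """
    path = np.atleast_2d(np.asarray(envelope, dtype=float))
    if len(path) < 20:
        raise CircumductionPathError("envelope needs >= 20 samples")
    centroid = path.mean(axis=0)
    rel = path - centroid
    ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    span = np.degrees(np.abs(ang.max() - ang.min()))
    if span < 350.0:
        raise CircumductionPathError(
            f"envelope spans only {span:.0f} deg of polar angle; not a closed loop"
        )
    conic = _fit_ellipse_conic(path[:, 0], path[:, 1])
    if conic[0] < 0:
        conic = -conic
    center, a, b, V = _conic_to_geometry(conic)
    major = V[:, 0]
    # acute angle from the FE axis (the plot's y direction)
    orientation = float(np.degrees(np.arccos(min(1.0, abs(major[1])))))
    phis = np.linspace(-np.pi, np.pi, n_rays, endpoint=False)
    u = np.column_stack([np.cos(phis), np.sin(phis)])
    Mn = np.array(
        [[conic[0], conic[1] / 2.0], [conic[1] / 2.0, conic[2]]]
    )
    Fc = conic[5] + 0.5 * (conic[3] * center[0] + conic[4] * center[1])
    Mn = Mn / (-Fc)
    r_ell = 1.0 / np.sqrt(np.einsum("ni,ij,nj->n", u, Mn, u))
    r_env = _envelope_radius_interp(path, center, phis)
    rmse = float(np.sqrt(np.mean((r_ell - r_env) ** 2)))
    return EllipseFit(
        center=(float(center[0]), float(center[1])),
        semi_major_deg=a,
        semi_minor_deg=b,
        orientation_deg=orientation,
        rmse_deg=rmse,
        conic=conic,
    )


# ---------------------------------------------------------------------------
# repeatability


@dataclass
class ChannelRMSE:
    channel: str
    value: float


@dataclass
class InterTrialResult:
    """Per-specimen inter-trial RMSEs and the across-specimen summary."""

    per_specimen_worst: list[ChannelRMSE]       # worst trial x channel, per specimen
    per_trial_rmse: list[np.ndarray]            # per specimen: (n_trials, n_channels)
    channels: tuple[str, ...]
    mean: float                                  # of the worst values, across specimens
    sd: float


def _trial_rmse_matrix(trials: list[np.ndarray]) -> np.ndarray:
    arrs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    n = min(len(a) for a in arrs)
    stack = np.stack([a[:n] for a in arrs])          # (trials, n, ch)
    # deviations computed relative to the first trial: algebraically the same
    # as subtracting the mean profile, but exactly zero for identical trials
    rel = stack - stack[0:1]
    dev = rel - rel.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(dev**2, axis=1))          # (trials, ch)


def inter_trial_rmse(
    specimens: list[list[np.ndarray]],
    channels: tuple[str, ...],
) -> InterTrialResult:
    """Inter-trial repeatability across specimens.

    For each specimen, trials are truncated to the shortest, the specimen
    mean profile computed, and the RMSE of every trial against that mean
    taken per channel.  The reported specimen value is the maximum over
    trials and channels (the channel "with the maximum error"); the summary
    is the mean +- sd of those worst values across specimens.
    """
    worst: list[ChannelRMSE] = []
    per_trial: list[np.ndarray] = []
    for trials in specimens:
        if len(trials) < 2:
            raise ValueError("inter-trial RMSE needs >= 2 trials per specimen")
        rmse = _trial_rmse_matrix(trials)
        per_trial.append(rmse)
        worst_per_channel = rmse.max(axis=0)
        j = int(np.argmax(worst_per_channel))
        worst.append(ChannelRMSE(channels[j], float(worst_per_channel[j])))
    vals = np.array([w.value for w in worst])
    return InterTrialResult(
        per_specimen_worst=worst,
        per_trial_rmse=per_trial,
        channels=tuple(channels),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )


@dataclass
class InterSpecimenResult:
    per_specimen_rmse: np.ndarray   # (n_specimens, n_channels)
    channels: tuple[str, ...]
    worst_channel: str
    mean: float                     # mean +- sd over specimens, worst channel
    sd: float
    n_points: int


def resample_profile(profile: np.ndarray, n_points: int) -> np.ndarray:
    """Linear resampling over normalized time [0, 1] to ``n_points`` samples."""
    arr = np.atleast_2d(np.asarray(profile, dtype=float))
    t_old = np.linspace(0.0, 1.0, len(arr))
    t_new = np.linspace(0.0, 1.0, n_points)
    return np.column_stack([np.interp(t_new, t_old, arr[:, j])
                            for j in range(arr.shape[1])])


def inter_specimen_rmse(
    specimen_profiles: list[np.ndarray],
    motion: str,
    channels: tuple[str, ...],
) -> InterSpecimenResult:
    """Inter-specimen repeatability of specimen mean profiles.

    Each specimen mean is linearly resampled over normalized time to 100
    points (200 for circumduction), an overall mean computed, and the RMSE
    of each specimen against the overall mean taken per channel.  Reported
    is the mean +- sd over specimens of the channel with the largest mean
    error.
    """
    if len(specimen_profiles) < 2:
        raise ValueError("inter-specimen RMSE needs >= 2 specimens")
    n_points = (
        INTERP_POINTS_CIRCUMDUCTION if motion == "circumduction" else INTERP_POINTS
    )
    resampled = np.stack(
        [resample_profile(p, n_points) for p in specimen_profiles]
    )  # (spec, n_points, ch)
    rel = resampled - resampled[0:1]  # exact zeros for identical specimens
    dev = rel - rel.mean(axis=0, keepdims=True)
    rmse = np.sqrt(np.mean(dev**2, axis=1))  # (spec, ch)
    j = int(np.argmax(rmse.mean(axis=0)))
    vals = rmse[:, j]
    return InterSpecimenResult(
        per_specimen_rmse=rmse,
        channels=tuple(channels),
        worst_channel=channels[j],
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_points=n_points,
    )
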