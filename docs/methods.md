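# Methods

This note records the models, conventions, numerical choices and known
limitations behind `wristsim`.

## Frames and angle conventions

The lab frame is right-handed: x points distally along the forearm axis, y
along the radioulnar direction (positive toward the sigmoid-notch / ulnar
side), z = x × y (dorsal). Wrist angles follow the radial-coordinate-system
convention — rotation about x is pronation(+)/supination(−), about y
flexion(+)/extension(−), about z ulnar(+)/radial(−) deviation — and are
decomposed with the intrinsic Cardan sequence y → z → x (flexion, deviation,
pronation), i.e. `R = Ry(fe) · Rz(rud) · Rx(prosup)`. The sequence is a
package choice: the axis labels fix only the axes, not the order, and the
flexion-first order mirrors the usual ISB-style recommendation mapped onto
these labels. Recomposition is exact away from gimbal lock; a warning fires
within 1° of |deviation| = 90°, and all generated paths stay well inside
±90°.

The anatomical radial system (RCS) takes x along the distal radial shaft,
origin at the shaft–articular-surface intersection, y through the sigmoid
notch center; the third-metacarpal system (MCS) takes x along the MCIII
diaphysis and y along the principal direction of the MCII/MCIII/MCIV
centroids, signed toward MCII. Neutral is defined as alignment of the two
systems. With that definition, the MCS y sign rule and the RCS notch rule
must point to the same side of the lab at neutral; the synthetic landmark
set is constructed accordingly (notch center and MCII centroid both on +y).
This is a sign-convention choice, not an anatomical claim; real-data users
supply their own landmark files and can flip the MCS rule if their atlas
differs. Wrist angle per frame is the decomposition of
`(R_radius·R_RCS)ᵀ (R_mc·R_MCS)`; a rigid motion applied to the whole arm
cancels exactly.

Right arms are handled by mirroring: marker data is reflected about the lab
sagittal (xz) plane — the radioulnar coordinate negated — before analysis,
so a single sign convention serves both sides. The right-arm wrist model is
likewise the y-mirror of the left, with the actuator axis map swapped to the
right-arm mounting (ECRL/ECU and FCR/FCU exchange axes; ECRB keeps axis 2).

## The virtual wrist

The specimen stand-in is a two-rod linkage joined by a universal joint at
the origin: a fixed proximal (forearm) rod and a distal (hand) rod that
rotates about the joint center. It deliberately reproduces the physical
model wrist used to record actuator profiles, not wrist anatomy. Tendons are
straight lines from fixed proximal exit points (mimicking the epicondyle
exits) to insertions at the base of the distal rod; no wrapping surfaces are
modelled, because moment-arm realism is a non-goal — the rig routes its
lines directly. Because the joint is universal, the equilibrium solver frees
only flexion and deviation; pronation is locked at zero (configurable).

Default geometry (all config-exposed; the rig's true dimensions are not
published, so these are one-time realistic choices): proximal rod 250 mm,
distal rod 80 mm, insertions 15 mm from the rod axis at 15 mm distal of the
joint, exit points at 30 mm radius, 180 mm proximal. Cross-section
directions put flexors volar (−z) and extensors dorsal (+z), ulnar tendons
at +y. The flexor volar depth is solved at build time so that the five
neutral-pose moment arms sum to zero about both free axes ("balanced
routing"): equal tendon forces then produce zero net joint torque at
neutral, which is what makes a 2 N equalization settle at the neutral pose —
the analogue of the symmetric Kevlar routing on the physical rig.

Motion paths: planar motions ramp from neutral to the signed amplitude and
back with a `sin²` profile normalized so the peak lands exactly on a sample.
Dart thrower's paths satisfy `rud = fe · tan(plane_angle)` exactly.
Circumduction traces a full ellipse in the RUD–FE plane, starting and ending
at the extension configuration, optionally tilted; it is exported as two
half-profiles (extension→UD→flexion, flexion→RD→extension) and rejoined in
analysis, reproducing the profile-length split-and-join workflow. An
optional coupling coefficient adds a proportional out-of-plane component to
planar motions, emulating the coupled motion real wrists show (e.g. ulnar
drift during flexion); it defaults to zero in the API and to the observed
out-of-plane/in-plane ratios in the pipeline defaults.

Excursion profiles are `rest_length − length(pose)` per tendon (positive =
actuator reels in), mapped to actuator axes. Profiles for neutral-starting
motions begin at 0 mm by construction; circumduction legitimately starts at
its extension displacement, and tracking jogs the actuators there gradually
before the first frame. Excursions beyond the 80 mm actuator travel raise an
error.

## Control twin

The control loops are represented by their converged contracts (no PID
gains, encoder quantization or motor dynamics), and the wrist is
quasi-static: at each frame the pose minimizes

E(q) = Σᵢ ½ kᵢ sᵢ(q)² + ½ c‖q‖²,

where sᵢ = max(0, stretch) is the unilateral series-spring stretch of tendon
i (sutures cannot push; slack ⇒ zero force), kᵢ the spring stiffness
(default 25 N/mm, config-exposed — the recording springs' stiffness is not
published), and c a small passive joint stiffness (default 0.01 N·mm/deg²)
that keeps a fully slack wrist determinate. Forces are Fᵢ = kᵢ sᵢ. The
minimization is a damped Newton iteration on the free axes with a
finite-difference Hessian of the analytic gradient, backtracking line search
(energy decreases monotonically), and a full-Newton fallback once the
predicted decrease falls below floating noise; the gradient norm at the
solution is below 10⁻⁸ N·mm/deg or an error is raised.

Force equalization solves the settled state of the feedback loop directly:
the pose where uniform target forces balance the passive stiffness, with
every actuator holding exactly the target stretch there. Encoders are
zeroed and tendon lengths re-referenced at that pose, and the fixed point is
verified by re-settling (forces within the tolerance, default 0.01 N, or a
convergence error with residuals). Tracking replays a displacement profile
frame by frame with the previous pose as warm start; logged forces must be
non-negative and under the 150 N load-cell capacity, and per-tendon
physiological caps (PCSA × 32 N/cm²) are enforced inclusively in `flag` or
`clamp` mode — never silently.

Round-trip fidelity (record excursions → track → recover angles) is ~0.3°
at the default stiffness. The residual comes from force redistribution away
from the uniform 2 N state at non-neutral poses; it shrinks as the spring
stiffness grows.

## Reconstruction chain

Cameras are ideal pinholes expressed as 11-coefficient direct linear
transforms; the default rig places two orthogonal views at 45° to the
forearm axis with a 110 cm source-to-image distance, 1024² px images and
2.56 px/mm at the detector. Image-intensifier undistortion is not modelled
(the synthetic cameras are ideal); the camera model keeps an `undistort`
hook so externally corrected points can be fed through the same path.
Calibration solves the DLT by linear least squares from the 64-bead cube
with Hartley-style coordinate normalization (coplanar or <6 points raise);
triangulation intersects the two view rays linearly and reports the RMS
reprojection residual; near-parallel rays warn.

Beads are grouped per bone (persistent IDs; tracking itself is out of
scope) and fitted to their CT-frame reference triad by orthogonal Procrustes
(SVD with the reflection excluded via a sign correction on the smallest
singular vector). A bone-frame with a missing bead is fitted from the
remaining beads when at least three are visible, otherwise left as an
explicit NaN gap — never interpolated.

Pose series are smoothed with a zero-phase (forward–backward) second-order
Butterworth filter at 2 Hz, applied to translations and hemisphere-aligned
quaternion components with even-reflection padding and renormalization.
Filtering in quaternion space avoids wrap and gimbal artifacts that
per-Euler-angle filtering can introduce; applying the filter to the pose
series (rather than to marker trajectories) is a documented choice, as the
exact smoothing target in the reference workflow is unspecified. The trial
durations in the synthetic protocol (4 s planar, 12 s circumduction) keep
the motion fundamental far below the 2 Hz cut-off, so smoothing attenuates
the signal by well under 0.1°.

## Analysis

Per motion: the five trials are truncated to the shortest, averaged per
sample, and (except circumduction) further truncated to end at the maximum
joint rotation — |FE| for flexion/extension, |RUD| for the deviations, and
√(FE² + RUD²) for the dart thrower's motions. In-plane ROM is the signed
extremum on the motion's axis; out-of-plane is the other axis read at that
same sample. Raw angles are corrected by the per-motion static trial in
rotation space, `R_corrected = R_staticᵀ R_raw` (exact for large offsets,
equal to subtraction for small ones, idempotent); a missing static trial is
an error, never a silent zero.

The dart thrower's plane is an ordinary least-squares regression of FE (y)
on RUD (x); the plane angle is the acute angle of the fitted line from the
pure-FE (sagittal) direction, arctan(1/|slope|); fits with R² < 0.7 are
flagged excluded. The circumduction envelope (two halves joined, duplicate
junction sample dropped, junction gaps over 2° diagnosed) is fitted with the
numerically stable direct least-squares conic fit constrained to an ellipse
(a hyperbola is impossible by construction); area is πab, orientation the
acute angle of the major axis from the FE axis, and the fit RMSE compares
100 equally spaced rays from the ellipse center against the envelope radius
interpolated linearly in polar angle about that same center (the ellipse
center is the only origin the fit defines).

Repeatability: inter-trial RMSE computes, per specimen and channel, the RMSE
of each trial against the specimen mean (trials truncated to the shortest);
the reported specimen value is the maximum over trials and channels, and the
summary is mean ± sd of those worst values across specimens. The result
object also exposes the full per-trial, per-channel matrix, whose mean is
the quantity sampling theory predicts (σ·√((n−1)/n) under iid noise) — the
max-based table statistic is biased upward of that by order statistics, so
validation uses the mean. Inter-specimen RMSE resamples each specimen mean
linearly over normalized time to exactly 100 points (200 for circumduction),
forms the overall mean, and reports mean ± sd over specimens of the channel
with the largest average error. Deviations are computed relative to the
first profile so identical inputs give exactly zero.

## Synthetic study conditions

The pipeline defaults emulate the pilot-study protocol: 6 specimens, 7
motions, 5 trials per motion plus a per-motion static trial, 2 N pre-load,
50 fps (30 fps circumduction), trial lengths 200 frames (360 for
circumduction) with small per-trial length jitter to exercise the
truncate-to-shortest rule. Commanded amplitudes are the observed
anatomical-wrist means (flexion 50.5°, extension 57.2°, RD 20.9°, UD 29.2°),
dart thrower's planes RE 20.4° / UF 26.2°, circumduction ellipse ~2608 deg²
with a 4.2° tilt; per-specimen variation draws amplitudes, plane angles,
ellipse axes, mounting offsets (base [1, 2, −1.5]°, sd 2°) and a ±5%
insertion-geometry scale from the seeded generator, emulating anatomical
variation and per-specimen profile scaling.

Noise levels are one-time choices placed in the repeatability regime such
studies report (sub-degree angle and sub-2 N force inter-trial RMSE): bead
centroid noise σ = 0.05 mm, smooth per-trial angle jitter 0.5° (low-order
sinusoids vanishing at the trial ends), force observation noise 0.4 N and
displacement observation noise 0.05 mm (band-limited). Trial-to-trial
force/displacement variability is injected at the observation level rather
than by re-solving the deterministic quasi-static rig per trial, which would
reproduce identical trials; angle variability, by contrast, flows physically
through jittered paths, noisy beads, triangulation and Procrustes.

What the generator does not emulate: soft-tissue mechanics (friction,
viscoelasticity), muscle physiology, carpal-row internal kinematics,
non-elliptical circumduction envelope depressions, bead detection/tracking
failures, and image distortion. Passing tests therefore validate the
measurement and analysis chain against known ground truth — not the
biological fidelity of the motion itself.

All randomness in a run flows from the single config seed; identical config
and seed reproduce byte-identical output files and manifest hashes.

## Problem sizes and runtime

The default full study (6 specimens × 7 motions × 5 trials) simulates,
reconstructs and analyzes in about a minute on one CPU; the test suite uses
reduced sizes (1–2 specimens, 100–240 frames) chosen so each end-to-end
check runs in seconds while leaving the statistical assertions comfortable
margins (e.g. 100-seed Monte-Carlo loops for calibration and Procrustes
accuracy, 200 replicates for the repeatability sampling-theory check).

## Known limitations

- The quasi-static, inertia-free rig model makes tendon-force magnitudes
  indicative only; they are meaningful for within-model comparisons.
- The Cardan sequence and the MCS y-sign are conventions; users comparing
  against other software should verify both.
- Ellipse fitting uses the constrained algebraic (not geometric) least
  squares; for the low-noise envelopes here the difference is negligible,
  but heavily distorted envelopes would bias the algebraic fit first.
- The equalized pose is the torque-balance point of the balanced routing; a
  deliberately unbalanced custom geometry will equalize slightly away from
  neutral, and the round-trip error grows accordingly.
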