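"""Digital twin of the motion simulator's control loops.

Three control features are modelled by their converged behaviour: (1) force
equalization across the five tendons to a user target (2 N by default)
before each motion, which also zeroes the encoders; (2) closed-loop actuator
displacement tracking of a 50 Hz profile; (3) per-tendon physiological force
caps (PCSA x 32 N/cm^2).  The wrist itself is quasi-static: at each frame
the pose minimizes the elastic energy of the five unilateral series springs
plus a small passive joint stiffness that keeps a slack wrist determinate.

Units: mm, degrees, N; energies in N*mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .wrist import ACTUATOR_TRAVEL_MM, ActuatorTravelError, JointAngles, WristModel

LOAD_CELL_CAPACITY_N = 150.0

#: physiological maxima per tendon (N), PCSA x specific tension 32 N/cm^2
DEFAULT_FORCE_CAPS = {"ECRL": 80.0, "ECRB": 86.0, "ECU": 74.0, "FCR": 125.0, "FCU": 211.0}
SPECIFIC_TENSION_N_PER_CM2 = 32.0


class ConvergenceError(RuntimeError):
    """A control loop or equilibrium solve failed to converge."""

    def __init__(self, message: str, residual=None, last_iterate=None):
        super().__init__(message)
        self.residual = residual
        self.last_iterate = last_iterate


@dataclass
class ForceCaps:
    """Maximum allowed force per tendon (inclusive bounds)."""

    caps: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FORCE_CAPS))

    def __post_init__(self) -> None:
        for name, cap in self.caps.items():
            if cap <= 0:
                raise ValueError(f"cap for {name} must be positive")

    @classmethod
    def from_pcsa(cls, pcsa_cm2: dict[str, float],
                  specific_tension: float = SPECIFIC_TENSION_N_PER_CM2) -> "ForceCaps":
        return cls({n: a * specific_tension for n, a in pcsa_cm2.items()})

    def as_array(self, names) -> np.ndarray:
        return np.array([self.caps[n] for n in names])


@dataclass
class Violation:
    frame: int
    tendon: str
    force_n: float
    cap_n: float

    @property
    def excess_n(self) -> float:
        return self.force_n - self.cap_n


def enforce_force_cap(
    forces: np.ndarray,
    caps: ForceCaps,
    tendon_names,
    mode: str = "flag",
) -> tuple[np.ndarray, list[Violation]]:
    """Check (and optionally clamp) tendon forces against their caps.

    ``forces`` is (n_frames, n_tendons).  Bounds are inclusive: a force
    exactly at its cap is not a violation.  ``flag`` returns the forces
    unchanged with the violation report; ``clamp`` limits each offending
    force to its cap and records the event -- never silently.
    """
    if mode not in ("flag", "clamp"):
        raise ValueError(f"mode must be 'flag' or 'clamp', got {mode!r}")
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    cap_arr = caps.as_array(tendon_names)
    violations = [
        Violation(int(i), tendon_names[j], float(forces[i, j]), float(cap_arr[j]))
        for i, j in zip(*np.nonzero(forces > cap_arr[None, :]))
    ]
    if mode == "clamp" and violations:
        forces = np.minimum(forces, cap_arr[None, :])
    return forces, violations


@dataclass
class MotionLog:
    """Synchronized 50 Hz log of tendon forces and actuator displacements."""

    time_s: np.ndarray
    forces_n: np.ndarray          # (n, 5), model tendon order
    displacements_mm: np.ndarray  # (n, 5), actuator axis order 1..5
    tendon_names: tuple[str, ...]
    fps: float = 50.0
    violations: list[Violation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.time_s)


def _rotation_and_derivatives(prosup: float, fe: float, rud: float):
    """R = Ry(fe) Rz(rud) Rx(prosup) and dR/d(angle in deg) for each angle."""
    a, b, c = np.radians([fe, rud, prosup])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Ry = np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])
    Rz = np.array([[cb, -sb, 0], [sb, cb, 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    dRy = np.array([[-sa, 0, ca], [0, 0, 0], [-ca, 0, -sa]])
    dRz = np.array([[-sb, -cb, 0], [cb, -sb, 0], [0, 0, 0]])
    dRx = np.array([[0, 0, 0], [0, -sc, -cc], [0, cc, -sc]])
    R = Ry @ Rz @ Rx
    deg = np.pi / 180.0
    dR_dfe = dRy @ Rz @ Rx * deg
    dR_drud = Ry @ dRz @ Rx * deg
    dR_dpro = Ry @ Rz @ dRx * deg
    return R, (dR_dpro, dR_dfe, dR_drud)  # pose order (prosup, fe, rud)


class WristSimulator:
    """Quasi-static tendon-driven wrist with displacement control.

    Parameters
    ----------
    model:
        The wrist linkage with per-tendon spring stiffnesses (N/mm).
    joint_stiffness:
        Passive stiffness regularizer (N*mm/deg^2); keeps the pose
        determinate when tendons go slack.  Small by construction.
    caps:
        Physiological force caps enforced during tracking.
    """

    def __init__(
        self,
        model: WristModel,
        joint_stiffness: float = 0.01,
        caps: ForceCaps | None = None,
        grad_tol: float = 1e-8,
        free_axes: tuple[int, ...] = (1, 2),
    ):
        self.model = model
        self.joint_stiffness = float(joint_stiffness)
        # the model wrist is a universal joint: flexion (1) and deviation (2)
        # are free; pronation (0) is locked unless explicitly freed
        self.free_axes = tuple(free_axes)
        self.caps = caps or ForceCaps()
        self.grad_tol = float(grad_tol)
        self._ins = np.array(
            [t.insertion_point - model.joint_center for t in model.tendons]
        )
        self._org = np.array([t.origin_point for t in model.tendons])
        self._k = np.array([t.stiffness for t in model.tendons])
        self._l0 = np.array([t.rest_length for t in model.tendons])
        # spring stretch at neutral with actuators at encoder zero (mm);
        # set by equalize(); zero means fully slack tendons
        self.stretch0 = np.zeros(len(model.tendons))
        self.encoder_zero = np.zeros(len(model.tendons))

    # -- geometry ---------------------------------------------------------
    def _lengths_and_grads(self, pose: np.ndarray):
        R, dRs = _rotation_and_derivatives(*pose)
        jc = self.model.joint_center
        world = jc + self._ins @ R.T
        diff = world - self._org
        lengths = np.linalg.norm(diff, axis=1)
        unit = diff / lengths[:, None]
        grads = np.stack(
            [np.einsum("ti,ij,tj->t", unit, dR, self._ins) for dR in dRs], axis=1
        )  # (5, 3) dl/d(pose_deg)
        return lengths, grads

    def lengths(self, pose: np.ndarray) -> np.ndarray:
        return self._lengths_and_grads(np.asarray(pose, dtype=float))[0]

    def _stretch(self, lengths: np.ndarray, d_axes: np.ndarray) -> np.ndarray:
        d_tendon = self._axes_to_tendon(d_axes)
        return self.stretch0 + d_tendon - (self._l0 - lengths)

    def _axes_to_tendon(self, d_axes: np.ndarray) -> np.ndarray:
        idx = [self.model.axis_map[t.name] - 1 for t in self.model.tendons]
        return np.asarray(d_axes, dtype=float)[idx]

    # -- energy -----------------------------------------------------------
    def energy(self, pose: np.ndarray, d_axes: np.ndarray) -> float:
        lengths = self.lengths(pose)
        s = np.maximum(self._stretch(lengths, d_axes), 0.0)
        elastic = 0.5 * np.sum(self._k * s**2)
        passive = 0.5 * self.joint_stiffness * np.sum(np.asarray(pose) ** 2)
        return float(elastic + passive)

    def _energy_grad(self, pose: np.ndarray, d_axes: np.ndarray):
        lengths, grads = self._lengths_and_grads(pose)
        s = self._stretch(lengths, d_axes)
        active = s > 0
        F = np.where(active, self._k * s, 0.0)
        E = 0.5 * np.sum(self._k * np.maximum(s, 0.0) ** 2) + \
            0.5 * self.joint_stiffness * np.sum(pose**2)
        g = F @ grads + self.joint_stiffness * pose
        return float(E), g, F

    def solve_equilibrium_pose(
        self,
        d_axes: np.ndarray,
        initial_pose: np.ndarray | None = None,
        max_iter: int = 100,
        energy_history: list | None = None,
    ) -> tuple[JointAngles, dict[str, float]]:
        """Pose minimizing the elastic energy at given actuator displacements.

        Damped-Newton descent with backtracking line search (energy decreases
        monotonically across iterations); the gradient norm at the solution
        is below ``grad_tol`` (N*mm/deg).  Returns a one-frame JointAngles
        and the per-tendon forces (N).
        """
        d_axes = np.asarray(d_axes, dtype=float)
        if np.any(np.abs(d_axes) > ACTUATOR_TRAVEL_MM):
            raise ActuatorTravelError("displacement outside the 80 mm actuator travel")
        q = np.zeros(3) if initial_pose is None else np.asarray(initial_pose, float).copy()
        free = list(self.free_axes)
        nf = len(free)

        def eval_at(qv):
            E, g, F = self._energy_grad(qv, d_axes)
            return E, g[free], F

        E, g, _ = eval_at(q)
        if energy_history is not None:
            energy_history.append(E)
        h = 1e-4  # deg, finite-difference step for the Hessian of the gradient
        for _ in range(max_iter):
            if np.linalg.norm(g) < self.grad_tol:
                break
            H = np.empty((nf, nf))
            for col, j in enumerate(free):
                qp = q.copy()
                qp[j] += h
                _, gp, _ = eval_at(qp)
                H[:, col] = (gp - g) / h
            H = 0.5 * (H + H.T)
            try:
                w = np.linalg.eigvalsh(H)
                if w[0] <= 1e-12:
                    H = H + (1e-8 + abs(w[0])) * np.eye(nf)
                step_f = -np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step_f = -g
            step = np.zeros(3)
            step[free] = step_f
            predicted = -np.dot(g, step_f)
            if predicted < 1e-12 * (1.0 + abs(E)):
                # decrease below floating noise: trust the Newton step
                q = np.clip(q + step, -89.0, 89.0)
                E, g, _ = eval_at(q)
                if energy_history is not None:
                    energy_history.append(E)
                continue
            alpha = 1.0
            for _ in range(40):
                trial = np.clip(q + alpha * step, -89.0, 89.0)
                E_new, g_new, _ = eval_at(trial)
                if E_new <= E + 1e-4 * alpha * np.dot(g, step_f) or E_new < E + 1e-15:
                    break
                alpha *= 0.5
            else:
                raise ConvergenceError(
                    "line search failed in equilibrium solve",
                    residual=float(np.linalg.norm(g)), last_iterate=q,
                )
            q = trial
            E, g = E_new, g_new
            if energy_history is not None:
                energy_history.append(E)
            if alpha * np.linalg.norm(step_f) < 1e-13:
                break  # stagnated at numerical precision
        if np.linalg.norm(g) >= self.grad_tol:
            raise ConvergenceError(
                f"equilibrium gradient {np.linalg.norm(g):.2e} N*mm/deg "
                f"did not reach {self.grad_tol:.0e}",
                residual=float(np.linalg.norm(g)), last_iterate=q,
            )
        _, _, F = self._energy_grad(q, d_axes)
        forces = {t.name: float(f) for t, f in zip(self.model.tendons, F)}
        return JointAngles(q[0:1], q[1:2], q[2:3]), forces

    # -- control features -------------------------------------------------
    def set_initial_forces(self, forces_n) -> None:
        """Set the neutral pretension of each tendon (N), e.g. before equalizing."""
        arr = (
            np.array([forces_n[t.name] for t in self.model.tendons], dtype=float)
            if isinstance(forces_n, dict)
            else np.asarray(forces_n, dtype=float)
        )
        if np.any(arr < 0):
            raise ValueError("tendon forces cannot be negative")
        self.stretch0 = arr / self._k

    def equalize_forces(
        self,
        target_n: float = 2.0,
        tol_n: float = 0.01,
        max_iter: int = 100,
    ) -> tuple[JointAngles, dict[str, float]]:
        """Equalize all tendon forces to the target and zero the encoders.

        Feedback loop: settle the wrist, measure forces, re-position each
        actuator by the force error over its spring stiffness, repeat until
        every force is within ``tol_n`` of the target.  On convergence the
        actuator positions become the encoder zeros and the settled pose is
        the reference for subsequent profiles.
        """
        if target_n < 0:
            raise ValueError("target force must be non-negative")
        # converged contract of the force-feedback loop: the wrist settles at
        # the pose where uniform target forces balance (plus the passive
        # stiffness), and each actuator holds exactly the target stretch there
        pose = self._uniform_force_pose(target_n, max_iter=max_iter)
        lengths = self.lengths(pose)
        self.stretch0 = np.full(5, target_n) / self._k
        self._l0 = lengths
        self.encoder_zero = np.zeros(5)
        # verify the fixed point: settling with zeroed encoders must return
        # the same pose and forces within tolerance
        sol, forces = self.solve_equilibrium_pose(np.zeros(5), initial_pose=pose)
        err = {
            t.name: float(target_n - forces[t.name]) for t in self.model.tendons
        }
        if max(abs(e) for e in err.values()) > tol_n:
            raise ConvergenceError(
                "force equalization did not converge", residual=err
            )
        return sol, forces

    def _uniform_force_pose(self, target_n: float, max_iter: int = 100) -> np.ndarray:
        """Pose where uniform tendon forces balance the passive stiffness."""
        free = list(self.free_axes)
        q = np.zeros(3)
        h = 1e-4

        def grad(qv: np.ndarray) -> np.ndarray:
            _, grads = self._lengths_and_grads(qv)
            return (target_n * grads.sum(axis=0) + self.joint_stiffness * qv)[free]

        g = grad(q)
        for _ in range(max_iter):
            if np.linalg.norm(g) < max(self.grad_tol, 1e-10):
                break
            H = np.empty((len(free), len(free)))
            for col, j in enumerate(free):
                qp = q.copy()
                qp[j] += h
                H[:, col] = (grad(qp) - g) / h
            step = np.zeros(3)
            try:
                step[free] = -np.linalg.solve(0.5 * (H + H.T), g)
            except np.linalg.LinAlgError:
                step[free] = -g
            if np.linalg.norm(step) > 20.0:
                step *= 20.0 / np.linalg.norm(step)
            q = np.clip(q + step, -89.0, 89.0)
            g = grad(q)
        return q

    def track_profile(
        self,
        profiles_mm: np.ndarray,
        fps: float = 50.0,
        cap_mode: str = "flag",
    ) -> tuple[MotionLog, JointAngles]:
        """Execute an actuator displacement profile frame by frame.

        ``profiles_mm`` is (n_frames, 5) in actuator-axis order, relative to
        the encoder zeros set by :meth:`equalize_forces`.  Each frame's
        equilibrium is solved with the previous frame as warm start.  Force
        caps are enforced per ``cap_mode``; no logged force may be negative
        or exceed the 150 N load-cell capacity.
        """
        profiles = np.atleast_2d(np.asarray(profiles_mm, dtype=float))
        if profiles.shape[1] != 5:
            raise ValueError("profiles must have 5 actuator columns")
        n = len(profiles)
        forces = np.empty((n, 5))
        angle_rows = np.empty((n, 3))
        pose = np.zeros(3)
        if np.linalg.norm(profiles[0]) > 0.5:
            # the profile starts away from neutral (circumduction starts at
            # its extension configuration): jog the actuators there gradually
            for frac in np.linspace(0.0, 1.0, 25)[1:]:
                sol, _ = self.solve_equilibrium_pose(frac * profiles[0],
                                                     initial_pose=pose)
                pose = sol.as_array()[0]
        for k in range(n):
            if np.any(np.abs(profiles[k]) > ACTUATOR_TRAVEL_MM):
                raise ActuatorTravelError(
                    f"frame {k}: displacement outside the 80 mm actuator travel"
                )
            sol, F = self.solve_equilibrium_pose(profiles[k], initial_pose=pose)
            pose = sol.as_array()[0]
            angle_rows[k] = pose
            forces[k] = [F[t.name] for t in self.model.tendons]
        if np.any(forces > LOAD_CELL_CAPACITY_N):
            raise ValueError("a tendon force exceeds the 150 N load-cell capacity")
        forces, violations = enforce_force_cap(
            forces, self.caps, self.model.tendon_names, mode=cap_mode
        )
        log = MotionLog(
            time_s=np.arange(n) / fps,
            forces_n=forces,
            displacements_mm=profiles.copy(),
            tendon_names=self.model.tendon_names,
            fps=fps,
            violations=violations,
        )
        angles = JointAngles(angle_rows[:, 0], angle_rows[:, 1], angle_rows[:, 2], fps=fps)
        return log, angles


def scale_profile(profile: np.ndarray, factor: float) -> np.ndarray:
    """Scale an actuator displacement profile to change motion magnitude."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return np.asarray(profile, dtype=float) * factor
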