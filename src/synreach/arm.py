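"""Rigid-body model of a 7-d.f. torque-controlled arm under gravity.

The arm mimics the kinematic layout of a human arm: three rotational joints
at the shoulder (flexion/extension, abduction/adduction, internal rotation),
two at the elbow (flexion, forearm pronation) and two at the wrist (flexion,
deviation).  Base frame: x forward, y lateral, z up, origin at the shoulder.

Zero configuration: the upper arm points 0.4 rad forward of straight down
(fixed shoulder mounting tilt) and the forearm is orthogonal to it (fixed
-pi/2 elbow mounting offset).  This centres the limit-bounded workspace on
the reaching volume: with a straight-arm zero, the elbow limits would make
the calibrated start position and several high targets unreachable.

Dynamics are computed by a world-frame recursive Newton-Euler algorithm
(inverse dynamics) and an RNEA-column mass matrix (forward dynamics),
integrated with semi-implicit Euler substeps.  All hot paths are numba
kernels in :mod:`synreach._dynamics`; an engine-backed implementation can be
swapped in by re-implementing the same array-level contract.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources

import numpy as np
import yaml

from . import _dynamics as dyn
from .errors import InvalidArgumentError, NoSolutionError, SimulationDivergedError

CONTROL_DT = 0.01  # s, the policy sampling interval

#: Cartesian start position of the fingertip for the original arm lengths.
Q_INITIAL_ORIGINAL = np.array([0.24, 0.0, 0.21])

_ORIGINAL_TOTAL_LENGTH = 0.36 + 0.27 + 0.10

# Table-style joint limits (rad), shoulder(3)/elbow(2)/wrist(2)
_LOWER = np.array([-1.57, -0.85, -0.85, -1.50, -1.50, -0.50, -1.05])
_UPPER = np.array([0.70, 1.57, 0.85, 1.05, 1.57, 0.50, 1.05])

_JOINT_AXIS_SPEC = (
    "shoulder_flexion:y",
    "shoulder_abduction:x",
    "shoulder_rotation:z",
    "elbow_flexion:y",
    "forearm_pronation:z",
    "wrist_flexion:y",
    "wrist_deviation:x",
)

_AXIS_VEC = {"x": (1.0, 0.0, 0.0), "y": (0.0, 1.0, 0.0), "z": (0.0, 0.0, 1.0)}

#: Fixed forward tilt (rad) of the shoulder mounting about the y axis.
SHOULDER_MOUNT_TILT = -0.4


@dataclasses.dataclass(frozen=True)
class ArmModel:
    """Kinematic and dynamic description of the 7-joint arm."""

    shoulder_to_elbow_length: float = 0.36
    elbow_to_wrist_length: float = 0.27
    wrist_to_fingertip_length: float = 0.10
    link_masses: tuple = (0.04, 0.024, 0.01)      # kg: upper arm, forearm, hand
    link_inertias: tuple | None = None            # kg m^2 transverse, about COM
    joint_lower_limits: tuple = tuple(_LOWER)
    joint_upper_limits: tuple = tuple(_UPPER)
    joint_axis_spec: tuple = _JOINT_AXIS_SPEC
    gravity: tuple = (0.0, 0.0, -9.81)
    torque_limit: float = 1.0                     # N m per joint
    joint_armature: float = 0.005                 # kg m^2 rotor inertia per joint
    joint_damping: float = 0.05                   # N m s/rad viscous joint damping
    integrator_substep: float = 0.002             # s
    name: str = "original"

    def __post_init__(self):
        lengths = (self.shoulder_to_elbow_length, self.elbow_to_wrist_length,
                   self.wrist_to_fingertip_length)
        if any(v <= 0 for v in lengths) or any(v <= 0 for v in self.link_masses):
            raise InvalidArgumentError("lengths and masses must be positive")
        lo = np.asarray(self.joint_lower_limits, dtype=float)
        hi = np.asarray(self.joint_upper_limits, dtype=float)
        if lo.shape != (7,) or hi.shape != (7,) or not np.all(lo < hi):
            raise InvalidArgumentError("need 7 joint limits with lower < upper")
        if len(self.joint_axis_spec) != 7:
            raise InvalidArgumentError("exactly 7 joints required")
        n_sub = CONTROL_DT / self.integrator_substep
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise InvalidArgumentError(
                "integrator_substep must divide the 10 ms control interval")
        if self.link_inertias is None:
            # slender-rod transverse inertia about each segment's COM
            inert = tuple(m * l * l / 12.0
                          for m, l in zip(self.link_masses, lengths))
            object.__setattr__(self, "link_inertias", inert)

    @property
    def total_length(self) -> float:
        return (self.shoulder_to_elbow_length + self.elbow_to_wrist_length
                + self.wrist_to_fingertip_length)

    @property
    def q_initial(self) -> np.ndarray:
        """Start position, scaled with total arm length from the original."""
        return Q_INITIAL_ORIGINAL * (self.total_length / _ORIGINAL_TOTAL_LENGTH)

    @property
    def n_substeps(self) -> int:
        return int(round(CONTROL_DT / self.integrator_substep))


@dataclasses.dataclass
class ArmState:
    """Joint angles (rad) and angular velocities (rad/s)."""

    joint_angles: np.ndarray
    joint_velocities: np.ndarray

    def __post_init__(self):
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        self.joint_velocities = np.asarray(self.joint_velocities, dtype=float)
        if self.joint_angles.shape != (7,) or self.joint_velocities.shape != (7,):
            raise InvalidArgumentError("state vectors must have length 7")
        if not (np.all(np.isfinite(self.joint_angles))
                and np.all(np.isfinite(self.joint_velocities))):
            raise InvalidArgumentError("state entries must be finite")


def _ry(angle):
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def chain_parameters(model: ArmModel):
    """Pack the model into the plain-array chain description of the kernels."""
    L1 = model.shoulder_to_elbow_length
    L2 = model.elbow_to_wrist_length
    L3 = model.wrist_to_fingertip_length
    m1, m2, m3 = model.link_masses
    I1, I2, I3 = model.link_inertias

    p = np.zeros((7, 3))
    p[3, 2] = -L1
    p[5, 2] = -L2
    E = np.stack([np.eye(3)] * 7)
    # zero-pose convention: upper arm tilted 0.4 rad forward of vertical,
    # forearm orthogonal to it.  The forward tilt centres the limit-bounded
    # workspace on the reaching volume (all four target planes reachable).
    E[0] = _ry(SHOULDER_MOUNT_TILT)
    E[3] = _ry(-math.pi / 2.0)  # forearm forward at zero elbow angle
    axis = np.array([_AXIS_VEC[s.split(":")[1]] for s in model.joint_axis_spec])
    m = np.zeros(7)
    com = np.zeros((7, 3))
    inert = np.zeros((7, 3, 3))
    # massive bodies ride the last joint frame of their segment
    for j, (mass, length, itr) in zip((2, 4, 6),
                                      ((m1, L1, I1), (m2, L2, I2), (m3, L3, I3))):
        m[j] = mass
        com[j, 2] = -length / 2.0
        axial = 0.5 * mass * 0.04 ** 2  # thin cylinder, 4 cm radius
        inert[j] = np.diag([itr, itr, axial])
    tip = np.array([0.0, 0.0, -L3])
    return p, E, axis, m, com, inert, tip


def _geom(model):
    p, E, axis, m, com, inert, tip = chain_parameters(model)
    return p, E, axis, tip


def _check_finite(name, arr):
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} contains non-finite entries")
    return arr


def forward_kinematics(model: ArmModel, joint_angles) -> np.ndarray:
    """Fingertip reference point in the base frame (m)."""
    q = _check_finite("joint_angles", joint_angles)
    p, E, axis, tip = _geom(model)
    return dyn.fingertip(q, p, E, axis, tip)


def jacobian(model: ArmModel, joint_angles) -> np.ndarray:
    """3x7 position Jacobian of the fingertip."""
    q = _check_finite("joint_angles", joint_angles)
    p, E, axis, tip = _geom(model)
    return dyn.tip_jacobian(q, p, E, axis, tip)


def fingertip_velocity(model: ArmModel, state: ArmState) -> np.ndarray:
    """Cartesian fingertip velocity, J(theta) theta_dot (m/s)."""
    return jacobian(model, state.joint_angles) @ state.joint_velocities


def inverse_dynamics(model: ArmModel, joint_angles, joint_velocities,
                     joint_accelerations) -> np.ndarray:
    """Torques producing the given accelerations, gravity included (N m)."""
    q = _check_finite("joint_angles", joint_angles)
    qd = _check_finite("joint_velocities", joint_velocities)
    qdd = _check_finite("joint_accelerations", joint_accelerations)
    p, E, axis, m, com, inert, tip = chain_parameters(model)
    return dyn.rnea(q, qd, qdd, p, E, axis, m, com, inert,
                    np.asarray(model.gravity, dtype=float),
                    model.joint_armature, model.joint_damping)


def forward_accelerations(model: ArmModel, state: ArmState, torque) -> np.ndarray:
    """Joint accelerations under the given torque (the inverse of RNEA)."""
    tau = _check_finite("torque", torque)
    p, E, axis, m, com, inert, tip = chain_parameters(model)
    free = np.ones(7, dtype=np.int64)
    return dyn._fused_forward_dynamics(
        state.joint_angles, state.joint_velocities, tau, p, E, axis, m, com,
        inert, np.asarray(model.gravity, dtype=float), model.joint_armature,
        model.joint_damping, free)


def step(model: ArmModel, state: ArmState, torque, locked_joints=None) -> ArmState:
    """Advance the dynamics one 10 ms control interval.

    Torques are clamped to ``+-torque_limit`` before integration; joint limits
    are enforced after every substep.  ``locked_joints`` (optional bool mask)
    holds the marked joints rigid via the reduced dynamics, which is useful
    for single-joint validation experiments.
    """
    tau = _check_finite("torque", torque)
    if tau.shape != (7,):
        raise InvalidArgumentError("torque must have length 7")
    p, E, axis, m, com, inert, tip = chain_parameters(model)
    free = np.ones(7, dtype=np.int64)
    if locked_joints is not None:
        free = (~np.asarray(locked_joints, dtype=bool)).astype(np.int64)
    q, qd, ok = dyn.control_step(
        state.joint_angles, state.joint_velocities, tau,
        p, E, axis, m, com, inert, np.asarray(model.gravity, dtype=float),
        model.joint_armature, model.joint_damping,
        np.asarray(model.joint_lower_limits, dtype=float),
        np.asarray(model.joint_upper_limits, dtype=float),
        model.torque_limit, model.integrator_substep, model.n_substeps, free)
    if not ok:
        raise SimulationDivergedError("integrator diverged during step",
                                      partial=ArmState(q, qd))
    return ArmState(q, qd)


def kinetic_energy(model: ArmModel, state: ArmState) -> float:
    p, E, axis, m, com, inert, tip = chain_parameters(model)
    M = dyn.mass_matrix(state.joint_angles, p, E, axis, m, com, inert,
                        model.joint_armature)
    return 0.5 * float(state.joint_velocities @ M @ state.joint_velocities)


def potential_energy(model: ArmModel, state: ArmState) -> float:
    p, E, axis, m, com, inert, tip = chain_parameters(model)
    R, o, a = dyn.frames(state.joint_angles, p, E, axis)
    g = np.asarray(model.gravity, dtype=float)
    pe = 0.0
    for i in range(7):
        xc = o[i] + R[i] @ com[i]
        pe -= m[i] * float(g @ xc)
    return pe


# ---------------------------------------------------------------------------
# initial-pose calibration (damped-least-squares IK from a fixed seed pose)

_IK_SEED = np.array([-0.9, 0.3, 0.0, -0.5, 0.0, 0.0, 0.0])
_pose_cache: dict = {}


def initial_pose(model: ArmModel, q_initial=None) -> np.ndarray:
    """Deterministic joint configuration whose fingertip equals ``q_initial``.

    Solved once by damped-least-squares IK (with a mid-range null-space bias)
    from a fixed seed pose, then cached per (model, target).
    """
    target = model.q_initial if q_initial is None else \
        _check_finite("q_initial", q_initial)
    key = (dataclasses.astuple(model), tuple(np.round(target, 12)))
    if key in _pose_cache:
        return _pose_cache[key].copy()
    pose = solve_ik(model, target, seed_pose=_IK_SEED)
    _pose_cache[key] = pose
    return pose.copy()


def solve_ik(model: ArmModel, target, seed_pose, tol=1e-9, max_iter=500,
             damping=0.02) -> np.ndarray:
    """Damped-least-squares inverse kinematics within joint limits."""
    target = _check_finite("target", target)
    lo = np.asarray(model.joint_lower_limits, dtype=float)
    hi = np.asarray(model.joint_upper_limits, dtype=float)
    mid = 0.5 * (lo + hi)
    q = np.clip(np.asarray(seed_pose, dtype=float).copy(), lo, hi)
    # phase 1 pulls toward a mid-range posture in the null space; phase 2
    # drops the bias and the damping so the position error can vanish
    for phase, lam, bias in ((0, damping, 0.1), (1, 1e-4, 0.0)):
        for _ in range(max_iter):
            err = target - forward_kinematics(model, q)
            if float(np.linalg.norm(err)) < tol:
                break
            J = jacobian(model, q)
            JJt = J @ J.T + (lam ** 2) * np.eye(3)
            dq = J.T @ np.linalg.solve(JJt, err)
            if bias:
                Jpinv = J.T @ np.linalg.inv(JJt)
                dq += bias * (np.eye(7) - Jpinv @ J) @ (mid - q)
            step_norm = float(np.linalg.norm(dq))
            if step_norm > 0.5:
                dq *= 0.5 / step_norm
            q = np.clip(q + dq, lo, hi)
    residual = float(np.linalg.norm(target - forward_kinematics(model, q)))
    if residual > 1e-6:
        raise NoSolutionError(
            f"IK failed: residual {residual:.2e} m for target {target}")
    return q


# ---------------------------------------------------------------------------
# presets and config files

def arm_preset(name: str) -> ArmModel:
    """Load one of the shipped presets: original, shorter, longer."""
    try:
        text = resources.files("synreach").joinpath(
            f"presets/{name}.yaml").read_text()
    except FileNotFoundError:
        raise InvalidArgumentError(f"unknown arm preset {name!r}") from None
    return model_from_yaml(text)


def model_from_yaml(text: str) -> ArmModel:
    data = yaml.safe_load(text)
    for key in ("link_masses", "link_inertias", "joint_lower_limits",
                "joint_upper_limits", "joint_axis_spec", "gravity"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return ArmModel(**data)


def model_to_yaml(model: ArmModel) -> str:
    data = dataclasses.asdict(model)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    return yaml.safe_dump(data, sort_keys=False)
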