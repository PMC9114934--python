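"""Surrogate reaching expert: minimum-jerk references + computed-torque control.

A stand-in for reinforcement-learned policies that needs no training: the
reach is planned as a joint-space minimum-jerk motion from the home pose to
the inverse-kinematics pose of the target (out over [0, t_target], back over
[t_target, t_finish], stationary at the reversal), and executed by inverse
dynamics along the reference plus PD correction on the simulated state.

Joint-space (rather than task-space) planning avoids Jacobian inversion near
singularities; the near-straightness of the resulting fingertip path is a
verified property of the tests, not a construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import arm as arm_mod
from .arm import ArmModel
from .errors import InvalidArgumentError
from .task import TaskSpec, Trajectory, run_episode


@dataclasses.dataclass(frozen=True)
class SurrogateConfig:
    """Tracking-controller gains, per unit joint inertia.

    The effective per-joint PD gains are these values multiplied by the
    diagonal of the mass matrix at the home pose, so every joint closes the
    loop at the same natural frequency (sqrt(pd_position_gain) rad/s).
    Uniform unscaled gains are discretely unstable at the 10 ms control rate
    on the low-inertia wrist joints.
    """

    pd_position_gain: float = 400.0  # 1/s^2 (stiffness per unit inertia)
    pd_velocity_gain: float = 40.0   # 1/s (damping per unit inertia)

    def __post_init__(self):
        if self.pd_position_gain <= 0 or self.pd_velocity_gain <= 0:
            raise InvalidArgumentError("PD gains must be positive")


def min_jerk_profile(tau: float):
    """Minimum-jerk scalar profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5.

    Returns (position, velocity, acceleration) fractions; the boundary
    conditions s(0)=0, s(1)=1 with zero velocity and acceleration at both
    ends make it the jerk-optimal point-to-point profile.
    """
    if not 0.0 <= tau <= 1.0:
        raise InvalidArgumentError("normalized time must lie in [0, 1]")
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    dds = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, ds, dds


def _reference(theta0, theta1, t, t_target, t_finish):
    """Out-and-back joint reference (position, velocity, acceleration)."""
    d = theta1 - theta0
    if t <= t_target:
        tau, scale = t / t_target, t_target
        base, sign = theta0, 1.0
    else:
        tau = (t - t_target) / (t_finish - t_target)
        scale = t_finish - t_target
        base, sign = theta1, -1.0
    tau = min(max(tau, 0.0), 1.0)
    s, ds, dds = min_jerk_profile(tau)
    return (base + sign * d * s,
            sign * d * ds / scale,
            sign * d * dds / scale**2)


def target_pose(model: ArmModel, task: TaskSpec, target) -> np.ndarray:
    """IK pose for the target, seeded from the home pose for determinism."""
    theta0 = arm_mod.initial_pose(model, task.home)
    return arm_mod.solve_ik(model, np.asarray(target, float), seed_pose=theta0)


def make_controller(model: ArmModel, task: TaskSpec, target,
                    config: SurrogateConfig | None = None):
    """Closure mapping observations to torques for one reaching episode."""
    config = config or SurrogateConfig()
    theta0 = arm_mod.initial_pose(model, task.home)
    theta1 = target_pose(model, task, target)
    from . import _dynamics as dyn
    p, E, axis, m, com, inert, tip = arm_mod.chain_parameters(model)
    inertia = np.diag(dyn.mass_matrix(theta0, p, E, axis, m, com, inert,
                                      model.joint_armature))
    kp = config.pd_position_gain * inertia
    kd = config.pd_velocity_gain * inertia

    def controller(obs):
        theta, dtheta, phi = obs[:7], obs[7:14], obs[17]
        t = phi * task.t_finish
        q_r, qd_r, qdd_r = _reference(theta0, theta1, t,
                                      task.t_target, task.t_finish)
        ff = arm_mod.inverse_dynamics(model, q_r, qd_r, qdd_r)
        return ff + kp * (q_r - theta) + kd * (qd_r - dtheta)

    return controller


def generate_expert_trajectory(model: ArmModel, task: TaskSpec, target,
                               config: SurrogateConfig | None = None
                               ) -> Trajectory:
    """One full surrogate-expert episode, rewards included."""
    controller = make_controller(model, task, target, config)
    traj = run_episode(model, task, target, controller)
    traj.metadata["source"] = "surrogate"
    return traj


def expert_trajectories(model: ArmModel, task: TaskSpec, targets,
                        config: SurrogateConfig | None = None) -> list:
    """Surrogate episodes for every target of a TargetSet."""
    return [generate_expert_trajectory(model, task, t, config)
            for t in targets]
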