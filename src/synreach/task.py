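"""The multi-directional reciprocating reaching task.

The fingertip starts at the calibrated home position ``q_initial``, must touch
a target ``q_target`` at ``t_target`` (0.5 s) and return home by ``t_finish``
(1 s).  Targets lie on a radius-``l`` circle in one of four planes through the
home position (horizontal, sagittal, frontal) or on a horizontal circle
raised by ``z`` (upper).  The reward is a pure penalty: a torque cost at every
sample plus position/velocity costs at the two checkpoints, so the best
attainable return is 0.

Episodes are 100 control samples of 10 ms.  Sample indexing is 1-based for
the reward: the reward of sample ``t`` is evaluated after the ``t``-th control
step, and "t = t_target" means sample 50, "t = t_finish" sample 100.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import arm as arm_mod
from . import _dynamics as dyn
from .arm import ArmModel, ArmState
from .errors import InvalidArgumentError, SimulationDivergedError

PLANES = ("horizontal", "sagittal", "frontal", "upper")


@dataclasses.dataclass(frozen=True)
class TaskSpec:
    """Timing, reward coefficients and target geometry of the reaching task."""

    q_initial: tuple = (0.24, 0.0, 0.21)  # m, fingertip home position
    t_target: float = 0.5                 # s, reach checkpoint
    t_finish: float = 1.0                 # s, return checkpoint / horizon
    control_interval: float = 0.01        # s
    samples_per_episode: int = 100
    k1: float = 0.002                     # velocity penalty coefficient
    k2: float = 0.2                       # torque penalty coefficient
    target_radius: float = 0.15           # m, l in the target formulas
    upper_offset: float = 0.05            # m, z lift of the upper plane

    def __post_init__(self):
        if not self.t_target < self.t_finish:
            raise InvalidArgumentError("t_target must precede t_finish")
        if abs(self.samples_per_episode * self.control_interval
               - self.t_finish) > 1e-9:
            raise InvalidArgumentError("T * dt must equal t_finish")
        if min(self.k1, self.k2, self.target_radius) <= 0:
            raise InvalidArgumentError("k1, k2 and target_radius must be > 0")

    @property
    def target_sample(self) -> int:
        """1-based sample index of the reach checkpoint (50 by default)."""
        return int(round(self.t_target / self.control_interval))

    @property
    def home(self) -> np.ndarray:
        return np.asarray(self.q_initial, dtype=float)


def task_for(model: ArmModel, **overrides) -> TaskSpec:
    """TaskSpec whose home position matches the arm's own calibration."""
    overrides.setdefault("q_initial", tuple(model.q_initial))
    return TaskSpec(**overrides)


@dataclasses.dataclass(frozen=True)
class TargetSet:
    """Reaching goals of one plane type."""

    plane_type: str
    direction_angles: tuple   # rad, the target-direction angle theta
    positions: tuple          # of 3-tuples, m

    def __post_init__(self):
        if len(self.direction_angles) != len(self.positions):
            raise InvalidArgumentError("angles and positions must align")

    def __len__(self):
        return len(self.positions)

    def __iter__(self):
        return (np.asarray(p) for p in self.positions)


def target_position(plane_type: str, theta: float, task: TaskSpec) -> np.ndarray:
    """One goal position on the given plane for direction angle theta."""
    qi = task.home
    l, z = task.target_radius, task.upper_offset
    s, c = np.sin(theta), np.cos(theta)
    if plane_type == "horizontal":
        return qi + np.array([-l * s, -l * c, 0.0])
    if plane_type == "sagittal":
        return qi + np.array([-l * s, 0.0, -l * c])
    if plane_type == "frontal":
        return qi + np.array([0.0, -l * s, -l * c])
    if plane_type == "upper":
        return qi + np.array([-l * s, -l * c, z])
    raise InvalidArgumentError(f"unknown plane type {plane_type!r}")


def make_targets(plane_type: str, n_directions: int, task: TaskSpec) -> TargetSet:
    """Targets at theta = 2 pi n / n_directions, n = 0..n_directions-1."""
    if n_directions < 1:
        raise InvalidArgumentError("n_directions must be positive")
    angles = tuple(2.0 * np.pi * n / n_directions for n in range(n_directions))
    positions = tuple(tuple(target_position(plane_type, th, task))
                      for th in angles)
    return TargetSet(plane_type, angles, positions)


def observe(state: ArmState, target: np.ndarray, t: float,
            task: TaskSpec) -> np.ndarray:
    """The 18-vector observation: angles(7), velocities(7), target(3), phi."""
    phi = t / task.t_finish
    return np.concatenate([state.joint_angles, state.joint_velocities,
                           np.asarray(target, dtype=float), [phi]])


def reward(task: TaskSpec, target, fingertip_pos, fingertip_vel, action,
           sample_index: int) -> float:
    """Penalty of one sample (always <= 0); checkpoint terms at 50 and 100."""
    a = np.asarray(action, dtype=float)
    r = -task.k2 * float(a @ a) * task.control_interval
    if sample_index == task.target_sample:
        anchor = np.asarray(target, dtype=float)
    elif sample_index == task.samples_per_episode:
        anchor = task.home
    else:
        return r
    e = anchor - np.asarray(fingertip_pos, dtype=float)
    v = np.asarray(fingertip_vel, dtype=float)
    return r - float(e @ e) - task.k1 * float(v @ v)


def rewards_for(task: TaskSpec, target, tippos, tipvel, actions) -> np.ndarray:
    """Vectorized per-sample rewards for a whole (T,*) rollout."""
    T = actions.shape[0]
    r = -task.k2 * np.einsum("ij,ij->i", actions, actions) * task.control_interval
    it = task.target_sample - 1
    e = np.asarray(target, float) - tippos[it]
    r[it] -= float(e @ e) + task.k1 * float(tipvel[it] @ tipvel[it])
    e = task.home - tippos[T - 1]
    r[T - 1] -= float(e @ e) + task.k1 * float(tipvel[T - 1] @ tipvel[T - 1])
    return r


@dataclasses.dataclass
class Trajectory:
    """One episode: observations, torque actions, fingertip path, rewards."""

    observations: np.ndarray        # (T, 18)
    actions: np.ndarray             # (T, 7) torques, N m
    fingertip_positions: np.ndarray  # (T, 3) m
    fingertip_velocities: np.ndarray  # (T, 3) m/s
    rewards: np.ndarray             # (T,)
    accumulated_reward: float       # G, the sum of rewards
    target_position: np.ndarray     # (3,)
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        T = self.actions.shape[0]
        for name in ("observations", "fingertip_positions",
                     "fingertip_velocities", "rewards"):
            if getattr(self, name).shape[0] != T:
                raise InvalidArgumentError(f"{name} length differs from actions")

    @property
    def T(self) -> int:
        return self.actions.shape[0]


def run_episode(model: ArmModel, task: TaskSpec, target, controller,
                seed=None) -> Trajectory:
    """Roll out observe -> act -> step -> reward for T samples.

    ``controller`` maps an 18-vector observation to a 7-vector torque.  The
    episode starts at the calibrated home pose with zero velocity.  On
    integrator divergence the partial trajectory is attached to the error.
    """
    target = np.asarray(target, dtype=float)
    T = task.samples_per_episode
    q0 = arm_mod.initial_pose(model, task.home)
    state = ArmState(q0, np.zeros(7))
    obs = np.zeros((T, 18))
    acts = np.zeros((T, 7))
    tippos = np.zeros((T, 3))
    tipvel = np.zeros((T, 3))
    done = T
    for t in range(T):
        o = observe(state, target, t * task.control_interval, task)
        a = np.asarray(controller(o), dtype=float)
        obs[t] = o
        acts[t] = np.clip(a, -model.torque_limit, model.torque_limit)
        try:
            state = arm_mod.step(model, state, acts[t])
        except SimulationDivergedError as err:
            state = err.partial
            done = t + 1
        tippos[t] = arm_mod.forward_kinematics(model, state.joint_angles)
        tipvel[t] = arm_mod.fingertip_velocity(model, state)
        if done <= t:
            break
    rew = rewards_for(task, target, tippos, tipvel, acts)
    traj = Trajectory(obs, acts, tippos, tipvel, rew, float(rew[:done].sum()),
                      target, {"seed": seed, "arm": model.name,
                               "source": "policy", "samples_done": done})
    if done < T:
        raise SimulationDivergedError("episode diverged", partial=traj)
    return traj


def run_open_loop(model: ArmModel, task: TaskSpec, target,
                  torques) -> Trajectory:
    """Fast open-loop rollout of a precomputed (T,7) torque sequence."""
    target = np.asarray(target, dtype=float)
    torques = np.asarray(torques, dtype=float)
    if torques.shape != (task.samples_per_episode, 7):
        raise InvalidArgumentError("torque sequence must be (T, 7)")
    q0 = arm_mod.initial_pose(model, task.home)
    p, E, axis, m, com, inert, tip = arm_mod.chain_parameters(model)
    angles, vels, tippos, tipvel, done = dyn.open_loop_episode(
        q0, torques, p, E, axis, m, com, inert,
        np.asarray(model.gravity, dtype=float), model.joint_armature,
        model.joint_damping,
        np.asarray(model.joint_lower_limits, dtype=float),
        np.asarray(model.joint_upper_limits, dtype=float),
        model.torque_limit, model.integrator_substep, model.n_substeps, tip)
    T = task.samples_per_episode
    phis = (np.arange(T) * task.control_interval) / task.t_finish
    prev_q = np.vstack([q0, angles[:-1]])
    prev_v = np.vstack([np.zeros(7), vels[:-1]])
    obs = np.hstack([prev_q, prev_v, np.tile(target, (T, 1)),
                     phis[:, None]])
    acts = np.clip(torques, -model.torque_limit, model.torque_limit)
    rew = rewards_for(task, target, tippos, tipvel, acts)
    traj = Trajectory(obs, acts, tippos, tipvel, rew, float(rew[:done].sum()),
                      target, {"arm": model.name, "source": "synergy",
                               "samples_done": int(done)})
    if done < T:
        raise SimulationDivergedError("episode diverged", partial=traj)
    return traj


def reaching_errors(traj: Trajectory, task: TaskSpec, target) -> tuple:
    """(error at q_target, error at q_initial) in centimetres."""
    it = task.target_sample - 1
    if_ = task.samples_per_episode - 1
    e_target = np.linalg.norm(traj.fingertip_positions[it]
                              - np.asarray(target, float))
    e_home = np.linalg.norm(traj.fingertip_positions[if_] - task.home)
    return 100.0 * float(e_target), 100.0 * float(e_home)


# ---------------------------------------------------------------------------
# trajectory containers: one .npz per batch plus a JSON metadata block

_ARRAY_FIELDS = ("observations", "actions", "fingertip_positions",
                 "fingertip_velocities", "rewards", "target_position")


def save_trajectories(path, trajectories) -> None:
    """Write a rollout batch to an .npz container with JSON metadata."""
    path = Path(path)
    arrays = {}
    meta = []
    for k, tr in enumerate(trajectories):
        for f in _ARRAY_FIELDS:
            arrays[f"{k}_{f}"] = getattr(tr, f)
        arrays[f"{k}_G"] = np.array(tr.accumulated_reward)
        meta.append(tr.metadata)
    arrays["n"] = np.array(len(meta))
    arrays["metadata_json"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_trajectories(path) -> list:
    path = Path(path)
    with np.load(path) as z:
        n = int(z["n"])
        meta = json.loads(bytes(z["metadata_json"]).decode())
        out = []
        for k in range(n):
            out.append(Trajectory(
                *(z[f"{k}_{f}"] for f in _ARRAY_FIELDS[:-1]),
                accumulated_reward=float(z[f"{k}_G"]),
                target_position=z[f"{k}_target_position"],
                metadata=meta[k]))
    return out


def trajectories_to_csv(path, trajectories) -> None:
    """Tidy CSV export: one row per (trajectory, sample)."""
    import pandas as pd

    rows = []
    for k, tr in enumerate(trajectories):
        for t in range(tr.T):
            row = {"trial": k, "sample": t,
                   "reward": tr.rewards[t]}
            for j in range(7):
                row[f"torque_{j}"] = tr.actions[t, j]
            for ax, name in enumerate("xyz"):
                row[f"tip_{name}"] = tr.fingertip_positions[t, ax]
                row[f"target_{name}"] = tr.target_position[ax]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def trials_from_csv(path) -> np.ndarray:
    """Read a tidy CSV back into an (N, T, M) signed action stack."""
    import pandas as pd

    df = pd.read_csv(path)
    torque_cols = sorted(c for c in df.columns if c.startswith("torque_"))
    trials = []
    for _, g in df.groupby("trial"):
        trials.append(g.sort_values("sample")[torque_cols].to_numpy())
    return np.stack(trials)
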