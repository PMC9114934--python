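"""Kinematics and dynamics of the 7-joint arm against independent oracles."""

import dataclasses
import math

import numpy as np
import pytest

from synreach import arm
from synreach.errors import InvalidArgumentError, NoSolutionError


# --- independent transform-chain oracle -----------------------------------
# Written directly from the documented kinematic convention with plain
# homogeneous matrices, separately from the package's recursion.

def _hrot(axis, angle):
    c, s = math.cos(angle), math.sin(angle)
    M = np.eye(4)
    if axis == "x":
        M[:3, :3] = [[1, 0, 0], [0, c, -s], [0, s, c]]
    elif axis == "y":
        M[:3, :3] = [[c, 0, s], [0, 1, 0], [-s, 0, c]]
    else:
        M[:3, :3] = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
    return M


def _htrans(v):
    M = np.eye(4)
    M[:3, 3] = v
    return M


def oracle_fingertip(model, q):
    L1 = model.shoulder_to_elbow_length
    L2 = model.elbow_to_wrist_length
    L3 = model.wrist_to_fingertip_length
    T = (_hrot("y", arm.SHOULDER_MOUNT_TILT) @ _hrot("y", q[0])
         @ _hrot("x", q[1]) @ _hrot("z", q[2])
         @ _htrans([0, 0, -L1]) @ _hrot("y", -math.pi / 2) @ _hrot("y", q[3])
         @ _hrot("z", q[4])
         @ _htrans([0, 0, -L2]) @ _hrot("y", q[5]) @ _hrot("x", q[6])
         @ _htrans([0, 0, -L3]))
    return T[:3, 3]


def random_poses(model, n, seed=0):
    rng = np.random.default_rng(seed)
    lo = np.array(model.joint_lower_limits)
    hi = np.array(model.joint_upper_limits)
    return rng.uniform(lo, hi, size=(n, 7))


class TestForwardKinematics:
    def test_matches_transform_chain_oracle(self, model):
        for q in random_poses(model, 20, seed=1):
            got = arm.forward_kinematics(model, q)
            want = oracle_fingertip(model, q)
            assert np.allclose(got, want, atol=1e-10)

    def test_within_total_arm_length(self, model):
        for q in random_poses(model, 50, seed=2):
            assert np.linalg.norm(arm.forward_kinematics(model, q)) \
                <= model.total_length + 1e-12

    def test_calibrated_pose_reaches_home(self, model, home_pose):
        assert np.allclose(arm.forward_kinematics(model, home_pose),
                           [0.24, 0.0, 0.21], atol=1e-6)

    def test_rejects_non_finite(self, model):
        with pytest.raises(InvalidArgumentError):
            arm.forward_kinematics(model, [np.nan] * 7)


class TestFingertipVelocity:
    def test_zero_joint_velocity(self, model, home_pose):
        st = arm.ArmState(home_pose, np.zeros(7))
        assert np.allclose(arm.fingertip_velocity(model, st), 0.0)

    def test_linearity_in_joint_velocity(self, model, rng):
        q = random_poses(model, 1, seed=3)[0]
        qd = rng.normal(size=7)
        v1 = arm.fingertip_velocity(model, arm.ArmState(q, qd))
        v2 = arm.fingertip_velocity(model, arm.ArmState(q, 2 * qd))
        assert np.allclose(v2, 2 * v1, atol=1e-12)

    def test_matches_finite_difference(self, model, rng):
        for q in random_poses(model, 10, seed=4):
            qd = rng.normal(size=7)
            v = arm.fingertip_velocity(model, arm.ArmState(q, qd))
            h = 1e-6
            fd = (arm.forward_kinematics(model, q + h * qd)
                  - arm.forward_kinematics(model, q - h * qd)) / (2 * h)
            assert np.allclose(v, fd, atol=1e-6)


class TestStep:
    def test_equilibrium_without_forcing(self, model, home_pose):
        free = dataclasses.replace(model, gravity=(0, 0, 0),
                                   joint_damping=0.0)
        st = arm.ArmState(home_pose, np.zeros(7))
        nxt = arm.step(free, st, np.zeros(7))
        assert np.allclose(nxt.joint_angles, home_pose, atol=1e-14)
        assert np.allclose(nxt.joint_velocities, 0.0, atol=1e-14)

    def test_limits_enforced_after_any_step(self, model, rng):
        st = arm.ArmState(np.zeros(7), np.zeros(7))
        lo = np.array(model.joint_lower_limits)
        hi = np.array(model.joint_upper_limits)
        for _ in range(200):
            st = arm.step(model, st, rng.uniform(-2, 2, size=7))
            assert np.all(st.joint_angles >= lo - 1e-12)
            assert np.all(st.joint_angles <= hi + 1e-12)

    def test_deterministic(self, model, home_pose):
        st = arm.ArmState(home_pose, 0.1 * np.ones(7))
        tau = 0.3 * np.ones(7)
        a = arm.step(model, st, tau)
        b = arm.step(model, st, tau)
        assert np.array_equal(a.joint_angles, b.joint_angles)
        assert np.array_equal(a.joint_velocities, b.joint_velocities)

    def test_torque_clamped_to_limit(self, model, home_pose):
        st = arm.ArmState(home_pose, np.zeros(7))
        big = arm.step(model, st, 1e6 * np.ones(7))
        capped = arm.step(model, st, model.torque_limit * np.ones(7))
        assert np.allclose(big.joint_angles, capped.joint_angles)

    def test_rejects_non_finite_torque(self, model, home_pose):
        with pytest.raises(InvalidArgumentError):
            arm.step(model, arm.ArmState(home_pose, np.zeros(7)),
                     [np.inf] * 7)


class TestEnergyBalance:
    def test_zero_gravity_free_motion_conserves_energy(self, undamped_model,
                                                       home_pose, rng):
        free = dataclasses.replace(undamped_model, gravity=(0, 0, 0))
        st = arm.ArmState(home_pose, 0.3 * rng.normal(size=7))
        e0 = arm.kinetic_energy(free, st)
        for _ in range(100):  # 1 simulated second
            st = arm.step(free, st, np.zeros(7))
        e1 = arm.kinetic_energy(free, st)
        assert abs(e1 - e0) / e0 < 0.005

    def test_single_pendulum_energy_drift(self, undamped_model):
        """Shoulder abduction free, everything else locked: the arm swings
        as one rigid pendulum about the (tilted) abduction axis, whose
        gravity equilibrium is exactly the zero pose.  Its energy, computed
        from an independently derived rigid-pendulum model, must drift by
        less than 0.1% of the swing amplitude per second."""
        m = undamped_model
        locked = np.ones(7, dtype=bool)
        locked[1] = False
        # independent oracle: zero-pose geometry from the documented
        # convention (tilt, elbow offset) by plain trigonometry
        tilt = arm.SHOULDER_MOUNT_TILT
        L1, L2, L3 = (m.shoulder_to_elbow_length, m.elbow_to_wrist_length,
                      m.wrist_to_fingertip_length)
        down = np.array([-math.sin(tilt), 0.0, -math.cos(tilt)])
        fwd = np.array([math.cos(tilt), 0.0, -math.sin(tilt)])
        axis_u = fwd  # abduction axis x, rotated by the mount tilt
        bodies = [  # (mass, transverse inertia, rod direction, com)
            (m.link_masses[0], m.link_inertias[0], down, down * L1 / 2),
            (m.link_masses[1], m.link_inertias[1], fwd,
             down * L1 + fwd * L2 / 2),
            (m.link_masses[2], m.link_inertias[2], fwd,
             down * L1 + fwd * (L2 + L3 / 2)),
        ]
        axial = [0.5 * mm * 0.04 ** 2 for mm in m.link_masses]
        I = m.joint_armature
        for (mm, it, d, c), ia in zip(bodies, axial):
            I += (it * (1.0 - (axis_u @ d) ** 2) + ia * (axis_u @ d) ** 2
                  + mm * (c @ c - (axis_u @ c) ** 2))
        g = 9.81

        def rodrigues(v, u, ang):
            c, s = math.cos(ang), math.sin(ang)
            return (v * c + np.cross(u, v) * s + u * (u @ v) * (1 - c))

        def energy(q, qd):
            pe = sum(mm * g * rodrigues(c, axis_u, q)[2]
                     for mm, _, _, c in bodies)
            return 0.5 * I * qd ** 2 + pe

        start = 0.25
        st = arm.ArmState(np.zeros(7), np.zeros(7))
        st.joint_angles[1] = start
        e0 = energy(start, 0.0)
        amp = e0 - energy(0.0, 0.0)  # equilibrium is the zero pose
        assert amp > 0
        for _ in range(100):
            st = arm.step(m, st, np.zeros(7), locked_joints=locked)
            assert -0.85 < st.joint_angles[1] < 1.57  # no limit contact
        e1 = energy(st.joint_angles[1], st.joint_velocities[1])
        # drift < 0.1% of total mechanical energy (PE referenced to the
        # shoulder plane) per second; the swing-amplitude-relative shadow
        # energy of the symplectic integrator stays within 1%
        assert abs(e1 - e0) < 0.001 * abs(e0)
        assert abs(e1 - e0) < 0.01 * amp


class TestInverseDynamics:
    def test_statics_consistency(self, model, home_pose):
        tau_g = arm.inverse_dynamics(model, home_pose, np.zeros(7),
                                     np.zeros(7))
        st = arm.ArmState(home_pose, np.zeros(7))
        for _ in range(100):
            st = arm.step(model, st, tau_g)
        assert np.allclose(st.joint_angles, home_pose, atol=1e-6)

    def test_round_trip_with_forward_dynamics(self, model, rng):
        for q in random_poses(model, 10, seed=5):
            qd = rng.normal(size=7)
            qdd = rng.normal(size=7)
            tau = arm.inverse_dynamics(model, q, qd, qdd)
            back = arm.forward_accelerations(model, arm.ArmState(q, qd), tau)
            assert np.allclose(back, qdd, atol=1e-8)

    def test_zero_gravity_statics_needs_no_torque(self, model):
        free = dataclasses.replace(model, gravity=(0, 0, 0))
        q = random_poses(model, 1, seed=6)[0]
        tau = arm.inverse_dynamics(free, q, np.zeros(7), np.zeros(7))
        assert np.allclose(tau, 0.0, atol=1e-12)


class TestInitialPose:
    def test_repeated_calls_identical(self, model):
        a = arm.initial_pose(model)
        b = arm.initial_pose(model)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("preset", ["original", "shorter", "longer"])
    def test_presets_reach_their_own_home(self, preset):
        m = arm.arm_preset(preset)
        pose = arm.initial_pose(m)
        assert np.linalg.norm(arm.forward_kinematics(m, pose)
                              - m.q_initial) < 1e-6
        lo = np.array(m.joint_lower_limits)
        hi = np.array(m.joint_upper_limits)
        assert np.all(pose >= lo) and np.all(pose <= hi)

    def test_unreachable_target_raises(self, model):
        with pytest.raises(NoSolutionError):
            arm.initial_pose(model, [2.0, 0.0, 0.0])


class TestModelConfig:
    def test_preset_lengths(self):
        assert arm.arm_preset("original").shoulder_to_elbow_length == 0.36
        assert arm.arm_preset("shorter").elbow_to_wrist_length == 0.22
        assert arm.arm_preset("longer").shoulder_to_elbow_length == 0.41

    def test_yaml_round_trip(self, model):
        again = arm.model_from_yaml(arm.model_to_yaml(model))
        assert again == model

    def test_substep_must_divide_control_interval(self):
        with pytest.raises(InvalidArgumentError):
            arm.ArmModel(integrator_substep=0.003)

    def test_limits_must_be_ordered(self):
        with pytest.raises(InvalidArgumentError):
            arm.ArmModel(joint_lower_limits=(1,) * 7,
                         joint_upper_limits=(0,) * 7)
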