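"""Kinematics, moment arms, inverse dynamics, and chain-energy checks."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neckforce.model import (
    MotionTrajectory,
    derive_kinematics,
    forward_markers,
    inverse_dynamics,
    mass_matrix,
    mechanical_energy,
    moment_arm_matrix,
    muscle_lengths,
    _rnea,
)

from .conftest import make_pendulum


class TestForwardKinematics:
    def test_neutral_pose_marker_layout(self, full_model):
        tp, lh, rh = forward_markers(full_model, np.zeros(6))
        assert tp[0] == pytest.approx(0.0) and tp[1] == pytest.approx(0.0)
        assert tp[2] > full_model.chain_length()          # above the chain top
        assert np.allclose(lh * [1, -1, 1], rh)           # sagittal mirror pair

    def test_axial_rotation_leaves_on_axis_marker_fixed(self, full_model):
        # TP sits on the rotation axis at neutral: pure axial rotation of
        # both articulations must not move it
        q = np.array([0.0, 0.0, 0.4, 0.0, 0.0, 0.3])
        tp0 = forward_markers(full_model, np.zeros(6))[0]
        tp = forward_markers(full_model, q)[0]
        assert np.allclose(tp, tp0, atol=1e-12)

    def test_flexion_matches_rotation_matrix_oracle(self):
        # single-articulation reduction: marker position at 90 deg flexion
        # equals the rotation matrix applied to the neutral offset
        model = make_pendulum()
        offset = np.array([0.01, 0.02, 0.15])
        model.marker_offsets = {"TP": offset, "LH": offset, "RH": offset}
        th = np.pi / 2
        Ry = np.array([[np.cos(th), 0, np.sin(th)],
                       [0, 1, 0],
                       [-np.sin(th), 0, np.cos(th)]])
        got = forward_markers(model, np.array([th]))[0]
        assert np.allclose(got, Ry @ offset, atol=1e-12)

    def test_sagittal_reflection_mirrors_markers_and_muscles(self, full_model):
        rng = np.random.default_rng(2)
        q = rng.uniform(-0.3, 0.3, 6)
        q_mirror = q * np.array([1, -1, -1, 1, -1, -1])   # flip bend + rotation
        pos = forward_markers(full_model, q)
        posm = forward_markers(full_model, q_mirror)
        assert np.allclose(posm[0], pos[0] * [1, -1, 1], atol=1e-12)  # TP mirrors
        assert np.allclose(posm[1], pos[2] * [1, -1, 1], atol=1e-12)  # LH <-> RH
        lengths = muscle_lengths(full_model, q)
        lengths_m = muscle_lengths(full_model, q_mirror)
        idx = {m.name: i for i, m in enumerate(full_model.muscles)}
        for i, m in enumerate(full_model.muscles):
            assert lengths_m[idx[m.partner]] == pytest.approx(lengths[i], abs=1e-12)


class TestMomentArms:
    def test_tendon_excursion_equivalence_at_random_poses(self, full_model):
        # every entry equals the negative length gradient by central
        # differences, at 20 random poses, for all 72 muscles
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(20):
            q = rng.uniform(-0.35, 0.35, 6)
            R = moment_arm_matrix(full_model, q)
            for j in range(6):
                qp, qm = q.copy(), q.copy()
                qp[j] += h
                qm[j] -= h
                fd = (muscle_lengths(full_model, qp)
                      - muscle_lengths(full_model, qm)) / (2 * h)
                assert np.abs(R[j] + fd).max() < 1e-4

    def test_muscle_through_joint_center_has_zero_arm(self):
        from neckforce.model import MuscleSpec
        model = make_pendulum()
        # a line through the joint origin along z: zero lever about y
        model.muscles = [MuscleSpec("thru", "right", "deep", "torso",
                                    np.array([0.0, 0.0, -0.1]), "head",
                                    np.array([0.0, 0.0, 0.1]), 100.0, "thru")]
        R = moment_arm_matrix(model, np.zeros(1))
        assert R[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_pairs_at_neutral(self, full_model):
        R = moment_arm_matrix(full_model, np.zeros(6))
        idx = {m.name: i for i, m in enumerate(full_model.muscles)}
        for i, m in enumerate(full_model.muscles):
            j = idx[m.partner]
            assert R[0, i] == pytest.approx(R[0, j], abs=1e-12)   # flexion equal
            assert R[1, i] == pytest.approx(-R[1, j], abs=1e-12)  # bending opposite


class TestInverseDynamics:
    def test_zero_lever_zero_gravity_moment(self):
        model = make_pendulum(com_z=0.0)      # COM on the joint axis
        assert inverse_dynamics(model, np.zeros(1))[0] == pytest.approx(0.0)

    def test_static_flexed_pendulum_matches_analytic_formula(self):
        # m g d sin(theta) with the population-mean head mass and lever
        model = make_pendulum(mass=6.377, com_z=0.1073)
        tau = inverse_dynamics(model, np.array([np.deg2rad(30.0)]))
        expected = 6.377 * 9.81 * 0.1073 * np.sin(np.deg2rad(30.0))
        assert abs(tau[0]) == pytest.approx(expected, rel=1e-9)
        assert abs(tau[0]) == pytest.approx(3.356, abs=5e-4)

    def test_newton_euler_limit_without_gravity(self):
        model = make_pendulum(com_z=0.0, inertia=0.05)
        qdd = np.array([2.5])
        tau = _rnea(model, np.zeros(1), np.zeros(1), qdd, with_gravity=False)
        assert tau[0] == pytest.approx(0.05 * 2.5, rel=1e-12)

    def test_passive_restoring_moment_reduces_demand(self):
        free = make_pendulum(stiffness=0.0)
        stiff = make_pendulum(stiffness=0.5)
        q = np.array([0.3])
        assert abs(inverse_dynamics(stiff, q)[0]) < abs(inverse_dynamics(free, q)[0])


class TestDifferentiation:
    def test_constant_angles_give_zero_derivatives(self):
        t = np.arange(100) / 100.0
        traj = derive_kinematics(MotionTrajectory(t, np.ones((100, 6)) * 0.2))
        assert np.allclose(traj.qd, 0) and np.allclose(traj.qdd, 0)

    def test_sine_derivative_accuracy(self):
        t = np.arange(0, 2, 0.01)
        q = np.sin(2 * np.pi * t)[:, None]
        traj = derive_kinematics(MotionTrajectory(t, q, ("fe",)))
        exact = 2 * np.pi * np.cos(2 * np.pi * t)
        interior = slice(1, -1)
        assert np.abs(traj.qd[interior, 0] - exact[interior]).max() <= 0.01

    def test_linear_ramp(self):
        t = np.arange(50) / 100.0
        traj = derive_kinematics(MotionTrajectory(t, (0.3 * t)[:, None], ("fe",)))
        assert np.allclose(traj.qd, 0.3)
        assert np.allclose(traj.qdd[1:-1], 0.0, atol=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            derive_kinematics(MotionTrajectory(np.array([0.0, 0.01]),
                                               np.zeros((2, 6))))


class TestEnergyConsistency:
    def test_free_swing_conserves_energy(self):
        # passive unactuated pendulum, no damping: total mechanical energy
        # along an integrated free swing stays constant, validating the
        # M/C/G assembly of the recursive Newton-Euler pass
        model = make_pendulum(mass=2.0, com_z=0.12, inertia=0.01)

        def rhs(_, y):
            q, qd = y[:1], y[1:]
            M = mass_matrix(model, q)
            bias = _rnea(model, q, qd, np.zeros(1))
            qdd = np.linalg.solve(M, -bias)
            return np.concatenate([qd, qdd])

        y0 = np.array([1.0, 0.0])
        sol = solve_ivp(rhs, (0, 1.5), y0, rtol=1e-10, atol=1e-12,
                        dense_output=True)
        e0 = mechanical_energy(model, y0[:1], y0[1:])
        for tt in np.linspace(0, 1.5, 10):
            y = sol.sol(tt)
            e = mechanical_energy(model, y[:1], y[1:])
            assert e == pytest.approx(e0, rel=1e-6)
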