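"""Muscle-redundancy solver: KKT oracles, constraints, and diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from neckforce.model import MotionTrajectory, inverse_dynamics, moment_arm_matrix
from neckforce.staticopt import (
    SOConfig,
    metabolic_cost,
    muscle_weights,
    solve_frame,
    solve_trajectory,
)

from .conftest import make_two_muscle_toy

UNWEIGHTED = SOConfig(w_deep=1.0, w_sup=1.0, lam1=0.0, lam2=0.0,
                      symmetry_mode="off")


def classical_static_optimization(R, tau, fmax):
    """Independent reference: min sum (f_i/f_i^max)^2 s.t. R f = tau, bounds.

    SLSQP (a different algorithmic path from the production solver)
    locates the optimum and hence the active bound set; the reduced KKT
    system on the free variables is then solved exactly, removing the
    iterative solver's terminal error.
    """
    n = len(fmax)
    res = minimize(
        lambda f: np.sum((f / fmax) ** 2),
        x0=np.full(n, 1.0),
        jac=lambda f: 2 * f / fmax**2,
        constraints=[{"type": "eq", "fun": lambda f: R @ f - tau,
                      "jac": lambda f: R}],
        bounds=[(0, fm) for fm in fmax],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    assert res.success
    f = np.clip(res.x, 0.0, fmax)
    free = (f > 1e-6) & (f < fmax - 1e-6)
    if free.any():
        m = R.shape[0]
        nf = int(free.sum())
        H = np.diag(2.0 / fmax[free] ** 2)
        K = np.zeros((nf + m, nf + m))
        K[:nf, :nf] = H
        K[:nf, nf:] = R[:, free].T
        K[nf:, :nf] = R[:, free]
        rhs = np.concatenate([np.zeros(nf),
                              tau - R[:, ~free] @ f[~free]])
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        f[free] = sol[:nf]
    assert np.linalg.norm(R @ f - tau) < 1e-8
    return f


class TestSolveFrame:
    def test_two_synergists_split_load_equally(self):
        # closed-form KKT: equal arms r, equal weights -> f = tau/(2r) each
        toy = make_two_muscle_toy(arm=0.02, f_max=100.0)
        f, info = solve_frame(toy, np.array([1.0]), config=UNWEIGHTED)
        assert info["status"] == "converged"
        assert np.allclose(f, [25.0, 25.0], atol=1e-6)

    def test_two_synergists_match_dense_grid_search(self):
        # brute-force verification on the feasible line f2 = tau/r - f1
        toy = make_two_muscle_toy(arm=0.02, f_max=100.0)
        f, _ = solve_frame(toy, np.array([1.0]), config=UNWEIGHTED)
        f1 = np.linspace(0, 50, 200001)
        f2 = 50.0 - f1
        cost = (f1 / 100) ** 2 + (f2 / 100) ** 2
        best = f1[np.argmin(cost)]
        assert f[0] == pytest.approx(best, abs=1e-3)

    def test_zero_moment_zero_force(self, reduced_model):
        cfg = SOConfig(lam1=0.0, symmetry_mode="off")
        f, info = solve_frame(reduced_model, np.zeros(6), config=cfg)
        assert info["status"] == "converged"
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_matches_independent_classical_solver(self, reduced_model):
        # lam1 = lam2 = 0, uniform weights: production path vs SLSQP oracle
        q = np.array([0.2, 0.1, -0.1, 0.2, 0.05, -0.1])
        R = moment_arm_matrix(reduced_model, q)
        tau = inverse_dynamics(reduced_model, q)
        f, info = solve_frame(reduced_model, tau, config=UNWEIGHTED, R=R)
        ref = classical_static_optimization(R, tau, reduced_model.f_max)
        assert info["status"] == "converged"
        assert np.abs(f - ref).max() < 1e-6

    def test_deep_muscle_carries_more_force(self):
        # identical geometry and f_max; w_deep = 0.8 < w_sup = 1.2 must
        # shift load onto the deep stabilizer for any nonzero demand
        toy = make_two_muscle_toy(depths=("deep", "superficial"))
        cfg = SOConfig(lam1=0.0, lam2=0.0, symmetry_mode="off")
        f, _ = solve_frame(toy, np.array([1.2]), config=cfg)
        assert f[0] > f[1] > 0

    def test_hard_symmetry_equalizes_partners(self, reduced_model):
        q = np.array([0.25, 0.0, 0.0, 0.25, 0.0, 0.0])
        tau = inverse_dynamics(reduced_model, q)
        cfg = SOConfig(symmetry_mode="hard")
        f, info = solve_frame(reduced_model, tau, config=cfg,
                              R=moment_arm_matrix(reduced_model, q))
        assert info["status"] == "converged"
        idx = {m.name: i for i, m in enumerate(reduced_model.muscles)}
        for i, m in enumerate(reduced_model.muscles):
            assert f[i] == pytest.approx(f[idx[m.partner]], abs=1e-6)

    def test_infeasible_demand_flagged_not_silently_dropped(self, reduced_model):
        tau = np.array([500.0, 0, 0, 0, 0, 0])   # far beyond muscle capacity
        f, info = solve_frame(reduced_model, tau)
        assert info["status"] == "infeasible"
        assert info["residual"] > 1.0


class TestMetabolicCost:
    def test_zero_force_zero_cost(self, reduced_model):
        cfg = SOConfig()
        n = len(reduced_model.muscles)
        assert np.allclose(
            metabolic_cost(np.zeros(n), np.zeros(n), 0.01, reduced_model, cfg), 0)

    def test_maximal_force_unit_cost_and_homogeneity(self, reduced_model):
        cfg = SOConfig()
        fmax = reduced_model.f_max
        assert np.allclose(
            metabolic_cost(fmax, fmax, 0.01, reduced_model, cfg), 1.0)
        f = 0.3 * fmax
        assert np.allclose(
            metabolic_cost(2 * f, f, 0.01, reduced_model, cfg),
            2 * metabolic_cost(f, f, 0.01, reduced_model, cfg))

    def test_unknown_selector_rejected(self, reduced_model):
        cfg = SOConfig(metabolic_form="mystery")
        with pytest.raises(ValueError):
            metabolic_cost(np.zeros(16), np.zeros(16), 0.01, reduced_model, cfg)


@pytest.fixture(scope="module")
def short_motion():
    from neckforce.model import derive_kinematics
    t = np.arange(120) / 100.0
    q = np.zeros((120, 6))
    q[:, 0] = 0.25 * 0.5 * (1 - np.cos(2 * np.pi * t / 1.2))
    q[:, 3] = q[:, 0]
    return derive_kinematics(MotionTrajectory(t, q))


class TestSolveTrajectory:

    def test_constant_posture_gives_stationary_forces(self, reduced_model):
        t = np.arange(40) / 100.0
        q = np.tile([0.15, 0, 0, 0.15, 0, 0], (40, 1))
        fs = solve_trajectory(reduced_model, MotionTrajectory(t, q))
        assert all(s == "converged" for s in fs.status)
        assert np.allclose(fs.forces[1:], fs.forces[1], atol=1e-6)
        rates = np.diff(fs.forces[1:], axis=0)
        assert np.sum(rates**2) == pytest.approx(0.0, abs=1e-9)

    def test_moment_closure_and_bounds(self, reduced_model, short_motion):
        fs = solve_trajectory(reduced_model, short_motion)
        assert all(s == "converged" for s in fs.status)
        assert fs.residuals.max() <= SOConfig().equality_tolerance
        assert fs.forces.min() >= 0
        assert np.all(fs.forces <= reduced_model.f_max + 1e-9)

    def test_rate_penalty_monotone_in_lambda2(self, reduced_model, short_motion):
        def rate_penalty(lam2):
            fs = solve_trajectory(reduced_model, short_motion,
                                  SOConfig(lam2=lam2, symmetry_mode="off"))
            dn = np.diff(fs.forces, axis=0) / reduced_model.f_max
            return np.sum(dn**2, axis=1)
        low, high = rate_penalty(0.001), rate_penalty(0.01)
        # scalarization guarantees the aggregate trade-off strictly; frame
        # by frame the sequential solves allow sub-percent wiggle
        assert high.sum() < low.sum()
        assert np.all(high <= low * 1.01 + 1e-12)

    def test_bitwise_determinism(self, reduced_model, short_motion):
        a = solve_trajectory(reduced_model, short_motion)
        b = solve_trajectory(reduced_model, short_motion)
        assert np.array_equal(a.forces, b.forces)

    def test_matches_classical_oracle_along_motion(self, reduced_model, short_motion):
        fs = solve_trajectory(reduced_model, short_motion, UNWEIGHTED)
        for t in (5, 60, 110):
            R = moment_arm_matrix(reduced_model, short_motion.q[t])
            tau = inverse_dynamics(reduced_model, short_motion.q[t],
                                   short_motion.qd[t], short_motion.qdd[t])
            ref = classical_static_optimization(R, tau, reduced_model.f_max)
            assert np.abs(fs.forces[t] - ref).max() < 1e-6


def test_weight_vector_follows_depth_classes(reduced_model):
    w = muscle_weights(reduced_model, SOConfig())
    for wi, m in zip(w, reduced_model.muscles):
        assert wi == (0.8 if m.depth_class == "deep" else 1.2)
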