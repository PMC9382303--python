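"""Cost functionals, Jacobians, adjoint gradient, line search, descent."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from neuroct import (ControlSignal, CostWeights, OptimizationSettings,
                     TargetSpec, bisection_line_search, evaluate_cost,
                     fd_gradient_oracle, running_cost_gradient,
                     system_jacobians, consistent_state, residual_h, simulate)
from neuroct.control import ControlProblem
from neuroct.model import ALG_IDX, DIFF_IDX

from _dae_adjoint import dae_adjoint_gradient


def _rect_control(amp_E=0.4, amp_I=0.0, T=500.0, dt=0.1, w0=210.0, w1=270.0):
    n = int(T / dt) + 1
    t = dt * np.arange(n)
    box = (t >= w0) & (t <= w1)
    return ControlSignal.from_nA(dt, amp_E * box, amp_I * box)


def _probe_control(problem, scale=1.0):
    n = problem.N + 1
    return ControlSignal.from_nA(
        problem.dt,
        scale * 0.08 * np.sin(np.linspace(0, 6, n)),
        scale * -0.06 * np.cos(np.linspace(0, 5, n)))


# ---------------------------------------------------------------------------
# cost functionals


def test_rectangle_cost_closed_form():
    """0.4 nA on E over 60 ms: F1_E = sqrt(9.6), F2_E = 4.8."""
    from neuroct.control import _channel_sq_integrals

    u = _rect_control()
    iE, iI = _channel_sq_integrals(u)
    assert np.sqrt(iE) == pytest.approx(np.sqrt(9.6), rel=2e-3)
    assert 0.5 * iE == pytest.approx(4.8, rel=4e-3)
    assert iI == 0.0


def test_cost_zero_iff_on_target_and_zero_control(params, table, setup_a):
    """u = 0 and r_E = r~ on [t0, T] gives exactly zero total cost."""
    target = TargetSpec(r_tilde=setup_a.down.r_E_Hz, t0=80.0, T=100.0)
    problem = ControlProblem(params, setup_a.background, table, setup_a.down,
                             target, dt=0.1)
    u = problem.zero_control()
    bd = problem.evaluate(u, CostWeights(W1=1.0, W2=1.0))
    assert bd.F1 == 0.0 and bd.F2 == 0.0
    assert bd.F_P < 1e-15
    # and it is nonzero as soon as the rate leaves the target
    target2 = TargetSpec(r_tilde=setup_a.down.r_E_Hz + 5.0, t0=80.0, T=100.0)
    problem2 = ControlProblem(params, setup_a.background, table,
                              setup_a.down, target2, dt=0.1)
    assert problem2.evaluate(u, CostWeights()).F_P > 0


def test_cost_homogeneity(shrunken_problem):
    """Scaling u -> 2u doubles F1 and quadruples F2."""
    u1 = _probe_control(shrunken_problem, scale=0.5)
    u2 = _probe_control(shrunken_problem, scale=1.0)
    w = CostWeights(W1=1.0, W2=1.0)
    bd1 = shrunken_problem.evaluate(u1, w)
    bd2 = shrunken_problem.evaluate(u2, w)
    assert bd2.F1 == pytest.approx(2 * bd1.F1, rel=1e-12)
    assert bd2.F2 == pytest.approx(4 * bd1.F2, rel=1e-12)


def test_grid_mismatch_rejected(params, table, setup_a):
    target = TargetSpec(r_tilde=10.0, t0=80.0, T=100.0)
    problem = ControlProblem(params, setup_a.background, table, setup_a.down,
                             target, dt=0.1)
    traj = problem.simulate(problem.zero_control())
    wrong = ControlSignal.zero(100.0, 0.2)
    with pytest.raises(ValueError, match="grid"):
        evaluate_cost(traj, wrong, target, CostWeights())


# ---------------------------------------------------------------------------
# running-cost gradient


def test_running_gradient_zero_channel_convention():
    u = _rect_control(amp_E=0.4, amp_I=0.0)
    g = running_cost_gradient(u, CostWeights(W1=1.0))
    assert np.all(g[:, 1] == 0.0)                 # the "0 else" branch
    # rectangle channel: u / ||u|| is a rectangle of height amp/||u||
    norm = np.sqrt(np.trapezoid(u.u_E_nA ** 2, dx=0.1))
    nz = np.abs(u.u_E_nA) > 0
    assert g[nz, 0] == pytest.approx(0.4 / norm, rel=1e-12)
    assert np.all(g[~nz, 0] == 0.0)


def test_l2_gradient_is_u_itself():
    u = _rect_control(amp_E=0.3, amp_I=-0.2)
    g = running_cost_gradient(u, CostWeights(W2=2.0))
    assert np.allclose(g[:, 0], 2.0 * u.u_E_nA)
    assert np.allclose(g[:, 1], 2.0 * u.u_I_nA)


# ---------------------------------------------------------------------------
# residual Jacobians


def test_system_jacobians_match_finite_differences(params, table_coarse,
                                                   setup_a):
    """All five Jacobians agree with central FD of residual_h."""
    bg = setup_a.background
    rng = np.random.default_rng(17)
    h = 1e-7
    for _ in range(20):
        y = np.concatenate([rng.uniform(-0.5, 1.5, 2),
                            rng.uniform(0.05, 0.9, 4),
                            rng.uniform(0.0, 0.01, 4)])
        x = consistent_state(y, params, table_coarse).to_array()
        xdE = rng.uniform(0, 0.05, 2)
        xdI = rng.uniform(0, 0.05, 2)
        u = rng.uniform(-0.5, 0.5, 2)
        x_dot = rng.normal(0, 0.1, 16)
        Dx, DxE, DxI, Dxd, Du = system_jacobians(x, xdE, xdI, u, params, bg,
                                                 table_coarse)

        def res(x_=None, xdE_=None, xdI_=None, u_=None, xd_=None):
            return residual_h(
                xd_ if xd_ is not None else x_dot,
                x_ if x_ is not None else x,
                xdE_ if xdE_ is not None else xdE,
                xdI_ if xdI_ is not None else xdI,
                u_ if u_ is not None else u, params, bg, table_coarse)

        for j in range(16):
            e = np.zeros(16)
            e[j] = h
            fd = (res(x_=x + e) - res(x_=x - e)) / (2 * h)
            np.testing.assert_allclose(Dx[:, j], fd, rtol=2e-5, atol=2e-6)
            fd = (res(xd_=x_dot + e) - res(xd_=x_dot - e)) / (2 * h)
            np.testing.assert_allclose(Dxd[:, j], fd, rtol=1e-6, atol=1e-9)
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            fd = (res(xdE_=xdE + e) - res(xdE_=xdE - e)) / (2 * h)
            np.testing.assert_allclose(DxE[:, j], fd, rtol=1e-5, atol=1e-7)
            fd = (res(xdI_=xdI + e) - res(xdI_=xdI - e)) / (2 * h)
            np.testing.assert_allclose(DxI[:, j], fd, rtol=1e-5, atol=1e-7)
            fd = (res(u_=u + e) - res(u_=u - e)) / (2 * h)
            np.testing.assert_allclose(Du[:, j], fd, rtol=1e-6, atol=1e-9)


def test_jacobian_sparsity_structure(params, table_coarse, setup_a):
    y = np.array([0.5, 0.5, 0.2, 0.5, 0.2, 0.6, 0.003, 0.003, 0.003, 0.003])
    x = consistent_state(y, params, table_coarse).to_array()
    Dx, DxE, DxI, Dxd, Du = system_jacobians(
        x, np.array([0.01, 0.02]), np.array([0.01, 0.02]),
        np.array([0.0, 0.0]), params, setup_a.background, table_coarse)
    # s_EE row couples only to itself among current-time states
    row = Dx[8]
    assert row[8] != 0.0
    assert np.all(row[np.arange(16) != 8] == 0.0)
    # its delayed-rate input enters through D_xE
    assert DxE[8, 0] != 0.0
    # D_xdot has identity entries on differential rows only
    assert np.all(np.diag(Dxd)[DIFF_IDX] == 1.0)
    assert np.all(Dxd[ALG_IDX] == 0.0)
    # D_u: the mu-dot rows carry -1/tau
    assert Du[2, 0] == pytest.approx(-1.0 / x[6])
    assert Du[3, 1] == pytest.approx(-1.0 / x[7])
    assert np.count_nonzero(Du) == 2


# ---------------------------------------------------------------------------
# adjoint


def test_adjoint_final_condition_and_on_target_solution(params, table,
                                                        setup_a):
    """lam(T) = 0 always; lam = 0 when the trajectory sits on target."""
    target = TargetSpec(r_tilde=setup_a.down.r_E_Hz, t0=80.0, T=100.0)
    problem = ControlProblem(params, setup_a.background, table, setup_a.down,
                             target, dt=0.1)
    traj = problem.simulate(problem.zero_control())
    adj = problem.solve_adjoint(traj)
    assert np.all(adj.lam[-1] == 0.0)
    assert np.max(np.abs(adj.lam)) < 1e-9  # homogeneous terminal problem


def test_total_gradient_matches_fd_oracle(shrunken_problem):
    u = _probe_control(shrunken_problem)
    for w in (CostWeights(W1=1.0), CostWeights(W2=1.0),
              CostWeights(W1=0.3, W2=0.7)):
        traj = shrunken_problem.simulate(u)
        g = shrunken_problem.total_gradient(traj, u, w)
        g_fd = fd_gradient_oracle(shrunken_problem, u, w, epsilon=1e-6)
        err = np.linalg.norm(g - g_fd) / np.linalg.norm(g_fd)
        assert err < 1e-3


def test_directional_derivative_oracle(shrunken_problem):
    """<g, du> reproduces (F(u+e du) - F(u-e du)) / 2e within 0.1 %."""
    w = CostWeights(W1=1.0)
    u = _probe_control(shrunken_problem)
    traj = shrunken_problem.simulate(u)
    g = shrunken_problem.total_gradient(traj, u, w, units="mv")
    tw = shrunken_problem._trapz_weights()
    rng = np.random.default_rng(2)
    eps = 1e-6
    for _ in range(10):
        du = rng.normal(0, 0.05, (shrunken_problem.N + 1, 2))
        fp = shrunken_problem._total_cost_mv(u.u_E + eps * du[:, 0],
                                             u.u_I + eps * du[:, 1], w)
        fm = shrunken_problem._total_cost_mv(u.u_E - eps * du[:, 0],
                                             u.u_I - eps * du[:, 1], w)
        fd = (fp - fm) / (2 * eps)
        pred = float(np.sum(tw[:, None] * g * du))
        assert pred == pytest.approx(fd, rel=1e-3)


def test_dae_route_equals_chain_rule_route(shrunken_problem):
    """The 6x6 algebraic-solve adjoint reproduces the production gradient."""
    u = _probe_control(shrunken_problem)
    traj = shrunken_problem.simulate(u)
    ubar, _ = shrunken_problem._adjoint_raw(traj)
    ubar_ref = dae_adjoint_gradient(shrunken_problem, traj)
    np.testing.assert_allclose(ubar, ubar_ref, rtol=1e-8, atol=1e-13)


def test_descent_step_decreases_cost(shrunken_problem):
    w = CostWeights(W1=1.0)
    u = _probe_control(shrunken_problem)
    traj = shrunken_problem.simulate(u)
    g = shrunken_problem.total_gradient(traj, u, w, units="mv")
    c0 = shrunken_problem._total_cost_mv(u.u_E, u.u_I, w)
    s = 1e-3 / max(np.max(np.abs(g)), 1e-12)
    c1 = shrunken_problem._total_cost_mv(u.u_E - s * g[:, 0],
                                         u.u_I - s * g[:, 1], w)
    assert c1 < c0


def test_fd_oracle_running_cost_part_is_exact(shrunken_problem):
    """Oracle difference between W2=1 and W=0 equals the analytic u term."""
    u = _probe_control(shrunken_problem)
    g2 = fd_gradient_oracle(shrunken_problem, u, CostWeights(W2=1.0),
                            epsilon=1e-5, stride=7)
    g0 = fd_gradient_oracle(shrunken_problem, u, CostWeights(),
                            epsilon=1e-5, stride=7)
    diff = g2 - g0
    expect = np.zeros_like(diff)
    expect[::7, 0] = u.u_E_nA[::7]
    expect[::7, 1] = u.u_I_nA[::7]
    np.testing.assert_allclose(diff, expect, atol=5e-5)


def test_fd_oracle_epsilon_sweep_v_shape(shrunken_problem):
    """FD error vs the exact adjoint gradient is V-shaped in epsilon."""
    w = CostWeights(W2=1.0)
    u = _probe_control(shrunken_problem)
    traj = shrunken_problem.simulate(u)
    g = shrunken_problem.total_gradient(traj, u, w)
    errs = []
    for eps in (1e-2, 1e-6, 1e-10):
        g_fd = fd_gradient_oracle(shrunken_problem, u, w, epsilon=eps,
                                  stride=11)
        sl = slice(None, None, 11)
        errs.append(np.linalg.norm(g[sl] - g_fd[sl])
                    / np.linalg.norm(g[sl]))
    assert errs[1] < errs[0] and errs[1] < errs[2]


# ---------------------------------------------------------------------------
# line search and descent loop


def test_line_search_exact_on_halving_grid():
    """A quadratic with minimizer on the halving grid is hit exactly."""
    for k in (0, 2, 5):
        s_star = 10.0 / 2 ** k
        s = bisection_line_search(np.zeros(3), np.ones(3),
                                  lambda v: (v[0] - s_star) ** 2)
        assert s == s_star


def test_line_search_rejects_ascent_direction():
    s = bisection_line_search(np.zeros(2), np.ones(2),
                              lambda v: 1.0 + v[0] ** 2 + v[0])
    assert s == 0.0


@given(st.floats(0.05, 40.0), st.floats(-5.0, 5.0))
@hyp_settings(max_examples=30, deadline=None, derandomize=True)
def test_line_search_never_increases_cost(s_star, offset):
    def cost(v):
        return (v[0] - s_star) ** 2 + offset

    s = bisection_line_search(np.zeros(1), np.ones(1), cost)
    assert cost(np.array([s])) <= cost(np.zeros(1))


def test_optimize_terminates_on_optimal_start(params, table, setup_a):
    """From a settled state with its own rate as target, u = 0 is optimal."""
    target = TargetSpec(r_tilde=setup_a.down.r_E_Hz, t0=80.0, T=100.0)
    problem = ControlProblem(params, setup_a.background, table, setup_a.down,
                             target, dt=0.1)
    res = problem.optimize(problem.zero_control(), CostWeights(W1=1.0),
                           OptimizationSettings())
    assert res.converged
    assert res.iterations <= 2
    assert np.all(res.control.u_E == 0.0)


def test_optimize_cost_trace_monotone(shrunken_problem):
    res = shrunken_problem.optimize(_probe_control(shrunken_problem),
                                    CostWeights(W1=1.0),
                                    OptimizationSettings(),
                                    max_iterations=40)
    trace = res.cost_trace
    assert np.all(np.diff(trace) <= 1e-12)
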