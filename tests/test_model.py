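"""Mean-field model: algebraic update, delays, Euler integration, residuals."""

import numpy as np
import pytest

from neuroct import (BackgroundInput, ControlSignal, DelayedDrive,
                     ModelParameters, compute_delayed_drive, consistent_state,
                     mvms_to_nA, nA_to_mvms, residual_h, simulate)
from neuroct.model import IntegrationError, algebraic_update
from neuroct._kernels import pack_params


def test_unit_round_trip_is_exact():
    for value in (0.45, 0.475, -1.2345, 3.14159):
        assert mvms_to_nA(nA_to_mvms(value)) == value
    assert nA_to_mvms(0.2) == 1.0  # 0.2 nA per mV/ms at C = 200 pF


def test_background_input_conversion():
    bg = BackgroundInput.from_nA(0.45, 0.475)
    assert bg.mu_E_ext == pytest.approx(2.25)
    assert bg.as_nA == (0.45, 0.475)


def test_parameter_invariants():
    with pytest.raises(ValueError):
        ModelParameters(J_EI=+3.3)
    with pytest.raises(ValueError):
        ModelParameters(J_EE=-2.4)
    p = ModelParameters()
    assert p.tau_m == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# algebraic block


def test_sigma_reduces_to_external_noise(params, table_coarse):
    """All synaptic variances zero -> sigma equals the external amplitude."""
    st = algebraic_update((0.0, 0.0), (0,) * 4, (0,) * 4, DelayedDrive(),
                          params, table_coarse)
    assert st.sigma_E == pytest.approx(1.5)
    assert st.sigma_I == pytest.approx(1.5)


def test_algebraic_update_hits_table_nodes(params, table_coarse):
    """mu, sigma landing exactly on grid nodes return stored rate values."""
    t = table_coarse
    mu = float(t.mu_grid[60])
    # choose v_EE so that sigma_E lands exactly on a sigma grid node
    sig_target = float(t.sigma_grid[7])
    gEE = pack_params(params)[15]
    vee = (sig_target ** 2 - params.sigma_ext_E ** 2) / gEE
    st = algebraic_update((mu, 0.0), (0,) * 4, (vee, 0, 0, 0), DelayedDrive(),
                          params, t)
    assert st.sigma_E == pytest.approx(sig_target, rel=1e-14)
    assert st.r_E == pytest.approx(t.phi_r[60, 7], rel=1e-12)


def test_sigma_matches_independent_transcription(params, table_coarse):
    """sigma_E agrees with a from-scratch evaluation to 12 digits."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        v = rng.uniform(0, 0.02, 4)
        rd = rng.uniform(0, 5, 4)  # dimensionless delayed drives r_ab
        drive = DelayedDrive(r_EE=rd[0], r_EI=rd[1], r_IE=rd[2], r_II=rd[3])
        st = algebraic_update((0.5, 0.5), (0.1,) * 4, tuple(v), drive,
                              params, table_coarse)
        # independent transcription of the variance line
        tm = params.tau_m
        term_EE = 2 * params.J_EE ** 2 * v[0] * params.tau_s_E * tm \
            * (1 + rd[0]) / (tm + params.tau_s_E)
        term_EI = 2 * params.J_EI ** 2 * v[1] * params.tau_s_I * tm \
            * (1 + rd[1]) / (tm + params.tau_s_I)
        expected = np.sqrt(term_EE + term_EI + params.sigma_ext_E ** 2)
        assert st.sigma_E == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# delayed drives


def test_delayed_drive_constant_history_closed_form(params):
    r0 = 0.012  # kHz
    times = np.arange(0, 200.0, 0.1)
    ones = np.full_like(times, r0)
    d = compute_delayed_drive(times, ones, ones, params, 150.0)
    assert d.r_EE == pytest.approx(
        params.c_EE / abs(params.J_EE) * params.K_E * params.tau_s_E * r0)
    assert d.rho_EI == pytest.approx(
        (params.c_EI / params.J_EI) ** 2 * params.K_I
        * params.tau_s_I ** 2 * r0)


def test_delayed_drive_zero_history(params):
    times = np.arange(0, 100.0, 0.1)
    z = np.zeros_like(times)
    d = compute_delayed_drive(times, z, z, params, 50.0)
    for name in ("r_EE", "r_EI", "r_IE", "r_II",
                 "rho_EE", "rho_EI", "rho_IE", "rho_II"):
        assert getattr(d, name) == 0.0


def test_step_latency_is_receiver_delay(params):
    """A rate step at t=100 ms reaches r_EE at 104 ms and r_IE at 102 ms."""
    dt = 0.1
    times = np.arange(0, 200.0 + dt / 2, dt)
    rE = np.where(times >= 100.0, 0.02, 0.0)
    rI = np.zeros_like(times)

    def drives(t):
        return compute_delayed_drive(times, rE, rI, params, t)

    assert drives(104.0 - dt).r_EE == 0.0
    assert drives(104.0).r_EE > 0.0
    assert drives(102.0 - dt).r_IE == 0.0
    assert drives(102.0).r_IE > 0.0


def test_insufficient_history_raises(params):
    times = np.arange(50.0, 100.0, 0.1)
    z = np.zeros_like(times)
    with pytest.raises(ValueError, match="history"):
        compute_delayed_drive(times, z, z, params, 52.0)


# ---------------------------------------------------------------------------
# forward integration


def test_fixed_point_invariance(params, table, setup_a):
    """Free simulation from a settled state drifts < 1e-6 kHz over 500 ms."""
    for state in (setup_a.down, setup_a.up):
        traj = simulate(params, setup_a.background,
                        ControlSignal.zero(500.0, 0.1), state, table)
        assert np.max(np.abs(traj["r_E"] - traj["r_E"][0])) < 1e-6


def test_rectangle_pulse_switches_down_to_up(params, table, setup_a):
    """A +0.4 nA pulse on E over [210, 270] ms flips down -> up."""
    n = int(500 / 0.1) + 1
    t = 0.1 * np.arange(n)
    uE = np.where((t >= 210) & (t <= 270), 0.4, 0.0)
    u = ControlSignal.from_nA(0.1, uE, np.zeros(n))
    traj = simulate(params, setup_a.background, u, setup_a.down, table)
    assert traj.final_state.r_E_Hz > setup_a.down.r_E_Hz + 1.0
    assert traj.final_state.r_E_Hz == pytest.approx(setup_a.up.r_E_Hz,
                                                    abs=0.1)


def test_euler_error_scales_linearly_in_dt(params, table, setup_a):
    """sup-norm trajectory difference roughly halves from dt to dt/2."""

    def run(dt):
        n = int(200 / dt) + 1
        t = dt * np.arange(n)
        uE = np.where((t >= 50) & (t <= 90), 0.1, 0.0)
        u = ControlSignal.from_nA(dt, uE, np.zeros(n))
        return simulate(params, setup_a.background, u, setup_a.down, table)

    r1 = run(0.1)["r_E"][::1]
    r2 = run(0.05)["r_E"][::2]
    r4 = run(0.025)["r_E"][::4]
    e12 = np.max(np.abs(r1 - r4))
    e24 = np.max(np.abs(r2 - r4))
    assert 1.3 < e12 / e24 < 4.0


def test_time_invariance_of_autonomous_dynamics(params, table, setup_a):
    """Shifting the control shifts the trajectory (constant background)."""
    dt = 0.1

    def pulse(T, onset):
        n = int(T / dt) + 1
        t = dt * np.arange(n)
        uE = np.where((t >= onset) & (t <= onset + 40), 0.08, 0.0)
        return ControlSignal.from_nA(dt, uE, np.zeros(n))

    trajA = simulate(params, setup_a.background, pulse(300, 50),
                     setup_a.down, table)
    trajB = simulate(params, setup_a.background, pulse(350, 100),
                     setup_a.down, table)
    shift = int(50 / dt)
    diff = np.abs(trajB["r_E"][shift:] - trajA["r_E"])
    assert diff.max() < 1e-7


def test_dt_must_divide_delays(params, table, setup_a):
    with pytest.raises(ValueError, match="divide"):
        simulate(params, setup_a.background, ControlSignal.zero(10.0, 0.3),
                 setup_a.down, table)


def test_blowup_reports_step_index(params, table, setup_a):
    n = int(100 / 0.1) + 1
    u = ControlSignal.from_nA(0.1, np.full(n, 5.0), np.full(n, -5.0))
    with pytest.raises(IntegrationError) as err:
        simulate(params, setup_a.background, u, setup_a.down, table,
                 clamp=True)
    assert err.value.step >= 0


# ---------------------------------------------------------------------------
# residual form


def _independent_residual(x_dot, x, xdE, xdI, u, p, bg):
    """Second, independent transcription of the model equations."""
    names = ("rE", "rI", "muE", "muI", "sE", "sI", "tE", "tI",
             "see", "sei", "sie", "sii", "vee", "vei", "vie", "vii")
    d = dict(zip(names, x))
    tm = p.tau_m
    out = np.empty(16)
    # delayed drives, receiver-indexed
    conv = {}
    for pair, (c, J, K, ts, rd) in {
            "EE": (p.c_EE, p.J_EE, p.K_E, p.tau_s_E, xdE[0]),
            "EI": (p.c_EI, p.J_EI, p.K_I, p.tau_s_I, xdE[1]),
            "IE": (p.c_IE, p.J_IE, p.K_E, p.tau_s_E, xdI[0]),
            "II": (p.c_II, p.J_II, p.K_I, p.tau_s_I, xdI[1])}.items():
        conv[pair] = (c / abs(J) * K * ts * rd,
                      (c / J) ** 2 * K * ts ** 2 * rd)
    out[2] = x_dot[2] - (p.J_EE * d["see"] + p.J_EI * d["sei"]
                         + bg.mu_E_ext + u[0] - d["muE"]) / d["tE"]
    out[3] = x_dot[3] - (p.J_IE * d["sie"] + p.J_II * d["sii"]
                         + bg.mu_I_ext + u[1] - d["muI"]) / d["tI"]
    out[4] = d["sE"] - np.sqrt(
        2 * p.J_EE ** 2 * d["vee"] * p.tau_s_E * tm * (1 + conv["EE"][0])
        / (tm + p.tau_s_E)
        + 2 * p.J_EI ** 2 * d["vei"] * p.tau_s_I * tm * (1 + conv["EI"][0])
        / (tm + p.tau_s_I) + p.sigma_ext_E ** 2)
    out[5] = d["sI"] - np.sqrt(
        2 * p.J_IE ** 2 * d["vie"] * p.tau_s_E * tm * (1 + conv["IE"][0])
        / (tm + p.tau_s_E)
        + 2 * p.J_II ** 2 * d["vii"] * p.tau_s_I * tm * (1 + conv["II"][0])
        / (tm + p.tau_s_I) + p.sigma_ext_I ** 2)
    for row, (sname, pair, ts) in zip(
            (8, 9, 10, 11),
            [("see", "EE", p.tau_s_E), ("sei", "EI", p.tau_s_I),
             ("sie", "IE", p.tau_s_E), ("sii", "II", p.tau_s_I)]):
        s = d[sname]
        out[row] = x_dot[row] + s / ts - (1 - s) * conv[pair][0] / ts
    for row, (sname, vname, pair, ts) in zip(
            (12, 13, 14, 15),
            [("see", "vee", "EE", p.tau_s_E), ("sei", "vei", "EI", p.tau_s_I),
             ("sie", "vie", "IE", p.tau_s_E), ("sii", "vii", "II", p.tau_s_I)]):
        s, v = d[sname], d[vname]
        rab, rho = conv[pair]
        out[row] = x_dot[row] - ((1 - s) ** 2 * rho
                                 + (rho - 2 * ts * (rab + 1)) * v) / ts ** 2
    return out


def test_residual_matches_independent_transcription(params, table_coarse,
                                                    setup_a):
    """All non-table residual rows agree to 12 digits with a second
    hand-written transcription of the model equations."""
    bg = setup_a.background
    rng = np.random.default_rng(5)
    rows = [2, 3, 4, 5, 8, 9, 10, 11, 12, 13, 14, 15]
    for _ in range(10):
        y = np.concatenate([
            rng.uniform(-1, 2, 2),          # mu
            rng.uniform(0.05, 0.9, 4),      # s
            rng.uniform(0.0, 0.01, 4),      # v
        ])
        st = consistent_state(y, params, table_coarse)
        x = st.to_array()
        x_dot = rng.normal(0, 0.1, 16)
        xdE = rng.uniform(0, 0.05, 2)
        xdI = rng.uniform(0, 0.05, 2)
        u = rng.uniform(-1, 1, 2)
        h = residual_h(x_dot, x, xdE, xdI, u, params, bg, table_coarse)
        h2 = _independent_residual(x_dot, x, xdE, xdI, u, params, bg)
        for row in rows:
            assert h[row] == pytest.approx(h2[row], rel=1e-12, abs=1e-12)


def test_residual_vanishes_along_trajectory(params, table, setup_a):
    """Algebraic rows ~ 0 and differential rows O(dt) on a simulated path."""
    dt = 0.1
    n = int(100 / dt) + 1
    t = dt * np.arange(n)
    uE = np.where((t >= 20) & (t <= 60), 0.05, 0.0)
    control = ControlSignal.from_nA(dt, uE, np.zeros(n))
    traj = simulate(params, setup_a.background, control, setup_a.down, table)
    X = traj.X
    hist = setup_a.down.to_array()
    mE, mI = int(4 / dt), int(2 / dt)
    alg = [0, 1, 4, 5, 6, 7]
    diff = [2, 3, 8, 9, 10, 11, 12, 13, 14, 15]
    for k in (5, 100, 500, 900):
        x_dot = np.zeros(16)
        x_dot[diff] = (X[k + 1, diff] - X[k, diff]) / dt
        xdE = X[k - mE, :2] if k >= mE else hist[:2]
        xdI = X[k - mI, :2] if k >= mI else hist[:2]
        u = np.array([control.u_E[k], control.u_I[k]])
        h = residual_h(x_dot, X[k], xdE, xdI, u, params, setup_a.background,
                       table)
        assert np.max(np.abs(h[alg])) < 1e-12
        assert np.max(np.abs(h[diff])) < 1e-10  # Euler difference quotients
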