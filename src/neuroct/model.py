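"""Forward simulation of the two-population EIF mean-field model.

The model couples an excitatory (E) and an inhibitory (I) population.  Each
population is described by its mean membrane current ``mu_alpha`` and the
four synaptic channels by their mean activity ``s_ab`` and activity variance
``v_ab = sigma_s,ab^2`` (ten differential variables).  Six algebraic
variables follow instantaneously: the population rates
``r_alpha = Phi_r(mu_alpha, sigma_alpha)``, the membrane-current noise
amplitudes ``sigma_alpha`` and the effective timescales
``tau_alpha = Phi_tau(mu_alpha, sigma_alpha)``.  Rates reach the synapses
after the receiver-indexed delays ``d_E``/``d_I``, which makes the system a
delay differential-algebraic equation (DDAE); it is integrated with forward
Euler on a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import BackgroundInput, ModelParameters, mvms_to_nA, nA_to_mvms
from .transfer import TableRangeError, TransferTable

__all__ = [
    "STATE_NAMES",
    "SystemState",
    "DelayedDrive",
    "ControlSignal",
    "Trajectory",
    "IntegrationError",
    "algebraic_update",
    "compute_delayed_drive",
    "simulate",
    "residual_h",
    "settle_to_fixed_point",
    "consistent_state",
]

STATE_NAMES = (
    "r_E", "r_I", "mu_E", "mu_I", "sigma_E", "sigma_I", "tau_E", "tau_I",
    "s_EE", "s_EI", "s_IE", "s_II", "v_EE", "v_EI", "v_IE", "v_II",
)

#: canonical-order indices of the ten differential components
DIFF_IDX = np.array([2, 3, 8, 9, 10, 11, 12, 13, 14, 15])
#: canonical-order indices of the six algebraic components
ALG_IDX = np.array([0, 1, 4, 5, 6, 7])

PAIRS = ("EE", "EI", "IE", "II")


class IntegrationError(RuntimeError):
    """The forward integration violated a state invariant."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"state invariant violated at step {step}")


@dataclass
class SystemState:
    """All 16 model variables at one instant (internal units)."""

    r_E: float = 0.0
    r_I: float = 0.0
    mu_E: float = 0.0
    mu_I: float = 0.0
    sigma_E: float = 1.5
    sigma_I: float = 1.5
    tau_E: float = 20.0
    tau_I: float = 20.0
    s_EE: float = 0.0
    s_EI: float = 0.0
    s_IE: float = 0.0
    s_II: float = 0.0
    v_EE: float = 0.0
    v_EI: float = 0.0
    v_IE: float = 0.0
    v_II: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "SystemState":
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, x)})

    def diff_vars(self) -> np.ndarray:
        """The ten differential components in kernel ordering."""
        return self.to_array()[DIFF_IDX]

    @property
    def r_E_Hz(self) -> float:
        return 1000.0 * self.r_E

    @property
    def r_I_Hz(self) -> float:
        return 1000.0 * self.r_I

    def validate(self) -> None:
        if self.r_E < 0 or self.r_I < 0:
            raise ValueError("rates must be non-negative")
        if self.sigma_E <= 0 or self.sigma_I <= 0 or self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("sigma and tau must be positive")
        for p in PAIRS:
            s = getattr(self, f"s_{p}")
            v = getattr(self, f"v_{p}")
            if not (0.0 <= s <= 1.0) or v < 0:
                raise ValueError(f"synaptic channel {p} out of range: s={s}, v={v}")


@dataclass
class DelayedDrive:
    """Delayed synaptic drives r_ab (dimensionless) and rho_ab (ms)."""

    r_EE: float = 0.0
    r_EI: float = 0.0
    r_IE: float = 0.0
    r_II: float = 0.0
    rho_EE: float = 0.0
    rho_EI: float = 0.0
    rho_IE: float = 0.0
    rho_II: float = 0.0

    def validate(self) -> None:
        for name in ("r_EE", "r_EI", "r_IE", "r_II",
                     "rho_EE", "rho_EI", "rho_IE", "rho_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ControlSignal:
    """Two-channel control time series on a uniform grid.

    Internally stored in mV/ms (the unit in which the control enters the
    membrane-current equations); user-facing accessors convert to nA via the
    membrane capacitance.
    """

    dt: float
    u_E: np.ndarray
    u_I: np.ndarray
    C: float = 200.0

    def __post_init__(self) -> None:
        self.u_E = np.ascontiguousarray(self.u_E, dtype=np.float64)
        self.u_I = np.ascontiguousarray(self.u_I, dtype=np.float64)
        if self.u_E.shape != self.u_I.shape or self.u_E.ndim != 1:
            raise ValueError("u_E and u_I must be 1-d arrays of equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def zero(cls, T: float, dt: float, C: float = 200.0) -> "ControlSignal":
        n = int(round(T / dt))
        return cls(dt, np.zeros(n + 1), np.zeros(n + 1), C)

    @classmethod
    def from_nA(cls, dt: float, u_E_nA, u_I_nA, C: float = 200.0) -> "ControlSignal":
        f = 1000.0 / C
        return cls(dt, np.asarray(u_E_nA) * f, np.asarray(u_I_nA) * f, C)

    @property
    def t(self) -> np.ndarray:
        return self.dt * np.arange(self.u_E.size)

    @property
    def T(self) -> float:
        return self.dt * (self.u_E.size - 1)

    @property
    def u_E_nA(self) -> np.ndarray:
        return self.u_E * (self.C / 1000.0)

    @property
    def u_I_nA(self) -> np.ndarray:
        return self.u_I * (self.C / 1000.0)

    def as_nA(self) -> np.ndarray:
        """Stacked (2, N+1) array in nA."""
        return np.vstack([self.u_E_nA, self.u_I_nA])

    def copy(self) -> "ControlSignal":
        return ControlSignal(self.dt, self.u_E.copy(), self.u_I.copy(), self.C)


@dataclass
class Trajectory:
    """Simulated model trajectory on a uniform time grid."""

    t: np.ndarray
    X: np.ndarray                      # (N+1, 16) canonical ordering
    control: ControlSignal
    params: ModelParameters
    background: BackgroundInput
    history: SystemState = field(default_factory=SystemState)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def T(self) -> float:
        return float(self.t[-1])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.X[:, STATE_NAMES.index(name)]

    def state_at(self, k: int) -> SystemState:
        return SystemState.from_array(self.X[k])

    @property
    def final_state(self) -> SystemState:
        return self.state_at(-1)

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.t}
        for i, n in enumerate(STATE_NAMES):
            data[n] = self.X[:, i]
        data["u_E_nA"] = self.control.u_E_nA
        data["u_I_nA"] = self.control.u_I_nA
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary operations


def compute_delayed_drive(times: np.ndarray, r_E: np.ndarray, r_I: np.ndarray,
                          params: ModelParameters, t: float) -> DelayedDrive:
    """Delayed drives at time t from a sampled rate history.

    ``r_ab(t) = (c_ab/|J_ab|) K_b tau_s,b r_b(t - d_a)`` and
    ``rho_ab(t) = (c_ab/J_ab)^2 K_b tau_s,b^2 r_b(t - d_a)``; the delay is
    indexed by the receiving population ``a``.
    """
    times = np.asarray(times, float)
    for d in (params.d_E, params.d_I):
        if t - d < times[0] - 1e-12:
            raise ValueError(
                f"rate history starts at t={times[0]:g} ms, need t={t - d:g} ms"
            )
    rE_dE = float(np.interp(t - params.d_E, times, r_E))
    rI_dE = float(np.interp(t - params.d_E, times, r_I))
    rE_dI = float(np.interp(t - params.d_I, times, r_E))
    rI_dI = float(np.interp(t - params.d_I, times, r_I))
    P = _kernels.pack_params(params)
    return DelayedDrive(
        r_EE=P[4] * rE_dE, r_EI=P[5] * rI_dE,
        r_IE=P[6] * rE_dI, r_II=P[7] * rI_dI,
        rho_EE=P[8] * rE_dE, rho_EI=P[9] * rI_dE,
        rho_IE=P[10] * rE_dI, rho_II=P[11] * rI_dI,
    )


def algebraic_update(mu: tuple[float, float], sbar, var_s,
                     drive: DelayedDrive, params: ModelParameters,
                     table: TransferTable, clamp: bool = False) -> SystemState:
    """Resolve the six algebraic variables given the differential ones.

    ``mu`` is (mu_E, mu_I), ``sbar`` and ``var_s`` are (EE, EI, IE, II)
    tuples.  Computes sigma_alpha from the synaptic variances and the
    delayed drives, then the rates and effective timescales from the
    transfer tables.  The returned state satisfies the algebraic residual
    rows exactly.
    """
    P = _kernels.pack_params(params)
    gEE, gEI, gIE, gII = P[15], P[16], P[17], P[18]
    vee, vei, vie, vii = var_s
    SE = (gEE * vee * (1.0 + drive.r_EE) + gEI * vei * (1.0 + drive.r_EI)
          + params.sigma_ext_E ** 2)
    SI = (gIE * vie * (1.0 + drive.r_IE) + gII * vii * (1.0 + drive.r_II)
          + params.sigma_ext_I ** 2)
    if SE <= 0 or SI <= 0:
        raise ValueError("membrane-current variance must be positive")
    sigma_E, sigma_I = float(np.sqrt(SE)), float(np.sqrt(SI))
    rE, tauE, *_ = table.interpolate(mu[0], sigma_E, clamp=clamp)
    rI, tauI, *_ = table.interpolate(mu[1], sigma_I, clamp=clamp)
    return SystemState(
        r_E=rE, r_I=rI, mu_E=mu[0], mu_I=mu[1],
        sigma_E=sigma_E, sigma_I=sigma_I, tau_E=tauE, tau_I=tauI,
        s_EE=sbar[0], s_EI=sbar[1], s_IE=sbar[2], s_II=sbar[3],
        v_EE=var_s[0], v_EI=var_s[1], v_IE=var_s[2], v_II=var_s[3],
    )


def consistent_state(y: np.ndarray, params: ModelParameters,
                     table: TransferTable, clamp: bool = False,
                     n_iter: int = 100, tol: float = 1e-14) -> SystemState:
    """Self-consistent full state for constant history.

    Under a constant rate history the delayed rates equal the instantaneous
    ones, which makes the algebraic block an implicit fixed point
    ``r = Phi_r(mu, sigma(v, r))``; it is resolved by damped iteration.
    """
    y = np.asarray(y, float)
    mu = (y[0], y[1])
    sbar = tuple(y[2:6])
    var_s = tuple(y[6:10])
    P = _kernels.pack_params(params)
    rE, rI = 0.0, 0.0
    state = None
    for _ in range(n_iter):
        drive = DelayedDrive(
            r_EE=P[4] * rE, r_EI=P[5] * rI, r_IE=P[6] * rE, r_II=P[7] * rI,
            rho_EE=P[8] * rE, rho_EI=P[9] * rI, rho_IE=P[10] * rE,
            rho_II=P[11] * rI,
        )
        state = algebraic_update(mu, sbar, var_s, drive, params, table,
                                 clamp=clamp)
        if abs(state.r_E - rE) < tol and abs(state.r_I - rI) < tol:
            break
        rE, rI = state.r_E, state.r_I
    return state


def simulate(params: ModelParameters, background: BackgroundInput,
             control: ControlSignal, initial: SystemState,
             table: TransferTable, clamp: bool = False,
             s_tol: float = _kernels.DEFAULT_S_TOL) -> Trajectory:
    """Forward Euler integration of the controlled DDAE system.

    The pre-t=0 history is constant at ``initial`` (the tasks always start
    from a settled fixed point).  ``dt`` must divide both synaptic delays.
    """
    dt = control.dt
    mE = int(round(params.d_E / dt))
    mI = int(round(params.d_I / dt))
    if abs(mE * dt - params.d_E) > 1e-9 or abs(mI * dt - params.d_I) > 1e-9:
        raise ValueError(f"dt={dt} must divide the delays d_E={params.d_E}, "
                         f"d_I={params.d_I}")
    P = _kernels.pack_params(params)
    X, status, bad, bad_mu, bad_sig = _kernels.forward_sim(
        initial.diff_vars(), initial.r_E, initial.r_I,
        control.u_E, control.u_I,
        background.mu_E_ext, background.mu_I_ext,
        P, table.mu_grid, table.sigma_grid, table.phi_r, table.phi_tau,
        dt, mE, mI, 1 if clamp else 0, s_tol)
    if status == 1:
        raise TableRangeError(bad_mu, bad_sig, table)
    if status == 2:
        raise IntegrationError(bad)
    t = dt * np.arange(X.shape[0])
    return Trajectory(t=t, X=X, control=control, params=params,
                      background=background, history=initial)


def residual_h(x_dot: np.ndarray, x: np.ndarray, x_delay_E: np.ndarray,
               x_delay_I: np.ndarray, u: np.ndarray,
               params: ModelParameters, background: BackgroundInput,
               table: TransferTable, clamp: bool = False) -> np.ndarray:
    """The 16 residual rows h(x_dot, x, x(t-d_E), x(t-d_I), u) of the model.

    Row ordering matches :data:`STATE_NAMES`; ``u`` is (u_E, u_I) in mV/ms.
    Algebraic rows have no ``x_dot`` entry; differential rows are
    ``x_dot_i - f_i``.
    """
    P = _kernels.pack_params(params)
    JEE, JEI, JIE, JII = P[0], P[1], P[2], P[3]
    aEE, aEI, aIE, aII = P[4], P[5], P[6], P[7]
    bEE, bEI, bIE, bII = P[8], P[9], P[10], P[11]
    tsE, tsI = P[12], P[13]
    gEE, gEI, gIE, gII = P[15], P[16], P[17], P[18]

    (rE, rI, muE, muI, sigE, sigI, tauE, tauI,
     see, sei, sie, sii, vee, vei, vie, vii) = x
    rEE, rEI = aEE * x_delay_E[0], aEI * x_delay_E[1]
    rIE, rII = aIE * x_delay_I[0], aII * x_delay_I[1]
    rhoEE, rhoEI = bEE * x_delay_E[0], bEI * x_delay_E[1]
    rhoIE, rhoII = bIE * x_delay_I[0], bII * x_delay_I[1]

    phiE = table.interpolate(muE, sigE, clamp=clamp)
    phiI = table.interpolate(muI, sigI, clamp=clamp)

    h = np.empty(16)
    h[0] = rE - phiE[0]
    h[1] = rI - phiI[0]
    h[2] = x_dot[2] - (JEE * see + JEI * sei + background.mu_E_ext
                       + u[0] - muE) / tauE
    h[3] = x_dot[3] - (JIE * sie + JII * sii + background.mu_I_ext
                       + u[1] - muI) / tauI
    h[4] = sigE - np.sqrt(gEE * vee * (1.0 + rEE) + gEI * vei * (1.0 + rEI)
                          + params.sigma_ext_E ** 2)
    h[5] = sigI - np.sqrt(gIE * vie * (1.0 + rIE) + gII * vii * (1.0 + rII)
                          + params.sigma_ext_I ** 2)
    h[6] = tauE - phiE[1]
    h[7] = tauI - phiI[1]
    h[8] = x_dot[8] + see / tsE - (1.0 - see) * rEE / tsE
    h[9] = x_dot[9] + sei / tsI - (1.0 - sei) * rEI / tsI
    h[10] = x_dot[10] + sie / tsE - (1.0 - sie) * rIE / tsE
    h[11] = x_dot[11] + sii / tsI - (1.0 - sii) * rII / tsI
    h[12] = x_dot[12] - ((1.0 - see) ** 2 * rhoEE
                         + (rhoEE - 2.0 * tsE * (rEE + 1.0)) * vee) / tsE ** 2
    h[13] = x_dot[13] - ((1.0 - sei) ** 2 * rhoEI
                         + (rhoEI - 2.0 * tsI * (rEI + 1.0)) * vei) / tsI ** 2
    h[14] = x_dot[14] - ((1.0 - sie) ** 2 * rhoIE
                         + (rhoIE - 2.0 * tsE * (rIE + 1.0)) * vie) / tsE ** 2
    h[15] = x_dot[15] - ((1.0 - sii) ** 2 * rhoII
                         + (rhoII - 2.0 * tsI * (rII + 1.0)) * vii) / tsI ** 2
    return h


def settle_to_fixed_point(params: ModelParameters, background: BackgroundInput,
                          initial_guess: SystemState, table: TransferTable,
                          max_T: float = 6000.0, dt: float = 0.1,
                          window: float = 50.0, tol: float = 1e-9,
                          clamp: bool = False):
    """Free-run the model until the state is stationary.

    Simulates with u = 0 until the sup-norm difference between the state at
    ``t`` and at ``t - window`` drops below ``tol``, or ``max_T`` is
    reached.  Returns ``(state, converged)``; oscillatory or non-settling
    dynamics yield ``converged=False``.
    """
    control = ControlSignal.zero(max_T, dt, C=params.C)
    traj = simulate(params, background, control, initial_guess, table,
                    clamp=clamp)
    m = int(round(window / dt))
    X = traj.X
    for k in range(m, X.shape[0], max(m // 10, 1)):
        if np.max(np.abs(X[k] - X[k - m])) < tol:
            return traj.state_at(k), True
    return traj.final_state, False
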