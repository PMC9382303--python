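"""Cost functionals, adjoint gradients and gradient-descent optimization.

The control task is to steer the mean-field model from a settled fixed point
to a target excitatory rate ``r~`` by adding currents u_E(t), u_I(t) to the
membrane-current equations.  The total cost

    F = F_P + W1 * F1 + W2 * F2

combines the precision cost

    F_P = 1/2 * 1/(T - t0) * int_t0^T (r_E(t) - r~)^2 dt      [r in Hz]

with a sparsity-promoting cost F1 = sum_a sqrt(int_0^T u_a^2 dt) and an
energy cost F2 = 1/2 int_0^T ||u||^2 dt, with u measured in nA and t in ms.
All cost integrals use trapezoid quadrature on the simulation grid.

The gradient of F with respect to the control is assembled from the adjoint
(costate) system, which is integrated backward in time on the forward grid;
the delayed couplings of the DDAE turn into time-advanced costate terms that
vanish for t > T - d_alpha, and the algebraic rows are eliminated pointwise.
The implementation is the exact discrete adjoint of the forward Euler
scheme, so the adjoint gradient matches finite differences of the discrete
cost to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .model import (ControlSignal, SystemState, Trajectory, simulate)
from .params import BackgroundInput, ModelParameters
from .transfer import TransferTable

__all__ = [
    "CostWeights",
    "TargetSpec",
    "CostBreakdown",
    "AdjointState",
    "OptimizationSettings",
    "OptimizationResult",
    "ControlProblem",
    "evaluate_cost",
    "running_cost_gradient",
    "system_jacobians",
    "bisection_line_search",
    "fd_gradient_oracle",
]


@dataclass(frozen=True)
class CostWeights:
    """Weights of the control-strength penalties (dimensionless)."""

    W1: float = 0.0
    W2: float = 0.0

    def __post_init__(self):
        if self.W1 < 0 or self.W2 < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class TargetSpec:
    """Target excitatory rate and the precision-measurement window."""

    r_tilde: float          # Hz
    t0: float = 480.0       # ms, precision onset
    T: float = 500.0        # ms, horizon
    precision_mask: str = "r_E"

    def __post_init__(self):
        if not (0 <= self.t0 < self.T):
            raise ValueError("require 0 <= t0 < T")
        if self.precision_mask != "r_E":
            raise NotImplementedError(
                "only the excitatory-rate precision cost is supported")


@dataclass
class CostBreakdown:
    F_P: float
    F1_E: float
    F1_I: float
    F2_E: float
    F2_I: float
    weights: CostWeights

    @property
    def F1(self) -> float:
        return self.F1_E + self.F1_I

    @property
    def F2(self) -> float:
        return self.F2_E + self.F2_I

    @property
    def total(self) -> float:
        return self.F_P + self.weights.W1 * self.F1 + self.weights.W2 * self.F2

    def at_weights(self, weights: CostWeights) -> "CostBreakdown":
        return replace(self, weights=weights)


@dataclass
class AdjointState:
    """16-component costate time series on the simulation grid."""

    t: np.ndarray
    lam: np.ndarray     # (N+1, 16)


@dataclass(frozen=True)
class OptimizationSettings:
    s_init: float = 10.0
    eps_s: float = 1e-30
    eps_u: float = 1e-12
    max_iterations: int = 2000
    anneal_period: int = 30          # iterations between weight redraws
    max_anneal_blocks: int = 20
    cost_rtol: float = 1e-10         # relative block-to-block cost change
    rng_seed: int = 0

    def __post_init__(self):
        if self.s_init <= 0 or self.eps_s <= 0 or self.eps_u <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class OptimizationResult:
    control: ControlSignal
    cost: CostBreakdown
    iterations: int
    converged: bool
    cost_trace: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.cost.total


# ---------------------------------------------------------------------------
# cost evaluation


def _channel_sq_integrals(control: ControlSignal) -> tuple[float, float]:
    """Trapezoid integrals of u_alpha^2 dt with u in nA."""
    dt = control.dt
    iE = float(np.trapezoid(control.u_E_nA ** 2, dx=dt))
    iI = float(np.trapezoid(control.u_I_nA ** 2, dx=dt))
    return iE, iI


def evaluate_cost(traj: Trajectory, control: ControlSignal,
                  target: TargetSpec, weights: CostWeights) -> CostBreakdown:
    """Cost breakdown of a trajectory/control pair (u in nA, t in ms)."""
    dt = control.dt
    if abs(traj.dt - dt) > 1e-12 or traj.X.shape[0] != control.u_E.size:
        raise ValueError("trajectory and control must share the time grid")
    k0 = int(round(target.t0 / dt))
    N = control.u_E.size - 1
    if abs(k0 * dt - target.t0) > 1e-9 or abs(N * dt - target.T) > 1e-9:
        raise ValueError("t0 and T must lie on the simulation grid")
    rE_Hz = 1000.0 * traj["r_E"][k0:]
    F_P = 0.5 * float(np.trapezoid((rE_Hz - target.r_tilde) ** 2, dx=dt)) \
        / (target.T - target.t0)
    iE, iI = _channel_sq_integrals(control)
    return CostBreakdown(F_P=F_P, F1_E=np.sqrt(iE), F1_I=np.sqrt(iI),
                         F2_E=0.5 * iE, F2_I=0.5 * iI, weights=weights)


def running_cost_gradient(control: ControlSignal,
                          weights: CostWeights) -> np.ndarray:
    """Pointwise gradient of W1*f1 + W2*f2 w.r.t. u in nA, shape (N+1, 2).

    The sparsity branch normalizes each channel by its own L2 time-norm,
    with gradient zero on identically-zero channels; the energy branch is
    simply u itself.
    """
    iE, iI = _channel_sq_integrals(control)
    g = np.zeros((control.u_E.size, 2))
    uE, uI = control.u_E_nA, control.u_I_nA
    if weights.W1 > 0:
        if iE > 0:
            g[:, 0] += weights.W1 * uE / np.sqrt(iE)
        if iI > 0:
            g[:, 1] += weights.W1 * uI / np.sqrt(iI)
    if weights.W2 > 0:
        g[:, 0] += weights.W2 * uE
        g[:, 1] += weights.W2 * uI
    return g


# ---------------------------------------------------------------------------
# the control problem object


class ControlProblem:
    """A switching/tracking task on the E-I mean-field model.

    Bundles the model parameters, background point, transfer table, initial
    (settled) state and the cost target, and exposes simulation, cost,
    adjoint-gradient and gradient-descent optimization on a fixed grid.
    """

    def __init__(self, params: ModelParameters, background: BackgroundInput,
                 table: TransferTable, initial: SystemState,
                 target: TargetSpec, dt: float = 0.1, clamp: bool = False,
                 s_tol: float = _kernels.DEFAULT_S_TOL):
        self.params = params
        self.background = background
        self.table = table
        self.initial = initial
        self.target = target
        self.dt = dt
        self.clamp = clamp
        self.s_tol = s_tol
        self.N = int(round(target.T / dt))
        self.k0 = int(round(target.t0 / dt))
        if abs(self.N * dt - target.T) > 1e-9 or abs(self.k0 * dt - target.t0) > 1e-9:
            raise ValueError("T and t0 must be multiples of dt")
        self.mE = int(round(params.d_E / dt))
        self.mI = int(round(params.d_I / dt))
        if abs(self.mE * dt - params.d_E) > 1e-9 or abs(self.mI * dt - params.d_I) > 1e-9:
            raise ValueError("dt must divide the synaptic delays")
        self._P = _kernels.pack_params(params)
        # nA per internal mV/ms
        self._nA_per_mv = params.C / 1000.0

    # -- basic operations -------------------------------------------------

    def zero_control(self) -> ControlSignal:
        return ControlSignal.zero(self.target.T, self.dt, C=self.params.C)

    def simulate(self, control: ControlSignal) -> Trajectory:
        return simulate(self.params, self.background, control, self.initial,
                        self.table, clamp=self.clamp, s_tol=self.s_tol)

    def evaluate(self, control: ControlSignal,
                 weights: CostWeights) -> CostBreakdown:
        return evaluate_cost(self.simulate(control), control, self.target,
                             weights)

    def _precision_cost_raw(self, uE_mv: np.ndarray, uI_mv: np.ndarray) -> float:
        fp, status = _kernels.forward_precision_cost(
            self.initial.diff_vars(), self.initial.r_E, self.initial.r_I,
            uE_mv, uI_mv, self.background.mu_E_ext, self.background.mu_I_ext,
            self._P, self.table.mu_grid, self.table.sigma_grid,
            self.table.phi_r, self.table.phi_tau, self.dt, self.mE, self.mI,
            1 if self.clamp else 0, self.s_tol, self.k0, self.target.r_tilde)
        return fp

    # -- adjoint gradient -------------------------------------------------

    def solve_adjoint(self, traj: Trajectory) -> AdjointState:
        """Backward (adjoint) pass for the precision cost; lam(T) = 0."""
        _, lam = self._adjoint_raw(traj)
        return AdjointState(t=traj.t, lam=lam)

    def _adjoint_raw(self, traj: Trajectory):
        return _kernels.adjoint_precision_gradient(
            traj.X, traj.history.r_E, traj.history.r_I,
            traj.control.u_E, traj.control.u_I,
            self.background.mu_E_ext, self.background.mu_I_ext,
            self._P, self.table.mu_grid, self.table.sigma_grid,
            self.table.phi_r, self.table.phi_tau, self.dt, self.mE, self.mI,
            1 if self.clamp else 0, self.k0, self.target.r_tilde)

    def _trapz_weights(self) -> np.ndarray:
        w = np.full(self.N + 1, self.dt)
        w[0] = w[-1] = 0.5 * self.dt
        return w

    def total_gradient(self, traj: Trajectory, control: ControlSignal,
                       weights: CostWeights, units: str = "nA") -> np.ndarray:
        """Functional gradient density g(t) per channel, shape (N+1, 2).

        ``int g(t) du(t) dt`` (trapezoid) equals the first variation of the
        total cost; with ``units='nA'`` the perturbation du is measured in
        nA, with ``units='mv'`` in mV/ms.
        """
        ubar, _ = self._adjoint_raw(traj)
        w = self._trapz_weights()
        g_nA = running_cost_gradient(control, weights) \
            + (ubar / w[:, None]) / self._nA_per_mv
        if units == "nA":
            return g_nA
        elif units == "mv":
            return g_nA * self._nA_per_mv
        raise ValueError(f"unknown units {units!r}")

    # -- scalar cost for the line search ----------------------------------

    def _total_cost_mv(self, uE_mv, uI_mv, weights: CostWeights,
                       quad: tuple | None = None, s: float = 0.0) -> float:
        """Total cost of u (mV/ms samples); control quadratics optional.

        ``quad = (AE, BE, CE, AI, BI, CI)`` are the coefficients of
        int (u0 + s d)^2 dt per channel in nA^2 ms, so the strength costs
        are closed-form in the step size s.
        """
        fp = self._precision_cost_raw(uE_mv, uI_mv)
        if not np.isfinite(fp):
            return np.inf
        if quad is None:
            c = ControlSignal(self.dt, uE_mv, uI_mv, C=self.params.C)
            iE, iI = _channel_sq_integrals(c)
        else:
            AE, BE, CE, AI, BI, CI = quad
            iE = max(AE + 2 * BE * s + CE * s * s, 0.0)
            iI = max(AI + 2 * BI * s + CI * s * s, 0.0)
        return (fp + weights.W1 * (np.sqrt(iE) + np.sqrt(iI))
                + weights.W2 * 0.5 * (iE + iI))

    # -- optimization ------------------------------------------------------

    def optimize(self, control0: ControlSignal, weights: CostWeights,
                 settings: OptimizationSettings | None = None,
                 mask: tuple[bool, bool] = (True, True),
                 max_iterations: int | None = None,
                 callback=None) -> OptimizationResult:
        """Gradient descent with bisection line search at fixed weights.

        Iterates forward simulation, adjoint pass, descent step
        ``d = -(grad_u f + lam^T D_u h)`` masked to the allowed channels,
        and a halving line search started at ``s_init``; terminates when
        the control update stays below ``eps_u`` in every component or the
        iteration budget is exhausted.  Accepted iterations never increase
        the cost.
        """
        settings = settings or OptimizationSettings()
        max_iter = max_iterations if max_iterations is not None \
            else settings.max_iterations
        uE = control0.u_E.copy()
        uI = control0.u_I.copy()
        w = self._trapz_weights()
        trace = []
        converged = False
        it = 0
        cost = self._total_cost_mv(uE, uI, weights)
        if not np.isfinite(cost):
            raise ValueError("initial control yields an infeasible trajectory")
        for it in range(1, max_iter + 1):
            control = ControlSignal(self.dt, uE, uI, C=self.params.C)
            traj = self.simulate(control)
            g_mv = self.total_gradient(traj, control, weights, units="mv")
            dE = -g_mv[:, 0] if mask[0] else np.zeros_like(uE)
            dI = -g_mv[:, 1] if mask[1] else np.zeros_like(uI)
            if max(np.max(np.abs(dE)), np.max(np.abs(dI))) == 0.0:
                trace.append(cost)
                converged = True
                break
            # closed-form channel quadratics in the step size (nA^2 ms)
            f2 = self._nA_per_mv ** 2
            AE = float(np.sum(w * uE * uE)) * f2
            BE = float(np.sum(w * uE * dE)) * f2
            CE = float(np.sum(w * dE * dE)) * f2
            AI = float(np.sum(w * uI * uI)) * f2
            BI = float(np.sum(w * uI * dI)) * f2
            CI = float(np.sum(w * dI * dI)) * f2
            quad = (AE, BE, CE, AI, BI, CI)

            def cost_at(s):
                return self._total_cost_mv(uE + s * dE, uI + s * dI,
                                           weights, quad=quad, s=s)

            s, new_cost = _line_search(cost_at, cost, settings)
            trace.append(cost)
            if s == 0.0:
                converged = True
                break
            uE = uE + s * dE
            uI = uI + s * dI
            cost = new_cost
            du = s * max(np.max(np.abs(dE)), np.max(np.abs(dI)))
            if callback is not None:
                callback(it, cost, du)
            if du < settings.eps_u:
                converged = True
                break
        trace.append(cost)
        control = ControlSignal(self.dt, uE, uI, C=self.params.C)
        breakdown = self.evaluate(control, weights)
        return OptimizationResult(control=control, cost=breakdown,
                                  iterations=it, converged=converged,
                                  cost_trace=np.asarray(trace))


def _line_search(cost_at, cost0: float, settings: OptimizationSettings):
    """Halving line search: start at s_init, halve until past the minimum.

    Returns (s, cost) of the best improving step, or (0, cost0) when no
    step above eps_s improves on the current cost.
    """
    s = settings.s_init
    best_s, best_c = 0.0, cost0
    improved = False
    while s >= settings.eps_s:
        c = cost_at(s)
        if c < best_c:
            best_s, best_c = s, c
            improved = True
        elif improved:
            break
        s *= 0.5
    return best_s, best_c


def bisection_line_search(u: np.ndarray, direction: np.ndarray,
                          cost_evaluator,
                          settings: OptimizationSettings | None = None):
    """Standalone halving line search over ``cost_evaluator(u + s*d)``."""
    settings = settings or OptimizationSettings()
    if not np.any(direction):
        raise ValueError("descent direction must be nonzero")
    s, _ = _line_search(lambda s: cost_evaluator(u + s * direction),
                        cost_evaluator(u), settings)
    return s


def fd_gradient_oracle(problem: ControlProblem, control: ControlSignal,
                       weights: CostWeights, epsilon: float = 1e-6,
                       stride: int = 1) -> np.ndarray:
    """Central finite differences of the total cost w.r.t. control samples.

    Returns the same per-channel gradient-density convention as
    :meth:`ControlProblem.total_gradient` (units nA), evaluated at every
    ``stride``-th grid point (others zero).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    w = problem._trapz_weights()
    g = np.zeros((control.u_E.size, 2))
    base = (control.u_E.copy(), control.u_I.copy())
    mv_per_nA = 1.0 / problem._nA_per_mv

    def total(uE, uI):
        return problem._total_cost_mv(uE, uI, weights)

    for c, arr in enumerate(base):
        other = base[1 - c]
        for k in range(0, arr.size, stride):
            up = arr.copy()
            dn = arr.copy()
            up[k] += epsilon * mv_per_nA
            dn[k] -= epsilon * mv_per_nA
            if c == 0:
                fp = total(up, other)
                fm = total(dn, other)
            else:
                fp = total(other, up)
                fm = total(other, dn)
            g[k, c] = (fp - fm) / (2 * epsilon) / w[k]
    return g


# ---------------------------------------------------------------------------
# analytic residual Jacobians (Eq.-level interface; also used by the
# DAE-form adjoint cross-check in the test suite)


def system_jacobians(x: np.ndarray, x_delay_E: np.ndarray,
                     x_delay_I: np.ndarray, u: np.ndarray,
                     params: ModelParameters, background: BackgroundInput,
                     table: TransferTable, clamp: bool = False):
    """Analytic Jacobians (D_x h, D_xE h, D_xI h, D_xdot h, D_u h).

    ``x`` is a 16-component state in canonical ordering; the delayed
    arguments only matter through their rate components (columns 0 and 1 of
    D_xE/D_xI).  ``u`` is (u_E, u_I) in mV/ms.
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

    _, _, drEm, drEs, dtEm, dtEs = table.interpolate(muE, sigE, clamp=clamp)
    _, _, drIm, drIs, dtIm, dtIs = table.interpolate(muI, sigI, clamp=clamp)

    Dx = np.zeros((16, 16))
    DxE = np.zeros((16, 16))
    DxI = np.zeros((16, 16))
    Dxd = np.zeros((16, 16))
    Du = np.zeros((16, 2))

    # rate rows: r_a - Phi_r(mu_a, sigma_a)
    Dx[0, 0] = 1.0
    Dx[0, 2] = -drEm
    Dx[0, 4] = -drEs
    Dx[1, 1] = 1.0
    Dx[1, 3] = -drIm
    Dx[1, 5] = -drIs
    # membrane-current rows
    mE_num = JEE * see + JEI * sei + background.mu_E_ext + u[0] - muE
    mI_num = JIE * sie + JII * sii + background.mu_I_ext + u[1] - muI
    Dx[2, 2] = 1.0 / tauE
    Dx[2, 6] = mE_num / tauE ** 2
    Dx[2, 8] = -JEE / tauE
    Dx[2, 9] = -JEI / tauE
    Dx[3, 3] = 1.0 / tauI
    Dx[3, 7] = mI_num / tauI ** 2
    Dx[3, 10] = -JIE / tauI
    Dx[3, 11] = -JII / tauI
    Dxd[2, 2] = 1.0
    Dxd[3, 3] = 1.0
    Du[2, 0] = -1.0 / tauE
    Du[3, 1] = -1.0 / tauI
    # sigma rows; the derivative denominators use the residual's own
    # sqrt(S), which equals the state's sigma only on consistent states
    sqSE = np.sqrt(gEE * vee * (1.0 + rEE) + gEI * vei * (1.0 + rEI)
                   + params.sigma_ext_E ** 2)
    sqSI = np.sqrt(gIE * vie * (1.0 + rIE) + gII * vii * (1.0 + rII)
                   + params.sigma_ext_I ** 2)
    Dx[4, 4] = 1.0
    Dx[4, 12] = -gEE * (1.0 + rEE) / (2.0 * sqSE)
    Dx[4, 13] = -gEI * (1.0 + rEI) / (2.0 * sqSE)
    DxE[4, 0] = -gEE * vee * aEE / (2.0 * sqSE)
    DxE[4, 1] = -gEI * vei * aEI / (2.0 * sqSE)
    Dx[5, 5] = 1.0
    Dx[5, 14] = -gIE * (1.0 + rIE) / (2.0 * sqSI)
    Dx[5, 15] = -gII * (1.0 + rII) / (2.0 * sqSI)
    DxI[5, 0] = -gIE * vie * aIE / (2.0 * sqSI)
    DxI[5, 1] = -gII * vii * aII / (2.0 * sqSI)
    # tau rows
    Dx[6, 6] = 1.0
    Dx[6, 2] = -dtEm
    Dx[6, 4] = -dtEs
    Dx[7, 7] = 1.0
    Dx[7, 3] = -dtIm
    Dx[7, 5] = -dtIs
    # synaptic activity rows: s' + s/ts - (1-s) r_ab / ts
    pair = [
        (8, see, rEE, tsE, aEE, DxE, 0),
        (9, sei, rEI, tsI, aEI, DxE, 1),
        (10, sie, rIE, tsE, aIE, DxI, 0),
        (11, sii, rII, tsI, aII, DxI, 1),
    ]
    for row, s, rab, ts, a_c, Dd, ch in pair:
        Dx[row, row] = (1.0 + rab) / ts
        Dd[row, ch] += -(1.0 - s) * a_c / ts
        Dxd[row, row] = 1.0
    # variance rows
    pairv = [
        (12, 8, see, vee, rEE, rhoEE, tsE, aEE, bEE, DxE, 0),
        (13, 9, sei, vei, rEI, rhoEI, tsI, aEI, bEI, DxE, 1),
        (14, 10, sie, vie, rIE, rhoIE, tsE, aIE, bIE, DxI, 0),
        (15, 11, sii, vii, rII, rhoII, tsI, aII, bII, DxI, 1),
    ]
    for row, srow, s, v, rab, rho, ts, a_c, b_c, Dd, ch in pairv:
        Dx[row, srow] = 2.0 * (1.0 - s) * rho / ts ** 2
        Dx[row, row] = -(rho - 2.0 * ts * (rab + 1.0)) / ts ** 2
        Dd[row, ch] += -((1.0 - s) ** 2 * b_c + b_c * v
                         - 2.0 * ts * a_c * v) / ts ** 2
        Dxd[row, row] = 1.0
    return Dx, DxE, DxI, Dxd, Du
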