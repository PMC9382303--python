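"""Numba kernels for the E-I EIF mean-field model.

State ordering (16 components)::

    0 r_E   1 r_I    2 mu_E   3 mu_I   4 sigma_E  5 sigma_I  6 tau_E  7 tau_I
    8 s_EE  9 s_EI  10 s_IE  11 s_II  12 v_EE    13 v_EI    14 v_IE  15 v_II

where ``v`` denotes the synaptic-activity variance sigma_s^2.  The ten
differential variables, in the reduced ordering used by the kernels, are::

    y = [mu_E, mu_I, s_EE, s_EI, s_IE, s_II, v_EE, v_EI, v_IE, v_II]

Delays follow the receiver convention: every input arriving at population
``alpha`` is delayed by ``d_alpha``, so the pairs (EE, EI) read rates at
``t - d_E`` and the pairs (IE, II) read rates at ``t - d_I``.

Units are the internal ones (ms, mV/ms, kHz); the control channels enter the
kernels in mV/ms.

The packed parameter vector ``P`` (see :func:`pack_params`)::

    0..3   J_EE, J_EI, J_IE, J_II
    4..7   a_EE, a_EI, a_IE, a_II      (r_ab = a_ab * r_b(t - d_a))
    8..11  b_EE, b_EI, b_IE, b_II      (rho_ab = b_ab * r_b(t - d_a))
    12,13  tau_s_E, tau_s_I
    14     tau_m
    15..18 g_EE, g_EI, g_IE, g_II      (sigma_a^2 = sum_b g_ab v_ab (1+r_ab) + sigma_ext_a^2)
    19,20  sigma_ext_E^2, sigma_ext_I^2
    21     k_u = 1000/C                (mV/ms per nA)

Status codes: 0 ok, 1 table range violated, 2 state invariant violated.
"""

import numpy as np
from numba import njit

from .transfer import _bilinear

# fraction by which s may leave [0, 1] (or v go negative) before the
# integration is flagged as blown up; forward Euler at dt = 0.1 ms
# overshoots the variance equations by O(1e-3) during strong transients,
# so the abort guard only triggers on genuine blow-ups
DEFAULT_S_TOL = 1e-2


def pack_params(params) -> np.ndarray:
    """Pack ModelParameters into the flat kernel vector."""
    p = np.empty(22)
    p[0:4] = (params.J_EE, params.J_EI, params.J_IE, params.J_II)
    tsE, tsI, tm = params.tau_s_E, params.tau_s_I, params.tau_m
    # r_ab = (c_ab/|J_ab|) K_b tau_s_b r_b(t-d_a);  rho_ab scales with tau_s^2
    p[4] = params.c_EE / abs(params.J_EE) * params.K_E * tsE
    p[5] = params.c_EI / abs(params.J_EI) * params.K_I * tsI
    p[6] = params.c_IE / abs(params.J_IE) * params.K_E * tsE
    p[7] = params.c_II / abs(params.J_II) * params.K_I * tsI
    p[8] = (params.c_EE / params.J_EE) ** 2 * params.K_E * tsE ** 2
    p[9] = (params.c_EI / params.J_EI) ** 2 * params.K_I * tsI ** 2
    p[10] = (params.c_IE / params.J_IE) ** 2 * params.K_E * tsE ** 2
    p[11] = (params.c_II / params.J_II) ** 2 * params.K_I * tsI ** 2
    p[12], p[13], p[14] = tsE, tsI, tm
    p[15] = 2.0 * params.J_EE ** 2 * tsE * tm / (tm + tsE)
    p[16] = 2.0 * params.J_EI ** 2 * tsI * tm / (tm + tsI)
    p[17] = 2.0 * params.J_IE ** 2 * tsE * tm / (tm + tsE)
    p[18] = 2.0 * params.J_II ** 2 * tsI * tm / (tm + tsI)
    p[19] = params.sigma_ext_E ** 2
    p[20] = params.sigma_ext_I ** 2
    p[21] = 1000.0 / params.C
    return p


@njit(cache=True)
def _interp2(mug, sgg, F, G, mu, sig, clamp):
    """Interpolate both tables at one point with range handling.

    Returns (fF, dF/dmu, dF/dsig, fG, dG/dmu, dG/dsig, status).  In clamp
    mode out-of-range coordinates are clipped and the corresponding partial
    derivative is zeroed (the clipped interpolant is constant there).
    """
    status = 0
    zmu = False
    zsig = False
    if mu < mug[0] or mu > mug[-1]:
        if clamp:
            mu = min(max(mu, mug[0]), mug[-1])
            zmu = True
        else:
            status = 1
    if sig < sgg[0] or sig > sgg[-1]:
        if clamp:
            sig = min(max(sig, sgg[0]), sgg[-1])
            zsig = True
        else:
            status = 1
    if status != 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, status
    f, dfm, dfs = _bilinear(mug, sgg, F, mu, sig)
    g, dgm, dgs = _bilinear(mug, sgg, G, mu, sig)
    if zmu:
        dfm = 0.0
        dgm = 0.0
    if zsig:
        dfs = 0.0
        dgs = 0.0
    return f, dfm, dfs, g, dgm, dgs, status


@njit(cache=True)
def forward_sim(y0, r0E, r0I, uE, uI, muextE, muextI, P, mug, sgg, Fr, Ft,
                dt, mE, mI, clamp, s_tol):
    """Forward Euler integration of the controlled DDAE system.

    y0 : (10,) initial differential state; the pre-t=0 history is constant
    with excitatory/inhibitory rates r0E/r0I (kHz).  uE/uI are sampled on the
    time grid (N+1 points, mV/ms).  Returns (X, status, bad_step, bad_mu,
    bad_sigma) with X of shape (N+1, 16) in the canonical ordering.
    """
    N = uE.shape[0] - 1
    X = np.zeros((N + 1, 16))
    JEE, JEI, JIE, JII = P[0], P[1], P[2], P[3]
    aEE, aEI, aIE, aII = P[4], P[5], P[6], P[7]
    bEE, bEI, bIE, bII = P[8], P[9], P[10], P[11]
    tsE, tsI = P[12], P[13]
    gEE, gEI, gIE, gII = P[15], P[16], P[17], P[18]
    se2, si2 = P[19], P[20]

    y = y0.copy()
    for k in range(N + 1):
        # delayed rates (receiver convention)
        kE = k - mE
        kI = k - mI
        rdE_E = X[kE, 0] if kE >= 0 else r0E
        rdE_I = X[kE, 1] if kE >= 0 else r0I
        rdI_E = X[kI, 0] if kI >= 0 else r0E
        rdI_I = X[kI, 1] if kI >= 0 else r0I
        rEE = aEE * rdE_E
        rEI = aEI * rdE_I
        rIE = aIE * rdI_E
        rII = aII * rdI_I
        muE, muI = y[0], y[1]
        see, sei, sie, sii = y[2], y[3], y[4], y[5]
        vee, vei, vie, vii = y[6], y[7], y[8], y[9]
        SE = gEE * vee * (1.0 + rEE) + gEI * vei * (1.0 + rEI) + se2
        SI = gIE * vie * (1.0 + rIE) + gII * vii * (1.0 + rII) + si2
        if SE <= 0.0 or SI <= 0.0 or not (np.isfinite(SE) and np.isfinite(SI)):
            return X, 2, k, muE, 0.0
        sigE = np.sqrt(SE)
        sigI = np.sqrt(SI)
        rE, _, _, tauE, _, _, st = _interp2(mug, sgg, Fr, Ft, muE, sigE, clamp)
        if st != 0:
            return X, 1, k, muE, sigE
        rI, _, _, tauI, _, _, st = _interp2(mug, sgg, Fr, Ft, muI, sigI, clamp)
        if st != 0:
            return X, 1, k, muI, sigI
        X[k, 0] = rE
        X[k, 1] = rI
        X[k, 2] = muE
        X[k, 3] = muI
        X[k, 4] = sigE
        X[k, 5] = sigI
        X[k, 6] = tauE
        X[k, 7] = tauI
        X[k, 8] = see
        X[k, 9] = sei
        X[k, 10] = sie
        X[k, 11] = sii
        X[k, 12] = vee
        X[k, 13] = vei
        X[k, 14] = vie
        X[k, 15] = vii
        if k == N:
            break
        rhoEE = bEE * rdE_E
        rhoEI = bEI * rdE_I
        rhoIE = bIE * rdI_E
        rhoII = bII * rdI_I
        fmuE = (JEE * see + JEI * sei + muextE + uE[k] - muE) / tauE
        fmuI = (JIE * sie + JII * sii + muextI + uI[k] - muI) / tauI
        fsee = (-see + (1.0 - see) * rEE) / tsE
        fsei = (-sei + (1.0 - sei) * rEI) / tsI
        fsie = (-sie + (1.0 - sie) * rIE) / tsE
        fsii = (-sii + (1.0 - sii) * rII) / tsI
        fvee = ((1.0 - see) ** 2 * rhoEE
                + (rhoEE - 2.0 * tsE * (rEE + 1.0)) * vee) / tsE ** 2
        fvei = ((1.0 - sei) ** 2 * rhoEI
                + (rhoEI - 2.0 * tsI * (rEI + 1.0)) * vei) / tsI ** 2
        fvie = ((1.0 - sie) ** 2 * rhoIE
                + (rhoIE - 2.0 * tsE * (rIE + 1.0)) * vie) / tsE ** 2
        fvii = ((1.0 - sii) ** 2 * rhoII
                + (rhoII - 2.0 * tsI * (rII + 1.0)) * vii) / tsI ** 2
        y[0] = muE + dt * fmuE
        y[1] = muI + dt * fmuI
        y[2] = see + dt * fsee
        y[3] = sei + dt * fsei
        y[4] = sie + dt * fsie
        y[5] = sii + dt * fsii
        y[6] = vee + dt * fvee
        y[7] = vei + dt * fvei
        y[8] = vie + dt * fvie
        y[9] = vii + dt * fvii
        for j in range(2, 6):
            if y[j] < -s_tol or y[j] > 1.0 + s_tol:
                return X, 2, k + 1, 0.0, 0.0
        for j in range(6, 10):
            if y[j] < -s_tol:
                return X, 2, k + 1, 0.0, 0.0
        if not np.isfinite(y[0]) or not np.isfinite(y[1]):
            return X, 2, k + 1, 0.0, 0.0
    return X, 0, -1, 0.0, 0.0


@njit(cache=True)
def forward_precision_cost(y0, r0E, r0I, uE, uI, muextE, muextI, P, mug, sgg,
                           Fr, Ft, dt, mE, mI, clamp, s_tol, k0, r_target_Hz):
    """Forward integration returning only the precision cost F_P.

    F_P = (1/2) * 1/(T-t0) * int_{t0}^{T} (r_E[Hz] - r~)^2 dt with trapezoid
    quadrature on the sample grid; k0 is the grid index of t0.
    """
    N = uE.shape[0] - 1
    JEE, JEI, JIE, JII = P[0], P[1], P[2], P[3]
    aEE, aEI, aIE, aII = P[4], P[5], P[6], P[7]
    bEE, bEI, bIE, bII = P[8], P[9], P[10], P[11]
    tsE, tsI = P[12], P[13]
    gEE, gEI, gIE, gII = P[15], P[16], P[17], P[18]
    se2, si2 = P[19], P[20]

    nbuf = mE + 1 if mE > mI else mI + 1
    bufE = np.empty(nbuf)
    bufI = np.empty(nbuf)
    for i in range(nbuf):
        bufE[i] = r0E
        bufI[i] = r0I
    acc = 0.0
    y = y0.copy()
    for k in range(N + 1):
        kE = k - mE
        kI = k - mI
        rdE_E = bufE[kE % nbuf] if kE >= 0 else r0E
        rdE_I = bufI[kE % nbuf] if kE >= 0 else r0I
        rdI_E = bufE[kI % nbuf] if kI >= 0 else r0E
        rdI_I = bufI[kI % nbuf] if kI >= 0 else r0I
        rEE = aEE * rdE_E
        rEI = aEI * rdE_I
        rIE = aIE * rdI_E
        rII = aII * rdI_I
        muE, muI = y[0], y[1]
        see, sei, sie, sii = y[2], y[3], y[4], y[5]
        vee, vei, vie, vii = y[6], y[7], y[8], y[9]
        SE = gEE * vee * (1.0 + rEE) + gEI * vei * (1.0 + rEI) + se2
        SI = gIE * vie * (1.0 + rIE) + gII * vii * (1.0 + rII) + si2
        if SE <= 0.0 or SI <= 0.0 or not (np.isfinite(SE) and np.isfinite(SI)):
            return np.inf, 2
        sigE = np.sqrt(SE)
        sigI = np.sqrt(SI)
        rE, _, _, tauE, _, _, st = _interp2(mug, sgg, Fr, Ft, muE, sigE, clamp)
        if st != 0:
            return np.inf, 1
        rI, _, _, tauI, _, _, st = _interp2(mug, sgg, Fr, Ft, muI, sigI, clamp)
        if st != 0:
            return np.inf, 1
        bufE[k % nbuf] = rE
        bufI[k % nbuf] = rI
        if k >= k0:
            w = 0.5 if (k == k0 or k == N) else 1.0
            d = 1000.0 * rE - r_target_Hz
            acc += w * d * d
        if k == N:
            break
        rhoEE = bEE * rdE_E
        rhoEI = bEI * rdE_I
        rhoIE = bIE * rdI_E
        rhoII = bII * rdI_I
        fmuE = (JEE * see + JEI * sei + muextE + uE[k] - muE) / tauE
        fmuI = (JIE * sie + JII * sii + muextI + uI[k] - muI) / tauI
        y[0] = muE + dt * fmuE
        y[1] = muI + dt * fmuI
        y[2] = see + dt * (-see + (1.0 - see) * rEE) / tsE
        y[3] = sei + dt * (-sei + (1.0 - sei) * rEI) / tsI
        y[4] = sie + dt * (-sie + (1.0 - sie) * rIE) / tsE
        y[5] = sii + dt * (-sii + (1.0 - sii) * rII) / tsI
        y[6] = vee + dt * ((1.0 - see) ** 2 * rhoEE
                           + (rhoEE - 2.0 * tsE * (rEE + 1.0)) * vee) / tsE ** 2
        y[7] = vei + dt * ((1.0 - sei) ** 2 * rhoEI
                           + (rhoEI - 2.0 * tsI * (rEI + 1.0)) * vei) / tsI ** 2
        y[8] = vie + dt * ((1.0 - sie) ** 2 * rhoIE
                           + (rhoIE - 2.0 * tsE * (rIE + 1.0)) * vie) / tsE ** 2
        y[9] = vii + dt * ((1.0 - sii) ** 2 * rhoII
                           + (rhoII - 2.0 * tsI * (rII + 1.0)) * vii) / tsI ** 2
        for j in range(2, 6):
            if y[j] < -s_tol or y[j] > 1.0 + s_tol:
                return np.inf, 2
        for j in range(6, 10):
            if y[j] < -s_tol:
                return np.inf, 2
        if not np.isfinite(y[0]) or not np.isfinite(y[1]):
            return np.inf, 2
    T_minus_t0 = dt * (N - k0)
    return 0.5 * acc * dt / T_minus_t0, 0


@njit(cache=True)
def adjoint_precision_gradient(X, r0E, r0I, uE, uI, muextE, muextI, P, mug,
                               sgg, Fr, Ft, dt, mE, mI, clamp, k0,
                               r_target_Hz):
    """Exact discrete adjoint of :func:`forward_sim` for the precision cost.

    Returns (ubar, lam): ``ubar[k, c]`` is dF_P/du_c[k] with u in mV/ms
    (running costs are handled by the caller); ``lam`` is the 16-component
    costate time series (per-unit-time density convention, lam(T) = 0).

    The delayed couplings of the underlying DDAE adjoint appear as
    time-advanced contributions: the sensitivity of the cost to the rate at
    step k collects terms from steps k+d_E/dt and k+d_I/dt, which is the
    discrete counterpart of the indicator-masked delayed Jacobians of the
    continuous costate equation.
    """
    N = X.shape[0] - 1
    JEE, JEI, JIE, JII = P[0], P[1], P[2], P[3]
    aEE, aEI, aIE, aII = P[4], P[5], P[6], P[7]
    bEE, bEI, bIE, bII = P[8], P[9], P[10], P[11]
    tsE, tsI = P[12], P[13]
    gEE, gEI, gIE, gII = P[15], P[16], P[17], P[18]

    Tfac = 1.0 / (dt * (N - k0))
    ubar = np.zeros((N + 1, 2))
    lam = np.zeros((N + 1, 16))
    rbar = np.zeros((N + 1, 2))
    ybar = np.zeros(10)      # dF/dy_{k+1}
    nyb = np.zeros(10)
    for k in range(N, -1, -1):
        wk = dt * (0.5 if (k == 0 or k == N) else 1.0)
        muE, muI = X[k, 2], X[k, 3]
        sigE, sigI = X[k, 4], X[k, 5]
        tauE, tauI = X[k, 6], X[k, 7]
        rE = X[k, 0]
        see, sei, sie, sii = X[k, 8], X[k, 9], X[k, 10], X[k, 11]
        vee, vei, vie, vii = X[k, 12], X[k, 13], X[k, 14], X[k, 15]
        kE = k - mE
        kI = k - mI
        rdE_E = X[kE, 0] if kE >= 0 else r0E
        rdE_I = X[kE, 1] if kE >= 0 else r0I
        rdI_E = X[kI, 0] if kI >= 0 else r0E
        rdI_I = X[kI, 1] if kI >= 0 else r0I
        rEE = aEE * rdE_E
        rEI = aEI * rdE_I
        rIE = aIE * rdI_E
        rII = aII * rdI_I
        _, drEm, drEs, _, dtEm, dtEs, _ = _interp2(mug, sgg, Fr, Ft, muE,
                                                   sigE, 1)
        _, drIm, drIs, _, dtIm, dtIs, _ = _interp2(mug, sgg, Fr, Ft, muI,
                                                   sigI, 1)
        if clamp == 0:
            # strict mode: forward verified coverage, keep full derivatives
            pass
        # adjoint of the algebraic outputs
        abar_rE = rbar[k, 0]
        abar_rI = rbar[k, 1]
        if k >= k0:
            wp = dt * (0.5 if (k == k0 or k == N) else 1.0)
            abar_rE += wp * Tfac * (1000.0 * rE - r_target_Hz) * 1000.0
        abar_tauE = 0.0
        abar_tauI = 0.0
        if k < N:
            fmuE = (JEE * see + JEI * sei + muextE + uE[k] - muE) / tauE
            fmuI = (JIE * sie + JII * sii + muextI + uI[k] - muI) / tauI
            abar_tauE = -dt * ybar[0] * fmuE / tauE
            abar_tauI = -dt * ybar[1] * fmuI / tauI
            ubar[k, 0] = dt * ybar[0] / tauE
            ubar[k, 1] = dt * ybar[1] / tauI
        sigbarE = abar_rE * drEs + abar_tauE * dtEs
        sigbarI = abar_rI * drIs + abar_tauI * dtIs
        mubarE = abar_rE * drEm + abar_tauE * dtEm
        mubarI = abar_rI * drIm + abar_tauI * dtIm
        inv2sE = 0.5 / sigE
        inv2sI = 0.5 / sigI
        vbarEE = sigbarE * gEE * (1.0 + rEE) * inv2sE
        vbarEI = sigbarE * gEI * (1.0 + rEI) * inv2sE
        vbarIE = sigbarI * gIE * (1.0 + rIE) * inv2sI
        vbarII = sigbarI * gII * (1.0 + rII) * inv2sI
        # deferred contributions to the delayed rates (sigma path)
        if kE >= 0:
            rbar[kE, 0] += sigbarE * gEE * vee * aEE * inv2sE
            rbar[kE, 1] += sigbarE * gEI * vei * aEI * inv2sE
        if kI >= 0:
            rbar[kI, 0] += sigbarI * gIE * vie * aIE * inv2sI
            rbar[kI, 1] += sigbarI * gII * vii * aII * inv2sI
        for j in range(10):
            nyb[j] = ybar[j]
        if k < N:
            rhoEE = bEE * rdE_E
            rhoEI = bEI * rdE_I
            rhoIE = bIE * rdI_E
            rhoII = bII * rdI_I
            # delayed-rate contributions of the s/v rows
            if kE >= 0:
                rbar[kE, 0] += dt * (ybar[2] * (1.0 - see) * aEE / tsE
                                     + ybar[6] * ((1.0 - see) ** 2 * bEE
                                                  + bEE * vee
                                                  - 2.0 * tsE * aEE * vee) / tsE ** 2)
                rbar[kE, 1] += dt * (ybar[3] * (1.0 - sei) * aEI / tsI
                                     + ybar[7] * ((1.0 - sei) ** 2 * bEI
                                                  + bEI * vei
                                                  - 2.0 * tsI * aEI * vei) / tsI ** 2)
            if kI >= 0:
                rbar[kI, 0] += dt * (ybar[4] * (1.0 - sie) * aIE / tsE
                                     + ybar[8] * ((1.0 - sie) ** 2 * bIE
                                                  + bIE * vie
                                                  - 2.0 * tsE * aIE * vie) / tsE ** 2)
                rbar[kI, 1] += dt * (ybar[5] * (1.0 - sii) * aII / tsI
                                     + ybar[9] * ((1.0 - sii) ** 2 * bII
                                                  + bII * vii
                                                  - 2.0 * tsI * aII * vii) / tsI ** 2)
            # (df/dy)^T ybar
            nyb[0] += -dt * ybar[0] / tauE
            nyb[1] += -dt * ybar[1] / tauI
            nyb[2] += dt * (ybar[0] * JEE / tauE
                            + ybar[2] * (-1.0 - rEE) / tsE
                            + ybar[6] * (-2.0 * (1.0 - see) * rhoEE) / tsE ** 2)
            nyb[3] += dt * (ybar[0] * JEI / tauE
                            + ybar[3] * (-1.0 - rEI) / tsI
                            + ybar[7] * (-2.0 * (1.0 - sei) * rhoEI) / tsI ** 2)
            nyb[4] += dt * (ybar[1] * JIE / tauI
                            + ybar[4] * (-1.0 - rIE) / tsE
                            + ybar[8] * (-2.0 * (1.0 - sie) * rhoIE) / tsE ** 2)
            nyb[5] += dt * (ybar[1] * JII / tauI
                            + ybar[5] * (-1.0 - rII) / tsI
                            + ybar[9] * (-2.0 * (1.0 - sii) * rhoII) / tsI ** 2)
            nyb[6] += dt * ybar[6] * (rhoEE - 2.0 * tsE * (rEE + 1.0)) / tsE ** 2
            nyb[7] += dt * ybar[7] * (rhoEI - 2.0 * tsI * (rEI + 1.0)) / tsI ** 2
            nyb[8] += dt * ybar[8] * (rhoIE - 2.0 * tsE * (rIE + 1.0)) / tsE ** 2
            nyb[9] += dt * ybar[9] * (rhoII - 2.0 * tsI * (rII + 1.0)) / tsI ** 2
        nyb[0] += mubarE
        nyb[1] += mubarI
        nyb[6] += vbarEE
        nyb[7] += vbarEI
        nyb[8] += vbarIE
        nyb[9] += vbarII
        # costate storage (density convention)
        if k < N:
            lam[k, 2] = -dt * ybar[0] / wk
            lam[k, 3] = -dt * ybar[1] / wk
            for j in range(8):
                lam[k, 8 + j] = -dt * ybar[2 + j] / wk
            lam[k, 0] = -abar_rE / wk
            lam[k, 1] = -abar_rI / wk
            lam[k, 4] = -sigbarE / wk
            lam[k, 5] = -sigbarI / wk
            lam[k, 6] = -abar_tauE / wk
            lam[k, 7] = -abar_tauI / wk
        for j in range(10):
            ybar[j] = nyb[j]
    return ubar, lam
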