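"""Independent DAE-form adjoint: matrix reverse pass via the residual
Jacobians.

This reference integrates the costate equation backward on the forward grid
in its differential-algebraic partition: the six algebraic costate
components are solved from a 6x6 linear system at every step, the delayed
Jacobians enter as time-advanced couplings, and the control gradient is
assembled from D_u h.  It shares no code with the production adjoint kernel
beyond the residual Jacobians themselves, which are FD-verified separately.
"""

import numpy as np

from neuroct.control import system_jacobians
from neuroct.model import DIFF_IDX, ALG_IDX


def dae_adjoint_gradient(problem, traj):
    """dF_P/du (mV/ms samples), same convention as the adjoint kernel."""
    X = traj.X
    N = X.shape[0] - 1
    dt = problem.dt
    mE, mI = problem.mE, problem.mI
    k0 = problem.k0
    r_t = problem.target.r_tilde
    Tfac = 1.0 / (dt * (N - k0))
    uE, uI = traj.control.u_E, traj.control.u_I
    hist = traj.history.to_array()

    def x_at(k):
        return X[k] if k >= 0 else hist

    jac_cache = {}

    def jacs(k):
        if k not in jac_cache:
            jac_cache[k] = system_jacobians(
                X[k], x_at(k - mE)[:2], x_at(k - mI)[:2],
                np.array([uE[k], uI[k]]), problem.params,
                problem.background, problem.table, clamp=problem.clamp)
        return jac_cache[k]

    ybar = np.zeros(10)
    rbar = np.zeros((N + 1, 2))
    ubar = np.zeros((N + 1, 2))
    for k in range(N, -1, -1):
        Dx, DxE, DxI, _, Du = jacs(k)
        abar = np.zeros(6)
        # deferred delayed-rate contributions land on the rate outputs
        abar[0] += rbar[k, 0]
        abar[1] += rbar[k, 1]
        if k >= k0:
            wp = dt * (0.5 if (k == k0 or k == N) else 1.0)
            abar[0] += wp * Tfac * (1000.0 * X[k, 0] - r_t) * 1000.0
        if k < N:
            df_da = -Dx[np.ix_(DIFF_IDX, ALG_IDX)]
            abar += dt * df_da.T @ ybar
        A = Dx[np.ix_(ALG_IDX, ALG_IDX)]
        lam_a = np.linalg.solve(A.T, -abar)
        dH_dy = Dx[np.ix_(ALG_IDX, DIFF_IDX)]
        df_dy = -Dx[np.ix_(DIFF_IDX, DIFF_IDX)]
        nyb = dH_dy.T @ lam_a
        if k < N:
            nyb += ybar + dt * df_dy.T @ ybar
            ubar[k] = -dt * Du[DIFF_IDX].T @ ybar
            if k - mE >= 0:
                rbar[k - mE] += -dt * DxE[np.ix_(DIFF_IDX, [0, 1])].T @ ybar
            if k - mI >= 0:
                rbar[k - mI] += -dt * DxI[np.ix_(DIFF_IDX, [0, 1])].T @ ybar
        if k - mE >= 0:
            rbar[k - mE] += DxE[np.ix_(ALG_IDX, [0, 1])].T @ lam_a
        if k - mI >= 0:
            rbar[k - mI] += DxI[np.ix_(ALG_IDX, [0, 1])].T @ lam_a
        ybar = nyb
    return ubar
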