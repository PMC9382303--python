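"""Regime mapping, boundary distances and fixed-point stability.

Depending on the static background drives (mu_E_ext, mu_I_ext) the model
settles into a low-activity down state, a high-activity up state, an E-I
limit cycle, or a bistable regime where down and up states coexist.  This
module classifies points of the background-input plane by settling the free
model from a down-like and an up-like probe state, builds regime maps,
measures distances to regime boundaries, and checks fixed-point stability
through the numerical Jacobian of the reduced (delay-collapsed,
algebraically substituted) ten-variable ODE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (ControlSignal, IntegrationError, SystemState,
                    consistent_state, simulate)
from .params import BackgroundInput, ModelParameters
from .transfer import TransferTable

__all__ = [
    "RegimeMap",
    "BoundaryDistances",
    "ClassifierSettings",
    "classify_point",
    "build_regime_map",
    "boundary_distances",
    "jacobian_eigenvalues",
    "reduced_rhs",
    "find_saddle",
]

REGIMES = ("down", "up", "bistable", "oscillatory")

# probe states for the two basins; the down probe starts with engaged
# inhibitory synapses (an all-zero start transiently fires strongly and can
# fall into the up basin), the up probe with elevated synaptic activity
DOWN_PROBE = np.array([-0.5, 1.0, 0.0, 0.7, 0.0, 0.85,
                       0.0, 0.005, 0.0, 0.005])
UP_PROBE = np.array([2.0, 1.0, 0.6, 0.6, 0.6, 0.6,
                     0.01, 0.01, 0.01, 0.01])


@dataclass(frozen=True)
class ClassifierSettings:
    """Numerical settings of the regime classifier."""

    settle_T: float = 2000.0       # ms free run per probe
    osc_window: float = 200.0      # ms; peak-to-peak window at the end
    osc_threshold: float = 1.0     # Hz; above -> oscillatory
    bistable_threshold: float = 1.0  # Hz separation between fixed points
    rate_split: float = 15.0       # Hz; down/up split of settled rates
    settle_window: float = 50.0    # ms for the stationarity check
    settle_tol: float = 1e-9
    dt_fallbacks: tuple = (0.1, 0.05, 0.02, 0.01)


def _free_run(params, background, table, y_probe, cs: ClassifierSettings):
    """Simulate the free model from a probe; refine dt on Euler blow-up."""
    state0 = consistent_state(y_probe, params, table, clamp=True)
    for dt in cs.dt_fallbacks:
        try:
            traj = simulate(params, background,
                            ControlSignal.zero(cs.settle_T, dt, params.C),
                            state0, table, clamp=True)
            return traj
        except IntegrationError:
            continue
    return None


def _analyze_run(traj, cs: ClassifierSettings):
    """Returns (mean rate Hz, peak-to-peak Hz, settled flag, final state)."""
    dt = traj.dt
    n = int(round(cs.osc_window / dt))
    rE = 1000.0 * traj["r_E"][-n:]
    ptp = float(rE.max() - rE.min())
    m = int(round(cs.settle_window / dt))
    settled = bool(np.max(np.abs(traj.X[-1] - traj.X[-1 - m])) < cs.settle_tol)
    return float(rE.mean()), ptp, settled, traj.final_state


def classify_point(params: ModelParameters, background: BackgroundInput,
                   table: TransferTable,
                   settings: ClassifierSettings | None = None):
    """Classify one background point; returns (label, info dict).

    ``info`` carries the settled down/up rates (Hz) where defined and the
    final probe states.
    """
    cs = settings or ClassifierSettings()
    info: dict = {"r_down": np.nan, "r_up": np.nan,
                  "state_down": None, "state_up": None}
    runs = []
    for probe in (DOWN_PROBE, UP_PROBE):
        traj = _free_run(params, background, table, probe, cs)
        if traj is None:
            info["diagnostics"] = "integration failed at all dt fallbacks"
            return "oscillatory", info
        runs.append(_analyze_run(traj, cs))
    (r_lo, ptp_lo, set_lo, st_lo), (r_hi, ptp_hi, set_hi, st_hi) = runs
    if max(ptp_lo, ptp_hi) > cs.osc_threshold:
        return "oscillatory", info
    if abs(r_hi - r_lo) > cs.bistable_threshold:
        info.update(r_down=min(r_lo, r_hi), r_up=max(r_lo, r_hi),
                    state_down=st_lo if r_lo < r_hi else st_hi,
                    state_up=st_hi if r_hi > r_lo else st_lo)
        return "bistable", info
    r = 0.5 * (r_lo + r_hi)
    if r >= cs.rate_split:
        info.update(r_up=r, state_up=st_hi)
        return "up", info
    info.update(r_down=r, state_down=st_lo)
    return "down", info


@dataclass
class RegimeMap:
    """Regime labels on a rectangular grid of background inputs (nA)."""

    mu_E_nA: np.ndarray
    mu_I_nA: np.ndarray
    labels: np.ndarray           # (nE, nI) object/str array
    r_down: np.ndarray           # Hz, NaN where undefined
    r_up: np.ndarray
    params: ModelParameters | None = None
    settings: ClassifierSettings = field(default_factory=ClassifierSettings)

    def label_at(self, iE: int, iI: int) -> str:
        return str(self.labels[iE, iI])

    def nodes_with(self, label: str):
        """Array of (mu_E, mu_I) nA coordinates with the given label."""
        idx = np.argwhere(self.labels == label)
        return np.array([[self.mu_E_nA[i], self.mu_I_nA[j]] for i, j in idx])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, mE in enumerate(self.mu_E_nA):
            for j, mI in enumerate(self.mu_I_nA):
                rows.append({"mu_E_ext_nA": mE, "mu_I_ext_nA": mI,
                             "label": str(self.labels[i, j]),
                             "r_down_Hz": self.r_down[i, j],
                             "r_up_Hz": self.r_up[i, j]})
        return pd.DataFrame(rows)

    def export(self, csv_path, json_path=None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            import json

            meta = {
                "mu_E_nA": [float(self.mu_E_nA[0]), float(self.mu_E_nA[-1]),
                            int(self.mu_E_nA.size)],
                "mu_I_nA": [float(self.mu_I_nA[0]), float(self.mu_I_nA[-1]),
                            int(self.mu_I_nA.size)],
                "osc_threshold_Hz": self.settings.osc_threshold,
                "bistable_threshold_Hz": self.settings.bistable_threshold,
                "rate_split_Hz": self.settings.rate_split,
            }
            with open(json_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def build_regime_map(params: ModelParameters, table: TransferTable,
                     mu_E_nA: np.ndarray, mu_I_nA: np.ndarray,
                     settings: ClassifierSettings | None = None,
                     progress: bool = False) -> RegimeMap:
    """Classify every node of a background-input grid (coordinates in nA)."""
    cs = settings or ClassifierSettings()
    mu_E_nA = np.asarray(mu_E_nA, float)
    mu_I_nA = np.asarray(mu_I_nA, float)
    nE, nI = mu_E_nA.size, mu_I_nA.size
    labels = np.empty((nE, nI), dtype=object)
    r_down = np.full((nE, nI), np.nan)
    r_up = np.full((nE, nI), np.nan)
    for i, mE in enumerate(mu_E_nA):
        for j, mI in enumerate(mu_I_nA):
            bg = BackgroundInput.from_nA(mE, mI, params.C)
            lab, info = classify_point(params, bg, table, cs)
            labels[i, j] = lab
            r_down[i, j] = info["r_down"]
            r_up[i, j] = info["r_up"]
        if progress:
            print(f"regime map: row {i + 1}/{nE}", flush=True)
    return RegimeMap(mu_E_nA, mu_I_nA, labels, r_down, r_up, params=params,
                     settings=cs)


@dataclass
class BoundaryDistances:
    """Distances (nA) from a bistable point to a target-regime boundary."""

    d_E_dist: float | None
    d_I_dist: float | None
    d_min: float
    target_regime: str


def _bisect_boundary(params, table, p_inside, p_outside, target, cs,
                     tol=1e-3):
    """Bisect between a non-target and a target point; returns the crossing."""
    a = np.asarray(p_inside, float)
    b = np.asarray(p_outside, float)
    while np.linalg.norm(b - a) > tol:
        m = 0.5 * (a + b)
        lab, _ = classify_point(params,
                                BackgroundInput.from_nA(*m, params.C),
                                table, cs)
        if lab == target:
            b = m
        else:
            a = m
    return 0.5 * (a + b)


def boundary_distances(regime_map: RegimeMap, point_nA, target_regime: str,
                       table: TransferTable,
                       params: ModelParameters | None = None,
                       tol: float = 1e-3) -> BoundaryDistances:
    """Horizontal, vertical and shortest distance to a regime boundary.

    Axis distances follow the grid row/column through ``point_nA`` to the
    first target-regime node and are refined by bisection; ``d_min`` is the
    minimum over bisection-refined crossings toward the nearest
    target-regime nodes.  An axis with no target node is reported as None.
    """
    params = params or regime_map.params
    cs = regime_map.settings
    p = np.asarray(point_nA, float)
    iE = int(np.argmin(np.abs(regime_map.mu_E_nA - p[0])))
    iI = int(np.argmin(np.abs(regime_map.mu_I_nA - p[1])))

    def axis_distance(axis):
        vals = regime_map.mu_E_nA if axis == 0 else regime_map.mu_I_nA
        best = None
        for direction in (+1, -1):
            idx = iE if axis == 0 else iI
            k = idx + direction
            while 0 <= k < vals.size:
                lab = (regime_map.labels[k, iI] if axis == 0
                       else regime_map.labels[iE, k])
                if lab == target_regime:
                    outside = p.copy()
                    outside[axis] = vals[k]
                    cross = _bisect_boundary(params, table, p, outside,
                                             target_regime, cs, tol)
                    d = abs(cross[axis] - p[axis])
                    if best is None or d < best:
                        best = d
                    break
                k += direction
        return best

    dE = axis_distance(0)
    dI = axis_distance(1)
    # shortest distance: refine toward the nearest target nodes
    nodes = regime_map.nodes_with(target_regime)
    if nodes.size == 0:
        raise ValueError(f"no {target_regime!r} nodes in the regime map")
    dist = np.linalg.norm(nodes - p, axis=1)
    cands = nodes[np.argsort(dist)[:5]]
    d_min = np.inf
    for node in cands:
        cross = _bisect_boundary(params, table, p, node, target_regime, cs,
                                 tol)
        d_min = min(d_min, float(np.linalg.norm(cross - p)))
    for d in (dE, dI):
        if d is not None:
            d_min = min(d_min, d)
    return BoundaryDistances(d_E_dist=dE, d_I_dist=dI, d_min=d_min,
                             target_regime=target_regime)


# ---------------------------------------------------------------------------
# reduced ODE, Jacobian stability, saddle search


def reduced_rhs(y: np.ndarray, params: ModelParameters,
                background: BackgroundInput, table: TransferTable,
                clamp: bool = False) -> np.ndarray:
    """Right-hand side of the delay-collapsed ten-variable ODE.

    The algebraic block is resolved self-consistently (delays do not move
    fixed points, so delayed rates are replaced by instantaneous ones).
    """
    st = consistent_state(y, params, table, clamp=clamp)
    from ._kernels import pack_params

    P = pack_params(params)
    JEE, JEI, JIE, JII = P[0], P[1], P[2], P[3]
    aEE, aEI, aIE, aII = P[4], P[5], P[6], P[7]
    bEE, bEI, bIE, bII = P[8], P[9], P[10], P[11]
    tsE, tsI = P[12], P[13]
    rEE, rEI = aEE * st.r_E, aEI * st.r_I
    rIE, rII = aIE * st.r_E, aII * st.r_I
    rhoEE, rhoEI = bEE * st.r_E, bEI * st.r_I
    rhoIE, rhoII = bIE * st.r_E, bII * st.r_I
    f = np.empty(10)
    f[0] = (JEE * st.s_EE + JEI * st.s_EI + background.mu_E_ext
            - st.mu_E) / st.tau_E
    f[1] = (JIE * st.s_IE + JII * st.s_II + background.mu_I_ext
            - st.mu_I) / st.tau_I
    f[2] = (-st.s_EE + (1 - st.s_EE) * rEE) / tsE
    f[3] = (-st.s_EI + (1 - st.s_EI) * rEI) / tsI
    f[4] = (-st.s_IE + (1 - st.s_IE) * rIE) / tsE
    f[5] = (-st.s_II + (1 - st.s_II) * rII) / tsI
    f[6] = ((1 - st.s_EE) ** 2 * rhoEE
            + (rhoEE - 2 * tsE * (rEE + 1)) * st.v_EE) / tsE ** 2
    f[7] = ((1 - st.s_EI) ** 2 * rhoEI
            + (rhoEI - 2 * tsI * (rEI + 1)) * st.v_EI) / tsI ** 2
    f[8] = ((1 - st.s_IE) ** 2 * rhoIE
            + (rhoIE - 2 * tsE * (rIE + 1)) * st.v_IE) / tsE ** 2
    f[9] = ((1 - st.s_II) ** 2 * rhoII
            + (rhoII - 2 * tsI * (rII + 1)) * st.v_II) / tsI ** 2
    return f


def jacobian_eigenvalues(params: ModelParameters, background: BackgroundInput,
                         fixed_point: SystemState, table: TransferTable,
                         h: float = 1e-6, residual_tol: float = 1e-6,
                         clamp: bool = False) -> np.ndarray:
    """Eigenvalues of the reduced-ODE Jacobian at a settled fixed point.

    The Jacobian is a central finite difference of :func:`reduced_rhs`;
    delays are collapsed, so this checks stability of the delay-free
    linearization.  Raises if the input is not settled.
    """
    y0 = fixed_point.diff_vars()
    f0 = reduced_rhs(y0, params, background, table, clamp=clamp)
    if np.max(np.abs(f0)) > residual_tol:
        raise ValueError(
            f"fixed point residual {np.max(np.abs(f0)):.2e} exceeds "
            f"{residual_tol:.0e}; settle the state first")
    J = np.empty((10, 10))
    for j in range(10):
        step = h * max(1.0, abs(y0[j]))
        yp = y0.copy()
        ym = y0.copy()
        yp[j] += step
        ym[j] -= step
        J[:, j] = (reduced_rhs(yp, params, background, table, clamp=clamp)
                   - reduced_rhs(ym, params, background, table, clamp=clamp)) \
            / (2 * step)
    return np.linalg.eigvals(J)


def find_saddle(params: ModelParameters, background: BackgroundInput,
                table: TransferTable, down: SystemState, up: SystemState,
                probe_T: float = 1500.0, dt: float = 0.1,
                tol: float = 1e-10) -> SystemState:
    """Unstable fixed point between the two attractors.

    Bisects along the line connecting the down and up states to locate the
    basin boundary, takes the slowest point of a trajectory started at the
    boundary as initial guess, and polishes it with a Newton-type root solve
    of the reduced ODE.
    """
    from scipy.optimize import root

    y_dn = down.diff_vars()
    y_up = up.diff_vars()
    r_dn, r_up = down.r_E_Hz, up.r_E_Hz
    r_mid = 0.5 * (r_dn + r_up)

    def endpoint_rate(s):
        y = (1 - s) * y_dn + s * y_up
        st = consistent_state(y, params, table, clamp=True)
        traj = simulate(params, background,
                        ControlSignal.zero(probe_T, dt, params.C), st, table,
                        clamp=True)
        return 1000.0 * traj["r_E"][-1], traj

    lo, hi = 0.0, 1.0
    traj_b = None
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        r_end, traj_b = endpoint_rate(mid)
        if r_end > r_mid:
            hi = mid
        else:
            lo = mid
    # slowest mid-range point of the boundary trajectory: the lingering
    # passage near the saddle, away from either attractor
    X = traj_b.X
    rE_Hz = 1000.0 * X[:, 0]
    dX = np.max(np.abs(np.diff(X, axis=0)), axis=1)
    mid = (rE_Hz[:-1] > min(r_dn, r_up) + 0.5) \
        & (rE_Hz[:-1] < max(r_dn, r_up) - 5.0)
    if not mid.any():
        raise RuntimeError("no mid-range segment on the boundary trajectory")
    idx = np.where(mid)[0]
    order = idx[np.argsort(dX[idx])]
    yidx = np.array([2, 3, 8, 9, 10, 11, 12, 13, 14, 15])

    def is_attractor(st):
        return (abs(st.r_E_Hz - r_dn) < 0.5 or abs(st.r_E_Hz - r_up) < 0.5)

    for k_slow in order[:10]:
        y_guess = X[k_slow][yidx]
        sol = root(lambda y: reduced_rhs(y, params, background, table,
                                         clamp=True),
                   y_guess, method="hybr", tol=tol)
        if not sol.success:
            continue
        st = consistent_state(sol.x, params, table, clamp=True)
        if not is_attractor(st):
            return st
    raise RuntimeError("saddle search converged only to the attractors")
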