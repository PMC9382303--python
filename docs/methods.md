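# Methods

## Model

The package simulates a mean-field description of two recurrently coupled
populations of exponential integrate-and-fire (EIF) neurons, one excitatory
(E) and one inhibitory (I). Sixteen variables describe the motif: per
population the mean membrane current `μ_α` (mV/ms), its noise amplitude
`σ_α` (mV·ms^-1/2), the instantaneous rate `r_α` (kHz) and the effective
membrane-current timescale `τ_α` (ms); per synaptic channel
(EE, EI, IE, II) the mean fraction of active synapses `s̄_αβ` and its
variance `σ²_s,αβ`. Ten variables are differential (the μ's, s̄'s and
variances), six are algebraic: `r_α = Φ_r(μ_α, σ_α)`,
`τ_α = Φ_τ(μ_α, σ_α)`, and `σ_α` follows in closed form from the synaptic
variances, the delayed drives, and the external noise floor `σ_ext = 1.5
mV·ms^-1/2`. Rates reach the synapses after a delay indexed by the
*receiving* population (`d_E = 4 ms` for inputs to E, `d_I = 2 ms` for
inputs to I), making the system a delay differential-algebraic equation.
Control currents `u_E, u_I` add to the membrane-current equations; they are
handled internally in mV/ms and reported in nA (`1 mV/ms ≙ 0.2 nA` at
`C = 200 pF`, exact in floating point).

Units of `σ`: dimensional consistency of the membrane-current variance
(terms `2J²σ_s²τ_sτ_m/(τ_m+τ_s)`) forces `σ` in mV·ms^-1/2; the numerical
value of the external noise amplitude is 1.5.

## Transfer functions

`Φ_r` is the stationary rate of a single EIF neuron under Gaussian white
noise with mean `μ` and amplitude `σ`, obtained by threshold integration of
the stationary Fokker–Planck equation: the scaled density `p = P/r` is
integrated backward from an absorbing boundary at the spike threshold
`V_s = -40 mV` with an exponential (exact per-step) integrator, flux
reinjection at the reset `V_r = -70 mV`, a reflecting lower bound at
`V_lb = -200 mV` (halving it changes rates by < 0.1 %, verified by test),
voltage step 0.02 mV, and the refractory correction
`r = 1/(T_ref + ∫p dV)`. `Φ_r` is validated against Euler–Maruyama
simulations of the EIF neuron itself (agreement ≤ 1 % at rates above a few
Hz, within MC error).

`Φ_τ` — the timescale with which the mean membrane current relaxes — is
deliberately pinned only by its contract (positive, smooth, tabulated,
replaceable by an externally supplied table). The recipe implemented here:
solve the linearized Fokker–Planck system for the rate response `R(ω)` to
mean-input modulation at probe frequencies {1, 2.5, 5, 10, 20, 50} Hz and
fit a single-pole low-pass filter `R(0)/(1 + iωτ)` in least squares, with
`τ` clamped to [0.1, 100] ms. In the fluctuation-driven regime this gives
`τ` of order `τ_m`; in the mean-driven regime the rate tracks its input
nearly instantaneously (the response is flat or phase-advanced) and the fit
returns the lower clamp. The response solver is verified against
`∂Φ_r/∂μ` at ω → 0 (agreement ~1e-4 relative). Below a rate floor of
1e-12 kHz the response is numerically unresolved and `τ` is continued
constant toward low `μ`.

Both functions are tabulated on `μ ∈ [-10, 10] mV/ms × σ ∈ [0.5, 5]` at
401 × 81 nodes (0.05 mV/ms spacing in μ; chosen so that doubling the
resolution moves interpolated rates by < 1 % through the steep low-rate
knee) and interpolated bilinearly. The partial derivatives used by the
Jacobians are the exact derivatives of the bilinear interpolant, so the
forward model and the adjoint differentiate one identical function. Out-of
range queries raise by default; clamping to the bounding box (with zero
derivative in the clamped direction) is an explicit opt-in used by the
regime mapper and the strong-drive horizon sweeps, where optimal controls
intentionally push `μ` outside the free-dynamics envelope — mirroring
lookup-table saturation in table-driven implementations generally.

## Forward integration and its stability envelope

Forward Euler with `dt = 0.1 ms` (dt must divide both delays; the pre-t=0
history is constant at the initial state, appropriate because every task
starts from a settled fixed point). The synaptic equations are explicit and
have a finite stability envelope: the variance equations destabilize when
the excitatory rate exceeds ~150 Hz at `dt = 0.1`. During strong transients
Euler overshoots `s̄` and `σ²_s` by O(1e-3); states are therefore *not*
clipped, and the integration aborts (with the step index) only when a
variable leaves its admissible range by more than `s_tol = 1e-2`. The
horizon sweeps relax `s_tol` further because their short-horizon optima are
strong pulses. Cost evaluations of infeasible trials return +inf, which the
line search rejects — gradient consistency is never corrupted by clipping.

## Costs and the adjoint gradient

`F_P = ½·1/(T−t0)·∫_{t0}^T (r_E − r̃)² dt` with rates in Hz and time in ms;
`F1 = Σ_α √(∫ u_α² dt)` and `F2 = ½∫‖u‖² dt` with `u` in nA. All integrals
use trapezoid quadrature on the simulation grid. This unit system
reproduces printed-magnitude costs (a ~0.5 nA, ~50 ms pulse has F1 ≈ 3).
The L1 gradient normalizes each channel by its own L2 time-norm and is zero
on identically-zero channels; the L2 gradient is `u_α` itself (the actual
derivative of `½‖u‖²` — an absolute-value variant fails the
finite-difference oracle and is therefore not used).

The gradient is computed by the exact discrete adjoint
(discretize-then-differentiate) of the forward Euler scheme: one backward
sweep on the forward grid in which the six algebraic costate components are
eliminated pointwise and the delayed couplings appear as time-advanced
contributions active for `t ≤ T − d_α`, with `λ(T) = 0`. Because the
reverse pass is the exact transpose of the forward recursion, adjoint and
central finite-difference gradients agree to ~1e-7 relative (the FD
noise floor), rather than only to O(dt). An independent matrix-form
implementation of the same backward DAE recursion — solving the 6×6
algebraic block from the residual Jacobians at every step — is kept in the
test suite and agrees with the production kernel to 1e-8.

## Optimization

Gradient descent with a halving line search: start at `s = 10`, halve until
the cost passes its minimum, return the best improving step (0 if no step
above `ε_s = 1e-30` improves, which signals numerical convergence);
accepted iterations never increase the cost. Termination when every control
sample moves by less than `ε_u = 1e-12`, or on the iteration budget.
Line-search cost evaluations use a rate-buffer forward kernel plus
closed-form quadratics in the step size for the control-strength terms.

The staged task protocol per initialization: (1) ten iterations at `W = 10`
with the control restricted to the initialization's channels; (2) both
channels released; (3) annealing blocks of 30 iterations with
`W ~ U(0, W_max)` redrawn per block from a seeded generator, until the
reported cost stabilizes (relative change < 1e-9, at most 12 blocks in the
standard settings); (4) up to 300 final iterations at the reporting weight
`W = 1`, where the total cost is measured. `W_max` for the annealing is the
analytic crossover estimate `F_P(u=0)/F_j(u)` (beyond it, staying in the
initial state is cheaper than switching); the precise threshold is
available separately through a warm-started bisection (`find_W_max`,
1 % tolerance). Three rectangle initializations (±0.4 nA over
[210, 270] ms on E, on I, or both; signs flipped for up→down; the window
scales with T below 500 ms) compete, and the lowest-cost result wins. An
initialization whose transient leaves the integrator's stability envelope
is skipped and flagged rather than crashed on, and the remaining ones
compete.

Iteration budgets (10 + ≤360 annealed + 300 polish per initialization)
were fixed from convergence diagnostics — the reported cost typically
stabilizes to ~1e-9 relative within a few annealing blocks — and keep a
full four-task point under ~3 minutes on one core; deep convergence runs
(16 blocks, 1500 polish iterations) change converged costs by < 1e-5
relative and none of the qualitative outcomes.

## State-space analysis

The regime classifier settles the free model from a down-like probe
(inhibitory synapses engaged; an all-zero start transiently fires strongly
and can fall into the wrong basin) and an up-like probe for 2000 ms,
falling back to smaller `dt` (0.05, 0.02, 0.01) if the explicit integrator
blows up at high-rate nodes. Labels: *oscillatory* if the final-200 ms
peak-to-peak excitatory rate exceeds 1 Hz (far below limit-cycle
amplitudes, far above numerical drift); *bistable* if the two probes settle
more than 1 Hz apart; otherwise *down*/*up* split at 15 Hz. Axis and
shortest distances to a regime boundary are refined by bisection between
differing-label points to 1e-3 nA. Fixed-point stability uses a central
finite-difference Jacobian of the reduced ten-variable ODE
(algebraic block substituted self-consistently, delays collapsed — delays
do not move fixed points but can in principle affect stability, a known
approximation of this check). The basin-boundary saddle is found by
bisecting initial conditions along the line between the attractors, taking
the slowest mid-range point of the boundary trajectory, and polishing with
a Newton-type root solve of the reduced ODE; the long-horizon optimal
trajectories plateau at this saddle to ~1e-4 relative distance.

## What depends on the transfer-function backend

The package computes every quantity from its own first-principles transfer
tables. `Φ_r` is tied down by the Monte-Carlo oracle, but `Φ_τ` is an
under-determined modeling ingredient, and the *depth of the basins of
attraction* in the bistable regime turns out to be sensitive to this
backend: with the tables computed here, the down state at the reference
points is deeper in rate (~0.006 Hz) yet dynamically shallower than in
table-driven implementations with other `Φ` variants — a ~0.1 nA rectangle
already switches the state. Consequences, all visible in the acceptance
tests: converged switching costs are several-fold smaller than
literature-scale values obtained with a different backend; the E- and
I-channel optima are distinct local minima with clearly different costs
(so across-channel initialization degeneracy does not hold, while ±40 ms
time-shifted warm starts of one optimum do re-converge to equal cost at
five significant digits — the flat-plateau degeneracy survives); at some
bistable points the optimum is impulsive (a near-single-sample kick
suffices to tip the shallow basin), which breaks the linear scaling of the
*amplitude* with boundary distance even though the *cost*-versus-distance
correlations remain > 0.99; and the dominance pattern of the down→up tasks
shifts toward the excitatory channel. Externally generated tables can be
loaded through the same interface (`load_table`) to test bit-compatibility
against other implementations; all downstream code runs unchanged.

## Problem sizes used in tests and the reproduction script

Gradient-correctness checks run on a shrunken problem (T = 50 ms,
dt = 0.5 ms). The regime map for structural tests is 20×20 over
[0, 0.8]² nA; the scaling analysis samples 10 bistable nodes of an 11×11
map over the bistable window. The reproduction script runs the full
protocol (T = 500 ms, t0 = 480 ms, dt = 0.1 ms) for all eight tasks in a
few minutes of single-core time.

## Known limitations

- Forward Euler only; no adaptive or implicit integrator, so very strong
  drives require table clamping and a relaxed invariant guard.
- The deterministic (noise-free) model only; no stochastic forcing, no
  expectation-valued precision cost.
- Delay-free linearization for stability checks; no characteristic-equation
  analysis of the delayed system, no continuation of limit cycles.
- First-order optimizer; no box constraints on the control, no closed-loop
  control.
- `Φ_τ` rests on a single-pole fit of the linear response; the mean-driven
  regime is represented by the lower clamp of `τ`.
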