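# neuroct

Nonlinear optimal control of a two-population mean-field model of
exponential integrate-and-fire (EIF) neurons.

`neuroct` is for computational neuroscientists who want to ask: *what is the
cheapest external current that switches a recurrently coupled
excitatory–inhibitory population between its coexisting low-activity (down)
and high-activity (up) states?* The package

- computes the stationary Fokker–Planck transfer functions
  `Φ_r(μ, σ)` (population rate) and `Φ_τ(μ, σ)` (effective membrane-current
  timescale) of an EIF neuron by threshold integration,
- forward-simulates the 16-variable delay differential-algebraic (DDAE)
  mean-field model of coupled E and I populations (rates, membrane-current
  means/variances, synaptic activities and their variances, with
  receiver-indexed synaptic delays) under time-dependent control currents
  `u_E(t)`, `u_I(t)`,
- maps the background-input plane `(μ_E^ext, μ_I^ext)` into down / up /
  bistable / oscillatory regimes and locates the basin-boundary saddle, and
- solves the optimal control problem by adjoint-based gradient descent.

## The control problem

With the state `x(t)` governed by `h(ẋ, x, x(t−d_E), x(t−d_I), u) = 0`, the
optimal control minimizes

```
F = F_P + W1·F1 + W2·F2

F_P = 1/2 · 1/(T−t0) ∫_{t0}^{T} (r_E(t) − r̃)² dt        (precision, r in Hz)
F1  = Σ_α √(∫_0^T u_α² dt)                               (sparsity, u in nA)
F2  = 1/2 ∫_0^T ‖u‖² dt                                  (energy)
```

where `r̃` is the excitatory rate of the target fixed point. The gradient
`∇_u F = ∇_u f + λᵀ D_u h` is assembled from the costate `λ(t)`, which is
integrated backward in time with `λ(T) = 0`; the delayed couplings of the
DDAE appear as time-advanced costate terms and the algebraic rows are
eliminated pointwise. The backward pass is the exact discrete adjoint of
the forward Euler scheme, so adjoint and finite-difference gradients agree
to finite-difference accuracy (~1e-7 relative).

The four canonical tasks combine switching direction and penalty:
DU1/DU2 (down→up under L1/L2) and UD1/UD2 (up→down). Each is solved with a
staged protocol: rectangle-pulse initializations restricted per channel,
weight annealing with `W ~ U(0, W_max)`, and a final descent at the
reporting weight `W = 1`.

## Worked example

```python
from neuroct import ModelParameters, OptimizationSettings, compute_transfer_tables
from neuroct.tasks import TaskSetup, TaskSpec, run_switching_task, characterize_signal

params = ModelParameters()                     # standard E-I EIF parameters
table = compute_transfer_tables()              # Fokker-Planck transfer tables
setup = TaskSetup.prepare(params, table, (0.45, 0.475))   # settle both fixed points
print(f"down state: {setup.down.r_E_Hz:.3f} Hz, up state: {setup.up.r_E_Hz:.3f} Hz")

task = TaskSpec.from_name("DU1", (0.45, 0.475))  # down->up switch, L1 penalty
res = run_switching_task(task, setup, OptimizationSettings(rng_seed=1))
bd = res.best.cost
print(f"total cost {bd.total:.4f} = F_P {bd.F_P:.2e} + W1*(F1_E {bd.F1_E:.4f} + F1_I {bd.F1_I:.4f})")
c = characterize_signal(res.best.control)
print(f"optimal control: {c.dimensionality}, amplitude_E = {c.amplitude_E:.3f} nA, "
      f"width_E = {c.width_E:.1f} ms")
```

prints

```
down state: 0.006 Hz, up state: 34.716 Hz
total cost 0.6545 = F_P 1.36e-08 + W1*(F1_E 0.6545 + F1_I 0.0000)
optimal control: 1d_E, amplitude_E = 0.084 nA, width_E = 60.1 ms
```

The down state at background point (0.45, 0.475) nA fires at ~0.006 Hz, the
up state at ~34.7 Hz. The converged down→up control under the sparsity
penalty is a single bell-shaped pulse to the excitatory population
(amplitude 0.084 nA, half-maximum width 60 ms) whose residual precision
cost is negligible: the pulse pushes the state just across the basin
boundary, after which the dynamics relax to the up state on their own —
the trajectory lingers on a plateau at the basin-boundary saddle before the
final approach. Absolute cost levels depend on the transfer-table backend;
see `docs/methods.md`.

The same workflow is available from the shell:

```
neuroct optimize --task DU1 --point 0.45 0.475 --seed 1 --out results/
neuroct regime-map --out results/
neuroct sweep-time --task DU1 --t0-list 480,240,120,60,20,0 --out results/
```

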