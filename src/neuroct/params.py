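"""Parameter containers and unit conventions.

Internal unit system
--------------------
time            ms
voltage         mV
rates           kHz (= ms^-1)
mean input mu   mV ms^-1        (a current divided by the membrane capacitance)
noise sigma     mV ms^-1/2
control u       mV ms^-1 internally; user-facing I/O in nA

A mean input of 1 mV ms^-1 corresponds to a physical current of
``C * 1 mV/ms``; with C = 200 pF that is 0.2 nA.  The conversion is exact in
floating point (a multiplication by ``C/1000`` resp. ``1000/C``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "EIFParameters",
    "ModelParameters",
    "BackgroundInput",
    "nA_to_mvms",
    "mvms_to_nA",
]


def nA_to_mvms(current_nA: float, C_pF: float = 200.0) -> float:
    """Convert a current in nA to a capacitance-normalized drive in mV/ms."""
    return current_nA * 1000.0 / C_pF


def mvms_to_nA(mu_mvms: float, C_pF: float = 200.0) -> float:
    """Convert a capacitance-normalized drive in mV/ms to a current in nA."""
    return mu_mvms * C_pF / 1000.0


@dataclass(frozen=True)
class EIFParameters:
    """Single-neuron exponential integrate-and-fire parameters.

    The exponential spike-generating current is
    ``g_L * Delta_T * exp((V - V_T)/Delta_T)``; a spike is registered when the
    membrane voltage crosses ``V_s``, after which it is reset to ``V_r`` and
    clamped for the refractory time ``T_ref``.
    """

    C: float = 200.0       # membrane capacitance, pF
    g_L: float = 10.0      # leak conductance, nS
    E_L: float = -65.0     # leak reversal potential, mV
    Delta_T: float = 1.5   # threshold slope factor, mV
    V_T: float = -50.0     # threshold voltage, mV
    V_s: float = -40.0     # spike threshold, mV
    V_r: float = -70.0     # reset potential, mV
    T_ref: float = 1.5     # refractory time, ms

    def __post_init__(self) -> None:
        if not (self.V_r < self.V_T < self.V_s):
            raise ValueError(
                f"require V_r < V_T < V_s, got {self.V_r}, {self.V_T}, {self.V_s}"
            )
        for name in ("C", "g_L", "Delta_T", "T_ref"):
            if getattr(self, name) <= 0 and name != "T_ref":
                raise ValueError(f"{name} must be positive")
        if self.T_ref < 0:
            raise ValueError("T_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the two-population (E/I) EIF mean-field model.

    Synaptic couplings ``J_ab`` are maximum synaptic currents from population
    ``b`` to population ``a`` in mV/ms (inhibitory ones negative), ``c_ab``
    the maximum postsynaptic current amplitudes, ``K_E``/``K_I`` the mean
    in-degrees and ``d_E``/``d_I`` the synaptic delays *to* the excitatory and
    inhibitory population (receiver-indexed).
    """

    J_EE: float = 2.4
    J_EI: float = -3.3
    J_IE: float = 2.6
    J_II: float = -1.6
    c_EE: float = 0.3
    c_IE: float = 0.3
    c_EI: float = 0.5
    c_II: float = 0.5
    tau_s_E: float = 2.0    # excitatory synaptic time constant, ms
    tau_s_I: float = 5.0    # inhibitory synaptic time constant, ms
    d_E: float = 4.0        # synaptic delay to excitatory neurons, ms
    d_I: float = 2.0        # synaptic delay to inhibitory neurons, ms
    K_E: float = 800.0
    K_I: float = 200.0
    sigma_ext_E: float = 1.5   # mV ms^-1/2
    sigma_ext_I: float = 1.5   # mV ms^-1/2
    eif: EIFParameters = field(default_factory=EIFParameters)

    def __post_init__(self) -> None:
        if not (self.J_EE > 0 and self.J_IE > 0):
            raise ValueError("excitatory couplings J_EE, J_IE must be positive")
        if not (self.J_EI < 0 and self.J_II < 0):
            raise ValueError("inhibitory couplings J_EI, J_II must be negative")
        for name in ("c_EE", "c_IE", "c_EI", "c_II", "tau_s_E", "tau_s_I",
                     "d_E", "d_I", "K_E", "K_I", "sigma_ext_E", "sigma_ext_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def C(self) -> float:
        return self.eif.C

    @property
    def tau_m(self) -> float:
        return self.eif.tau_m

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BackgroundInput:
    """Static background drives to the E and I population (internal mV/ms)."""

    mu_E_ext: float
    mu_I_ext: float
    C: float = 200.0

    @classmethod
    def from_nA(cls, mu_E_nA: float, mu_I_nA: float, C: float = 200.0) -> "BackgroundInput":
        return cls(nA_to_mvms(mu_E_nA, C), nA_to_mvms(mu_I_nA, C), C)

    @property
    def as_nA(self) -> tuple[float, float]:
        return (mvms_to_nA(self.mu_E_ext, self.C), mvms_to_nA(self.mu_I_ext, self.C))

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.mu_E_ext) and math.isfinite(self.mu_I_ext)):
            raise ValueError("background inputs must be finite")
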