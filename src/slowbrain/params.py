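"""Model parameters for the adaptive E-I mean-field node and the brain network.

Units follow the convention of the mean-field model: currents are expressed as
current densities in mV/ms (multiply by the membrane capacitance C = 200 pF to
obtain nA, i.e. 1 mV/ms * C = 0.2 nA), rates are carried internally in kHz
(ms^-1) and converted to Hz only at I/O boundaries, times are in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import hashlib
import json


@dataclass(frozen=True)
class AdexParams:
    """Single-neuron AdEx parameters of the underlying spiking populations.

    With the subthreshold adaptation conductance ``a`` fixed at 0 the neuron
    reduces to an exponential integrate-and-fire model; spike-triggered
    adaptation acts at the population level (see :class:`NodeParams`).
    """

    C: float = 200.0        # membrane capacitance, pF
    g_L: float = 10.0       # leak conductance, nS
    E_L: float = -65.0      # leak reversal potential, mV
    Delta_T: float = 1.5    # threshold slope factor, mV
    V_T: float = -50.0      # threshold voltage, mV
    V_s: float = -40.0      # spike cutoff voltage, mV
    V_r: float = -70.0      # reset voltage, mV
    T_ref: float = 1.5      # refractory period, ms
    E_A: float = -80.0      # adaptation reversal potential, mV
    a: float = 0.0          # subthreshold adaptation conductance, nS

    def __post_init__(self) -> None:
        if not (self.V_r < self.V_T < self.V_s):
            raise ValueError("require V_r < V_T < V_s")
        if self.C <= 0 or self.g_L <= 0 or self.Delta_T <= 0 or self.T_ref < 0:
            raise ValueError("C, g_L, Delta_T must be > 0 and T_ref >= 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L

    def digest(self) -> str:
        """Stable hash of the parameter set, used to key cached tables."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class NodeParams:
    """Parameters of one cortical node (E and I population pair).

    Defaults are the reference parameterization of the whole-brain model;
    the six starred quantities (mu_E_ext, mu_I_ext, sigma_ou, b, tau_A and the
    network-level K_gl) are the free parameters explored by the fitting
    procedure.
    """

    # external drive
    mu_E_ext: float = 0.0       # mean external input to E, mV/ms *
    mu_I_ext: float = 0.0       # mean external input to I, mV/ms *
    sigma_ou: float = 0.0       # OU noise strength, mV/ms^(3/2) *
    tau_ou: float = 5.0         # OU time constant, ms
    sigma_ext: float = 1.5      # SD of external input, mV/ms

    # synaptic structure
    K_e: float = 800.0          # excitatory inputs per neuron
    K_i: float = 200.0          # inhibitory inputs per neuron
    c_EE: float = 0.3           # max AMPA PSC amplitude, mV/ms
    c_IE: float = 0.3
    c_EI: float = 0.5           # max GABA PSC amplitude, mV/ms
    c_II: float = 0.5
    J_EE: float = 2.4           # max synaptic current E->E, mV/ms
    J_IE: float = 2.6           # E->I
    J_EI: float = -3.3          # I->E
    J_II: float = -1.6          # I->I
    tau_s_E: float = 2.0        # excitatory synaptic time constant, ms
    tau_s_I: float = 5.0        # inhibitory synaptic time constant, ms
    d_E: float = 4.0            # synaptic delay onto E, ms
    d_I: float = 2.0            # synaptic delay onto I, ms

    # spike-frequency adaptation (E population only)
    b: float = 0.0              # spike-triggered adaptation increment, pA *
    tau_A: float = 600.0        # adaptation time constant, ms *
    a: float = 0.0              # subthreshold adaptation conductance, nS
    E_A: float = -80.0          # adaptation reversal, mV

    adex: AdexParams = field(default_factory=AdexParams)

    def __post_init__(self) -> None:
        if self.tau_s_E <= 0 or self.tau_s_I <= 0 or self.tau_ou <= 0:
            raise ValueError("time constants must be positive")
        if self.b < 0 or self.tau_A <= 0:
            raise ValueError("b must be >= 0 and tau_A > 0")
        if self.sigma_ou < 0:
            raise ValueError("sigma_ou must be >= 0")

    def with_(self, **kw) -> "NodeParams":
        return replace(self, **kw)


#: Bounds of the six free parameters explored by the evolutionary fit:
#: (mu_E_ext, mu_I_ext) mV/ms, b pA, tau_A ms, K_gl, sigma_ou mV/ms^(3/2).
FREE_PARAM_BOUNDS = {
    "mu_E_ext": (0.0, 4.0),
    "mu_I_ext": (0.0, 4.0),
    "b": (0.0, 20.0),
    "tau_A": (5.0, 5000.0),
    "K_gl": (100.0, 400.0),
    "sigma_ou": (0.0, 0.5),
}

#: Reference "sleep model" parameterization (an up-to-down solution of the
#: multi-objective fit): strong tonic drive, weak adaptation with a very slow
#: time constant, moderate noise.
SLEEP_MODEL = dict(
    mu_E_ext=3.3, mu_I_ext=3.7, b=3.2, tau_A=4765.0, K_gl=265.0, sigma_ou=0.37
)

#: Sleep-regime conditions for the reference surrogate connectome
#: (synthetic_connectome(80, seed=1)): identical to SLEEP_MODEL except for
#: the adaptation strength, which is set to the surrogate's own critical
#: value (onset of global waves, determined once by the adaptation scan;
#: the critical value is connectome-specific).
SLEEP_MODEL_SURROGATE = {**SLEEP_MODEL, "b": 3.6}
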