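"""Cell models: right-hand sides and gating functions.

Six models are defined, each as a pure derivative function over a named
state vector plus a parameter dataclass:

* ``NapHParams`` — 2D conductance-based neuron with persistent sodium
  (instantaneous activation) and h-current; the classic generator of
  theta-band subthreshold resonance (leak+capacitance = LPF, I_h = HPF,
  I_Na,p = amplifier), augmented with threshold/reset spiking.
* ``LIFParams`` — leaky integrate-and-fire.
* ``CalciumLIFParams`` — LIF plus a spike-triggered calcium current
  (gate K, trigger N_C) acting as a spiking-level HPF.
* ``PlasticLIFParams`` — LIF driven through an AMPA-like synapse with
  short-term depression (D) and facilitation (F); the effective
  synaptic conductance is g_S*S*D*F and the product D*F plays the role
  of release probability.
* ``PyrParams`` — 4D pyramidal cell (transient sodium with
  instantaneous activation, delayed-rectifier potassium, h-current).
* ``IntParams`` — Wang-Buzsaki interneuron, optionally extended with a
  fast non-inactivating potassium (M-like) current for gamma-band
  resonance.

All derivative functions share the uniform signature

    deriv(y, I, vpre, gE, Ee, gI, Ei, p, dy)

where ``I`` is the total injected current (bias + periodic drive +
noise, uA/cm^2), ``vpre`` a presynaptic voltage (used only by the
plastic-synapse LIF), ``gE``/``gI`` total excitatory/inhibitory
synaptic conductances with reversals ``Ee``/``Ei``, ``p`` the packed
parameter vector and ``dy`` the output buffer.  The functions are
numba-compiled so the same code serves both the Python API and the
compiled integration kernels.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .integrator import SpikeMechanism

__all__ = [
    "H",
    "NapHParams", "LIFParams", "CalciumLIFParams",
    "PlasticSynapseParams", "PlasticLIFParams", "PyrParams", "IntParams",
    "nap_h_deriv", "lif_deriv", "calcium_lif_deriv",
    "synapse_gate_deriv", "plasticity_deriv", "pyr_deriv", "int_deriv",
    "AMPA_TAU_R", "AMPA_TAU_D", "AMPA_E", "GABA_TAU_R", "GABA_TAU_D", "GABA_E",
]

# Synapse-class constants (AMPA-like and GABA_A-like), shared by every
# network preset.
AMPA_TAU_R, AMPA_TAU_D, AMPA_E = 0.1, 3.0, 0.0
GABA_TAU_R, GABA_TAU_D, GABA_E = 0.3, 9.0, -80.0


# --------------------------------------------------------------------------
# gating primitives

@njit(cache=True)
def H(V):
    """Sigmoid transmitter-release function H(V) = (1+tanh(V/4))/2."""
    return 0.5 * (1.0 + np.tanh(V / 4.0))


@njit(cache=True)
def _vtrap(x, b):
    # a*(V+c)/(1-exp(-(V+c)/b)) terms have a removable singularity at
    # x = V+c = 0 with limit a*b; branch explicitly to avoid 0/0.
    if abs(x) < 1e-7:
        return b + 0.5 * x
    return x / (1.0 - np.exp(-x / b))


@njit(cache=True)
def naph_p_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 38.0) / 6.5))


@njit(cache=True)
def naph_r_inf(V):
    return 1.0 / (1.0 + np.exp((V + 79.2) / 9.78))


# -- 4D pyramidal cell (Traub-type kinetics) --

@njit(cache=True)
def pyr_alpha_h(V):
    return 0.128 * np.exp(-(V + 50.0) / 18.0)


@njit(cache=True)
def pyr_beta_h(V):
    return 4.0 / (1.0 + np.exp(-(V + 27.0) / 5.0))


@njit(cache=True)
def pyr_alpha_m(V):
    return 0.32 * _vtrap(V + 54.0, 4.0)


@njit(cache=True)
def pyr_beta_m(V):
    return 0.28 * _vtrap(-(V + 27.0), 5.0)


@njit(cache=True)
def pyr_alpha_n(V):
    return 0.032 * _vtrap(V + 52.0, 5.0)


@njit(cache=True)
def pyr_beta_n(V):
    return 0.5 * np.exp(-(V + 57.0) / 40.0)


@njit(cache=True)
def pyr_m_inf(V):
    a = pyr_alpha_m(V)
    return a / (a + pyr_beta_m(V))


@njit(cache=True)
def pyr_r_inf(V):
    return 1.0 / (1.0 + np.exp((V + 82.9) / 12.4))


@njit(cache=True)
def pyr_tau_r(V):
    """h-gate time constant, bell-shaped, ~68 ms near rest."""
    return 136.36 * np.exp(0.033 * (V + 75.0)) / (1.0 + np.exp(0.083 * (V + 75.0)))


# -- Wang-Buzsaki interneuron (phi = 5 -> 0.2 prefactor on tau_h, tau_n) --

@njit(cache=True)
def wb_alpha_h(V):
    return 0.07 * np.exp(-(V + 58.0) / 20.0)


@njit(cache=True)
def wb_beta_h(V):
    return 1.0 / (1.0 + np.exp(-(V + 28.0) / 10.0))


@njit(cache=True)
def wb_alpha_m(V):
    return 0.2 * _vtrap(V + 35.0, 10.0)


@njit(cache=True)
def wb_beta_m(V):
    return 4.0 * np.exp(-(V + 60.0) / 18.0)


@njit(cache=True)
def wb_alpha_n(V):
    return 0.01 * _vtrap(V + 34.0, 10.0)


@njit(cache=True)
def wb_beta_n(V):
    return 0.125 * np.exp(-(V + 44.0) / 80.0)


@njit(cache=True)
def wb_m_inf(V):
    a = wb_alpha_m(V)
    return a / (a + wb_beta_m(V))


@njit(cache=True)
def wb_q_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


@njit(cache=True)
def wb_tau_q(V):
    """M-like gate time constant: canonical M-current kinetics sped up
    tenfold (peak ~9 ms instead of ~90 ms), giving gamma-band dynamics."""
    x = V + 35.0
    return 40.0 / (3.3 * np.exp(x / 20.0) + np.exp(-x / 20.0))


# --------------------------------------------------------------------------
# derivative functions (uniform signature)

@njit(cache=True)
def _d_naph(y, I, vpre, gE, Ee, gI, Ei, p, dy):
    V, r = y[0], y[1]
    C, gL, EL, gp, ENa, gh, Eh, tau_r = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7]
    Isyn = gE * (V - Ee) + gI * (V - Ei)
    dy[0] = (I - gL * (V - EL) - gp * naph_p_inf(V) * (V - ENa)
             - gh * r * (V - Eh) - Isyn) / C
    dy[1] = (naph_r_inf(V) - r) / tau_r


@njit(cache=True)
def _d_lif(y, I, vpre, gE, Ee, gI, Ei, p, dy):
    V = y[0]
    C, gL, EL = p[0], p[1], p[2]
    Isyn = gE * (V - Ee) + gI * (V - Ei)
    dy[0] = (I - gL * (V - EL) - Isyn) / C


@njit(cache=True)
def _d_calif(y, I, vpre, gE, Ee, gI, Ei, p, dy):
    V, K, NC = y[0], y[1], y[2]
    C, gL, EL, gC, ECa = p[0], p[1], p[2], p[3], p[4]
    tau_act, tau_inact, tau_deact = p[5], p[6], p[7]
    Isyn = gE * (V - Ee) + gI * (V - Ei)
    dy[0] = (I - gL * (V - EL) - gC * K * (V - ECa) - Isyn) / C
    dy[1] = NC * (1.0 - K) / tau_act - K / tau_inact
    dy[2] = -NC / tau_deact


@njit(cache=True)
def _d_plif(y, I, vpre, gE, Ee, gI, Ei, p, dy):
    V, S, D, F = y[0], y[1], y[2], y[3]
    C, gL, EL, gS, ES = p[0], p[1], p[2], p[3], p[4]
    tau_r, tau_d, tau_rd, tau_dep, tau_rf, tau_fac = p[5], p[6], p[7], p[8], p[9], p[10]
    use_dep, use_fac = p[11], p[12]
    Hv = H(vpre)
    Isyn = gS * S * D * F * (V - ES) + gE * (V - Ee) + gI * (V - Ei)
    dy[0] = (I - gL * (V - EL) - Isyn) / C
    dy[1] = Hv * (1.0 - S) / tau_r - S / tau_d
    dy[2] = (-Hv * D / tau_rd + (1.0 - D) / tau_dep) if use_dep > 0.5 else 0.0
    dy[3] = (Hv * (1.0 - F) / tau_rf - F / tau_fac) if use_fac > 0.5 else 0.0


@njit(cache=True)
def _d_pyr(y, I, vpre, gE, Ee, gI, Ei, p, dy):
    V, h, n, r = y[0], y[1], y[2], y[3]
    C, gL, EL, gNa, ENa, gK, EK, gh, Eh = (p[0], p[1], p[2], p[3], p[4],
                                           p[5], p[6], p[7], p[8])
    m = pyr_m_inf(V)
    Isyn = gE * (V - Ee) + gI * (V - Ei)
    dy[0] = (I - gL * (V - EL) - gNa * h * m ** 3 * (V - ENa)
             - gK * n ** 4 * (V - EK) - gh * r * (V - Eh) - Isyn) / C
    ah, bh = pyr_alpha_h(V), pyr_beta_h(V)
    an, bn = pyr_alpha_n(V), pyr_beta_n(V)
    dy[1] = ah * (1.0 - h) - bh * h
    dy[2] = an * (1.0 - n) - bn * n
    dy[3] = (pyr_r_inf(V) - r) / pyr_tau_r(V)


@njit(cache=True)
def _d_int(y, I, vpre, gE, Ee, gI, Ei, p, dy):
    V, h, n, q = y[0], y[1], y[2], y[3]
    C, gL, EL, gNa, ENa, gK, EK, gM = (p[0], p[1], p[2], p[3], p[4],
                                       p[5], p[6], p[7])
    m = wb_m_inf(V)
    Isyn = gE * (V - Ee) + gI * (V - Ei)
    dy[0] = (I - gL * (V - EL) - gNa * h * m ** 3 * (V - ENa)
             - gK * n ** 4 * (V - EK) - gM * q * (V - EK) - Isyn) / C
    ah, bh = wb_alpha_h(V), wb_beta_h(V)
    an, bn = wb_alpha_n(V), wb_beta_n(V)
    # phi = 5 temperature factor on the sodium/potassium gates
    dy[1] = (ah / (ah + bh) - h) * (ah + bh) / 0.2
    dy[2] = (an / (an + bn) - n) * (an + bn) / 0.2
    dy[3] = (wb_q_inf(V) - q) / wb_tau_q(V)


# --------------------------------------------------------------------------
# parameter containers

def _check_nonneg(**kw):
    for k, v in kw.items():
        if v < 0:
            raise ValueError(f"{k} must be >= 0, got {v}")


@dataclass
class NapHParams:
    """I_Na,p + I_h model (2 states: V, r)."""
    C: float = 1.0
    g_L: float = 0.1
    E_L: float = -65.0
    g_p: float = 0.1
    E_Na: float = 55.0
    g_h: float = 1.0
    E_h: float = -20.0
    tau_r: float = 100.0
    V_th: float = -50.0
    V_reset: float = -70.0
    V_peak: float = 50.0
    T_spike: float = 1.0

    state_names = ("V", "r")
    deriv = staticmethod(_d_naph)
    clip01 = (1,)

    def __post_init__(self):
        _check_nonneg(C=self.C, g_L=self.g_L, g_p=self.g_p, g_h=self.g_h)
        if self.C == 0:
            raise ValueError("C must be positive")

    def pack(self) -> np.ndarray:
        return np.array([self.C, self.g_L, self.E_L, self.g_p, self.E_Na,
                         self.g_h, self.E_h, self.tau_r])

    def spike_mechanism(self) -> SpikeMechanism:
        return SpikeMechanism(self.V_th, self.V_reset, self.V_peak, self.T_spike)

    def initial_state(self, V0: float | None = None) -> np.ndarray:
        V0 = self.E_L if V0 is None else V0
        return np.array([V0, float(naph_r_inf(V0))])

    @classmethod
    def hpf_variant(cls, **kw):
        """Reduced-capacitance (C=0.1), g_p=0 illustration of the pure
        h-current high-pass filter."""
        return cls(C=0.1, g_p=0.0, **kw)

    @classmethod
    def rc_variant(cls, **kw):
        """Passive membrane: g_p = g_h = 0 (analytic RC low-pass)."""
        return cls(g_p=0.0, g_h=0.0, **kw)


@dataclass
class LIFParams:
    """Leaky integrate-and-fire (1 state: V)."""
    C: float = 1.0
    g_L: float = 0.1
    E_L: float = -60.0
    V_th: float = -50.0
    V_reset: float = -60.0
    V_peak: float = 50.0
    T_spike: float = 1.0

    state_names = ("V",)
    deriv = staticmethod(_d_lif)
    clip01 = ()

    def __post_init__(self):
        _check_nonneg(C=self.C, g_L=self.g_L)

    def pack(self) -> np.ndarray:
        return np.array([self.C, self.g_L, self.E_L])

    def spike_mechanism(self) -> SpikeMechanism:
        return SpikeMechanism(self.V_th, self.V_reset, self.V_peak, self.T_spike)

    def initial_state(self, V0: float | None = None) -> np.ndarray:
        return np.array([self.E_L if V0 is None else V0])


@dataclass
class CalciumLIFParams:
    """LIF with spike-triggered calcium current (states: V, K, N_C).

    After each spike the trigger N_C jumps to ``N_reset`` and decays
    with tau_deact; while N_C > 0 the calcium gate K activates slowly
    (tau_act/N_C) and inactivates fast (tau_inact), transiently easing
    the next spike — a spiking-level high-pass filter.
    """
    C: float = 1.0
    g_L: float = 0.5
    E_L: float = -60.0
    g_C: float = 0.08
    E_Ca: float = 100.0
    tau_act: float = 50.0
    tau_inact: float = 5.0
    tau_deact: float = 70.0
    N_reset: float = 0.1
    V_th: float = -50.0
    V_reset: float = -70.0
    V_peak: float = 50.0
    T_spike: float = 1.0

    state_names = ("V", "K", "N_C")
    deriv = staticmethod(_d_calif)
    clip01 = (1, 2)

    def __post_init__(self):
        _check_nonneg(C=self.C, g_L=self.g_L, g_C=self.g_C)

    def pack(self) -> np.ndarray:
        return np.array([self.C, self.g_L, self.E_L, self.g_C, self.E_Ca,
                         self.tau_act, self.tau_inact, self.tau_deact])

    def spike_mechanism(self) -> SpikeMechanism:
        return SpikeMechanism(self.V_th, self.V_reset, self.V_peak,
                              self.T_spike, aux_resets=[("N_C", self.N_reset)])

    def initial_state(self, V0: float | None = None) -> np.ndarray:
        return np.array([self.E_L if V0 is None else V0, 0.0, 0.0])


@dataclass
class PlasticSynapseParams:
    """Short-term-plasticity synapse (gate S, depression D, facilitation F)."""
    g_S: float = 0.175
    E_S: float = 0.0
    tau_r: float = AMPA_TAU_R
    tau_d: float = AMPA_TAU_D
    tau_reset_d: float = 0.1
    tau_dep: float = 100.0
    tau_reset_f: float = 0.2
    tau_fac: float = 300.0
    use_depression: bool = True
    use_facilitation: bool = True

    def __post_init__(self):
        _check_nonneg(g_S=self.g_S)


@dataclass
class PlasticLIFParams:
    """LIF receiving one plastic synapse driven by a presynaptic-voltage
    trace (states: V, S, D, F)."""
    C: float = 1.0
    g_L: float = 0.1
    E_L: float = -65.0
    V_th: float = -50.0
    V_reset: float = -70.0
    V_peak: float = 50.0
    T_spike: float = 0.1
    syn: PlasticSynapseParams = field(default_factory=PlasticSynapseParams)

    state_names = ("V", "S", "D", "F")
    deriv = staticmethod(_d_plif)
    clip01 = (1, 2, 3)

    def pack(self) -> np.ndarray:
        s = self.syn
        return np.array([self.C, self.g_L, self.E_L, s.g_S, s.E_S,
                         s.tau_r, s.tau_d, s.tau_reset_d, s.tau_dep,
                         s.tau_reset_f, s.tau_fac,
                         1.0 if s.use_depression else 0.0,
                         1.0 if s.use_facilitation else 0.0])

    def spike_mechanism(self) -> SpikeMechanism:
        return SpikeMechanism(self.V_th, self.V_reset, self.V_peak, self.T_spike)

    def initial_state(self, V0: float | None = None) -> np.ndarray:
        # resting fixed points: S=0, D=1; F=0 when dynamic, pinned to 1
        # when facilitation is disabled
        F0 = 0.0 if self.syn.use_facilitation else 1.0
        D0 = 1.0
        return np.array([self.E_L if V0 is None else V0, 0.0, D0, F0])


@dataclass
class PyrParams:
    """4D pyramidal cell with I_h (states: V, h, n, r); full spike dynamics."""
    C: float = 1.0
    g_L: float = 0.1
    E_L: float = -67.0
    g_Na: float = 100.0
    E_Na: float = 50.0
    g_K: float = 80.0
    E_K: float = -100.0
    g_h: float = 0.485
    E_h: float = -33.0
    V_detect: float = 0.0

    state_names = ("V", "h", "n", "r")
    deriv = staticmethod(_d_pyr)
    clip01 = (1, 2, 3)

    def pack(self) -> np.ndarray:
        return np.array([self.C, self.g_L, self.E_L, self.g_Na, self.E_Na,
                         self.g_K, self.E_K, self.g_h, self.E_h])

    def spike_mechanism(self) -> SpikeMechanism:
        return SpikeMechanism.detector(self.V_detect)

    def initial_state(self, V0: float | None = None) -> np.ndarray:
        V0 = self.E_L if V0 is None else V0
        ah, bh = pyr_alpha_h(V0), pyr_beta_h(V0)
        an, bn = pyr_alpha_n(V0), pyr_beta_n(V0)
        return np.array([V0, ah / (ah + bh), an / (an + bn),
                         float(pyr_r_inf(V0))])


@dataclass
class IntParams:
    """Wang-Buzsaki interneuron, + fast M-like current when g_M > 0
    (states: V, h, n, q); full spike dynamics."""
    C: float = 1.0
    g_L: float = 0.1
    E_L: float = -65.0
    g_Na: float = 35.0
    E_Na: float = 55.0
    g_K: float = 9.0
    E_K: float = -90.0
    g_M: float = 4.0
    V_detect: float = 0.0

    state_names = ("V", "h", "n", "q")
    deriv = staticmethod(_d_int)
    clip01 = (1, 2, 3)

    def pack(self) -> np.ndarray:
        return np.array([self.C, self.g_L, self.E_L, self.g_Na, self.E_Na,
                         self.g_K, self.E_K, self.g_M])

    def spike_mechanism(self) -> SpikeMechanism:
        return SpikeMechanism.detector(self.V_detect)

    def initial_state(self, V0: float | None = None) -> np.ndarray:
        V0 = self.E_L if V0 is None else V0
        ah, bh = wb_alpha_h(V0), wb_beta_h(V0)
        an, bn = wb_alpha_n(V0), wb_beta_n(V0)
        return np.array([V0, ah / (ah + bh), an / (an + bn),
                         float(wb_q_inf(V0))])


# --------------------------------------------------------------------------
# spec-level convenience wrappers (scalar in, scalar out)

def _call(deriv, y, I, vpre, p, n):
    y = np.asarray(y, dtype=float)
    dy = np.empty(n)
    deriv(y, float(I), float(vpre), 0.0, 0.0, 0.0, 0.0, p, dy)
    return dy


def nap_h_deriv(V, r, I_in, params: NapHParams | None = None):
    """(dV/dt, dr/dt) for the I_Na,p + I_h model."""
    params = params or NapHParams()
    d = _call(_d_naph, [V, r], I_in, 0.0, params.pack(), 2)
    return d[0], d[1]


def lif_deriv(V, I_in, params: LIFParams | None = None):
    params = params or LIFParams()
    return _call(_d_lif, [V], I_in, 0.0, params.pack(), 1)[0]


def calcium_lif_deriv(V, K, N_C, I_in, params: CalciumLIFParams | None = None):
    params = params or CalciumLIFParams()
    d = _call(_d_calif, [V, K, N_C], I_in, 0.0, params.pack(), 3)
    return d[0], d[1], d[2]


def synapse_gate_deriv(S, V_pre, tau_r=AMPA_TAU_R, tau_d=AMPA_TAU_D):
    """dS/dt = H(V_pre)(1-S)/tau_r - S/tau_d."""
    return H(V_pre) * (1.0 - S) / tau_r - S / tau_d


def plasticity_deriv(D, F, V_pre, syn: PlasticSynapseParams | None = None):
    """(dD/dt, dF/dt) for the depression/facilitation factors."""
    syn = syn or PlasticSynapseParams()
    Hv = H(V_pre)
    dD = -Hv * D / syn.tau_reset_d + (1.0 - D) / syn.tau_dep
    dF = Hv * (1.0 - F) / syn.tau_reset_f - F / syn.tau_fac
    return dD, dF


def pyr_deriv(V, h, n, r, I_in, I_syn=0.0, params: PyrParams | None = None):
    """Derivatives of the 4D pyramidal cell; I_syn is subtracted from I_in."""
    params = params or PyrParams()
    d = _call(_d_pyr, [V, h, n, r], I_in - I_syn, 0.0, params.pack(), 4)
    return d[0], d[1], d[2], d[3]


def int_deriv(V, h, n, q, I_in, I_syn=0.0, params: IntParams | None = None):
    params = params or IntParams()
    d = _call(_d_int, [V, h, n, q], I_in - I_syn, 0.0, params.pack(), 4)
    return d[0], d[1], d[2], d[3]
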