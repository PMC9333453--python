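"""Network motifs: all-to-all E/I coupling and the 3-layer feedforward net.

Synaptic formalism: each presynaptic neuron owns one activation gate

    dS/dt = H(V_pre)*(1-S)/tau_r - S/tau_d

shared by all of its postsynaptic targets, so state count scales with
cells, not synapse pairs.  The total synaptic current onto a cell is

    I_syn = sum_j g_class * S_j * (V_post - E_class)

summed over presynaptic partners by class (AMPA-like: tau_r/tau_d =
0.1/3 ms, E = 0 mV; GABA_A-like: 0.3/9 ms, E = -80 mV), entering the
voltage equation with a minus sign.  All-to-all sums include the
self-synapse; this only matters where a preset gives the corresponding
class a nonzero conductance (g_ii in the E/I presets).

Presets mirror the three shipped parameter tables (``presets/*.yaml``)
row-for-row; ``build_preset`` returns the exact constellation for each
figure-level experiment.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from numba import njit

from . import models as M
from .integrator import (SimResult, SimulationConfig, SimulationDivergedError,
                         trial_rng)
from .stimuli import SpikeTrain, StimulusTrace, make_chirp, make_constant

__all__ = [
    "Population",
    "NetworkSpec",
    "LayeredFeedforwardSpec",
    "total_synaptic_current",
    "build_preset",
    "simulate_network",
    "PRESET_NAMES",
]


def settled_state(model, I_bias: float, dt: float = 0.1,
                  settle_s: float = 1.0) -> np.ndarray:
    """Resting state of a cell under constant bias current.

    For threshold-reset models the subthreshold fixed point is found
    directly (dV/dt = 0 with gates at steady state, restricted to
    V < V_th); starting a simulation elsewhere can fire spurious
    onset spikes or, with spiking disabled, drift to a depolarised
    fixed point.  For the full-spike-dynamics models (PYR, INT) the
    state is settled by integration.
    """
    from scipy.optimize import brentq

    if isinstance(model, (M.PyrParams, M.IntParams)):
        from .integrator import integrate
        stim = make_constant(I_bias, settle_s, dt)
        res = integrate(model, stim, spike_mech=False)
        return np.array([res.V[-1]] +
                        [res.aux[k][-1] for k in model.state_names[1:]])
    if isinstance(model, M.NapHParams):
        def g(V):
            return (I_bias - model.g_L * (V - model.E_L)
                    - model.g_p * M.naph_p_inf(V) * (V - model.E_Na)
                    - model.g_h * M.naph_r_inf(V) * (V - model.E_h))
        grid = np.arange(model.V_th - 0.05, -120.0, -0.5)
        vals = np.array([g(v) for v in grid])
        sign_change = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
        if sign_change.size == 0:
            return model.initial_state()
        i = sign_change[0]
        V0 = brentq(g, grid[i + 1], grid[i])
        return model.initial_state(V0)
    # LIF family: linear subthreshold rest, capped at threshold
    V0 = model.E_L + I_bias / model.g_L if model.g_L > 0 else model.E_L
    return model.initial_state(min(V0, model.V_th))


def total_synaptic_current(V_post: float, terms) -> float:
    """I_syn = sum_j g_j * S_j * (V_post - E_j)  (uA/cm^2).

    ``terms`` iterates over (g, S, E_rev) triples.  The value is
    subtracted in dV/dt, so an excitatory synapse (E_rev > V_post)
    yields a negative I_syn, i.e. a depolarizing contribution.
    """
    return float(sum(g * S * (V_post - E) for g, S, E in terms))


# --------------------------------------------------------------------------
# specs

@dataclass
class Population:
    """One homogeneous population and its drive assignment."""
    name: str
    model: object                # a params dataclass from .models
    n: int
    sigma: float = 0.0
    I_bias: float = 0.0
    A_in: float = 0.0


@dataclass
class NetworkSpec:
    """All-to-all E/I network (covers 16E->4I and INT->PYR motifs)."""
    e_pop: Population
    i_pop: Population
    g_ee: float = 0.0
    g_ei: float = 0.0
    g_ie: float = 0.0
    g_ii: float = 0.0
    E_e: float = M.AMPA_E
    E_i: float = M.GABA_E
    tau_r_e: float = M.AMPA_TAU_R
    tau_d_e: float = M.AMPA_TAU_D
    tau_r_i: float = M.GABA_TAU_R
    tau_d_i: float = M.GABA_TAU_D
    chirp: tuple = (0.0, 40.0, 20.0)   # (f0, f1, T_s)

    def drives(self, dt: float) -> dict:
        """Per-population drive traces: I_bias + A_in * chirp waveform."""
        f0, f1, T = self.chirp
        out = {}
        for key, pop in (("e", self.e_pop), ("i", self.i_pop)):
            if pop.A_in != 0.0:
                out[key] = make_chirp(f0, f1, pop.A_in, pop.I_bias, T, dt)
            else:
                out[key] = make_constant(pop.I_bias, T, dt)
        return out


@dataclass
class LayeredFeedforwardSpec:
    """Diverging/converging feedforward net: 1 point-process source ->
    n2 plastic-synapse LIF -> 1 plain-synapse LIF.

    Layer 1 is a spike-train source (one spike per chirp cycle), not an
    ODE cell; every layer-2 neuron receives the same presynaptic gate
    and independent noise; layer 3 receives no noise.
    """
    n2: int = 50
    cell2: M.PlasticLIFParams = field(default_factory=lambda: M.PlasticLIFParams(
        syn=M.PlasticSynapseParams(g_S=0.2)))
    cell3: M.LIFParams = field(default_factory=lambda: M.LIFParams(
        E_L=-65.0, V_reset=-70.0, T_spike=0.1))
    g_s23: float = 0.12       # per-synapse, as in the per-connection formalism
    E_s23: float = M.AMPA_E
    sigma2: float = 0.25
    I_bias2: float = 1.2
    I_bias3: float = 0.0
    chirp: tuple = (0.0, 40.0, 20.0)
    pulse_ms: float = 0.1     # presynaptic-voltage pulse width (= T_spike)


PRESET_NAMES = ("fig2_EI", "fig2H_EI", "fig4_EI", "fig5_layers",
                "fig6_depression", "fig7_int_pyr", "fig8_gammaint_pyr",
                "fig8A_gamma_int", "fig8B_gamma_int", "fig7A_pyr")


def _load_table(name: str, variant: str | None = None) -> dict:
    path = importlib.resources.files("neurores.presets") / f"{name}.yaml"
    tab = yaml.safe_load(path.read_text())
    if variant is not None:
        tab.update(tab["variants"][variant])
    tab.pop("variants", None)
    return tab


def build_preset(name: str):
    """Return (spec, SimulationConfig) for a named figure-level preset."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid: {PRESET_NAMES}")

    if name in ("fig2_EI", "fig2H_EI"):
        t = _load_table("table1", "direct_to_I" if name == "fig2H_EI" else None)
        e_model = M.NapHParams(C=t["C"], g_L=t["g_L"], E_L=t["E_L_e"],
                               g_p=t["g_p"], E_Na=t["E_Na"], g_h=t["g_h"],
                               E_h=t["E_h"], tau_r=t["tau_h"], V_th=t["V_th"],
                               V_reset=t["V_reset_e"], V_peak=t["V_peak"],
                               T_spike=t["T_spike_e"])
        i_model = M.LIFParams(C=t["C"], g_L=t["g_L"], E_L=t["E_L_i"],
                              V_th=t["V_th"], V_reset=t["V_reset_i"],
                              V_peak=t["V_peak"], T_spike=t["T_spike_i"])
        spec = NetworkSpec(
            e_pop=Population("naph_E", e_model, t["N_e"], t["sigma_e"],
                             t["I_bias_e"], t["A_in_e"]),
            i_pop=Population("nrLIF_I", i_model, t["N_i"], t["sigma_i"],
                             t["I_bias_i"], t["A_in_i"]),
            g_ee=t["g_ee"], g_ei=t["g_ei"], g_ie=t["g_ie"], g_ii=t["g_ii"],
            E_e=t["E_e"], E_i=t["E_i"], tau_r_e=t["tau_r_e"],
            tau_d_e=t["tau_d_e"], tau_r_i=t["tau_r_i"], tau_d_i=t["tau_d_i"],
            chirp=(t["chirp"]["f0"], t["chirp"]["f1"], t["chirp"]["T"]))
        cfg = SimulationConfig(dt=t["dt"], T=t["chirp"]["T"])
        return spec, cfg

    if name == "fig4_EI":
        t = _load_table("table2")
        mk = lambda: M.LIFParams(C=t["C"], g_L=t["g_L"], E_L=t["E_L"],
                                 V_th=t["V_th"], V_reset=t["V_reset"],
                                 V_peak=t["V_peak"], T_spike=t["T_spike"])
        spec = NetworkSpec(
            e_pop=Population("rLIF_E", mk(), t["N_e"], t["sigma_e"],
                             t["I_bias_e"], t["A_in_e"]),
            i_pop=Population("nrLIF_I", mk(), t["N_i"], t["sigma_i"],
                             t["I_bias_i"], t["A_in_i"]),
            g_ee=t["g_ee"], g_ei=t["g_ei"], g_ie=t["g_ie"], g_ii=t["g_ii"],
            E_e=t["E_e"], E_i=t["E_i"], tau_r_e=t["tau_r_e"],
            tau_d_e=t["tau_d_e"], tau_r_i=t["tau_r_i"], tau_d_i=t["tau_d_i"],
            chirp=(t["chirp"]["f0"], t["chirp"]["f1"], t["chirp"]["T"]))
        return spec, SimulationConfig(dt=t["dt"], T=t["chirp"]["T"])

    if name == "fig5_layers":
        spec = LayeredFeedforwardSpec()
        return spec, SimulationConfig(dt=0.1, T=20.0)

    if name == "fig6_depression":
        # single LIF with depression-only plastic synapse (EPSP-driven)
        model = M.PlasticLIFParams(syn=M.PlasticSynapseParams(
            use_facilitation=False))
        return model, SimulationConfig(dt=0.1, T=20.0)

    # Table-3 family
    variant = {"fig7_int_pyr": "int_pyr",
               "fig7A_pyr": "pyr_direct",
               "fig8_gammaint_pyr": "gamma_int_pyr",
               "fig8A_gamma_int": "gamma_int_impedance",
               "fig8B_gamma_int": "gamma_int_spiking"}[name]
    t = _load_table("table3", variant)
    pyr = M.PyrParams(C=t["C_e"], g_L=t["g_L_e"], E_L=t["E_L_e"],
                      g_Na=t["g_Na_e"], E_Na=t["E_Na_e"], g_K=t["g_K_e"],
                      E_K=t["E_K_e"], g_h=t["g_h_e"], E_h=t["E_h_e"])
    intn = M.IntParams(C=t["C_i"], g_L=t["g_L_i"], E_L=t["E_L_i"],
                       g_Na=t["g_Na_i"], E_Na=t["E_Na_i"], g_K=t["g_K_i"],
                       E_K=t["E_K_i"], g_M=t["g_M_i"])
    spec = NetworkSpec(
        e_pop=Population("PYR", pyr, 1, t["sigma_e"], t["I_bias_e"], t["A_in_e"]),
        i_pop=Population("INT", intn, 1, t["sigma_i"], t["I_bias_i"], t["A_in_i"]),
        g_ee=t["g_ee"], g_ei=t["g_ei"], g_ie=t["g_ie"], g_ii=t["g_ii"],
        E_e=t["E_e"], E_i=t["E_i"], tau_r_e=t["tau_r_e"], tau_d_e=t["tau_d_e"],
        tau_r_i=t["tau_r_i"], tau_d_i=t["tau_d_i"],
        chirp=(t["chirp"]["f0"], t["chirp"]["f1"], t["chirp"]["T"]))
    return spec, SimulationConfig(dt=t["dt"], T=t["chirp"]["T"])


# --------------------------------------------------------------------------
# kernels

@njit(cache=True)
def _Hn(V):
    return 0.5 * (1.0 + np.tanh(V / 4.0))


@njit(cache=True)
def _ei_kernel(deriv_e, p_e, y0_e, mode_e, Vth_e, Vres_e, Vpk_e, ncl_e,
               clip_e, clip_i,
               deriv_i, p_i, y0_i, mode_i, Vth_i, Vres_i, Vpk_i, ncl_i,
               gee, gei, gie, gii, Ee, Ei,
               tau_re, tau_de, tau_ri, tau_di,
               Ie, Ii, noise, dt, max_spikes):
    Ne, me = y0_e.shape
    Ni, mi = y0_i.shape
    N = Ne + Ni
    n = Ie.shape[0]
    mmax = max(me, mi)
    Y = np.zeros((N, mmax))
    for c in range(Ne):
        Y[c, :me] = y0_e[c]
    for c in range(Ni):
        Y[Ne + c, :mi] = y0_i[c]
    S = np.zeros(N)
    K1 = np.empty((N, mmax))
    K2 = np.empty((N, mmax))
    YP = np.empty((N, mmax))
    dS1 = np.empty(N)
    dS2 = np.empty(N)
    SP = np.empty(N)
    Vrec = np.empty((n, N))
    spikes = np.empty((N, max_spikes))
    nsp = np.zeros(N, dtype=np.int64)
    clamp = np.zeros(N, dtype=np.int64)
    for c in range(N):
        Vrec[0, c] = Y[c, 0]
    for i in range(n - 1):
        # clamp overrides
        for c in range(N):
            if clamp[c] > 0:
                Y[c, 0] = Vpk_e if c < Ne else Vpk_i
        sumSe = 0.0
        sumSi = 0.0
        for c in range(Ne):
            sumSe += S[c]
        for c in range(Ni):
            sumSi += S[Ne + c]
        # stage 1
        for c in range(N):
            if c < Ne:
                gE = gee * sumSe
                gI = gei * sumSi
                deriv_e(Y[c, :me], Ie[i] + noise[c, i], 0.0, gE, Ee, gI, Ei,
                        p_e, K1[c, :me])
            else:
                gE = gie * sumSe
                gI = gii * sumSi
                deriv_i(Y[c, :mi], Ii[i] + noise[c, i], 0.0, gE, Ee, gI, Ei,
                        p_i, K1[c, :mi])
        for c in range(N):
            tr = tau_re if c < Ne else tau_ri
            td = tau_de if c < Ne else tau_di
            dS1[c] = _Hn(Y[c, 0]) * (1.0 - S[c]) / tr - S[c] / td
        # predictor
        for c in range(N):
            m = me if c < Ne else mi
            for j in range(m):
                YP[c, j] = Y[c, j] + dt * K1[c, j]
            if clamp[c] > 0:
                YP[c, 0] = Vpk_e if c < Ne else Vpk_i
            SP[c] = S[c] + dt * dS1[c]
        sumSe = 0.0
        sumSi = 0.0
        for c in range(Ne):
            sumSe += SP[c]
        for c in range(Ni):
            sumSi += SP[Ne + c]
        # stage 2
        for c in range(N):
            if c < Ne:
                gE = gee * sumSe
                gI = gei * sumSi
                deriv_e(YP[c, :me], Ie[i + 1] + noise[c, i], 0.0, gE, Ee,
                        gI, Ei, p_e, K2[c, :me])
            else:
                gE = gie * sumSe
                gI = gii * sumSi
                deriv_i(YP[c, :mi], Ii[i + 1] + noise[c, i], 0.0, gE, Ee,
                        gI, Ei, p_i, K2[c, :mi])
        for c in range(N):
            tr = tau_re if c < Ne else tau_ri
            td = tau_de if c < Ne else tau_di
            dS2[c] = _Hn(YP[c, 0]) * (1.0 - SP[c]) / tr - SP[c] / td
        # update
        for c in range(N):
            m = me if c < Ne else mi
            v_old = Y[c, 0]
            for j in range(m):
                Y[c, j] = Y[c, j] + 0.5 * dt * (K1[c, j] + K2[c, j])
            S[c] = S[c] + 0.5 * dt * (dS1[c] + dS2[c])
            if S[c] < 0.0:
                S[c] = 0.0
            elif S[c] > 1.0:
                S[c] = 1.0
            clip = clip_e if c < Ne else clip_i
            for j in range(clip.shape[0]):
                cj = clip[j]
                if Y[c, cj] < 0.0:
                    Y[c, cj] = 0.0
                elif Y[c, cj] > 1.0:
                    Y[c, cj] = 1.0
            mode = mode_e if c < Ne else mode_i
            Vth = Vth_e if c < Ne else Vth_i
            Vres = Vres_e if c < Ne else Vres_i
            Vpk = Vpk_e if c < Ne else Vpk_i
            ncl = ncl_e if c < Ne else ncl_i
            if clamp[c] > 0:
                Y[c, 0] = Vpk
                clamp[c] -= 1
                if clamp[c] == 0:
                    Y[c, 0] = Vres
            else:
                if not np.isfinite(Y[c, 0]) or abs(Y[c, 0]) > 200.0:
                    return Vrec[:i + 2], spikes, nsp, 1, c
                if mode == 0 and Y[c, 0] > Vth:
                    if nsp[c] >= max_spikes:
                        return Vrec[:i + 2], spikes, nsp, 2, c
                    spikes[c, nsp[c]] = (i + 1) * dt
                    nsp[c] += 1
                    if ncl > 0:
                        Y[c, 0] = Vpk
                        clamp[c] = ncl
                    else:
                        Y[c, 0] = Vres
                elif mode == 1 and v_old <= Vth < Y[c, 0]:
                    if nsp[c] >= max_spikes:
                        return Vrec[:i + 2], spikes, nsp, 2, c
                    spikes[c, nsp[c]] = (i + 1) * dt
                    nsp[c] += 1
            Vrec[i + 1, c] = Y[c, 0]
    return Vrec, spikes, nsp, 0, -1


@njit(cache=True)
def _layers_kernel(p2, psyn, vpre1, Ib2, noise2, gS12, ES12,
                   p3, gS23, ES23, Ib3,
                   Vth, Vres, Vpk, ncl, dt, n2, EL2, EL3, V20, V30,
                   max_spikes):
    n = vpre1.shape[0]
    tau_r, tau_d = psyn[0], psyn[1]
    tau_rd, tau_dep, tau_rf, tau_fac = psyn[2], psyn[3], psyn[4], psyn[5]
    use_dep, use_fac = psyn[6], psyn[7]
    C2, gL2 = p2[0], p2[1]
    C3, gL3 = p3[0], p3[1]
    # shared input gate (S1, D1, F1)
    S1, D1 = 0.0, 1.0
    F1 = 0.0 if use_fac > 0.5 else 1.0
    V2 = np.full(n2, V20)
    S2 = np.zeros(n2)
    V3 = V30
    clamp = np.zeros(n2 + 1, dtype=np.int64)
    spikes = np.empty((n2 + 1, max_spikes))
    nsp = np.zeros(n2 + 1, dtype=np.int64)
    Vrec = np.empty((n, 2))     # V of layer-2 cell 0 and of layer 3
    Vrec[0, 0] = V2[0]
    Vrec[0, 1] = V3
    for i in range(n - 1):
        for c in range(n2):
            if clamp[c] > 0:
                V2[c] = Vpk
        if clamp[n2] > 0:
            V3 = Vpk

        # ---- stage 1
        Hv = _Hn(vpre1[i])
        dS1a = Hv * (1.0 - S1) / tau_r - S1 / tau_d
        dD1a = (-Hv * D1 / tau_rd + (1.0 - D1) / tau_dep) if use_dep > 0.5 else 0.0
        dF1a = (Hv * (1.0 - F1) / tau_rf - F1 / tau_fac) if use_fac > 0.5 else 0.0
        g12 = gS12 * S1 * D1 * F1
        dV2a = np.empty(n2)
        dS2a = np.empty(n2)
        sS2 = 0.0
        for c in range(n2):
            dV2a[c] = (Ib2 + noise2[c, i] - gL2 * (V2[c] - EL2)
                       - g12 * (V2[c] - ES12)) / C2
            dS2a[c] = _Hn(V2[c]) * (1.0 - S2[c]) / tau_r - S2[c] / tau_d
            sS2 += S2[c]
        dV3a = (Ib3 - gL3 * (V3 - EL3) - gS23 * sS2 * (V3 - ES23)) / C3

        # ---- predictor
        S1p = S1 + dt * dS1a
        D1p = D1 + dt * dD1a
        F1p = F1 + dt * dF1a
        V2p = np.empty(n2)
        S2p = np.empty(n2)
        for c in range(n2):
            V2p[c] = V2[c] + dt * dV2a[c]
            if clamp[c] > 0:
                V2p[c] = Vpk
            S2p[c] = S2[c] + dt * dS2a[c]
        V3p = V3 + dt * dV3a
        if clamp[n2] > 0:
            V3p = Vpk

        # ---- stage 2
        Hv = _Hn(vpre1[i + 1])
        dS1b = Hv * (1.0 - S1p) / tau_r - S1p / tau_d
        dD1b = (-Hv * D1p / tau_rd + (1.0 - D1p) / tau_dep) if use_dep > 0.5 else 0.0
        dF1b = (Hv * (1.0 - F1p) / tau_rf - F1p / tau_fac) if use_fac > 0.5 else 0.0
        g12 = gS12 * S1p * D1p * F1p
        sS2 = 0.0
        for c in range(n2):
            sS2 += S2p[c]
        dV3b = (Ib3 - gL3 * (V3p - EL3) - gS23 * sS2 * (V3p - ES23)) / C3

        S1 = min(max(S1 + 0.5 * dt * (dS1a + dS1b), 0.0), 1.0)
        D1 = min(max(D1 + 0.5 * dt * (dD1a + dD1b), 0.0), 1.0)
        F1 = min(max(F1 + 0.5 * dt * (dF1a + dF1b), 0.0), 1.0)
        for c in range(n2):
            dV2b = (Ib2 + noise2[c, i] - gL2 * (V2p[c] - EL2)
                    - g12 * (V2p[c] - ES12)) / C2
            dS2b = _Hn(V2p[c]) * (1.0 - S2p[c]) / tau_r - S2p[c] / tau_d
            V2[c] = V2[c] + 0.5 * dt * (dV2a[c] + dV2b)
            S2[c] = min(max(S2[c] + 0.5 * dt * (dS2a[c] + dS2b), 0.0), 1.0)
        V3 = V3 + 0.5 * dt * (dV3a + dV3b)

        # ---- spikes / clamps (layer-2 cells then layer 3)
        for c in range(n2):
            if clamp[c] > 0:
                V2[c] = Vpk
                clamp[c] -= 1
                if clamp[c] == 0:
                    V2[c] = Vres
            else:
                if not np.isfinite(V2[c]) or abs(V2[c]) > 200.0:
                    return Vrec[:i + 2], spikes, nsp, 1, c
                if V2[c] > Vth:
                    if nsp[c] >= max_spikes:
                        return Vrec[:i + 2], spikes, nsp, 2, c
                    spikes[c, nsp[c]] = (i + 1) * dt
                    nsp[c] += 1
                    if ncl > 0:
                        V2[c] = Vpk
                        clamp[c] = ncl
                    else:
                        V2[c] = Vres
        if clamp[n2] > 0:
            V3 = Vpk
            clamp[n2] -= 1
            if clamp[n2] == 0:
                V3 = Vres
        else:
            if not np.isfinite(V3) or abs(V3) > 200.0:
                return Vrec[:i + 2], spikes, nsp, 1, n2
            if V3 > Vth:
                if nsp[n2] >= max_spikes:
                    return Vrec[:i + 2], spikes, nsp, 2, n2
                spikes[n2, nsp[n2]] = (i + 1) * dt
                nsp[n2] += 1
                if ncl > 0:
                    V3 = Vpk
                    clamp[n2] = ncl
                else:
                    V3 = Vres
        Vrec[i + 1, 0] = V2[0]
        Vrec[i + 1, 1] = V3
    return Vrec, spikes, nsp, 0, -1


# --------------------------------------------------------------------------
# drivers

def _mech_tuple(model, dt):
    mech = model.spike_mechanism()
    if mech.mode == "detect":
        return 1, mech.V_th, 0.0, 0.0, 0
    return (0, mech.V_th, mech.V_reset, mech.V_peak,
            int(round(mech.T_spike / dt)))


def simulate_network(spec, config: SimulationConfig, trial_id: int = 0,
                     drives: dict | None = None,
                     vpre1: StimulusTrace | None = None) -> SimResult:
    """Run one trial of a network preset.

    For ``NetworkSpec``: each population receives its own drive
    (I_bias + A_in-scaled chirp) and per-cell independent noise; the
    stream for cell c in trial k derives from (master_seed, c, k).
    For ``LayeredFeedforwardSpec``: ``vpre1`` is the layer-1
    presynaptic-voltage trace (built from the input spike train); if
    omitted it is generated from the spec's chirp (one spike per cycle).
    """
    dt = config.dt
    if isinstance(spec, LayeredFeedforwardSpec):
        return _simulate_layers(spec, config, trial_id, vpre1)
    if not isinstance(spec, NetworkSpec):
        raise TypeError(f"cannot simulate spec of type {type(spec).__name__}")

    if drives is None:
        drives = spec.drives(dt)
    Ie, Ii = drives["e"].value, drives["i"].value
    n = Ie.size
    Ne, Ni = spec.e_pop.n, spec.i_pop.n
    N = Ne + Ni
    noise = np.zeros((N, n - 1))
    for c in range(N):
        sig = spec.e_pop.sigma if c < Ne else spec.i_pop.sigma
        if sig > 0:
            noise[c] = trial_rng(config.master_seed, c, trial_id).normal(
                0.0, sig, n - 1) / np.sqrt(0.1 * dt)
    em, im = spec.e_pop.model, spec.i_pop.model
    ye = settled_state(em, spec.e_pop.I_bias, dt)
    yi = settled_state(im, spec.i_pop.I_bias, dt)
    y0_e = np.vstack([ye for _ in range(Ne)])
    y0_i = np.vstack([yi for _ in range(Ni)])
    mode_e, Vth_e, Vres_e, Vpk_e, ncl_e = _mech_tuple(em, dt)
    mode_i, Vth_i, Vres_i, Vpk_i, ncl_i = _mech_tuple(im, dt)
    max_spikes = int(n * dt) + 16
    clip_e = np.asarray(getattr(em, "clip01", ()), dtype=np.int64)
    clip_i = np.asarray(getattr(im, "clip01", ()), dtype=np.int64)
    Vrec, spikes, nsp, status, bad = _ei_kernel(
        em.deriv, em.pack(), y0_e, mode_e, Vth_e, Vres_e, Vpk_e, ncl_e,
        clip_e, clip_i,
        im.deriv, im.pack(), y0_i, mode_i, Vth_i, Vres_i, Vpk_i, ncl_i,
        spec.g_ee, spec.g_ei, spec.g_ie, spec.g_ii, spec.E_e, spec.E_i,
        spec.tau_r_e, spec.tau_d_e, spec.tau_r_i, spec.tau_d_i,
        np.ascontiguousarray(Ie, dtype=float),
        np.ascontiguousarray(Ii, dtype=float), noise, dt, max_spikes)
    if status == 1:
        raise SimulationDivergedError(f"network diverged in cell {bad}")
    if status == 2:
        raise SimulationDivergedError(f"spike-count overflow in cell {bad}")
    T = drives["e"].meta.get("T", (n - 1) * dt / 1000.0)
    trains = [SpikeTrain(np.sort(spikes[c, :nsp[c]]), T, trial_id)
              for c in range(N)]
    return SimResult(t=drives["e"].t, V=Vrec, aux={}, spikes=trains,
                     stimulus=drives["e"], trial_id=trial_id,
                     meta={"Ne": Ne, "Ni": Ni})


def _simulate_layers(spec: LayeredFeedforwardSpec, config: SimulationConfig,
                     trial_id: int, vpre1: StimulusTrace | None) -> SimResult:
    from .stimuli import make_periodic_spike_train, spikes_to_presynaptic_voltage
    dt = config.dt
    if vpre1 is None:
        f0, f1, T = spec.chirp
        chirp = make_chirp(f0, f1, 1.0, 0.0, T, dt)
        train1 = make_periodic_spike_train(chirp)
        vpre1 = spikes_to_presynaptic_voltage(train1, dt,
                                              pulse_ms=spec.pulse_ms)
    n = vpre1.n
    noise2 = np.zeros((spec.n2, n - 1))
    if spec.sigma2 > 0:
        for c in range(spec.n2):
            noise2[c] = trial_rng(config.master_seed, c, trial_id).normal(
                0.0, spec.sigma2, n - 1) / np.sqrt(0.1 * dt)
    c2, s = spec.cell2, spec.cell2.syn
    psyn = np.array([s.tau_r, s.tau_d, s.tau_reset_d, s.tau_dep,
                     s.tau_reset_f, s.tau_fac,
                     1.0 if s.use_depression else 0.0,
                     1.0 if s.use_facilitation else 0.0])
    mode, Vth, Vres, Vpk, ncl = _mech_tuple(c2, dt)
    max_spikes = int(n * dt) + 16
    Vrec, spikes, nsp, status, bad = _layers_kernel(
        np.array([c2.C, c2.g_L]), psyn,
        np.ascontiguousarray(vpre1.value, dtype=float),
        spec.I_bias2, noise2, s.g_S, s.E_S,
        np.array([spec.cell3.C, spec.cell3.g_L]), spec.g_s23, spec.E_s23,
        spec.I_bias3, Vth, Vres, Vpk, ncl, dt, spec.n2, c2.E_L,
        spec.cell3.E_L,
        float(settled_state(c2, spec.I_bias2, dt)[0]),
        float(settled_state(spec.cell3, spec.I_bias3, dt)[0]),
        max_spikes)
    if status == 1:
        raise SimulationDivergedError(f"layer network diverged in cell {bad}")
    if status == 2:
        raise SimulationDivergedError(f"spike-count overflow in cell {bad}")
    T = vpre1.meta.get("T", (n - 1) * dt / 1000.0)
    trains = [SpikeTrain(np.sort(spikes[c, :nsp[c]]), T, trial_id)
              for c in range(spec.n2 + 1)]
    return SimResult(t=vpre1.t, V=Vrec, aux={}, spikes=trains,
                     stimulus=vpre1, trial_id=trial_id,
                     meta={"n2": spec.n2})
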