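"""Declarative reproductions of the figure-level experiments.

Each scenario assembles stimuli, a model or network preset and a
metric battery into one callable, addressable by name through
``run_scenario`` and the CLI.  All scenarios are deterministic given
their seed (noise streams derive from (seed, cell, trial)).

Default sweep grids are reduced relative to the source experiments
(the ``full`` flag restores the dense grids); the problem sizes used
by each scenario are documented in the methods note.
"""

from __future__ import annotations

import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd

from . import metrics as mt
from . import models as M
from .integrator import SimulationConfig, integrate, run_trials
from .network import (LayeredFeedforwardSpec, build_preset, settled_state,
                      simulate_network)
from .stimuli import (SpikeTrain, make_chirp, make_constant,
                      make_periodic_spike_train, make_sinusoid,
                      make_synthetic_trains, spikes_to_presynaptic_voltage)

logger = logging.getLogger("neurores.scenarios")

__all__ = ["run_scenario", "sweep", "SCENARIOS", "scenario_names",
           "naph_impedance_curve", "minimal_spiking_amplitude",
           "calcium_rate_profile", "layers_coherence", "layers_sigma_sweep",
           "gamma_int_impedance", "gamma_int_spiking_band",
           "pyr_direct_resonance", "int_pyr_resonance", "epsp_profile",
           "plastic_lif_resonance", "rlif_rate_profile", "ei_network_coherence",
           "synthetic_train_metrics"]


# --------------------------------------------------------------------------
# building blocks

def impedance_curve_sinusoids(model, freqs, A_in, I_bias, T=3.0, dt=0.1,
                              settle=1.0) -> mt.ImpedanceProfile:
    """Steady-state impedance from per-frequency sinusoidal runs
    (noise-free, spiking disabled, started from the settled rest)."""
    y0 = settled_state(model, I_bias, dt)
    mags, phases = [], []
    for f in freqs:
        stim = make_sinusoid(f, A_in, I_bias, T, dt)
        res = integrate(model, stim, spike_mech=False, y0=y0)
        _, zm, zp = mt.impedance_point(res.V, stim, settle=settle)
        mags.append(zm)
        phases.append(zp)
    return mt.ImpedanceProfile(np.asarray(freqs, dtype=float),
                               np.asarray(mags), np.asarray(phases))


def naph_impedance_curve(A_in=0.05, I_bias=-1.85, freqs=None,
                         variant="full") -> mt.ImpedanceProfile:
    """Impedance of the I_Na,p+I_h model (or its RC / pure-h variants)."""
    freqs = np.arange(1.0, 40.0 + 0.25, 0.5) if freqs is None else freqs
    model = {"full": M.NapHParams,
             "rc": M.NapHParams.rc_variant,
             "hpf": M.NapHParams.hpf_variant}[variant]()
    return impedance_curve_sinusoids(model, freqs, A_in, I_bias)


def minimal_spiking_amplitude(freqs=None, I_bias=-1.85, T=3.0, dt=0.1,
                              settle=1.0, tol=1e-3,
                              lo=0.0, hi=0.3) -> float:
    """Minimal sinusoid amplitude at which the I_Na,p+I_h model fires,
    over any frequency in ``freqs``, found by bisection (sigma = 0)."""
    freqs = np.arange(1.0, 41.0) if freqs is None else np.asarray(freqs)
    model = M.NapHParams()
    y0 = settled_state(model, I_bias, dt)
    # scan frequencies nearest the subthreshold resonance first
    order = np.argsort(np.abs(freqs - 8.0))
    freqs = freqs[order]

    def fires(A):
        for f in freqs:
            stim = make_sinusoid(f, A, I_bias, T, dt)
            res = integrate(model, stim, y0=y0)
            if np.any(res.spikes.times >= settle * 1000.0):
                return True
        return False

    if not fires(hi):
        raise RuntimeError(f"upper bracket A={hi} does not produce spikes")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def rate_profile_sinusoids(model, freqs, A_in, I_bias, sigma=0.0, T=3.0,
                           dt=0.1, settle=1.0, seed=0,
                           spike_mech=None) -> mt.RateProfile:
    """Post-settle firing rate at each drive frequency."""
    y0 = settled_state(model, I_bias, dt)
    rates = []
    for f in freqs:
        stim = make_sinusoid(f, A_in, I_bias, T, dt)
        res = integrate(model, stim, spike_mech=spike_mech, sigma=sigma,
                        seed=seed, cell_id=int(round(10 * f)), y0=y0)
        nsp = np.count_nonzero(res.spikes.times >= settle * 1000.0)
        rates.append(nsp / (T - settle))
    return mt.RateProfile(np.asarray(freqs, dtype=float), np.asarray(rates))


def calcium_rate_profile(g_C=0.08, freqs=None, seed=0,
                         sigma=0.001) -> mt.RateProfile:
    """Calcium-LIF firing rate vs sinusoid frequency (Methods drive:
    I_bias=-3, A_in=8)."""
    freqs = np.arange(1.0, 41.0) if freqs is None else freqs
    model = M.CalciumLIFParams(g_C=g_C)
    return rate_profile_sinusoids(model, freqs, A_in=8.0, I_bias=-3.0,
                                  sigma=sigma, seed=seed)


def rlif_rate_profile(A_in=0.115, sigma=0.0, freqs=None, seed=0):
    """Resonant-LIF (spike discretization) rate vs drive frequency."""
    freqs = np.arange(1.0, 41.0) if freqs is None else freqs
    model = M.LIFParams()
    return rate_profile_sinusoids(model, freqs, A_in=A_in, I_bias=0.9,
                                  sigma=sigma, seed=seed)


# -- synaptic (EPSP) level --

def _presyn_from_sinusoid(rate_hz, T, dt, pulse_ms=0.1):
    # 0.1 ms pulses: the T_spike of the spiking cells in the synaptic
    # experiments; the printed tau_reset values assume this width
    train = make_periodic_spike_train(make_sinusoid(rate_hz, 1.0, 0.0, T, dt))
    return train, spikes_to_presynaptic_voltage(train, dt, pulse_ms=pulse_ms)


def epsp_profile(variant="dep_fac", rates=None, T=3.0, dt=0.1,
                 settle=1.0, pulse_ms=0.1) -> mt.RateProfile:
    """EPSP magnitude vs presynaptic rate for the plastic-synapse LIF
    (leaky integrator: spiking prevented by a high threshold).

    Variants: 'dep_fac', 'dep' (facilitation off), 'fac' (depression
    off), 'none' (both off).
    """
    rates = np.arange(1.0, 41.0) if rates is None else rates
    syn = M.PlasticSynapseParams(
        use_depression=variant in ("dep_fac", "dep"),
        use_facilitation=variant in ("dep_fac", "fac"))
    model = M.PlasticLIFParams(V_th=0.0, syn=syn)
    y0 = settled_state(model, 0.0, dt)
    bias = make_constant(0.0, T, dt)
    mags = []
    for r in rates:
        train, vpre = _presyn_from_sinusoid(r, T, dt, pulse_ms)
        res = integrate(model, bias, vpre=vpre, spike_mech=False, y0=y0)
        mags.append(mt.epsp_magnitude(res.V, train, res.t, settle=settle))
    return mt.RateProfile(np.asarray(rates, dtype=float), np.asarray(mags))


def plastic_lif_resonance(variant="dep_fac", sigma=0.05, I_bias=1.3,
                          trials=5, seed=0, T=20.0, dt=0.1,
                          f1=40.0, pulse_ms=0.1) -> dict:
    """Spiking resonance of the LIF driven through a plastic synapse by
    one presynaptic spike per chirp cycle."""
    syn = M.PlasticSynapseParams(
        use_depression=variant in ("dep_fac", "dep"),
        use_facilitation=variant in ("dep_fac", "fac"))
    model = M.PlasticLIFParams(syn=syn)
    chirp = make_chirp(0.0, f1, 1.0, 0.0, T, dt)
    train1 = make_periodic_spike_train(chirp)
    vpre = spikes_to_presynaptic_voltage(train1, dt, pulse_ms=pulse_ms)
    bias = make_constant(I_bias, T, dt)
    y0 = settled_state(model, I_bias, dt)
    trains = []
    for k in range(trials):
        res = integrate(model, bias, vpre=vpre, sigma=sigma, seed=seed,
                        trial_id=k, y0=y0)
        trains.append(res.spikes)
    x = _indicator(train1, vpre.n, dt)
    coh = mt.spike_input_coherence(trains, x, dt, f_max=f1)
    peak = mt.find_resonant_peak(coh.f, coh.coh)
    fp = mt.fingerprint(trains, chirp)
    return {"coherence": coh, "fingerprint": fp, "peak": peak,
            "mean_rate": float(np.mean([t.rate() for t in trains]))}


# -- layered feedforward network (PSP resonance inheritance) --

def _indicator(train: SpikeTrain, n: int, dt: float) -> np.ndarray:
    y = np.zeros(n)
    idx = np.round(train.times / dt).astype(np.int64)
    y[idx[(idx >= 0) & (idx < n)]] = 1.0
    return y


def layers_coherence(sigma2=0.48, trials=10, seed=0) -> dict:
    """3-layer feedforward run: mean layer-2 and layer-3 coherence with
    the input spike train, pooled over trials."""
    spec, cfg = build_preset("fig5_layers")
    spec.sigma2 = sigma2
    cfg.master_seed = seed
    dt = cfg.dt
    f0, f1, T = spec.chirp
    chirp = make_chirp(f0, f1, 1.0, 0.0, T, dt)
    train1 = make_periodic_spike_train(chirp)
    vpre1 = spikes_to_presynaptic_voltage(train1, dt)
    results = [simulate_network(spec, cfg, trial_id=k, vpre1=vpre1)
               for k in range(trials)]
    x = _indicator(train1, vpre1.n, dt)
    n2 = spec.n2
    coh_cells = []
    for c in range(n2):
        coh_cells.append(mt.spike_input_coherence(
            [r.spikes[c] for r in results], x, dt, f_max=f1).coh)
    f = mt.spike_input_coherence([results[0].spikes[0]], x, dt, f_max=f1).f
    layer2_mean = np.mean(coh_cells, axis=0)
    coh3 = mt.spike_input_coherence([r.spikes[n2] for r in results], x, dt,
                                    f_max=f1)
    p2 = mt.find_resonant_peak(f, layer2_mean)
    p3 = mt.find_resonant_peak(coh3.f, coh3.coh)
    rate2 = float(np.mean([r.spikes[c].rate() for r in results
                           for c in range(n2)]))
    rate3 = float(np.mean([r.spikes[n2].rate() for r in results]))
    return {"f": f, "layer2_coherence": layer2_mean, "layer3_coherence":
            coh3.coh, "layer2_peak": p2, "layer3_peak": p3,
            "layer2_rate": rate2, "layer3_rate": rate3}


def layers_sigma_sweep(sigmas=None, trials=5, seed=0) -> pd.DataFrame:
    """Stochastic-resonance sweep of layer-2 noise; one row per level."""
    sigmas = np.arange(0.2, 0.901, 0.1) if sigmas is None else sigmas
    rows = []
    for s in sigmas:
        t0 = time.perf_counter()
        out = layers_coherence(sigma2=float(s), trials=trials, seed=seed)
        logger.info("sweep point sigma=%.3f trials=%d peak_coh=%.3f "
                    "runtime=%.1fs", s, trials,
                    out["layer2_peak"].magnitude, time.perf_counter() - t0)
        rows.append({"sigma": float(s),
                     "layer2_peak_coh": out["layer2_peak"].magnitude,
                     "layer2_peak_f": out["layer2_peak"].f_peak,
                     "layer3_peak_coh": out["layer3_peak"].magnitude,
                     "layer3_peak_f": out["layer3_peak"].f_peak,
                     "layer2_rate": out["layer2_rate"],
                     "layer3_rate": out["layer3_rate"]})
    return pd.DataFrame(rows)


# -- inhibition-induced network resonance --

def gamma_int_impedance(seed=0, settle_s=1.0) -> dict:
    """Subthreshold impedance of the isolated gamma-INT under the
    0-80 Hz chirp (A_in=0.5)."""
    spec, cfg = build_preset("fig8A_gamma_int")
    pop = spec.i_pop
    dt = cfg.dt
    f0, f1, T = spec.chirp
    y0 = settled_state(pop.model, pop.I_bias, dt, settle_s)
    stim = make_chirp(f0, f1, pop.A_in, pop.I_bias, T, dt)
    res = integrate(pop.model, stim, sigma=pop.sigma, seed=seed, y0=y0)
    prof = mt.impedance_profile(res.V, stim, settle=0.0, spikes=res.spikes)
    peak = mt.find_resonant_peak(prof.f, prof.Z_mag)
    return {"impedance": prof, "peak": peak}


def gamma_int_spiking_band(seed=0, settle_s=1.0, f_bin=2.0) -> dict:
    """Spiking band of the isolated gamma-INT under the stronger chirp
    (A_in=0.9): spikes assigned to the chirp's instantaneous frequency."""
    spec, cfg = build_preset("fig8B_gamma_int")
    pop = spec.i_pop
    dt = cfg.dt
    f0, f1, T = spec.chirp
    y0 = settled_state(pop.model, pop.I_bias, dt, settle_s)
    stim = make_chirp(f0, f1, pop.A_in, pop.I_bias, T, dt)
    res = integrate(pop.model, stim, sigma=pop.sigma, seed=seed, y0=y0)
    prof = mt.cycle_averaged_rate(res.spikes, stim, f_bin=f_bin)
    band = mt.spiking_band(prof, threshold=1.0)
    return {"rate_profile": prof, "band": band, "n_spikes": res.spikes.n}


def pyr_direct_resonance(trials=20, seed=0) -> dict:
    """Directly driven isolated PYR: pooled spike-input coherence."""
    spec, cfg = build_preset("fig7A_pyr")
    pop = spec.e_pop
    dt = cfg.dt
    f0, f1, T = spec.chirp
    stim = make_chirp(f0, f1, pop.A_in, pop.I_bias, T, dt)
    y0 = settled_state(pop.model, pop.I_bias, dt)
    trains = []
    for k in range(trials):
        res = integrate(pop.model, stim, sigma=pop.sigma, seed=seed,
                        trial_id=k, y0=y0)
        trains.append(res.spikes)
    coh = mt.spike_input_coherence(trains, stim, dt, f_max=f1)
    peak = mt.find_resonant_peak(coh.f, coh.coh)
    fp = mt.fingerprint(trains, stim)
    return {"coherence": coh, "peak": peak, "fingerprint": fp,
            "mean_rate": float(np.mean([t.rate() for t in trains]))}


def int_pyr_resonance(trials=20, seed=0, preset="fig7_int_pyr") -> dict:
    """INT->PYR network driven only at the INT: PYR coherence with the
    drive and PYR spike phase (near pi = input trough for feedforward
    inhibition)."""
    spec, cfg = build_preset(preset)
    cfg.master_seed = seed
    dt = cfg.dt
    f0, f1, T = spec.chirp
    drive = make_chirp(f0, f1, spec.i_pop.A_in, spec.i_pop.I_bias, T, dt)
    pyr_trains, int_trains = [], []
    for k in range(trials):
        res = simulate_network(spec, cfg, trial_id=k)
        pyr_trains.append(res.spikes[0])
        int_trains.append(res.spikes[1])
    coh = mt.spike_input_coherence(pyr_trains, drive, dt, f_max=f1)
    peak = mt.find_resonant_peak(coh.f, coh.coh)
    fp = mt.fingerprint(pyr_trains, drive)
    band = (max(peak.f_peak - 2.0, 1.0), peak.f_peak + 2.0)
    phase = fp.preferred_phase(*band)
    return {"coherence": coh, "peak": peak, "fingerprint": fp,
            "pyr_phase": phase,
            "pyr_rate": float(np.mean([t.rate() for t in pyr_trains])),
            "int_rate": float(np.mean([t.rate() for t in int_trains]))}


# -- E/I networks (inheritance of membrane-potential / spiking resonance) --

def ei_network_coherence(preset="fig2_EI", trials=1, seed=0) -> dict:
    """All-to-all E/I network under the chirp drive: per-population
    mean spike-input coherence."""
    spec, cfg = build_preset(preset)
    cfg.master_seed = seed
    dt = cfg.dt
    f0, f1, T = spec.chirp
    wave = make_chirp(f0, f1, 1.0, 0.0, T, dt)
    results = [simulate_network(spec, cfg, trial_id=k) for k in range(trials)]
    Ne, Ni = spec.e_pop.n, spec.i_pop.n
    f = None
    coh_e, coh_i = [], []
    for c in range(Ne + Ni):
        coh = mt.spike_input_coherence([r.spikes[c] for r in results],
                                       wave, dt, f_max=f1)
        f = coh.f
        (coh_e if c < Ne else coh_i).append(coh.coh)
    mean_e = np.mean(coh_e, axis=0)
    mean_i = np.mean(coh_i, axis=0)
    return {"f": f, "e_coherence": mean_e, "i_coherence": mean_i,
            "e_peak": mt.find_resonant_peak(f, mean_e),
            "i_peak": mt.find_resonant_peak(f, mean_i),
            "e_rate": float(np.mean([r.spikes[c].rate() for r in results
                                     for c in range(Ne)])),
            "i_rate": float(np.mean([r.spikes[Ne + c].rate() for r in results
                                     for c in range(Ni)]))}


# -- synthetic spike trains (metric illustration) --

def synthetic_train_metrics(mode="rate_band", seed=0, T=10.0,
                            base_rate=10.0) -> dict:
    """Cycle-averaged rates, fingerprint and coherence for the
    synthetic rate-band / phase-band spike trains."""
    pairs = make_synthetic_trains(mode, T=T, base_rate=base_rate, seed=seed)
    dt = 1.0
    f_grid = np.array([f for f, _ in pairs])
    rates = np.array([tr.rate() for _, tr in pairs])
    coh_vals = []
    # fingerprint assembled across per-frequency blocks
    nph = 36
    ph_edges = np.linspace(0, 2 * np.pi, nph + 1)
    f_edges = np.concatenate([f_grid - 0.5, [f_grid[-1] + 0.5]])
    counts = np.zeros((f_grid.size, nph))
    occ = np.zeros((f_grid.size, nph))
    for i, (f, tr) in enumerate(pairs):
        stim = make_sinusoid(f, 1.0, 0.0, T, dt)
        ph = np.mod(2 * np.pi * f * tr.times / 1000.0 - 0.5 * np.pi,
                    2 * np.pi)
        counts[i], _ = np.histogram(ph, bins=ph_edges)
        occ[i] = T / nph
        coh = mt.spike_input_coherence(tr, stim, dt, seg_s=2.0)
        coh_vals.append(float(coh.coh[np.argmin(np.abs(coh.f - f))]))
    fp = mt.Fingerprint(f_edges, ph_edges, counts, occ)
    return {"f": f_grid, "rate": rates, "coherence_at_f": np.array(coh_vals),
            "fingerprint": fp}


# --------------------------------------------------------------------------
# registry / orchestration

def _s_fig2A(seed=0, trials=None, full=False, **kw):
    step = 0.25 if full else 0.5
    prof = naph_impedance_curve(freqs=np.arange(1.0, 40.0 + step / 2, step),
                                **kw)
    peak = mt.find_resonant_peak(prof.f, prof.Z_mag, smooth_bins=1)
    return {"summary": {"f_peak": peak.f_peak, "peak_magnitude":
                        peak.magnitude, "resonant": peak.resonant},
            "profiles": {"impedance": prof}}


def _s_fig2B(seed=0, trials=None, full=False, **kw):
    A = minimal_spiking_amplitude(**kw)
    return {"summary": {"A_min": A}, "profiles": {}}


def _s_fig3F(seed=0, trials=None, full=False, g_C=0.08, **kw):
    prof = calcium_rate_profile(g_C=g_C, seed=seed, **kw)
    band = mt.spiking_band(prof)
    s = {"band": band, "mean_rate": float(prof.rate.mean())}
    if band:
        s.update(f_peak=band[2], peak_magnitude=float(prof.rate.max()),
                 low_pass=band[3])
    return {"summary": s, "profiles": {"rate": prof}}


def _s_fig3H(seed=0, trials=None, full=False, **kw):
    gcs = np.arange(0.04, 0.121, 0.01) if full else \
        np.arange(0.04, 0.121, 0.02)
    rows = []
    for g in gcs:
        prof = calcium_rate_profile(g_C=float(g), seed=seed)
        band = mt.spiking_band(prof)
        width = band[1] - band[0] if band else 0.0
        rows.append({"g_C": float(g), "band_width": float(width),
                     "center": band[2] if band else np.nan})
    return {"summary": {"table": rows}, "profiles": {}}


def _s_fig5B(seed=0, trials=None, full=False, variant="dep_fac", **kw):
    prof = epsp_profile(variant=variant, **kw)
    peak = mt.find_resonant_peak(prof.f, prof.rate)
    return {"summary": {"f_peak": peak.f_peak,
                        "peak_magnitude": peak.magnitude,
                        "resonant": peak.resonant},
            "profiles": {"epsp": prof}}


def _s_fig5GHI(seed=0, trials=None, full=False, sigma2=0.48, **kw):
    out = layers_coherence(sigma2=sigma2, trials=trials or 10, seed=seed)
    return {"summary": {
        "layer2_peak_coh": out["layer2_peak"].magnitude,
        "layer2_peak_f": out["layer2_peak"].f_peak,
        "layer3_peak_coh": out["layer3_peak"].magnitude,
        "layer3_peak_f": out["layer3_peak"].f_peak,
        "layer2_rate": out["layer2_rate"], "layer3_rate": out["layer3_rate"]},
        "profiles": {"layer2": mt.CoherenceSpectrum(out["f"],
                                                    out["layer2_coherence"]),
                     "layer3": mt.CoherenceSpectrum(out["f"],
                                                    out["layer3_coherence"])}}


def _s_fig5JKL(seed=0, trials=None, full=False, **kw):
    sig = np.arange(0.0, 2.001, 0.025) if full else None
    df = layers_sigma_sweep(sigmas=sig, trials=trials or 5, seed=seed)
    i = int(df["layer2_peak_coh"].idxmax())
    return {"summary": {"sigma_star": float(df.loc[i, "sigma"]),
                        "layer2_peak_coh": float(df.loc[i, "layer2_peak_coh"]),
                        "table": df.to_dict("records")},
            "profiles": {}, "tables": {"sweep": df}}


def _s_fig6(seed=0, trials=None, full=False, **kw):
    out = plastic_lif_resonance(variant="dep", sigma=0.05, I_bias=1.2,
                                trials=trials or 5, seed=seed)
    return {"summary": {"f_peak": out["peak"].f_peak,
                        "peak_coh": out["peak"].magnitude,
                        "mean_rate": out["mean_rate"]},
            "profiles": {"coherence": out["coherence"]}}


def _s_fig7A(seed=0, trials=None, full=False, **kw):
    out = pyr_direct_resonance(trials=trials or 20, seed=seed)
    return {"summary": {"f_peak": out["peak"].f_peak,
                        "peak_coh": out["peak"].magnitude,
                        "mean_rate": out["mean_rate"]},
            "profiles": {"coherence": out["coherence"]}}


def _s_fig7B(seed=0, trials=None, full=False, **kw):
    out = int_pyr_resonance(trials=trials or 20, seed=seed)
    return {"summary": {"f_peak": out["peak"].f_peak,
                        "peak_coh": out["peak"].magnitude,
                        "pyr_phase": out["pyr_phase"],
                        "pyr_rate": out["pyr_rate"]},
            "profiles": {"coherence": out["coherence"]}}


def _s_fig8A(seed=0, trials=None, full=False, **kw):
    out = gamma_int_impedance(seed=seed)
    return {"summary": {"f_peak": out["peak"].f_peak,
                        "peak_magnitude": out["peak"].magnitude},
            "profiles": {"impedance": out["impedance"]}}


def _s_fig8B(seed=0, trials=None, full=False, **kw):
    out = gamma_int_spiking_band(seed=seed)
    band = out["band"]
    s = {"n_spikes": out["n_spikes"]}
    if band:
        s.update(band_lo=band[0], band_hi=band[1], band_center=band[2])
    return {"summary": s, "profiles": {"rate": out["rate_profile"]}}


def _s_fig8C(seed=0, trials=None, full=False, **kw):
    out = int_pyr_resonance(trials=trials or 20, seed=seed,
                            preset="fig8_gammaint_pyr")
    return {"summary": {"f_peak": out["peak"].f_peak,
                        "peak_coh": out["peak"].magnitude,
                        "pyr_phase": out["pyr_phase"]},
            "profiles": {"coherence": out["coherence"]}}


def _s_fig2G(seed=0, trials=None, full=False, preset="fig2_EI", **kw):
    out = ei_network_coherence(preset=preset, trials=trials or 1, seed=seed)
    return {"summary": {"e_peak_f": out["e_peak"].f_peak,
                        "e_peak_coh": out["e_peak"].magnitude,
                        "i_peak_f": out["i_peak"].f_peak,
                        "i_peak_coh": out["i_peak"].magnitude,
                        "e_rate": out["e_rate"], "i_rate": out["i_rate"]},
            "profiles": {
                "e": mt.CoherenceSpectrum(out["f"], out["e_coherence"]),
                "i": mt.CoherenceSpectrum(out["f"], out["i_coherence"])}}


def _s_fig1(mode):
    def run(seed=0, trials=None, full=False, **kw):
        out = synthetic_train_metrics(mode=mode, seed=seed, **kw)
        in_band = (out["f"] >= 8) & (out["f"] <= 12)
        return {"summary": {
            "in_band_rate": float(out["rate"][in_band].mean()),
            "out_band_rate": float(out["rate"][~in_band].mean()),
            "in_band_coh": float(out["coherence_at_f"][in_band].mean()),
            "out_band_coh": float(out["coherence_at_f"][~in_band].mean())},
            "profiles": {}}
    return run


SCENARIOS = {
    "fig1C_rate_band": _s_fig1("rate_band"),
    "fig1D_phase_band": _s_fig1("phase_band"),
    "fig2A_impedance": _s_fig2A,
    "fig2B_minimal_amplitude": _s_fig2B,
    "fig2G_ei_network": _s_fig2G,
    "fig3F_calcium_band": _s_fig3F,
    "fig3H_gc_sweep": _s_fig3H,
    "fig5B_epsp": _s_fig5B,
    "fig5GHI_layers": _s_fig5GHI,
    "fig5JKL_noise_sweep": _s_fig5JKL,
    "fig6_depression_network": _s_fig6,
    "fig7A_pyr_direct": _s_fig7A,
    "fig7B_int_pyr": _s_fig7B,
    "fig8A_gamma_impedance": _s_fig8A,
    "fig8B_gamma_spiking": _s_fig8B,
    "fig8C_gammaint_pyr": _s_fig8C,
}


def scenario_names():
    return sorted(SCENARIOS)


def run_scenario(name: str, seed: int = 0, trials: int | None = None,
                 overrides: dict | None = None, out_dir=None,
                 full: bool = False) -> dict:
    """Run a named scenario; optionally write its outputs to ``out_dir``
    (summary.json + one delimited text file per profile)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"valid: {', '.join(scenario_names())}")
    overrides = dict(overrides or {})
    t0 = time.perf_counter()
    out = SCENARIOS[name](seed=seed, trials=trials, full=full, **overrides)
    logger.info("scenario=%s seed=%d trials=%s runtime=%.1fs", name, seed,
                trials, time.perf_counter() - t0)
    out.setdefault("profiles", {})
    out["summary"]["scenario"] = name
    out["summary"]["seed"] = seed
    if out_dir is not None:
        d = pathlib.Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "summary.json", "w") as fh:
            json.dump(out["summary"], fh, indent=2, default=float)
        for key, prof in out["profiles"].items():
            prof.to_text(d / f"{key}.tsv")
        for key, df in out.get("tables", {}).items():
            df.to_csv(d / f"{key}.csv", index=False)
    return out


def sweep(axis: str, values, scenario: str, seed: int = 0,
          trials: int | None = None, **kw) -> pd.DataFrame:
    """Run ``scenario`` once per value of the override ``axis``.

    Returns one row per sweep value with the scenario's peak frequency,
    peak magnitude and mean rate (where reported); all rows share seeds.
    """
    rows = []
    for v in values:
        s = run_scenario(scenario, seed=seed, trials=trials,
                         overrides={axis: v}, **kw)["summary"]
        rows.append({
            "value": v,
            "f_peak": s.get("f_peak", s.get("band_center", np.nan)),
            "peak_magnitude": s.get("peak_magnitude",
                                    s.get("peak_coh", np.nan)),
            "mean_rate": s.get("mean_rate", np.nan)})
    return pd.DataFrame(rows)
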