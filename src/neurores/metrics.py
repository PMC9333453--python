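"""Resonance metrics.

* Impedance amplitude/phase profiles from single-frequency runs
  (steady-state voltage amplitude divided by drive amplitude) or from
  chirp runs (ratio of Fourier transforms, magnitude-smoothed).
* Cycle-averaged firing rate vs input frequency.
* 2D frequency x phase "fingerprint" of instantaneous firing rates
  (spike counts per bin divided by the time spent in the bin).
* Spike-input spectral coherence: magnitude of the complex coherence
  between the input waveform and the spike train (binary indicator on
  the integration grid), estimated by Welch segment-averaged
  cross-spectra pooled over trials.  Coherence is 1 under perfect
  phase locking and decays to the 1/n_segments bias floor for spikes
  unrelated to the input.
* EPSP magnitude (steady-state per-cycle peak-to-trough) vs
  presynaptic rate.
* Peak extraction with an interior-peak ("resonant") flag.

Phase convention everywhere: phase 0 = maximum of the input waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .stimuli import (SpikeTrain, StimulusTrace, instantaneous_frequency,
                      instantaneous_phase)

__all__ = [
    "ImpedanceProfile", "CoherenceSpectrum", "Fingerprint", "RateProfile",
    "EpspProfile", "PeakResult",
    "impedance_point", "impedance_profile", "cycle_averaged_rate",
    "fingerprint", "spike_input_coherence", "epsp_magnitude",
    "find_resonant_peak", "spiking_band", "rc_impedance",
]


@dataclass
class ImpedanceProfile:
    f: np.ndarray            # Hz
    Z_mag: np.ndarray        # mV per uA/cm^2
    Z_phase: np.ndarray      # rad, in (-pi, pi]

    def to_text(self, path):
        np.savetxt(path, np.column_stack([self.f, self.Z_mag, self.Z_phase]),
                   fmt="%.6f", delimiter="\t", header="f_Hz\tZmag\tZphase")


@dataclass
class CoherenceSpectrum:
    f: np.ndarray
    coh: np.ndarray          # in [0, 1]
    n_segments: int = 0
    meta: dict = field(default_factory=dict)

    def to_text(self, path):
        np.savetxt(path, np.column_stack([self.f, self.coh]),
                   fmt="%.6f", delimiter="\t", header="f_Hz\tcoherence")


@dataclass
class RateProfile:
    f: np.ndarray            # Hz (input frequency or presynaptic rate)
    rate: np.ndarray         # spk/s

    def to_text(self, path):
        np.savetxt(path, np.column_stack([self.f, self.rate]),
                   fmt="%.6f", delimiter="\t", header="f_Hz\trate_spk_s")


EpspProfile = RateProfile     # same shape: (presynaptic rate, magnitude mV)


@dataclass
class Fingerprint:
    """Instantaneous firing rate over (frequency, phase) bins."""
    f_edges: np.ndarray        # Hz, len nf+1
    phase_edges: np.ndarray    # rad, len np+1, covering one cycle
    counts: np.ndarray         # (nf, np) spike counts
    occupancy: np.ndarray      # (nf, np) seconds spent per bin

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.counts / self.occupancy
        return np.where(self.occupancy > 0, r, 0.0)

    @property
    def f_centers(self) -> np.ndarray:
        return 0.5 * (self.f_edges[:-1] + self.f_edges[1:])

    @property
    def phase_centers(self) -> np.ndarray:
        return 0.5 * (self.phase_edges[:-1] + self.phase_edges[1:])

    def expanded(self):
        """(phase_centers, rate) over 1.5 cycles for display."""
        nph = self.phase_centers.size
        half = nph // 2
        ph = np.concatenate([self.phase_centers,
                             self.phase_centers[:half] + 2 * np.pi])
        return ph, np.concatenate([self.rate, self.rate[:, :half]], axis=1)

    def rate_marginal(self) -> RateProfile:
        """Phase-marginal: cycle-averaged rate per frequency bin."""
        occ = self.occupancy.sum(axis=1)
        cnt = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cnt / occ
        return RateProfile(self.f_centers, np.where(occ > 0, r, 0.0))

    def preferred_phase(self, f_lo=None, f_hi=None) -> float:
        """Circular mean spike phase, optionally within a frequency band."""
        fc = self.f_centers
        sel = np.ones(fc.size, bool)
        if f_lo is not None:
            sel &= fc >= f_lo
        if f_hi is not None:
            sel &= fc <= f_hi
        w = self.counts[sel].sum(axis=0)
        z = np.sum(w * np.exp(1j * self.phase_centers))
        return float(np.mod(np.angle(z), 2 * np.pi))


@dataclass
class PeakResult:
    f_peak: float
    magnitude: float
    resonant: bool           # True iff the (smoothed) peak is interior


class SpikesInWindowError(ValueError):
    """Raised when a subthreshold metric receives a spiking trace."""


def _settle_index(t: np.ndarray, settle_s: float) -> int:
    return int(np.searchsorted(t, settle_s * 1000.0))


def rc_impedance(f_hz, g_L: float, C: float):
    """Closed-form impedance of the passive RC membrane (magnitude, phase)."""
    f_hz = np.asarray(f_hz, dtype=float)
    # membrane time constant C/g_L is in ms; f in Hz
    w = 2 * np.pi * f_hz * (C / g_L) / 1000.0
    return (1.0 / g_L) / np.sqrt(1.0 + w ** 2), -np.arctan(w)


def impedance_point(V: np.ndarray, stim: StimulusTrace, settle: float = 1.0,
                    spikes: SpikeTrain | None = None):
    """(f, Z_mag, Z_phase) from a single-frequency subthreshold run.

    Z_mag = (max V - min V) / (2 A_in) over the post-settle window;
    Z_phase from the lag of the voltage peak relative to the input
    peak, in the final full cycle.
    """
    if stim.kind != "sinusoid":
        raise ValueError("impedance_point requires a sinusoid stimulus")
    i0 = _settle_index(stim.t, settle)
    if spikes is not None and np.any(spikes.times >= stim.t[i0]):
        raise SpikesInWindowError(
            "spikes in analysis window; use a subthreshold amplitude")
    f, A = stim.meta["f"], stim.meta["A_in"]
    Vw, tw = V[i0:], stim.t[i0:]
    Zmag = (Vw.max() - Vw.min()) / (2.0 * A)
    if f == 0:
        return 0.0, Zmag, 0.0
    period = 1000.0 / f
    j0 = np.searchsorted(tw, tw[-1] - period)
    j = j0 + int(np.argmax(Vw[j0:]))
    phase_at_vpeak = instantaneous_phase(stim, tw[j])[()]
    Zph = -float(phase_at_vpeak)
    Zph = np.mod(Zph + np.pi, 2 * np.pi) - np.pi
    return f, float(Zmag), float(Zph)


def impedance_profile(V: np.ndarray, stim: StimulusTrace, settle: float = 1.0,
                      smooth_hz: float = 2.0,
                      spikes: SpikeTrain | None = None) -> ImpedanceProfile:
    """Impedance profile from a chirp run: |FFT(V - <V>)/FFT(I - I_bias)|
    over the swept band, magnitude-smoothed with a ``smooth_hz`` moving
    average."""
    if stim.kind != "chirp":
        raise ValueError("impedance_profile requires a chirp stimulus")
    i0 = _settle_index(stim.t, settle)
    if spikes is not None and np.any(spikes.times >= stim.t[i0]):
        raise SpikesInWindowError(
            "spikes in analysis window; use a subthreshold amplitude")
    Vw = V[i0:] - V[i0:].mean()
    Iw = stim.value[i0:] - stim.meta["I_bias"]
    fs = 1000.0 / stim.dt
    fr = np.fft.rfftfreq(Vw.size, 1.0 / fs)
    Z = np.fft.rfft(Vw) / np.fft.rfft(Iw)
    f0 = max(stim.meta["f0"], 0.5)
    sel = (fr >= f0) & (fr <= stim.meta["f1"])
    fsel, Zsel = fr[sel], Z[sel]
    df = fr[1] - fr[0]
    w = max(1, int(round(smooth_hz / df)))
    kern = np.ones(w) / w
    mag = np.convolve(np.abs(Zsel), kern, mode="same")
    phase = np.angle(Zsel)
    return ImpedanceProfile(fsel, mag, phase)


def cycle_averaged_rate(spikes, stim: StimulusTrace, settle: float = 0.0,
                        f_bin: float = 1.0) -> RateProfile:
    """Firing rate vs input frequency.

    Spikes are assigned to the instantaneous frequency of the stimulus
    at their time of occurrence; the count in each frequency bin is
    divided by the (pooled) time the stimulus spent in that bin.
    ``spikes`` may be one SpikeTrain or a list (trials pooled).
    """
    trains = [spikes] if isinstance(spikes, SpikeTrain) else list(spikes)
    fp = fingerprint(trains, stim, settle=settle, f_bin=f_bin, n_phase_bins=1)
    return RateProfile(fp.f_centers, fp.rate_marginal().rate)


def fingerprint(spikes, stim: StimulusTrace, settle: float = 0.0,
                f_bin: float = 1.0, n_phase_bins: int = 36) -> Fingerprint:
    """Occupancy-normalised 2D (frequency, phase) map of firing rates.

    Counts pool all trials; occupancy is the stimulus time per bin
    multiplied by the number of trials.
    """
    trains = [spikes] if isinstance(spikes, SpikeTrain) else list(spikes)
    i0 = _settle_index(stim.t, settle)
    t = stim.t[i0:]
    f_t = instantaneous_frequency(stim, t)
    ph_t = instantaneous_phase(stim, t)
    fmin = np.floor(f_t.min() / f_bin) * f_bin
    fmax = np.ceil(f_t.max() / f_bin) * f_bin
    if fmax <= fmin:
        fmax = fmin + f_bin
    f_edges = np.arange(fmin, fmax + 0.5 * f_bin, f_bin)
    ph_edges = np.linspace(0.0, 2 * np.pi, n_phase_bins + 1)
    occ, _, _ = np.histogram2d(f_t, ph_t, bins=(f_edges, ph_edges))
    occ *= stim.dt / 1000.0 * len(trains)
    cnt = np.zeros_like(occ)
    for tr in trains:
        st = tr.times[tr.times >= stim.t[i0]]
        if st.size == 0:
            continue
        fs = instantaneous_frequency(stim, st)
        ps = instantaneous_phase(stim, st)
        c, _, _ = np.histogram2d(fs, ps, bins=(f_edges, ph_edges))
        cnt += c
    return Fingerprint(f_edges, ph_edges, cnt, occ)


def spike_input_coherence(spikes, input_series, dt: float,
                          seg_s: float = 2.0, overlap: float = 0.5,
                          f_max: float | None = None) -> CoherenceSpectrum:
    """Magnitude of the spectral coherence between an input series and
    spike trains.

    ``input_series`` is either a StimulusTrace or an array on the same
    dt grid (a current waveform, or a binary indicator of an input
    spike train).  ``spikes`` is one SpikeTrain or a list of trains
    (trials); each train is converted to a binary indicator on the
    grid and cross-/auto-spectra are averaged over Welch segments
    (Hann window, ``overlap`` fraction) and pooled over trials before
    forming |S_xy| / sqrt(S_xx * S_yy).
    """
    x = input_series.value if isinstance(input_series, StimulusTrace) else \
        np.asarray(input_series, dtype=float)
    trains = [spikes] if isinstance(spikes, SpikeTrain) else list(spikes)
    fs = 1000.0 / dt
    nperseg = int(round(seg_s * fs))
    nov = int(round(overlap * nperseg))
    n = x.size
    total = 0
    Pxy = Pxx = Pyy = None
    any_spikes = False
    for tr in trains:
        y = np.zeros(n)
        idx = np.round(tr.times / dt).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n)]
        y[idx] = 1.0
        any_spikes = any_spikes or idx.size > 0
        f, pxy = signal.csd(x, y, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=nov)
        _, pxx = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nov)
        _, pyy = signal.welch(y, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nov)
        if Pxy is None:
            Pxy, Pxx, Pyy = pxy, pxx, pyy
        else:
            Pxy = Pxy + pxy
            Pxx = Pxx + pxx
            Pyy = Pyy + pyy
        total += max(1, (n - nov) // (nperseg - nov))
    if not any_spikes:
        coh = np.zeros_like(f)
        meta = {"zero_spikes": True}
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(Pxy) / np.sqrt(Pxx * Pyy)
        coh = np.nan_to_num(coh, nan=0.0)
        meta = {"zero_spikes": False}
    if f_max is not None:
        sel = f <= f_max
        f, coh = f[sel], coh[sel]
    return CoherenceSpectrum(f, np.clip(coh, 0.0, 1.0), n_segments=total,
                             meta=meta)


def epsp_magnitude(V: np.ndarray, presyn: SpikeTrain, t: np.ndarray,
                   settle: float = 1.0,
                   spikes: SpikeTrain | None = None) -> float:
    """Steady-state per-cycle PSP peak-to-trough (mV).

    For a periodic presynaptic train: after the settle period, the
    voltage excursion (max - min) is measured within each complete
    inter-spike cycle and averaged.
    """
    if spikes is not None and spikes.n > 0:
        raise SpikesInWindowError(
            "postsynaptic spikes present; raise V_th to measure EPSPs")
    st = presyn.times[presyn.times >= settle * 1000.0]
    if st.size < 2:
        # single (or no) EPSP: global excursion after settle
        i0 = np.searchsorted(t, settle * 1000.0)
        return float(V[i0:].max() - V[i0:].min())
    mags = []
    for a, b in zip(st[:-1], st[1:]):
        ia, ib = np.searchsorted(t, a), np.searchsorted(t, b)
        if ib > ia + 1:
            mags.append(V[ia:ib].max() - V[ia:ib].min())
    return float(np.mean(mags))


def find_resonant_peak(f, value, smooth_bins: int = 3) -> PeakResult:
    """Argmax of a profile after moving-average smoothing.

    Ties break toward the lowest frequency; the profile is flagged
    resonant only if the peak is interior (not at either grid end).
    """
    f = np.asarray(f, dtype=float)
    v = np.asarray(value, dtype=float)
    if f.size == 0:
        raise ValueError("empty profile")
    if smooth_bins > 1 and v.size >= smooth_bins:
        kern = np.ones(smooth_bins) / smooth_bins
        vs = np.convolve(v, kern, mode="same")
        # renormalise the shrinking edge windows
        norm = np.convolve(np.ones_like(v), kern, mode="same")
        vs = vs / norm
    else:
        vs = v
    i = int(np.argmax(vs))          # argmax returns the first (lowest-f) tie
    return PeakResult(float(f[i]), float(vs[i]),
                      bool(0 < i < f.size - 1))


def spiking_band(profile: RateProfile, threshold: float = 1.0):
    """Contiguous frequency band with sustained spiking.

    Returns (f_lo, f_hi, center, low_pass) where the band is the
    longest contiguous run of bins with rate >= threshold (spk/s) and
    ``low_pass`` flags a band starting at the lowest frequency bin.
    Returns None if no bin reaches threshold.
    """
    above = profile.rate >= threshold
    if not above.any():
        return None
    best, cur = None, None
    for i, a in enumerate(above):
        if a:
            cur = (cur[0], i) if cur else (i, i)
            if best is None or cur[1] - cur[0] > best[1] - best[0]:
                best = cur
        else:
            cur = None
    i0, i1 = best
    f_lo, f_hi = profile.f[i0], profile.f[i1]
    return (float(f_lo), float(f_hi), float(0.5 * (f_lo + f_hi)), i0 == 0)
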