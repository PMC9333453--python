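"""Input generators: periodic currents, chirps, spike trains, noise.

Every input used by the simulation pipeline is generated here — there is
no external data.  Units follow the package-wide convention: time in ms,
voltage in mV, current density in uA/cm^2, conductance in mS/cm^2.
Frequencies are accepted in Hz and converted internally (f/1000 per ms).

The two deterministic drive waveforms are a single-frequency sinusoid

    I_in(t) = I_bias + A_in * sin(2*pi*f*t)

and a chirp whose instantaneous frequency rises linearly from f0 to f1
over the record duration T,

    I_in(t) = I_bias + A_in * cos(pi + 2*pi*f0*t + pi*(f1-f0)*t^2/T).

Periodic presynaptic spike trains place one spike at each local maximum
of such a waveform; a presynaptic-voltage trace encodes a train as a
two-valued signal (50 mV within 1 ms of a spike, -60 mV otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusTrace",
    "SpikeTrain",
    "NoiseSpec",
    "make_sinusoid",
    "make_chirp",
    "make_constant",
    "make_periodic_spike_train",
    "spikes_to_presynaptic_voltage",
    "make_noise_steps",
    "make_synthetic_trains",
    "instantaneous_frequency",
    "instantaneous_phase",
]


def _grid(T: float, dt: float) -> np.ndarray:
    """Uniform time grid in ms for a record of T seconds at step dt ms."""
    if T <= 0:
        raise ValueError(f"record duration must be positive, got T={T} s")
    if dt <= 0:
        raise ValueError(f"time step must be positive, got dt={dt} ms")
    n = int(round(T * 1000.0 / dt)) + 1
    return np.arange(n) * dt


@dataclass
class StimulusTrace:
    """A time-gridded input waveform.

    ``value`` is a current density (uA/cm^2) for current drives, or a
    voltage (mV) for presynaptic-voltage traces.  ``kind`` is one of
    {"sinusoid", "chirp", "spike_train_voltage", "constant"}; ``meta``
    carries the generating parameters (f or (f0, f1) in Hz, A_in,
    I_bias, T in s).
    """

    t: np.ndarray
    value: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1])

    def to_text(self, path) -> None:
        """Write as two-column delimited text (t_ms, value)."""
        np.savetxt(path, np.column_stack([self.t, self.value]),
                   fmt="%.6f", delimiter="\t", header="t_ms\tvalue")


@dataclass
class SpikeTrain:
    """Sorted spike times in ms over a record of ``T`` seconds."""

    times: np.ndarray
    T: float
    trial_id: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > 1000.0 * self.T):
            raise ValueError("spike times must lie in [0, 1000*T] ms")

    @property
    def n(self) -> int:
        return self.times.size

    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return self.n / self.T

    def to_text(self, path) -> None:
        np.savetxt(path, self.times, fmt="%.4f", header="spike_time_ms")


@dataclass
class NoiseSpec:
    """Per-step Gaussian membrane-noise specification.

    ``sigma`` (mV) is the standard deviation of the per-step draw
    eta_k ~ N(0, sigma); the draw is multiplied by the fixed noise
    conductance g_N = 1 mS/cm^2 to yield a current in uA/cm^2.  The
    draw is made once per integration step (not scaled by sqrt(dt)),
    so the effective noise is dt-dependent by construction; the dt of
    each scenario is part of its preset.
    """

    sigma: float
    g_N: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def make_sinusoid(f: float, A_in: float, I_bias: float, T: float,
                  dt: float = 0.1) -> StimulusTrace:
    """Single-frequency sinusoidal current, f in Hz, T in s, dt in ms."""
    if f < 0:
        raise ValueError("frequency must be >= 0")
    t = _grid(T, dt)
    value = I_bias + A_in * np.sin(2.0 * np.pi * (f / 1000.0) * t)
    return StimulusTrace(t, value, "sinusoid",
                         {"f": f, "A_in": A_in, "I_bias": I_bias, "T": T})


def make_constant(I_bias: float, T: float, dt: float = 0.1) -> StimulusTrace:
    t = _grid(T, dt)
    return StimulusTrace(t, np.full(t.size, float(I_bias)), "constant",
                         {"A_in": 0.0, "I_bias": I_bias, "T": T})


def make_chirp(f0: float, f1: float, A_in: float, I_bias: float, T: float,
               dt: float = 0.1) -> StimulusTrace:
    """Linear chirp: instantaneous frequency ramps f0 -> f1 (Hz) over T s."""
    if f0 < 0 or f1 < f0:
        raise ValueError("chirp requires 0 <= f0 <= f1")
    t = _grid(T, dt)
    ts = t / 1000.0  # s
    theta = 2.0 * np.pi * f0 * ts + np.pi * (f1 - f0) * ts ** 2 / T
    value = I_bias + A_in * np.cos(np.pi + theta)
    return StimulusTrace(t, value, "chirp",
                         {"f0": f0, "f1": f1, "A_in": A_in, "I_bias": I_bias,
                          "T": T})


def instantaneous_frequency(stim: StimulusTrace, t_ms) -> np.ndarray:
    """Instantaneous frequency (Hz) of a sinusoid or chirp at times t_ms.

    Computed analytically from the known phase function, not from the
    samples.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if stim.kind == "sinusoid":
        return np.full(t_ms.shape, stim.meta["f"])
    if stim.kind == "chirp":
        f0, f1, T = stim.meta["f0"], stim.meta["f1"], stim.meta["T"]
        return f0 + (f1 - f0) * (t_ms / 1000.0) / T
    raise ValueError(f"no instantaneous frequency for kind={stim.kind!r}")


def instantaneous_phase(stim: StimulusTrace, t_ms) -> np.ndarray:
    """Instantaneous phase in [0, 2*pi), with phase 0 at the waveform peak."""
    t_ms = np.asarray(t_ms, dtype=float)
    ts = t_ms / 1000.0
    if stim.kind == "sinusoid":
        f = stim.meta["f"]
        # value ~ sin(2*pi*f*t): peak at phase pi/2 of the sine argument
        phi = 2.0 * np.pi * f * ts - 0.5 * np.pi
    elif stim.kind == "chirp":
        f0, f1, T = stim.meta["f0"], stim.meta["f1"], stim.meta["T"]
        theta = 2.0 * np.pi * f0 * ts + np.pi * (f1 - f0) * ts ** 2 / T
        # value ~ cos(pi + theta): peak where theta = pi (mod 2*pi)
        phi = theta - np.pi
    else:
        raise ValueError(f"no instantaneous phase for kind={stim.kind!r}")
    return np.mod(phi, 2.0 * np.pi)


def make_periodic_spike_train(stim: StimulusTrace) -> SpikeTrain:
    """One spike at each local maximum of a sinusoid or chirp waveform."""
    if stim.kind not in ("sinusoid", "chirp", "constant"):
        raise ValueError("periodic spike train requires a sinusoid or chirp")
    v = stim.value
    if stim.kind == "constant" or np.ptp(v) == 0:
        return SpikeTrain(np.empty(0), stim.meta["T"])
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    idx = np.nonzero(interior)[0] + 1
    return SpikeTrain(stim.t[idx], stim.meta["T"])


def spikes_to_presynaptic_voltage(train: SpikeTrain, dt: float = 0.1,
                                  v_spike: float = 50.0,
                                  v_rest: float = -60.0,
                                  pulse_ms: float = 1.0) -> StimulusTrace:
    """Two-valued presynaptic-voltage encoding of a spike train.

    V_pre(t) = 50 mV if a spike occurred within the last 1 ms, else
    -60 mV.  Spikes closer than 1 ms merge into one prolonged pulse.
    """
    t = _grid(train.T, dt)
    v = np.full(t.size, v_rest)
    n_pulse = int(round(pulse_ms / dt))
    for ts in train.times:
        i0 = int(np.ceil(ts / dt - 1e-9))
        v[i0:i0 + n_pulse] = v_spike
    return StimulusTrace(t, v, "spike_train_voltage",
                         {"T": train.T, "pulse_ms": pulse_ms})


def make_noise_steps(spec: NoiseSpec, n_steps: int) -> np.ndarray:
    """I.i.d. per-step noise currents g_N * eta_k, eta_k ~ N(0, sigma)."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(spec.seed)
    if spec.sigma == 0:
        return np.zeros(n_steps)
    return spec.g_N * rng.normal(0.0, spec.sigma, n_steps)


def make_synthetic_trains(mode: str,
                          f_grid=None,
                          base_rate: float = 10.0,
                          band=(8.0, 12.0),
                          kappa_in: float = 4.0,
                          kappa_out: float = 0.0,
                          T: float = 10.0,
                          seed: int = 0) -> list[tuple[float, SpikeTrain]]:
    """Synthetic spike trains illustrating the two kinds of spiking resonance.

    For each frequency f in ``f_grid`` (Hz) a T-second record of a
    sinusoidal drive at f is emulated.  In mode ``"rate_band"`` the
    number of spikes per cycle is Poisson with mean ``base_rate/f``,
    doubled for f inside ``band`` (cycle-averaged firing-rate
    resonance); spike phases are uniform.  In mode ``"phase_band"``
    the per-cycle count keeps the same mean at all frequencies, but
    phases are drawn from a von Mises distribution centred on the
    input peak whose concentration is ``kappa_in`` inside the band and
    ``kappa_out`` outside (spike-timing resonance).

    Returns a list of (f, SpikeTrain) pairs.
    """
    if mode not in ("rate_band", "phase_band"):
        raise ValueError("mode must be 'rate_band' or 'phase_band'")
    if f_grid is None:
        f_grid = np.arange(1.0, 21.0)
    f_grid = np.asarray(f_grid, dtype=float)
    if not (f_grid.min() <= band[0] <= band[1] <= f_grid.max()):
        raise ValueError("band must lie within the frequency grid")
    rng = np.random.default_rng(seed)
    out = []
    for f in f_grid:
        n_cycles = int(np.floor(T * f))
        lam = base_rate / f
        in_band = band[0] <= f <= band[1]
        if mode == "rate_band" and in_band:
            lam *= 2.0
        counts = rng.poisson(lam, n_cycles)
        period_ms = 1000.0 / f
        times = []
        for k in range(n_cycles):
            c = counts[k]
            if c == 0:
                continue
            if mode == "rate_band":
                phases = rng.uniform(0.0, 2.0 * np.pi, c)
            else:
                kappa = kappa_in if in_band else kappa_out
                if kappa == 0:
                    phases = rng.uniform(0.0, 2.0 * np.pi, c)
                else:
                    phases = np.mod(rng.vonmises(0.0, kappa, c), 2.0 * np.pi)
            # phase 0 = input peak, at the quarter-period of cycle k
            t0 = k * period_ms + 0.25 * period_ms
            times.extend(t0 + phases / (2.0 * np.pi) * period_ms)
        times = np.sort(np.asarray(times))
        times = times[times < 1000.0 * T]
        # enforce strict ordering (coincident draws are vanishingly rare)
        keep = np.concatenate([[True], np.diff(times) > 0])
        out.append((float(f), SpikeTrain(times[keep], T)))
    return out
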