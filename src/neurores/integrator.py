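"""Fixed-step RK2 integration with threshold-clamp-reset spiking.

The integration scheme is the explicit second-order Runge-Kutta
endpoint (modified Euler / Heun) method:

    k1 = f(t, y),  k2 = f(t+dt, y + dt*k1),  y' = y + dt/2*(k1 + k2)

One Gaussian noise current is drawn per step and enters the voltage
derivative identically in both stages (noise is *not* sqrt(dt)-scaled;
the per-step draw is the model definition, so results are
dt-dependent by construction and each scenario's dt is part of its
preset).

Spiking is handled once per full step, after the update:

* ``reset`` mechanism (integrate-and-fire family): if V > V_th a spike
  is logged at that step's time, V is clamped to V_peak for
  round(T_spike/dt) steps — during which the other state variables
  keep evolving with V = V_peak in their derivatives and no further
  spike can be logged — then V <- V_reset and any auxiliary resets
  (e.g. N_C <- N_reset in the calcium LIF) are applied.
* ``detect`` mechanism (full spike dynamics): a spike is logged at
  each upward crossing of the detection voltage; the state is never
  touched.

Intra-step threshold crossings are not interpolated: spike times live
on the integration grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .stimuli import SpikeTrain, StimulusTrace

__all__ = [
    "SimulationConfig",
    "SpikeMechanism",
    "SimResult",
    "SimulationDivergedError",
    "rk2_step",
    "integrate",
    "run_trials",
    "trial_rng",
]

_MODE_RESET, _MODE_DETECT, _MODE_NONE = 0, 1, 2


class SimulationDivergedError(RuntimeError):
    """Raised when a state variable leaves the physical range."""


@dataclass
class SimulationConfig:
    """Global simulation settings: dt (ms), T (s), trials, master seed."""
    dt: float = 0.1
    T: float = 3.0
    n_trials: int = 1
    master_seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class SpikeMechanism:
    """Threshold spiking description.

    ``aux_resets`` maps state-variable names to post-spike values,
    applied together with the voltage reset at the end of the clamp.
    """
    V_th: float
    V_reset: float = 0.0
    V_peak: float = 50.0
    T_spike: float = 1.0
    aux_resets: list = field(default_factory=list)
    mode: str = "reset"

    def __post_init__(self):
        if self.mode == "reset":
            if not (self.V_reset < self.V_th < self.V_peak):
                raise ValueError("require V_reset < V_th < V_peak")
            if self.T_spike < 0:
                raise ValueError("T_spike must be >= 0")

    @classmethod
    def detector(cls, V_detect: float = 0.0) -> "SpikeMechanism":
        """Spike detection without reset, for models with full spike
        dynamics."""
        return cls(V_th=V_detect, mode="detect")


@dataclass
class SimResult:
    """Traces, auxiliary states and spike times from one trial."""
    t: np.ndarray
    V: np.ndarray                       # (n,) or (n, n_cells)
    aux: dict                           # name -> trace
    spikes: "SpikeTrain | list"         # per cell
    stimulus: "StimulusTrace | None"
    trial_id: int = 0
    meta: dict = field(default_factory=dict)

    def save_npz(self, path) -> None:
        aux = {f"aux_{k}": v for k, v in self.aux.items()}
        if isinstance(self.spikes, SpikeTrain):
            sp = {"spikes": self.spikes.times}
        else:
            sp = {f"spikes_{i}": s.times for i, s in enumerate(self.spikes)}
        np.savez_compressed(path, t=self.t, V=self.V, **aux, **sp)

    def save_text(self, prefix) -> None:
        cols = [self.t, np.atleast_2d(self.V.T).T]
        np.savetxt(f"{prefix}_traces.tsv", np.column_stack(cols),
                   fmt="%.5f", delimiter="\t")
        trains = ([self.spikes] if isinstance(self.spikes, SpikeTrain)
                  else self.spikes)
        for i, s in enumerate(trains):
            s.to_text(f"{prefix}_spikes_cell{i}.txt")


def rk2_step(state, deriv_fn, dt, noise_increment=0.0):
    """One modified-Euler step; reference implementation.

    ``deriv_fn(state) -> array``; ``noise_increment`` is added to the
    first (voltage) component of the derivative in both stages.
    """
    state = np.asarray(state, dtype=float)
    k1 = np.asarray(deriv_fn(state), dtype=float).copy()
    k1[0] += noise_increment
    k2 = np.asarray(deriv_fn(state + dt * k1), dtype=float).copy()
    k2[0] += noise_increment
    out = state + 0.5 * dt * (k1 + k2)
    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.isfinite(out)))
        raise SimulationDivergedError(f"non-finite derivative in state {bad}")
    return out


@njit(cache=True)
def _single_cell_kernel(deriv, p, y0, I, vpre, noise, dt, mode,
                        Vth, Vreset, Vpeak, n_clamp,
                        reset_idx, reset_val, clip_idx, max_spikes):
    n = I.shape[0]
    m = y0.shape[0]
    Y = np.empty((n, m))
    y = y0.copy()
    Y[0] = y
    k1 = np.empty(m)
    k2 = np.empty(m)
    yp = np.empty(m)
    sp = np.empty(max_spikes)
    ns = 0
    clamp = 0
    status = 0
    bad = -1
    for i in range(n - 1):
        eta = noise[i]
        if clamp > 0:
            y[0] = Vpeak
        v_old = y[0]
        deriv(y, I[i] + eta, vpre[i], 0.0, 0.0, 0.0, 0.0, p, k1)
        for j in range(m):
            yp[j] = y[j] + dt * k1[j]
        if clamp > 0:
            yp[0] = Vpeak
        deriv(yp, I[i + 1] + eta, vpre[i + 1], 0.0, 0.0, 0.0, 0.0, p, k2)
        for j in range(m):
            y[j] = y[j] + 0.5 * dt * (k1[j] + k2[j])
        # gating/plasticity variables are probabilities: clamp the rare
        # RK2 overshoot during spike upstrokes back into [0, 1]
        for j in range(clip_idx.shape[0]):
            c = clip_idx[j]
            if y[c] < 0.0:
                y[c] = 0.0
            elif y[c] > 1.0:
                y[c] = 1.0
        if clamp > 0:
            y[0] = Vpeak
            clamp -= 1
            if clamp == 0:
                y[0] = Vreset
                for j in range(reset_idx.shape[0]):
                    y[reset_idx[j]] = reset_val[j]
        else:
            for j in range(m):
                if not np.isfinite(y[j]):
                    status = 1
                    bad = j
                    Y[i + 1] = y
                    return Y[:i + 2], sp[:ns], status, bad
            if abs(y[0]) > 200.0:
                status = 1
                bad = 0
                Y[i + 1] = y
                return Y[:i + 2], sp[:ns], status, bad
            if mode == 0 and y[0] > Vth:
                if ns >= max_spikes:
                    return Y[:i + 2], sp[:ns], 2, -1
                sp[ns] = (i + 1) * dt
                ns += 1
                if n_clamp > 0:
                    y[0] = Vpeak
                    clamp = n_clamp
                else:
                    y[0] = Vreset
                    for j in range(reset_idx.shape[0]):
                        y[reset_idx[j]] = reset_val[j]
            elif mode == 1 and v_old <= Vth < y[0]:
                if ns >= max_spikes:
                    return Y[:i + 2], sp[:ns], 2, -1
                sp[ns] = (i + 1) * dt
                ns += 1
        Y[i + 1] = y
    return Y, sp[:ns], status, bad


def trial_rng(master_seed: int, cell_id: int = 0, trial_id: int = 0):
    """Independent, reproducible RNG stream per (seed, cell, trial)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(cell_id), int(trial_id)]))


def integrate(model, stimulus: StimulusTrace, config: SimulationConfig | None = None,
              spike_mech: "SpikeMechanism | None | bool" = None,
              sigma: float = 0.0, seed: int = 0,
              vpre: StimulusTrace | None = None,
              y0: np.ndarray | None = None,
              cell_id: int = 0, trial_id: int = 0) -> SimResult:
    """Integrate one cell driven by ``stimulus`` (and optionally a
    presynaptic-voltage trace ``vpre``).

    ``spike_mech=None`` uses the model's default; ``spike_mech=False``
    disables spiking entirely (pure subthreshold run).  ``sigma`` is
    the per-step noise SD in mV (g_N = 1 mS/cm^2); the stream is
    reproducibly derived from (seed, cell_id, trial_id).
    """
    dt = stimulus.dt
    if config is not None:
        if abs(config.dt - dt) > 1e-12:
            raise ValueError("stimulus grid does not match config dt")
        if abs(stimulus.meta.get("T", config.T) - config.T) > 1e-12:
            raise ValueError("stimulus duration does not match config T")
    I = np.ascontiguousarray(stimulus.value, dtype=float)
    n = I.size
    if vpre is not None:
        if vpre.n != n or abs(vpre.dt - dt) > 1e-12:
            raise ValueError("vpre grid does not match stimulus grid")
        vp = np.ascontiguousarray(vpre.value, dtype=float)
    else:
        vp = np.zeros(n)
    if sigma > 0:
        # eta ~ N(0, sigma) is the membrane-voltage increment g_N*eta/C
        # accumulated per reference step of 0.1 ms; at finer dt the
        # per-step increments scale as proper white noise, sqrt(dt/0.1).
        # As a current this is g_N*eta/sqrt(0.1*dt); one draw per step,
        # shared by both RK2 stages.
        noise = trial_rng(seed, cell_id, trial_id).normal(
            0.0, sigma, n - 1) / np.sqrt(0.1 * dt)
    else:
        noise = np.zeros(n - 1)

    mech = spike_mech if spike_mech is not None else model.spike_mechanism()
    if mech is False:
        mode, Vth, Vreset, Vpeak, n_clamp = _MODE_NONE, 0.0, 0.0, 0.0, 0
        idx, val = np.empty(0, dtype=np.int64), np.empty(0)
    else:
        names = list(model.state_names)
        idx = np.array([names.index(k) for k, _ in mech.aux_resets],
                       dtype=np.int64)
        val = np.array([float(v) for _, v in mech.aux_resets])
        if mech.mode == "detect":
            mode, Vth, Vreset, Vpeak, n_clamp = _MODE_DETECT, mech.V_th, 0.0, 0.0, 0
        else:
            mode, Vth, Vreset, Vpeak = _MODE_RESET, mech.V_th, mech.V_reset, mech.V_peak
            n_clamp = int(round(mech.T_spike / dt))

    y_init = model.initial_state() if y0 is None else np.asarray(y0, dtype=float)
    max_spikes = int(stimulus.duration_ms) + 16
    clip_idx = np.asarray(getattr(model, "clip01", ()), dtype=np.int64)
    Y, sp, status, bad = _single_cell_kernel(
        model.deriv, model.pack(), y_init, I, vp, noise, dt, mode,
        Vth, Vreset, Vpeak, n_clamp, idx, val, clip_idx, max_spikes)
    if status == 1:
        name = model.state_names[bad] if bad >= 0 else "V"
        raise SimulationDivergedError(
            f"simulation diverged in state {name!r} at t={Y.shape[0] * dt:.3f} ms")
    if status == 2:
        raise SimulationDivergedError("spike-count overflow (rate > ~1 kHz)")
    T = stimulus.meta.get("T", stimulus.duration_ms / 1000.0)
    aux = {nm: Y[:, j] for j, nm in enumerate(model.state_names) if j > 0}
    return SimResult(t=stimulus.t, V=Y[:, 0], aux=aux,
                     spikes=SpikeTrain(sp, T, trial_id),
                     stimulus=stimulus, trial_id=trial_id)


def run_trials(model, stimulus: StimulusTrace, config: SimulationConfig,
               spike_mech=None, sigma: float = 0.0,
               cell_id: int = 0) -> list[SimResult]:
    """Repeat ``integrate`` with independent noise streams per trial;
    the stimulus is identical across trials."""
    return [integrate(model, stimulus, config, spike_mech=spike_mech,
                      sigma=sigma, seed=config.master_seed,
                      cell_id=cell_id, trial_id=k)
            for k in range(config.n_trials)]
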