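# Methods

This note documents the models, numerical conventions and estimator
choices implemented in `neurores`, the defaults they use, and what the
shipped experiments do and do not demonstrate.

## Units and integration

All quantities use mV, ms, μA/cm², mS/cm² and μF/cm²; frequencies are
accepted in Hz and converted internally (f/1000 per ms). Models are
systems of ODEs advanced with the explicit second-order Runge–Kutta
endpoint (modified Euler) scheme at a fixed step, `dt = 0.1 ms` for the
integrate-and-fire-family experiments and `dt = 0.025 ms` for the full
spike-dynamics (PYR/INT) experiments. The step is part of each scenario
preset: several experiment outcomes are step-dependent by construction
(see *Noise*), so `dt` is a model parameter, not a numerical knob.

Threshold spiking (integrate-and-fire family): the threshold test `V >
V_th` runs once per full step, after the update; intra-step crossings
are not interpolated, so spike times live on the integration grid. On a
spike, `V` is clamped to `V_peak` for `round(T_spike/dt)` steps — the
other state variables keep integrating with `V = V_peak`, so
spike-driven variables (the calcium trigger, synaptic gates of the
presynaptic cell) see the depolarisation — then `V ← V_reset` and any
auxiliary resets (e.g. `N_C ← N_reset`) apply. No spike can be logged
during the clamp, which acts as an absolute refractory period. For the
PYR and INT, which generate their own spike waveforms, spikes are
logged at upward crossings of 0 mV and the state is never touched.

Voltage divergence (|V| > 200 mV outside a clamp, or any non-finite
state) raises an error naming the offending state variable.

### Gate variables are probabilities

Activation/inactivation gates, the calcium pair (K, N_C) and the
plasticity factors (S, D, F) are clamped to [0, 1] after every full
step. The continuous dynamics keep them inside the unit interval, but
the RK2 predictor can overshoot during a spike upstroke (where some
time constants collapse below the step); the clamp removes those
transient excursions without otherwise altering trajectories. Terms of
the form `a·x/(1 − e^(−x/b))` are evaluated as `a·b` at the removable
singularity `x = 0`.

## Noise

Membrane-potential variability is an additive white-noise term: one
Gaussian draw `η ~ N(0, σ)` per integration step, multiplied by the
fixed noise conductance `g_N = 1 mS/cm²` and entering the voltage
derivative identically in both RK2 stages. `σ` (mV) is defined as the
*voltage increment per reference step of 0.1 ms*: at `dt = 0.1` each
step adds `g_N·η/C` to the voltage; at finer steps the increments scale
as white noise, `√(dt/0.1)`. The stationary subthreshold voltage SD is
then `σ·√(τ_m/(2·0.1))` for a membrane time constant `τ_m` (ms) — about
7σ at τ_m = 10 ms. This convention ties the σ values quoted in the
presets to the membrane-potential fluctuations they are meant to
describe and keeps the dt = 0.025 experiments consistent with the
dt = 0.1 ones. Noise streams are per (master seed, cell id, trial id)
via `numpy.random.SeedSequence`, so every cell and trial is independent
and individually reproducible.

## Cell models

* **I_Na,p + I_h** (states V, r):
  `C·dV/dt = I − g_L(V−E_L) − g_p·p∞(V)(V−E_Na) − g_h·r(V−E_h)`,
  `dr/dt = (r∞(V) − r)/τ_r`, with `p∞(V) = 1/(1+e^{−(V+38)/6.5})`,
  `r∞(V) = 1/(1+e^{(V+79.2)/9.78})`, τ_r = 100 ms. Defaults: C=1,
  g_L=0.1, E_L=−65, g_p=0.1, E_Na=55, g_h=1, E_h=−20; spiking at
  V_th=−50 with reset −70, peak 50, T_spike=1. Named variants: `rc`
  (g_p=g_h=0, the analytic RC membrane) and `hpf` (g_p=0, C=0.1).
* **LIF**: `C·dV/dt = I − g_L(V−E_L)`; C=1, g_L=0.1, E_L=−60,
  V_th=−50, V_reset=−60, T_spike=1.
* **Calcium-LIF** (V, K, N_C): adds `− g_C·K(V−E_Ca)` with
  `dK/dt = N_C(1−K)/τ_act − K/τ_inact`, `dN_C/dt = −N_C/τ_deact` and the
  spike reset `N_C ← 0.1`; g_L=0.5, g_C=0.08, E_Ca=100, τ_act=50,
  τ_inact=5, τ_deact=70, drive I_bias=−3, A_in=8.
* **Plastic-synapse LIF** (V, S, D, F): `C·dV/dt = I − g_L(V−E_L) −
  g_S·S·D·F·(V−E_S)` with `dS/dt = H(V_pre)(1−S)/τ_r − S/τ_d`,
  `dD/dt = −H(V_pre)·D/τ_reset_d + (1−D)/τ_dep`,
  `dF/dt = H(V_pre)(1−F)/τ_reset_f − F/τ_fac`;
  τ_r/τ_d = 0.1/3 (AMPA-like), τ_reset_d=0.1, τ_dep=100, τ_reset_f=0.2,
  τ_fac=300, g_S=0.175, E_S=0. Disabling depression or facilitation pins
  the factor at 1.
* **PYR** (V, h, n, r): Traub-type kinetics with instantaneous sodium
  activation (m = m∞(V)), `n⁴` delayed rectifier and an I_h gate with
  `r∞(V) = 1/(1+e^{(V+82.9)/12.4})` and the bell-shaped
  `τ_r(V) = 136.36·e^{0.033(V+75)}/(1+e^{0.083(V+75)})` (≈68 ms near
  rest). g_Na=100, g_K=80, g_h=0.485, E_K=−100, E_L=−67.
* **INT**: the Wang–Buzsáki interneuron (φ = 5 temperature factor, i.e.
  a 0.2 prefactor on τ_h and τ_n) plus, when `g_M > 0`, a fast
  non-inactivating potassium current `g_M·q(V−E_K)` with
  `q∞(V) = 1/(1+e^{−(V+35)/10})` and
  `τ_q(V) = 40/(3.3·e^{(V+35)/20} + e^{−(V+35)/20})` — canonical
  M-current kinetics sped up tenfold (peak ≈9 ms), placing its
  restorative action in the gamma band.

### Initial conditions

Simulations start from the settled resting state under the bias
current: for threshold models the subthreshold fixed point is located
directly (root of dV/dt = 0 with gates at steady state, restricted to
V < V_th), and for PYR/INT the state is settled by a 1-s integration.
This matters for the I_Na,p+I_h model, which also possesses a
depolarised fixed point near −15 mV: starting at E_L with r = r∞(E_L)
overshoots the physiological rest entirely. Metric windows discard a
settling period (default 1 s) where applicable.

## Synapses and networks

Each presynaptic neuron owns a single activation gate `S` (AMPA-like
0.1/3 ms, E = 0; GABA_A-like 0.3/9 ms, E = −80) shared by all of its
targets, so network state scales with cells rather than synapse pairs.
The total synaptic current on a cell is `Σ g_class·S_j·(V_post −
E_class)` over presynaptic partners; all-to-all sums include the
self-synapse, which only matters where a preset gives that class a
nonzero conductance (g_ii in the E/I presets). Shipped presets
(`presets/*.yaml`, mirrored row-for-row into `build_preset`):

* `fig2_EI` / `fig2H_EI` — 16 I_Na,p+I_h E-cells → 4 non-resonant LIF
  I-cells (g_ie = 0.05, g_ii = 0.05), chirp to the E-cells (or, in the
  variant, a 16-fold stronger chirp to the I-cells only).
* `fig4_EI` — 16 resonant LIF → 4 noisy LIF, g_ie = 0.01.
* `fig5_layers` — one point-process source firing a spike at each peak
  of a 0–40 Hz, 20 s chirp → 50 plastic-synapse LIF (g_S = 0.2, bias
  1.2, independent noise) → one plain-synapse LIF (g per synapse 0.12,
  no noise). The source is a spike train, not an ODE cell; its
  presynaptic-voltage encoding uses 0.1 ms pulses, matching the
  T_spike of every spiking cell in these experiments (the τ_reset
  values above are calibrated to that pulse width; the generic
  `spikes_to_presynaptic_voltage` default remains the 1-ms rule).
* `fig7_int_pyr`, `fig8*` — feedforward INT→PYR (g_ei = 0.4, all other
  classes 0), with the M-current disabled (`fig7`) or enabled plus the
  stronger gamma drives (`fig8` variants).

## Metrics

* **Impedance**: for single-frequency runs, `Z_mag = (max V − min V)/
  (2A_in)` over the post-settle window and phase from the lag of the
  voltage peak; for chirp runs, the ratio of FFTs of (V − mean) and
  (I − I_bias), magnitude-smoothed over 2 Hz. Runs containing spikes in
  the window are rejected.
* **Coherence**: spike trains enter as binary indicators on the dt
  grid; Welch segment averaging with 2-s Hann windows and 50% overlap;
  cross- and auto-spectra are pooled over segments and trials before
  forming `|S_xy|/√(S_xx·S_yy)`. Absolute coherence values depend on
  the segment length (a config knob); the bias floor for unrelated
  trains scales as 1/n_segments. Zero-spike inputs return an all-zero
  spectrum flagged in metadata.
* **Fingerprint**: spikes counted in (frequency, phase) bins — 1 Hz ×
  36 phase bins per cycle by default — divided by the pooled time spent
  in each bin; phase 0 is the input maximum, and instantaneous
  frequency/phase come from the analytic phase function of the
  stimulus, not a Hilbert transform. The phase marginal reproduces the
  cycle-averaged rate profile exactly.
* **EPSP magnitude**: steady-state per-cycle peak-to-trough after the
  settle window, one value per presynaptic rate.
* **Peak extraction**: moving-average smoothing (default 3 bins), ties
  toward the lowest frequency, and a profile counts as *resonant* only
  if its peak is interior to the grid. Spiking bands are the longest
  contiguous run of frequency bins with rate ≥ 1 spk/s; a band starting
  at the lowest bin is flagged low-pass.

## Synthetic spike trains

`make_synthetic_trains` generates the two canonical illustrations of
spiking resonance: `rate_band` draws per-cycle spike counts from a
Poisson distribution whose mean doubles inside the 8–12 Hz band
(cycle-averaged firing-rate resonance, uniform phases), and
`phase_band` keeps the mean count flat but draws phases from a von
Mises distribution concentrated (κ = 4 by default) inside the band
(spike-timing resonance). Defaults: 1–20 Hz grid, 10 spk/s base rate,
10 s per frequency. These trains emulate only the statistics the
metrics are designed to detect — no refractoriness, adaptation or
history dependence — so passing metric tests on them validates the
estimators, not any biophysics.

## Problem sizes

The scenario battery is sized for a desktop core: per-frequency runs
use 3-s records (1 s discarded), chirp runs 10–20 s; the layered
network pools 10 trials of 50 cells and its noise sweep uses 0.1-mV
steps over 0.2–0.9 mV with 5 trials per level (the `--full` flag
restores the dense 0.025-mV grid over 0–2 mV); the PYR/INT experiments
pool 20 trials at dt = 0.025 ms. The full acceptance battery runs in a
few minutes; numba compiles the kernels once per session.

## Known limitations

* Several experiments operate deliberately close to threshold, and
  outcomes there are sensitive at the 0.1-mV scale. The I_Na,p+I_h
  rest sits 2.8 mV below threshold and its post-spike reset lies
  outside the rest state's basin of attraction, so sustained firing
  follows any first spike; the calcium-LIF drive grazes threshold
  exactly (E_L + (I_bias+A_in)/g_L = V_th), so with its default noise
  (σ = 0.001) the spiking band does not ignite above the lowest
  frequencies and the model behaves as a low-pass spiking filter; the
  layered network's EPSPs peak ≈2.2 mV against a 3-mV threshold gap,
  which caps the attainable layer-2 coherence (~0.1) and makes its
  noise sweep monotone rather than peaked. These regimes are inherent
  to the parameter sets as shipped; the mechanisms (calcium-dependent
  bandwidth, coherence inheritance, stochastic ignition) respond as
  expected when the margins are varied.
* Noise is defined per reference step (see above); results with σ > 0
  are reproducible but convention-dependent, and no exact
  Euler–Maruyama limit is implied.
* Event times are not interpolated within steps; spike times are
  accurate to dt.
* Plotting is deliberately out of scope; all outputs are arrays,
  delimited text and JSON.
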