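# E/I network inheriting spiking resonance of the isolated LIF:
# 16 resonant LIF E-cells -> 4 non-resonant LIF I-cells.
N_e: 16
N_i: 4
C: 1.0
g_L: 0.1
E_L: -60.0
V_th: -50.0
V_reset: -60.0
V_peak: 50.0
T_spike: 1.0
tau_r_e: 0.1
tau_d_e: 3.0
E_e: 0.0
tau_r_i: 0.3
tau_d_i: 9.0
E_i: -80.0
g_ie: 0.01
g_ee: 0.0
g_ei: 0.0
g_ii: 0.05
sigma_e: 0.02
I_bias_e: 0.9
A_in_e: 0.115
sigma_i: 2.0
I_bias_i: 0.0
A_in_i: 0.0
chirp: {f0: 0.0, f1: 40.0, T: 20.0}
dt: 0.1
variants:
  high_noise:
    sigma_e: 0.08
  strong_coupling:
    g_ie: 1.0
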