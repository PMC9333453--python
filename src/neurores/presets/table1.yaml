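# E/I network inheriting membrane-potential (theta) resonance:
# 16 I_Na,p+I_h E-cells -> 4 non-resonant LIF I-cells, all-to-all by class.
N_e: 16
N_i: 4
C: 1.0
g_L: 0.1
V_th: -50.0
V_peak: 50.0
E_L_e: -65.0
g_p: 0.1
E_Na: 55.0
g_h: 1.0
E_h: -20.0
tau_h: 100.0
V_reset_e: -70.0
T_spike_e: 1.0
E_L_i: -60.0
V_reset_i: -60.0
T_spike_i: 0.1
tau_r_e: 0.1     # AMPA rise
tau_d_e: 3.0     # AMPA decay
E_e: 0.0
tau_r_i: 0.3     # GABA_A rise
tau_d_i: 9.0     # GABA_A decay
E_i: -80.0
g_ie: 0.05       # E to I
g_ee: 0.0
g_ei: 0.0
g_ii: 0.05
sigma_e: 0.0125
I_bias_e: -1.85
A_in_e: 0.14125
sigma_i: 3.0
I_bias_i: -1.0
A_in_i: 0.0
chirp: {f0: 0.0, f1: 40.0, T: 20.0}
dt: 0.1
variants:
  direct_to_I:        # periodic drive only to the I-cells, 16-fold amplitude
    A_in_e: 0.0
    A_in_i: 2.26
  strong_coupling:
    g_ie: 1.0
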