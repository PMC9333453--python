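# IPSP-induced network resonance: INT -> PYR via one GABA_A synapse.
C_e: 1.0
g_L_e: 0.1
E_L_e: -67.0
g_Na_e: 100.0
E_Na_e: 50.0
g_K_e: 80.0
E_K_e: -100.0
g_h_e: 0.485
E_h_e: -33.0
C_i: 1.0
g_L_i: 0.1
E_L_i: -65.0
g_Na_i: 35.0
E_Na_i: 55.0
g_K_i: 9.0
E_K_i: -90.0
g_M_i: 4.0       # 0 for the non-gamma INT
tau_r_e: 0.1
tau_d_e: 3.0
E_e: 0.0
tau_r_i: 0.3
tau_d_i: 9.0
E_i: -80.0
g_ie: 0.0
g_ee: 0.0
g_ei: 0.4        # INT to PYR
g_ii: 0.0
sigma_e: 0.1
I_bias_e: -2.7
A_in_e: 0.0
sigma_i: 0.1
I_bias_i: -0.5
A_in_i: 0.5
chirp: {f0: 0.0, f1: 40.0, T: 20.0}
dt: 0.025
variants:
  pyr_direct:          # isolated PYR, direct chirp drive
    g_ei: 0.0
    A_in_e: 0.2
    A_in_i: 0.0
  int_pyr:             # non-gamma INT driving the PYR
    g_M_i: 0.0
  gamma_int_impedance: # isolated gamma-INT, subthreshold chirp (0-80 Hz, 10 s)
    g_ei: 0.0
    sigma_i: 0.0
    I_bias_i: 3.8
    A_in_i: 0.5
    chirp: {f0: 0.0, f1: 80.0, T: 10.0}
  gamma_int_spiking:   # isolated gamma-INT, suprathreshold chirp
    g_ei: 0.0
    sigma_i: 0.0
    I_bias_i: 3.8
    A_in_i: 0.9
    chirp: {f0: 0.0, f1: 80.0, T: 10.0}
  gamma_int_pyr:       # full gamma-INT -> PYR network
    sigma_i: 0.0
    I_bias_i: 3.7
    A_in_i: 2.1
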