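"""Network assembly: synaptic currents, presets, causality, decoupling."""

import numpy as np
import pytest

from neurores import models as M
from neurores.integrator import SimulationConfig, integrate
from neurores.network import (LayeredFeedforwardSpec, NetworkSpec, Population,
                              build_preset, settled_state, simulate_network,
                              total_synaptic_current)


class TestSynapticCurrent:
    def test_all_gates_closed(self):
        assert total_synaptic_current(-60.0, [(0.5, 0.0, 0.0)]) == 0.0

    def test_excitatory_sign(self):
        # one E synapse at S=1: I_syn = g*(V-E) < 0 for V < E, so the
        # -I_syn term in dV/dt depolarizes
        I = total_synaptic_current(-60.0, [(1.0, 1.0, 0.0)])
        assert I == pytest.approx(-60.0)

    def test_shunting_at_reversal(self):
        assert total_synaptic_current(-80.0, [(0.7, 1.0, -80.0)]) == 0.0


class TestPresets:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="fig7_int_pyr"):
            build_preset("nope")

    def test_theta_ei_preset_values(self):
        spec, cfg = build_preset("fig2_EI")
        assert (spec.e_pop.n, spec.i_pop.n) == (16, 4)
        assert spec.g_ie == 0.05 and spec.g_ii == 0.05
        assert spec.e_pop.sigma == 0.0125 and spec.i_pop.sigma == 3.0
        assert spec.e_pop.A_in == 0.14125
        assert spec.e_pop.model.tau_r == 100.0
        assert cfg.dt == 0.1

    def test_drive_to_I_variant_sixteen_fold(self):
        spec, _ = build_preset("fig2H_EI")
        assert spec.e_pop.A_in == 0.0
        assert spec.i_pop.A_in == pytest.approx(16 * 0.14125)

    def test_lif_ei_preset_values(self):
        spec, _ = build_preset("fig4_EI")
        assert spec.g_ie == 0.01
        assert spec.e_pop.sigma == 0.02
        assert spec.e_pop.A_in == 0.115
        assert spec.e_pop.I_bias == 0.9

    def test_int_pyr_preset_values(self):
        spec, cfg = build_preset("fig7_int_pyr")
        assert spec.g_ei == 0.4
        assert spec.g_ee == spec.g_ie == spec.g_ii == 0.0
        assert spec.i_pop.A_in == 0.5
        assert spec.e_pop.I_bias == -2.7
        assert spec.i_pop.model.g_M == 0.0
        assert cfg.dt == 0.025

    def test_gamma_preset_has_m_current(self):
        spec, _ = build_preset("fig8_gammaint_pyr")
        assert spec.i_pop.model.g_M == 4.0


class TestSettledState:
    def test_naph_rest_is_subthreshold_fixed_point(self):
        m = M.NapHParams()
        y0 = settled_state(m, -1.85)
        assert y0[0] < m.V_th
        dv, dr = M.nap_h_deriv(y0[0], y0[1], -1.85, m)
        assert abs(dv) < 1e-6 and abs(dr) < 1e-9

    def test_lif_rest_linear(self):
        y0 = settled_state(M.LIFParams(), 0.9)
        assert y0[0] == pytest.approx(-51.0)


def _two_cell_spec(**kw):
    e = Population("e", M.LIFParams(), 1, sigma=kw.get("sig_e", 0.5),
                   I_bias=0.9, A_in=0.1)
    i = Population("i", M.LIFParams(), 1, sigma=kw.get("sig_i", 0.5),
                   I_bias=0.0, A_in=0.0)
    return NetworkSpec(e_pop=e, i_pop=i, g_ie=kw.get("g_ie", 0.0),
                       chirp=(0.0, 40.0, kw.get("T", 1.0)))


class TestNetworkSimulation:
    def test_decoupled_cells_match_isolated_runs(self):
        # all synaptic conductances zero: every cell reproduces its
        # isolated trajectory bit-exactly (same noise streams)
        spec = _two_cell_spec(T=1.0)
        cfg = SimulationConfig(dt=0.1, T=1.0, master_seed=3)
        net = simulate_network(spec, cfg, trial_id=0)
        drives = spec.drives(0.1)
        solo_e = integrate(spec.e_pop.model, drives["e"], sigma=0.5,
                           seed=3, cell_id=0, trial_id=0,
                           y0=settled_state(spec.e_pop.model, 0.9))
        solo_i = integrate(spec.i_pop.model, drives["i"], sigma=0.5,
                           seed=3, cell_id=1, trial_id=0,
                           y0=settled_state(spec.i_pop.model, 0.0))
        assert np.array_equal(net.V[:, 0], solo_e.V)
        assert np.array_equal(net.V[:, 1], solo_i.V)

    def test_feedforward_causality(self):
        # E -> I only: changing the downstream (I) noise must leave the
        # upstream (E) trace untouched
        cfg = SimulationConfig(dt=0.1, T=1.0, master_seed=3)
        a = simulate_network(_two_cell_spec(g_ie=0.05, sig_i=0.5), cfg)
        b = simulate_network(_two_cell_spec(g_ie=0.05, sig_i=2.0), cfg)
        assert np.array_equal(a.V[:, 0], b.V[:, 0])
        assert not np.array_equal(a.V[:, 1], b.V[:, 1])

    def test_coupling_changes_target(self):
        cfg = SimulationConfig(dt=0.1, T=1.0, master_seed=3)
        a = simulate_network(_two_cell_spec(g_ie=0.0), cfg)
        b = simulate_network(_two_cell_spec(g_ie=0.5), cfg)
        assert not np.array_equal(a.V[:, 1], b.V[:, 1])

    def test_trial_reproducibility(self):
        cfg = SimulationConfig(dt=0.1, T=1.0, master_seed=9)
        a = simulate_network(_two_cell_spec(), cfg, trial_id=4)
        b = simulate_network(_two_cell_spec(), cfg, trial_id=4)
        assert np.array_equal(a.V, b.V)

    def test_int_pyr_relaxes_without_drive(self):
        # energy sanity: zero drive, zero noise -> bounded trajectories
        spec, cfg = build_preset("fig7_int_pyr")
        spec.e_pop.sigma = spec.i_pop.sigma = 0.0
        spec.e_pop.A_in = spec.i_pop.A_in = 0.0
        cfg = SimulationConfig(dt=cfg.dt, T=5.0)
        spec.chirp = (0.0, 40.0, 5.0)
        res = simulate_network(spec, cfg)
        assert np.all(np.abs(res.V) < 120.0)
        assert np.all(np.isfinite(res.V))


class TestLayeredNetwork:
    def test_shared_input_gate_and_noise_independence(self):
        spec = LayeredFeedforwardSpec(n2=4, sigma2=0.0)
        spec.chirp = (0.0, 40.0, 2.0)
        cfg = SimulationConfig(dt=0.1, T=2.0, master_seed=1)
        res = simulate_network(spec, cfg)
        # sigma=0: all layer-2 cells see the same shared gate and are
        # identical, so their spike trains coincide
        t0 = res.spikes[0].times
        for c in range(1, 4):
            assert np.array_equal(res.spikes[c].times, t0)

    def test_layer3_silent_without_layer2_spikes(self):
        spec = LayeredFeedforwardSpec(n2=4, sigma2=0.0, I_bias2=-5.0)
        spec.chirp = (0.0, 40.0, 2.0)
        cfg = SimulationConfig(dt=0.1, T=2.0, master_seed=1)
        res = simulate_network(spec, cfg)
        assert all(res.spikes[c].n == 0 for c in range(4))
        assert res.spikes[4].n == 0
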