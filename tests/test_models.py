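"""Gating curves, derivative functions, plasticity dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurores import models as M
from neurores.integrator import integrate
from neurores.metrics import rc_impedance
from neurores.network import settled_state
from neurores.scenarios import impedance_curve_sinusoids
from neurores.stimuli import (SpikeTrain, make_constant,
                              spikes_to_presynaptic_voltage)


class TestGatingCurves:
    @pytest.mark.parametrize("fn,mid", [
        (M.naph_p_inf, -38.0),
        (M.naph_r_inf, -79.2),
        (M.pyr_r_inf, -82.9),
        (M.wb_q_inf, -35.0),
    ])
    def test_sigmoid_midpoints(self, fn, mid):
        assert fn(mid) == pytest.approx(0.5, abs=1e-12)

    def test_release_sigmoid(self):
        assert M.H(0.0) == pytest.approx(0.5)
        assert M.H(50.0) == pytest.approx(1.0, abs=1e-10)
        assert M.H(-60.0) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("fn", [
        M.naph_p_inf, M.naph_r_inf, M.pyr_r_inf, M.wb_q_inf, M.pyr_m_inf,
        M.wb_m_inf,
    ])
    def test_steady_states_bounded_and_monotone(self, fn):
        V = np.arange(-120.0, 60.5, 0.5)
        x = np.array([fn(v) for v in V])
        assert np.all((x >= 0) & (x <= 1))
        d = np.diff(x)
        assert np.all(d >= -1e-12) or np.all(d <= 1e-12)

    def test_time_constants_positive(self):
        V = np.arange(-120.0, 60.5, 0.5)
        for fn in (M.pyr_tau_r, M.wb_tau_q):
            assert np.all(np.array([fn(v) for v in V]) > 0)
        for a, b in ((M.pyr_alpha_h, M.pyr_beta_h),
                     (M.pyr_alpha_n, M.pyr_beta_n),
                     (M.wb_alpha_h, M.wb_beta_h),
                     (M.wb_alpha_n, M.wb_beta_n)):
            assert np.all([a(v) + b(v) > 0 for v in V])

    def test_removable_singularities(self):
        # alpha_m-type terms are continuous through V = -c with limit a*b
        assert M.pyr_alpha_m(-54.0) == pytest.approx(0.32 * 4.0, rel=1e-6)
        assert M.pyr_alpha_m(-54.0) == pytest.approx(
            M.pyr_alpha_m(-54.0 + 1e-5), rel=1e-4)
        assert M.wb_alpha_m(-35.0) == pytest.approx(0.2 * 10.0, rel=1e-6)
        assert M.pyr_alpha_n(-52.0) == pytest.approx(0.032 * 5.0, rel=1e-6)


class TestDerivatives:
    def test_lif_rest(self):
        assert M.lif_deriv(-60.0, 0.0) == pytest.approx(0.0)

    def test_naph_fixed_point(self, naph_rest):
        dv, dr = M.nap_h_deriv(naph_rest[0], naph_rest[1], -1.85)
        assert abs(dv) < 1e-6 and abs(dr) < 1e-9

    def test_calcium_pure_decay_without_trigger(self):
        _, dK, dNC = M.calcium_lif_deriv(-60.0, 0.4, 0.0, 0.0)
        p = M.CalciumLIFParams()
        assert dK == pytest.approx(-0.4 / p.tau_inact)
        assert dNC == 0.0

    def test_calcium_gate_equilibrium(self):
        # fixed N_C: dK/dt = 0 at K* = N_C*tau_inact/(N_C*tau_inact+tau_act)
        p = M.CalciumLIFParams()
        NC = 0.1
        K_star = NC * p.tau_inact / (NC * p.tau_inact + p.tau_act)
        _, dK, _ = M.calcium_lif_deriv(-60.0, K_star, NC, 0.0)
        assert abs(dK) < 1e-12

    def test_plasticity_resting_fixed_points(self):
        dD, dF = M.plasticity_deriv(1.0, 0.0, -60.0)
        assert abs(dD) < 1e-12 and abs(dF) < 1e-12

    def test_synapse_gate_decay_constant(self):
        # single presynaptic pulse: S decays with tau_d = 3 ms
        model = M.PlasticLIFParams(syn=M.PlasticSynapseParams(
            use_depression=False, use_facilitation=False))
        train = SpikeTrain([50.0], 0.5)
        vpre = spikes_to_presynaptic_voltage(train, 0.1)
        res = integrate(model, make_constant(0.0, 0.5, 0.1), vpre=vpre,
                        spike_mech=False)
        S = res.aux["S"]
        i0 = np.argmax(S)
        t = res.t[i0:] - res.t[i0]
        tau = np.polyfit(t[:200], np.log(S[i0:i0 + 200]), 1)[0]
        assert -1.0 / tau == pytest.approx(3.0, rel=0.05)

    def test_pyr_int_derivatives_finite(self):
        for V in np.arange(-120.0, 60.1, 5.0):
            assert np.all(np.isfinite(M.pyr_deriv(V, 0.5, 0.5, 0.5, 0.0)))
            assert np.all(np.isfinite(M.int_deriv(V, 0.5, 0.5, 0.5, 0.0)))


class TestStateBounds:
    """Gating/plasticity variables stay inside [0, 1] along trajectories."""

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(0.8, 1.2), bias=st.floats(-4.0, 2.0))
    def test_calcium_lif_bounds(self, scale, bias):
        p = M.CalciumLIFParams(g_C=0.08 * scale, tau_act=50 * scale,
                               tau_inact=5 * scale, tau_deact=70 * scale)
        res = integrate(p, make_constant(bias, 0.5, 0.1), sigma=0.5, seed=1)
        for k in ("K", "N_C"):
            assert np.all((res.aux[k] >= -1e-9) & (res.aux[k] <= 1 + 1e-9))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(0.8, 1.2), rate=st.floats(2.0, 30.0))
    def test_plasticity_bounds(self, scale, rate):
        from neurores.scenarios import _presyn_from_sinusoid
        syn = M.PlasticSynapseParams(tau_dep=100 * scale, tau_fac=300 * scale)
        model = M.PlasticLIFParams(syn=syn)
        _, vpre = _presyn_from_sinusoid(rate, 1.0, 0.1)
        res = integrate(model, make_constant(1.0, 1.0, 0.1), vpre=vpre)
        for k in ("S", "D", "F"):
            assert np.all((res.aux[k] >= -1e-9) & (res.aux[k] <= 1 + 1e-9))

    def test_naph_gate_bounds(self, naph_rest):
        from neurores.stimuli import make_sinusoid
        res = integrate(M.NapHParams(), make_sinusoid(8.0, 0.2, -1.85, 2.0, 0.1),
                        y0=naph_rest)
        assert np.all((res.aux["r"] >= 0) & (res.aux["r"] <= 1))

    def test_pyr_gate_bounds(self):
        p = M.PyrParams()
        y0 = settled_state(p, -2.7, 0.025)
        from neurores.stimuli import make_sinusoid
        res = integrate(p, make_sinusoid(10.0, 0.5, -2.7, 1.0, 0.025), y0=y0)
        for k in ("h", "n", "r"):
            assert np.all((res.aux[k] >= -1e-9) & (res.aux[k] <= 1 + 1e-9))


class TestAblations:
    def test_passive_reduction_matches_rc_curve(self):
        # g_p = g_h = 0 reduces the NapH model to the analytic RC membrane
        model = M.NapHParams.rc_variant()
        freqs = np.array([1.0, 5.0, 20.0])
        prof = impedance_curve_sinusoids(model, freqs, A_in=0.1, I_bias=0.0)
        expect, _ = rc_impedance(freqs, model.g_L, model.C)
        assert np.allclose(prof.Z_mag, expect, rtol=0.01)

    def test_disabled_plasticity_reduces_to_plain_synapse(self):
        # D==1, F==1 pinned: the plastic synapse must equal a plain
        # gate-only synapse trajectory
        from neurores.scenarios import _presyn_from_sinusoid
        _, vpre = _presyn_from_sinusoid(10.0, 1.0, 0.1)
        off = M.PlasticLIFParams(syn=M.PlasticSynapseParams(
            use_depression=False, use_facilitation=False))
        res = integrate(off, make_constant(0.0, 1.0, 0.1), vpre=vpre,
                        spike_mech=False)
        assert np.all(res.aux["D"] == 1.0)
        assert np.all(res.aux["F"] == 1.0)
        # conductance g_S*S*D*F == g_S*S
        on = M.PlasticLIFParams()
        res_on = integrate(on, make_constant(0.0, 1.0, 0.1), vpre=vpre,
                           spike_mech=False)
        assert not np.array_equal(res.V, res_on.V)  # plasticity matters
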