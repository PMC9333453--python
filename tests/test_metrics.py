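"""Impedance, coherence, fingerprint and peak-extraction metrics."""

import numpy as np
import pytest

from neurores import metrics as mt
from neurores.integrator import integrate
from neurores.models import NapHParams
from neurores.scenarios import impedance_curve_sinusoids
from neurores.stimuli import (SpikeTrain, make_chirp,
                              make_periodic_spike_train, make_sinusoid)


class TestImpedance:
    def test_rc_dc_limit(self):
        model = NapHParams.rc_variant()
        prof = impedance_curve_sinusoids(model, [0.2], A_in=0.1, I_bias=0.0,
                                         T=12.0)
        assert prof.Z_mag[0] == pytest.approx(1.0 / model.g_L, rel=0.01)

    def test_rc_matches_closed_form_within_1pct(self):
        model = NapHParams.rc_variant()
        freqs = np.arange(1.0, 41.0, 3.0)
        prof = impedance_curve_sinusoids(model, freqs, A_in=0.1, I_bias=0.0)
        mag, ph = mt.rc_impedance(freqs, model.g_L, model.C)
        assert np.allclose(prof.Z_mag, mag, rtol=0.01)

    def test_rc_phase_quarter_pi_at_corner(self):
        # f = 1/(2*pi*tau) -> phase = -pi/4
        model = NapHParams.rc_variant()       # tau = C/g_L = 10 ms
        f_corner = 1000.0 / (2 * np.pi * 10.0)
        prof = impedance_curve_sinusoids(model, [f_corner], A_in=0.1,
                                         I_bias=0.0)
        assert prof.Z_phase[0] == pytest.approx(-np.pi / 4, abs=0.05)

    def test_spikes_in_window_rejected(self):
        stim = make_sinusoid(5.0, 0.1, 0.0, 3.0, 0.1)
        sp = SpikeTrain([2500.0], 3.0)
        with pytest.raises(mt.SpikesInWindowError):
            mt.impedance_point(stim.value * 0, stim, settle=1.0, spikes=sp)


class TestCycleAveragedRate:
    def test_one_spike_per_cycle_gives_rate_equal_f(self):
        c = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        train = make_periodic_spike_train(c)
        prof = mt.cycle_averaged_rate(train, c, f_bin=2.0)
        sel = (prof.f > 4) & (prof.f < 36)
        assert np.allclose(prof.rate[sel], prof.f[sel], rtol=0.1)

    def test_empty_train(self):
        c = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        prof = mt.cycle_averaged_rate(SpikeTrain(np.empty(0), 20.0), c)
        assert np.all(prof.rate == 0)


class TestFingerprint:
    def test_count_conservation(self, rng):
        c = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        times = np.sort(rng.uniform(0, 20_000, 300))
        fp = mt.fingerprint(SpikeTrain(times, 20.0), c)
        assert fp.counts.sum() == 300
        assert np.sum(fp.rate * fp.occupancy) == pytest.approx(300)

    def test_homogeneous_poisson_flat(self, rng):
        c = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        trains = [SpikeTrain(np.sort(rng.uniform(0, 20_000, 400)), 20.0, k)
                  for k in range(30)]
        fp = mt.fingerprint(trains, c, f_bin=5.0, n_phase_bins=6)
        interior = fp.rate[1:-1]
        assert interior.std() / interior.mean() < 0.25

    def test_phase_marginal_matches_rate_profile(self, rng):
        c = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        times = np.sort(rng.uniform(0, 20_000, 500))
        fp = mt.fingerprint(SpikeTrain(times, 20.0), c, f_bin=2.0)
        prof = mt.cycle_averaged_rate(SpikeTrain(times, 20.0), c, f_bin=2.0)
        assert np.allclose(fp.rate_marginal().rate, prof.rate)

    def test_expanded_covers_one_and_a_half_cycles(self):
        c = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        fp = mt.fingerprint(SpikeTrain([100.0], 20.0), c, n_phase_bins=36)
        ph, rate = fp.expanded()
        assert ph.size == 54
        assert rate.shape[1] == 54
        assert ph[-1] > 2.9 * np.pi


class TestCoherence:
    def test_perfect_locking(self):
        s = make_sinusoid(10.0, 1.0, 0.0, 20.0, 0.1)
        train = make_periodic_spike_train(s)
        coh = mt.spike_input_coherence(train, s, 0.1)
        i = np.argmin(np.abs(coh.f - 10.0))
        assert coh.coh[i] > 0.99

    def test_random_spikes_near_bias_floor(self, rng):
        s = make_sinusoid(10.0, 1.0, 0.0, 20.0, 0.1)
        trains = [SpikeTrain(np.sort(rng.uniform(0, 20_000, 200)), 20.0, k)
                  for k in range(10)]
        coh = mt.spike_input_coherence(trains, s, 0.1)
        i = np.argmin(np.abs(coh.f - 10.0))
        # pooled estimator bias floor ~ 1/sqrt(n_segments)
        assert coh.coh[i] < 3.0 / np.sqrt(coh.n_segments)

    def test_bounded_for_arbitrary_trains(self, rng):
        s = make_chirp(0.0, 40.0, 1.0, 0.0, 20.0, 0.1)
        for k in range(3):
            n = int(rng.integers(1, 500))
            tr = SpikeTrain(np.sort(rng.choice(np.arange(0.1, 20_000, 0.1),
                                               n, replace=False)), 20.0)
            coh = mt.spike_input_coherence(tr, s, 0.1)
            assert np.all((coh.coh >= 0) & (coh.coh <= 1))

    def test_zero_spikes_flagged(self):
        s = make_sinusoid(10.0, 1.0, 0.0, 20.0, 0.1)
        coh = mt.spike_input_coherence(SpikeTrain(np.empty(0), 20.0), s, 0.1)
        assert np.all(coh.coh == 0)
        assert coh.meta["zero_spikes"]


class TestPeakExtraction:
    def test_monotone_profile_not_resonant(self):
        f = np.arange(1.0, 21.0)
        pk = mt.find_resonant_peak(f, 1.0 / f, smooth_bins=1)
        assert not pk.resonant
        assert pk.f_peak == 1.0

    def test_symmetric_bump(self):
        f = np.arange(1.0, 21.0)
        pk = mt.find_resonant_peak(f, np.exp(-0.5 * (f - 10) ** 2))
        assert pk.f_peak == 10.0
        assert pk.resonant

    def test_tie_breaks_low(self):
        f = np.arange(1.0, 6.0)
        pk = mt.find_resonant_peak(f, [0, 1, 1, 1, 0], smooth_bins=1)
        assert pk.f_peak == 2.0

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            mt.find_resonant_peak(np.empty(0), np.empty(0))


class TestSpikingBand:
    def test_band_and_lowpass_flag(self):
        prof = mt.RateProfile(np.arange(1.0, 11.0),
                              np.array([0, 0, 0, 2, 5, 5, 3, 0, 0, 0.0]))
        lo, hi, center, low_pass = mt.spiking_band(prof)
        assert (lo, hi, center) == (4.0, 7.0, 5.5)
        assert not low_pass
        prof2 = mt.RateProfile(np.arange(1.0, 11.0),
                               np.array([4, 3, 2, 2, 0, 0, 0, 0, 0, 0.0]))
        assert mt.spiking_band(prof2)[3]
        assert mt.spiking_band(
            mt.RateProfile(np.arange(1.0, 4.0), np.zeros(3))) is None


class TestEpsp:
    def test_single_spike_unitary_amplitude(self):
        from neurores.models import PlasticLIFParams, PlasticSynapseParams
        from neurores.stimuli import make_constant, spikes_to_presynaptic_voltage
        model = PlasticLIFParams(syn=PlasticSynapseParams(
            use_depression=False, use_facilitation=False))
        train = SpikeTrain([1500.0], 3.0)
        vpre = spikes_to_presynaptic_voltage(train, 0.1, pulse_ms=0.1)
        res = integrate(model, make_constant(0.0, 3.0, 0.1), vpre=vpre,
                        spike_mech=False)
        mag = mt.epsp_magnitude(res.V, train, res.t, settle=1.0)
        direct = res.V[15000:].max() - res.V[15000:].min()
        assert mag == pytest.approx(direct, rel=1e-9)
        assert mag > 1.0  # a real EPSP

    def test_postsynaptic_spikes_rejected(self):
        with pytest.raises(mt.SpikesInWindowError):
            mt.epsp_magnitude(np.zeros(10), SpikeTrain([1.0], 1.0),
                              np.arange(10.0), spikes=SpikeTrain([5.0], 1.0))
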