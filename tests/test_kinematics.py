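"""Swim-cycle segmentation, gain/phase estimation and modulation metrics."""

import numpy as np
import pytest

from tadgaze import kinematics as kin

RATE = 500.0


def sine(freq, duration, amp=1.0, phase_deg=0.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t + np.deg2rad(phase_deg))


class TestLowpass:
    def test_passband_amplitude_preserved(self):
        x = sine(6.0, 4.0, amp=5.0)
        y = kin.lowpass_20(x, RATE)
        assert np.ptp(y[500:-500]) == pytest.approx(10.0, rel=0.02)

    def test_high_frequency_attenuated(self):
        y = kin.lowpass_20(sine(60.0, 4.0), RATE)
        assert np.ptp(y[500:-500]) < 0.2  # > 20 dB down

    def test_dc_preserved(self):
        y = kin.lowpass_20(np.full(2000, 3.5), RATE)
        assert np.allclose(y, 3.5)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            kin.lowpass_20(np.ones(100), 30.0)


class TestSegmentation:
    def test_sine_cycle_count(self):
        onsets = kin.segment_swim_cycles(sine(6.0, 3.0, amp=10.0), RATE)
        assert onsets.size == 18

    def test_flat_trace_no_cycles(self):
        assert kin.segment_swim_cycles(np.zeros(3000), RATE).size == 0

    def test_noise_robust_with_hysteresis(self, rng):
        x = sine(6.0, 3.0, amp=10.0) + rng.normal(0, 1.0, int(3 * RATE))
        onsets = kin.segment_swim_cycles(kin.lowpass_20(x, RATE), RATE,
                                         hysteresis_deg=1.0)
        assert onsets.size == 18


class TestPerCycleAmplitudes:
    def test_peak_to_peak_values(self):
        tail = sine(6.0, 3.0, amp=5.0)
        eye = 0.4 * tail
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(eye, tail, onsets, RATE)
        assert np.allclose(tab["tail_ptp_deg"], 10.0, rtol=0.02)
        assert np.allclose(tab["eye_ptp_deg"], 4.0, rtol=0.02)
        assert np.allclose(tab["eye_ptp_deg"] / tab["tail_ptp_deg"], 0.4,
                           rtol=1e-6)

    def test_instantaneous_frequency(self):
        tail = sine(8.0, 2.0, amp=10.0)
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(tail, tail, onsets, RATE)
        assert np.nanmedian(tab["inst_freq_hz"]) == pytest.approx(8.0, rel=0.02)


class TestGainPhase:
    def test_scaled_copy_gain_and_zero_phase(self):
        tail = sine(6.0, 3.0, amp=10.0)
        eye = 0.5 * tail
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(eye, tail, onsets, RATE)
        gains, phase = kin.spino_ocular_gain_phase(tab, eye, tail, RATE)
        assert np.allclose(gains, 0.5, rtol=1e-6)
        assert phase == pytest.approx(0.0, abs=2.0)

    def test_delay_of_one_twelfth_cycle_is_30_degrees(self):
        tail = sine(6.0, 3.0, amp=10.0)
        eye = 0.5 * sine(6.0, 3.0, amp=10.0, phase_deg=-30.0)
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(eye, tail, onsets, RATE)
        _, phase = kin.spino_ocular_gain_phase(tab, eye, tail, RATE)
        assert phase == pytest.approx(30.0, abs=3.0)

    def test_amplitude_scaling_invariance(self):
        tail = sine(6.0, 3.0, amp=10.0)
        eye = 0.4 * np.roll(tail, 5)
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab1 = kin.per_cycle_amplitudes(eye, tail, onsets, RATE)
        g1, _ = kin.spino_ocular_gain_phase(tab1, eye, tail, RATE)
        k = 3.0
        onsets2 = kin.segment_swim_cycles(k * tail, RATE)
        tab2 = kin.per_cycle_amplitudes(k * eye, k * tail, onsets2, RATE)
        g2, _ = kin.spino_ocular_gain_phase(tab2, k * eye, k * tail, RATE)
        assert np.allclose(np.mean(g1), np.mean(g2), rtol=0.02)

    def test_too_few_cycles_rejected(self):
        tail = sine(6.0, 0.5, amp=10.0)
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(tail, tail, onsets, RATE)
        with pytest.raises(ValueError):
            kin.spino_ocular_gain_phase(tab, tail, tail, RATE)


class TestSinusoidFit:
    def test_identity_response(self):
        s = sine(1.0, 6.0, amp=10.0)
        fit = kin.sinusoid_response_fit(s, s, 1.0, RATE)
        assert fit.gain == pytest.approx(1.0, rel=1e-9)
        assert fit.phase_deg == pytest.approx(0.0, abs=1e-9)

    def test_scaled_shifted_response(self):
        s = sine(1.0, 6.0, amp=10.0)
        r = sine(1.0, 6.0, amp=5.0, phase_deg=30.0)
        fit = kin.sinusoid_response_fit(r, s, 1.0, RATE)
        assert fit.gain == pytest.approx(0.5, rel=1e-6)
        assert fit.phase_deg == pytest.approx(30.0, abs=1e-6)

    def test_zero_stimulus_rejected(self):
        with pytest.raises(ValueError):
            kin.sinusoid_response_fit(sine(1.0, 6.0), np.zeros(int(6 * RATE)),
                                      1.0, RATE)

    def test_too_short_rejected(self):
        s = sine(1.0, 2.0)
        with pytest.raises(ValueError):
            kin.sinusoid_response_fit(s, s, 1.0, RATE)


class TestEccentricity:
    def _cycles(self, eye, tail):
        onsets = kin.segment_swim_cycles(tail, RATE)
        return kin.per_cycle_amplitudes(eye, tail, onsets, RATE)

    def test_centered_oscillation_flat(self):
        tail = sine(6.0, 4.0, amp=10.0)
        tab = self._cycles(tail, tail)
        slow = kin.eccentricity_trace(tail, tab, RATE)
        assert np.nanmax(np.abs(slow)) < 0.5

    def test_carrier_recovery(self):
        tail = sine(6.0, 6.0, amp=10.0)
        carrier = sine(1.0, 6.0, amp=5.0)
        eye = 0.5 * tail + carrier
        tab = self._cycles(eye, tail)
        slow = kin.eccentricity_trace(eye, tab, RATE)
        sl = slow[int(RATE):int(5 * RATE)]
        assert np.ptp(sl) == pytest.approx(10.0, rel=0.1)

    def test_linear_drift_recovered(self):
        tail = sine(6.0, 4.0, amp=10.0)
        drift = np.linspace(0, 4, tail.size)
        eye = 0.5 * tail + drift
        tab = self._cycles(eye, tail)
        slow = kin.eccentricity_trace(eye, tab, RATE)
        mid = slice(int(RATE), int(3 * RATE))
        assert np.corrcoef(slow[mid], drift[mid])[0, 1] > 0.99

    def test_decomposition_residual_small(self):
        tail = sine(6.0, 6.0, amp=10.0)
        eye = 0.5 * np.roll(tail, 10) + sine(1.0, 6.0, amp=4.0)
        tab = self._cycles(eye, tail)
        slow = kin.eccentricity_trace(eye, tab, RATE)
        fast = eye - slow
        resid = eye - (slow + fast)
        assert np.var(resid) < 0.05 * np.var(eye)


class TestModulationAndDrift:
    def test_modulation_metrics_requires_four_cycles(self):
        tail = sine(6.0, 2.0, amp=10.0)
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(tail, tail, onsets, RATE)
        slow = np.zeros(tail.size)
        with pytest.raises(ValueError, match="4"):
            kin.modulation_metrics(tab, slow, 1.0, RATE)

    def test_imposed_depths_recovered(self):
        t = np.arange(int(8 * RATE)) / RATE
        tail = 10.0 * np.sin(2 * np.pi * 6 * t)
        mag_env = 1.0 + (4.0 / (2 * 10.0)) * np.sin(2 * np.pi * 1.0 * t)
        eye = 0.5 * tail * mag_env
        onsets = kin.segment_swim_cycles(tail, RATE)
        tab = kin.per_cycle_amplitudes(eye, tail, onsets, RATE)
        slow = kin.eccentricity_trace(eye, tab, RATE)
        mod = kin.modulation_metrics(tab, slow, 1.0, RATE)
        # imposed per-cycle eye ptp range = 0.5 * 20 * (2*0.2) = 4 deg
        assert mod.delta_magnitude_deg == pytest.approx(4.0, rel=0.15)
        assert mod.delta_eccentricity_deg < 1.0

    def test_drift_screen_stationary_passes(self):
        x = sine(1.0, 10.0, amp=10.0) + sine(6.0, 10.0, amp=3.0)
        ok, slope = kin.drift_screen(x, RATE, 1.0)
        assert ok and abs(slope) < 0.05

    def test_drift_screen_ramp_fails(self):
        t = np.arange(int(10 * RATE)) / RATE
        x = sine(1.0, 10.0, amp=10.0) + (10.0 / 60.0) * t  # 10 deg/min
        ok, slope = kin.drift_screen(x, RATE, 1.0)
        assert not ok and slope > 0.1

    def test_drift_screen_deterministic(self):
        t = np.arange(int(10 * RATE)) / RATE
        x = sine(1.0, 10.0, amp=10.0) + 0.0999 * t
        assert kin.drift_screen(x, RATE, 1.0) == kin.drift_screen(x, RATE, 1.0)
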