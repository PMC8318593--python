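"""Preprocessing chain: detrending, bright-interval z-scoring, Butterworth
filtering, Wiener deconvolution and exponential-kinetics fits."""

import numpy as np
import pytest
from scipy import signal

from ribbonsyn.calcium import convolve_causal
from ribbonsyn.preprocessing import (baseline_correct_linear,
                                     denoise_butterworth, fit_exponential,
                                     fit_rise_decay, indicator_kernel,
                                     preprocess_pair, shift_nonnegative,
                                     wiener_deconvolve_indicator,
                                     zscore_to_bright)
from ribbonsyn.synth import SyntheticStudy, generate_recording
from ribbonsyn.traces import IntervalSet, Trace


class TestBaselineCorrection:
    def test_pure_line_becomes_constant(self):
        t = 0.1 * np.arange(200)
        tr = Trace(2.0 + 0.3 * t, dt=0.1)
        out = baseline_correct_linear(tr)
        assert np.ptp(out.values) < 1e-9
        assert out.values.mean() == pytest.approx(tr.values.mean())

    def test_recovers_signal_under_drift(self, rng):
        dt = 1 / 15.6
        n = 1000
        sig_true = np.sin(2 * np.pi * 0.2 * dt * np.arange(n))
        drifted = Trace(sig_true + 0.01 * dt * np.arange(n), dt=dt)
        out = baseline_correct_linear(drifted)
        r = np.corrcoef(out.values, sig_true)[0, 1]
        assert r > 0.999

    def test_idempotent_on_driftfree(self, rng):
        tr = Trace(rng.standard_normal(500), dt=0.1)
        once = baseline_correct_linear(tr)
        twice = baseline_correct_linear(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)


class TestZScore:
    def _intervals(self):
        return IntervalSet((0.0, 5.0), [(5.0, 8.0), (11.0, 14.0)],
                           [(8.0, 11.0), (14.0, 17.0)])

    def test_bright_statistics_after(self, rng):
        iv = self._intervals()
        tr = Trace(rng.normal(3.0, 2.0, 1700), dt=0.01)
        out = zscore_to_bright(tr, iv)
        m = iv.bright_mask(out)
        assert out.values[m].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.values[m].std() == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        iv = self._intervals()
        x = rng.normal(0, 1, 1700)
        out1 = zscore_to_bright(Trace(x, dt=0.01), iv)
        out2 = zscore_to_bright(Trace(3.5 * x - 2.0, dt=0.01), iv)
        assert np.allclose(out1.values, out2.values, atol=1e-9)

    def test_flat_recording_rejected(self):
        iv = self._intervals()
        with pytest.raises(ValueError):
            zscore_to_bright(Trace(np.ones(1700), dt=0.01), iv)


class TestButterworth:
    def test_low_frequency_preserved(self):
        dt = 0.01
        t = dt * np.arange(3000)
        tr = Trace(np.sin(2 * np.pi * 1.0 * t), dt=dt)
        out = denoise_butterworth(tr)
        # forward-backward order-3 Butterworth at 5 Hz: |H(1 Hz)|^2 ~ 1
        amp = np.ptp(out.values[500:2500]) / 2
        assert amp == pytest.approx(1.0, abs=0.02)

    def test_high_frequency_attenuated_per_rolloff(self):
        dt = 0.005
        t = dt * np.arange(6000)
        tr = Trace(np.sin(2 * np.pi * 10.0 * t), dt=dt)
        out = denoise_butterworth(tr)
        amp = np.ptp(out.values[1000:5000]) / 2
        # analytic squared magnitude (filtfilt): 1/(1+(f/fc)^(2n))^2
        expect = 1.0 / (1.0 + (10.0 / 5.0) ** 6)
        assert amp == pytest.approx(expect, rel=0.1)

    def test_dc_gain_unity(self):
        out = denoise_butterworth(Trace(np.full(500, 2.5), dt=0.01))
        assert np.allclose(out.values, 2.5, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            denoise_butterworth(Trace(np.zeros(100), dt=0.2), cutoff=5.0)


class TestWiener:
    def test_roundtrip_recovery_below_1hz(self, rng):
        dt = 0.01
        n = 6000
        t = dt * np.arange(n)
        truth = (np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 0.7 * t))
        kern = indicator_kernel(0.25, dt)
        obs = convolve_causal(truth, kern, pad_initial=True)
        obs = obs + 0.05 * rng.standard_normal(n)
        out = wiener_deconvolve_indicator(Trace(obs, dt=dt), kern)
        sos = signal.butter(4, 1.0, fs=1 / dt, output="sos")
        lp_out = signal.sosfiltfilt(sos, out.values)
        lp_truth = signal.sosfiltfilt(sos, truth)
        r = np.corrcoef(lp_out[500:-500], lp_truth[500:-500])[0, 1]
        assert r >= 0.9

    def test_infinite_snr_is_exact_inverse(self, rng):
        dt = 0.01
        truth = np.sin(2 * np.pi * 0.5 * dt * np.arange(4000))
        kern = indicator_kernel(0.2, dt)
        obs = convolve_causal(truth, kern, pad_initial=True)
        out = wiener_deconvolve_indicator(Trace(obs, dt=dt), kern,
                                          snr_low=np.inf, snr_high=np.inf)
        assert np.max(np.abs(out.values[200:-200] - truth[200:-200])) < 1e-6

    def test_high_frequency_noise_suppressed(self, rng):
        dt = 0.01
        noise = rng.standard_normal(4000)
        kern = indicator_kernel(0.25, dt)
        out = wiener_deconvolve_indicator(Trace(noise, dt=dt), kern)
        # above 1 Hz the filter gain is |H| / (|H|^2 + 20) <= 1/(2*sqrt(20))
        spec_in = np.abs(np.fft.rfft(noise))
        spec_out = np.abs(np.fft.rfft(out.values))
        freqs = np.fft.rfftfreq(4000, dt)
        hf = freqs > 5.0
        assert np.median(spec_out[hf] / spec_in[hf]) < 1 / (2 * np.sqrt(20))

    def test_zero_kernel_rejected(self):
        from ribbonsyn.calcium import KernelSpec
        with pytest.raises(ValueError):
            wiener_deconvolve_indicator(
                Trace(np.ones(100), dt=0.01),
                KernelSpec(np.zeros(10), 0.01, "double_exponential"))


class TestShift:
    def test_minimum_becomes_zero_and_idempotent(self, rng):
        tr = Trace(rng.normal(-2.3, 1.0, 300), dt=0.01)
        out = shift_nonnegative(tr)
        assert out.values.min() == pytest.approx(0.0, abs=1e-12)
        again = shift_nonnegative(out)
        assert np.array_equal(out.values, again.values)


class TestExpFits:
    def test_decay_recovery_with_noise(self, rng):
        dt = 0.01
        t = dt * np.arange(400)
        x = 0.5 + 2.0 * np.exp(-t / 0.8) + 0.02 * rng.standard_normal(t.size)
        fit = fit_exponential(t, x)
        assert fit.tau == pytest.approx(0.8, rel=0.1)
        assert not fit.is_rise

    def test_noiseless_exact_recovery(self):
        t = 0.01 * np.arange(300)
        x = 1.0 + 3.0 * np.exp(-t / 0.5)
        fit = fit_exponential(t, x)
        assert fit.tau == pytest.approx(0.5, rel=1e-6)
        assert fit.a == pytest.approx(3.0, rel=1e-6)

    def test_rise_decay_and_delay(self, rng):
        dt = 1 / 15.6
        n = 200
        t = dt * np.arange(n)
        x = np.zeros(n)
        rise = (t >= 3.0) & (t < 4.0)
        x[rise] = 5.0 * (1 - np.exp(-(t[rise] - 3.0) / 0.2))
        decay = t >= 4.0
        x[decay] = 5.0 * (1 - np.exp(-1 / 0.2)) * np.exp(-(t[decay] - 4.0) / 0.8)
        x += 0.05 * rng.standard_normal(n)
        tr = Trace(x, dt=dt)
        fit_r, fit_d, delay = fit_rise_decay(tr, 3.0, 4.0, 8.0)
        assert fit_r.is_rise
        assert not fit_d.is_rise
        assert fit_d.tau == pytest.approx(0.8, rel=0.25)
        assert delay == pytest.approx(3.1, abs=0.3)

    def test_delay_undefined_when_never_above_threshold(self, rng):
        # uniform noise peaks at ~1.7 sigma, never crossing 3*std
        tr = Trace(rng.uniform(-1, 1, 300), dt=0.05)
        _, _, delay = fit_rise_decay(tr, 2.0, 5.0, 10.0)
        assert delay is None


class TestFullChain:
    def test_roundtrip_recovers_ground_truth_calcium(self):
        study = SyntheticStudy(seed=5)
        rec = generate_recording(study, 0)
        ca, glu = preprocess_pair(rec.ca_fluo, rec.glu_fluo, rec.intervals)
        # compare below 1 Hz, where the deconvolution SNR profile is high
        sos = signal.butter(4, 1.0, fs=ca.fs, output="sos")
        lp_est = signal.sosfiltfilt(sos, ca.values)
        truth = rec.ca_true.resample(ca.dt).values[:len(ca)]
        lp_truth = signal.sosfiltfilt(sos, truth)
        r = np.corrcoef(lp_est[100:-100], lp_truth[100:-100])[0, 1]
        assert r >= 0.9
        assert glu.values.min() == pytest.approx(0.0, abs=1e-12)
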