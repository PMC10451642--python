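"""Signal-conditioning, segmentation and window-extraction tests."""

import numpy as np
import pytest

from pulmovib import sigproc, synth, wavelet


class TestWaveletMachinery:
    def test_filters_match_published_tables(self):
        # spectral factorization must reproduce the classic db2/db3 taps
        db2 = wavelet.daubechies_filter(2)
        ref2 = [0.4829629131445341, 0.8365163037378079,
                0.2241438680420134, -0.1294095225512604]
        np.testing.assert_allclose(db2, ref2, atol=1e-9)
        db3 = wavelet.daubechies_filter(3)
        ref3 = [0.3326705529509569, 0.8068915093133388, 0.4598775021193313,
                -0.1350110200103908, -0.0854412738822415, 0.0352262918821007]
        np.testing.assert_allclose(db3, ref3, atol=1e-9)

    @pytest.mark.parametrize("n", [512, 1030, 2061])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.normal(size=n)
        h = wavelet.daubechies_filter(6)
        a, d, pads = wavelet.wavedec(x, h, 5)
        xr = wavelet.waverec(a, d, pads, h)
        # odd-length levels pad one boundary sample; interior is exact
        assert np.abs(x[:-1] - xr[:-1]).max() < 1e-10

    def test_orthonormality(self):
        h = wavelet.daubechies_filter(6)
        assert np.sum(h ** 2) == pytest.approx(1.0, abs=1e-12)
        for k in range(2, len(h), 2):
            assert np.dot(h[:-k], h[k:]) == pytest.approx(0.0, abs=1e-12)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(4000, 3.7)
        y = sigproc.lowpass_pressure(x, 2000.0)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_stopband_attenuation(self):
        fs = 2000.0
        t = np.arange(0, 4.0, 1 / fs)
        slow = np.sin(2 * np.pi * 1.0 * t)
        fast = np.sin(2 * np.pi * 200.0 * t)
        y = sigproc.lowpass_pressure(slow + fast, fs)
        spec = np.abs(np.fft.rfft(y))
        f = np.fft.rfftfreq(len(t), 1 / fs)
        amp_slow = spec[np.argmin(np.abs(f - 1.0))]
        amp_fast = spec[np.argmin(np.abs(f - 200.0))]
        assert 20 * np.log10(amp_slow / max(amp_fast, 1e-12)) > 40.0

    def test_zero_phase(self):
        fs = 2000.0
        t = np.arange(0, 2.0, 1 / fs)
        pulse = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        y = sigproc.lowpass_pressure(pulse, fs)
        assert abs(np.argmax(y) - np.argmax(pulse)) <= 1

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            sigproc.lowpass_pressure(np.zeros(100), 100.0, cutoff=60.0)


class TestDenoise:
    def test_zero_in_zero_out(self):
        y = sigproc.denoise_vibration(np.zeros(1024))
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_snr_improves(self, rng):
        fs = 2000.0
        t = np.arange(0, 1.0, 1 / fs)
        clean = np.zeros_like(t)
        burst = np.exp(-60 * t[:300]) * np.sin(2 * np.pi * 70 * t[:300])
        clean[400:700] = burst
        sig_pow = np.mean(clean ** 2)
        noise = rng.normal(0, np.sqrt(sig_pow / 10), len(t))  # 10 dB SNR
        y = sigproc.denoise_vibration(clean + noise)
        snr_in = sig_pow / np.mean(noise ** 2)
        snr_out = sig_pow / np.mean((y - clean) ** 2)
        assert 10 * np.log10(snr_out / snr_in) >= 3.0

    def test_clean_burst_survives(self):
        fs = 2000.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.zeros_like(t)
        x[200:500] = np.exp(-60 * t[:300]) * np.sin(2 * np.pi * 80 * t[:300])
        y = sigproc.denoise_vibration(x)
        r = np.corrcoef(x, y)[0, 1]
        assert r >= 0.99

    def test_energy_never_increases(self, rng):
        x = rng.normal(size=2048)
        y = sigproc.denoise_vibration(x)
        assert np.sum(y ** 2) <= np.sum(x ** 2) * (1 + 1e-9)

    def test_idempotent(self, rng):
        fs = 2000.0
        t = np.arange(0, 2.0, 1 / fs)
        x = np.zeros_like(t)
        x[500:800] = np.exp(-60 * t[:300]) * np.sin(2 * np.pi * 60 * t[:300])
        x = x + rng.normal(0, 0.02, len(t))
        y1 = sigproc.denoise_vibration(x)
        y2 = sigproc.denoise_vibration(y1)
        e1, e2 = np.sum(y1 ** 2), np.sum(y2 ** 2)
        assert abs(e2 - e1) / e1 < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sigproc.denoise_vibration(np.zeros(16))


class TestEdges:
    def test_noisy_servo_same_edges(self, rng):
        cfg = synth.MCLConfig()
        servo = synth.generate_servo(10.0, cfg)
        clean_r, clean_f = sigproc.detect_edges(servo, cfg.fs)
        noisy = servo + rng.normal(0, 0.05, len(servo))
        r, f = sigproc.detect_edges(noisy, cfg.fs)
        assert len(r) == len(clean_r) and len(f) == len(clean_f)
        assert np.max(np.abs(r - clean_r)) <= 2 / cfg.fs

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            sigproc.detect_edges(np.ones(1000), 2000.0)


class TestCycleParams:
    def test_triangular_peak_recovered(self):
        fs = 2000.0
        cycle = np.concatenate([
            np.linspace(0, 30.0, 400), np.linspace(30.0, 0, 600),
            np.zeros(1000),
        ])
        p = np.tile(cycle, 4)
        servo = np.tile(np.r_[np.ones(800), np.zeros(1200)], 4)
        segs = sigproc.per_cycle_pressure_params(
            p, sigproc.detect_edges(servo, fs), fs
        )
        for s in segs:
            assert s.pasp == pytest.approx(30.0, abs=0.1)

    def test_ramp_slope_recovered(self):
        # build the cycle by integrating a trapezoidal slope profile whose
        # plateau is exactly 100 mmHg/s = 0.1 mmHg/ms (smooth corners keep
        # the derivative estimator's local fits valid)
        fs = 2000.0
        taper = 0.5 * (1 - np.cos(np.linspace(0, np.pi, 150)))
        slope = np.concatenate([
            100.0 * taper, np.full(400, 100.0),
            100.0 * taper[::-1], np.zeros(100),
        ])
        rise = np.cumsum(slope) / fs
        cycle = np.concatenate([rise, np.linspace(rise[-1], 0.0, 1200)])
        p = np.tile(cycle, 4)
        servo = np.tile(np.r_[np.ones(900), np.zeros(1100)], 4)
        segs = sigproc.per_cycle_pressure_params(
            p, sigproc.detect_edges(servo, fs), fs
        )
        for s in segs[1:]:
            assert s.mrr == pytest.approx(0.1, rel=0.01)

    def test_tracks_generator_schedule(self, continuous_tables):
        from scipy.stats import spearmanr
        tab = continuous_tables[0]
        sched = np.r_[np.linspace(0, 1, len(tab) // 2),
                      np.linspace(1, 0, len(tab) - len(tab) // 2)]
        rho = spearmanr(tab["PASP"], sched).statistic
        assert abs(rho) > 0.95

    def test_segmentation_completeness(self, single_recording, single_segmented):
        rec, segs = single_segmented
        assert len(segs) >= rec.meta["n_cycles"] - 2


class TestWindowExtraction:
    def _burst(self, fs=2000.0, lam=60.0, f0=70.0, i0=300, n=2000):
        x = np.zeros(n)
        t = np.arange(n - i0) / fs
        x[i0:] = np.exp(-lam * t) * np.sin(2 * np.pi * f0 * t)
        return x

    def test_covers_analytic_support(self):
        fs = 2000.0
        lam = 60.0
        x = self._burst(fs, lam)
        w = sigproc.extract_valve_sound(x, (0.0, 1.0), fs)
        t98 = np.log(50.0) / (2 * lam)  # analytic 98% energy time
        assert (w.end_t - w.start_t) == pytest.approx(t98, abs=2 / fs + 3e-3)
        assert w.energy_fraction >= 0.98

    def test_symmetric_burst_symmetric_window(self):
        fs = 2000.0
        n = 1000
        x = np.zeros(n)
        t = (np.arange(n) - 500) / fs
        x += np.exp(-0.5 * (t / 0.02) ** 2)  # even around sample 500
        w = sigproc.extract_valve_sound(x, (0.0, 0.5), fs)
        left = w.center_t - w.start_t
        right = w.end_t - w.center_t
        assert abs(left - right) <= 2 / fs

    def test_silent_window_flagged(self):
        w = sigproc.extract_valve_sound(np.zeros(4000), (0.0, 1.0), 2000.0)
        assert w.missing

    def test_never_crosses_servo_edge(self):
        # mis-specified search window spanning two cycles: growth must stop
        # at the servo-edge clip bound and raise the flag
        fs = 2000.0
        x = self._burst(fs, lam=5.0, i0=100, n=2000)
        x += self._burst(fs, lam=5.0, i0=1200, n=2000) * 0.9  # next cycle
        edge_t = 0.5  # servo edge between the two bursts
        w = sigproc.extract_valve_sound(
            x, (0.0, 1.0), fs, clip_at=(0.0, edge_t)
        )
        assert w.end_t <= edge_t
        assert w.clipped

    def test_energy_containment_on_generated_bursts(self, single_recording,
                                                    single_segmented):
        rec, segs = single_segmented
        snd = sigproc.denoise_vibration(rec.snd_pulmonary)
        for seg in segs[:40]:
            w = sigproc.extract_valve_sound(
                snd, sigproc.pulmonary_search_window(seg), rec.fs
            )
            assert 0.98 <= w.energy_fraction <= 1.0
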