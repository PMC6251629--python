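"""Multitaper PSD, spectral smoothing, peak band power, spectrogram."""

import numpy as np
import pytest

from lfpkit.conditioning import BANDS
from lfpkit.spectral import (
    multitaper_psd,
    peak_band_power,
    smooth_spectrum,
    spectrogram,
)

FS = 1000.0


class TestMultitaperPsd:
    def test_white_noise_integral_matches_variance_and_is_flat(self, rng):
        x = rng.standard_normal(int(120 * FS))
        spec = multitaper_psd(x, rate=FS)
        assert spec.integral() == pytest.approx(x.var(), rel=0.05)
        sm = smooth_spectrum(spec, 1.0)
        m = (sm.freqs_hz >= 5) & (sm.freqs_hz <= 100)
        assert sm.power[m].max() / sm.power[m].min() < 2.0

    def test_agrees_with_plain_periodogram_on_white_noise(self, rng):
        # independent oracle: averaged boxcar periodogram over the same windows
        x = rng.standard_normal(int(60 * FS))
        spec = multitaper_psd(x, rate=FS, overlap=0.0)
        nwin = 2000
        segs = x[: (x.size // nwin) * nwin].reshape(-1, nwin)
        pxx = (np.abs(np.fft.rfft(segs, axis=1)) ** 2).mean(axis=0) / (FS * nwin)
        pxx[1:-1] *= 2
        m = (spec.freqs_hz > 2) & (spec.freqs_hz < 480)
        ratio = spec.power[m] / pxx[m]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("amp", [1.0, 2.0])
    def test_sinusoid_band_power_recovers_amplitude(self, amp):
        t = np.arange(int(120 * FS)) / FS
        spec = multitaper_psd(amp * np.sin(2 * np.pi * 40.0 * t), rate=FS)
        assert spec.integral(35.0, 45.0) == pytest.approx(amp ** 2 / 2, rel=0.10)
        assert peak_band_power(spec, BANDS["low_gamma"]).peak_freq_hz == \
            pytest.approx(40.0, abs=1.5)  # taper bandwidth W = NW/T

    def test_zero_signal_gives_zero_spectrum(self):
        spec = multitaper_psd(np.zeros(int(10 * FS)), rate=FS)
        assert np.allclose(spec.power, 0.0)

    def test_short_bouts_are_analyzed_whole(self):
        pieces = [np.sin(2 * np.pi * 40 * np.arange(1500) / FS)]
        spec = multitaper_psd(pieces, rate=FS)
        assert spec.n_windows == 1
        assert peak_band_power(spec, BANDS["low_gamma"]).peak_freq_hz == \
            pytest.approx(40.0, abs=2.5)

    def test_all_bouts_too_short_raises(self):
        with pytest.raises(ValueError, match="no segment"):
            multitaper_psd([np.zeros(400)], rate=FS)

    def test_doubling_amplitude_quadruples_band_power(self, rng):
        import lfpkit as lk

        base = lk.SimulationParams(duration_s=60.0, run_to_rest_hz=0.0,
                                   pink_noise_sd=0.0, theta_amp_run=0.0,
                                   highgamma_amp=0.0, line_noise_amp=0.0,
                                   ripple_amp_sd=0.0)
        powers = []
        for amp in (0.3, 0.6):
            sess = lk.simulate_session(
                lk.SimulationParams(**{**base.__dict__, "lowgamma_amp": amp}),
                seed=3)
            spec = multitaper_psd(sess.hpc.samples, rate=FS)
            powers.append(spec.integral(30.0, 60.0))
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.10)


class TestSmoothSpectrum:
    def test_constant_spectrum_unchanged(self, rng):
        spec = multitaper_psd(rng.standard_normal(int(30 * FS)), rate=FS)
        spec.power[:] = 0.7
        assert np.allclose(smooth_spectrum(spec, 2.0).power, 0.7)

    def test_interior_peak_widened_area_preserved(self, rng):
        spec = multitaper_psd(rng.standard_normal(int(30 * FS)), rate=FS)
        spec.power[:] = 0.0
        spec.power[200] = 10.0
        sm = smooth_spectrum(spec, 3.0)
        assert sm.power[200] < 10.0
        assert sm.power.sum() == pytest.approx(10.0, rel=0.01)

    def test_double_box_smoothing_equals_triangular_kernel(self, rng):
        # box * box = triangle: convolution oracle on the interior
        spec = multitaper_psd(rng.standard_normal(int(30 * FS)), rate=FS)
        nb = 5  # 2.5 Hz at 0.5 Hz resolution -> odd centered kernel
        twice = smooth_spectrum(smooth_spectrum(spec, 2.5), 2.5).power
        tri = np.convolve(np.ones(nb) / nb, np.ones(nb) / nb)
        oracle = np.convolve(spec.power, tri, mode="same")
        core = slice(3 * nb, spec.power.size - 3 * nb)
        assert np.allclose(twice[core], oracle[core], rtol=1e-9)


class TestPeakBandPower:
    def test_single_peak_found(self, rng):
        t = np.arange(int(30 * FS)) / FS
        spec = multitaper_psd(np.sin(2 * np.pi * 42.0 * t)
                              + 0.01 * rng.standard_normal(t.size), rate=FS)
        pk = peak_band_power(spec, BANDS["low_gamma"])
        assert pk.peak_freq_hz == pytest.approx(42.0, abs=1.5)

    def test_monotone_spectrum_peaks_at_band_edge(self, rng):
        spec = multitaper_psd(rng.standard_normal(int(10 * FS)), rate=FS)
        spec.power[:] = 1.0 / (1.0 + spec.freqs_hz)
        assert peak_band_power(spec, BANDS["low_gamma"]).peak_freq_hz == 30.0

    def test_matches_bruteforce_scan(self, rng):
        spec = multitaper_psd(rng.standard_normal(int(10 * FS)), rate=FS)
        spec.power[:] = rng.random(spec.power.size)
        pk = peak_band_power(spec, BANDS["high_gamma"])
        m = (spec.freqs_hz >= 65) & (spec.freqs_hz <= 100)
        assert pk.peak_power == spec.power[m].max()

    def test_band_outside_grid_errors(self, rng):
        spec = multitaper_psd(rng.standard_normal(2000), rate=100.0)
        with pytest.raises(ValueError):
            peak_band_power(spec, BANDS["ripple"])


class TestSpectrogram:
    def test_zero_signal_gives_zero_matrix(self):
        _, _, p = spectrogram(np.zeros(int(10 * FS)), FS)
        assert np.allclose(p, 0.0)

    def test_column_count(self):
        times, _, p = spectrogram(np.zeros(int(10 * FS)), FS,
                                  window_s=2.0, step_s=0.5)
        expected = (10000 - 2000) // 500 + 1
        assert p.shape[1] == expected == times.size

    def test_chirp_ridge_follows_instantaneous_frequency(self):
        from scipy.signal import chirp

        t = np.arange(int(60 * FS)) / FS
        x = chirp(t, f0=20.0, f1=80.0, t1=60.0)
        times, freqs, p = spectrogram(x, FS, window_s=2.0, step_s=2.0)
        ridge = freqs[np.argmax(p, axis=0)]
        f_inst = 20.0 + (80.0 - 20.0) * times / 60.0
        assert np.all(np.abs(ridge - f_inst) <= 2.0)

    def test_step_longer_than_window_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(5000), FS, window_s=1.0, step_s=2.0)
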