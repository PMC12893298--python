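"""Welch PSD, band powers, 1/f exponent fit and noise-increase factors."""
import numpy as np
import pytest

from poretrap import (Band, NIFSet, NoiseSpec, PSDEstimate,
                      SpectralUnavailableError, band_power, compute_nif,
                      fit_one_over_f, synth_colored_noise, welch_psd)


def _white(n, fs, sd=1.0, seed=0):
    return np.random.default_rng(seed).standard_normal(n) * sd


class TestWelch:
    def test_zero_signal_zero_psd(self):
        psd = welch_psd(np.zeros(8000), 1000.0)
        assert np.all(psd.s[psd.freqs > 0] == 0)

    def test_white_noise_level(self):
        """One-sided white PSD is 2 sigma^2 / fs."""
        fs = 20_000.0
        psd = welch_psd(_white(int(20 * fs), fs), fs)
        level = psd.s[(psd.freqs > 100) & (psd.freqs < fs / 2 - 100)].mean()
        assert level == pytest.approx(2.0 / fs, rel=0.10)

    def test_tone_band_power(self):
        """Band power around a pure tone of amplitude A equals A^2/2."""
        fs, f0, amp = 20_000.0, 1000.0, 0.3
        t = np.arange(int(10 * fs)) / fs
        psd = welch_psd(amp * np.sin(2 * np.pi * f0 * t), fs)
        p = band_power(psd, Band(f0 - 50, f0 + 50))
        assert p == pytest.approx(amp ** 2 / 2, rel=0.05)

    @pytest.mark.parametrize("alpha", [0.0, 0.5])
    def test_parseval(self, alpha):
        fs, n = 20_000.0, int(16 * 20_000)
        x = synth_colored_noise(n, fs, NoiseSpec(white_sd=0.5,
                                                 flicker_alpha=alpha,
                                                 flicker_amp=1e-4), seed=3)
        psd = welch_psd(x, fs)
        assert psd.parseval_ratio() == pytest.approx(1.0, abs=0.05)

    def test_short_segment_flagged(self):
        with pytest.raises(SpectralUnavailableError):
            welch_psd(np.ones(500), 1000.0, window_len=1000)


class TestBandPower:
    def test_flat_psd_rectangle(self):
        f = np.linspace(0, 500, 2001)
        psd = PSDEstimate(f, np.full_like(f, 3.0), 1000.0, 1000, 0.5, 1)
        assert band_power(psd, Band(10, 110)) == pytest.approx(300.0,
                                                               rel=1e-9)

    def test_band_additivity(self):
        fs = 25_000.0
        psd = welch_psd(_white(int(8 * fs), fs, seed=1), fs)
        parts = (band_power(psd, Band(1, 100)) +
                 band_power(psd, Band(100, 1000)) +
                 band_power(psd, Band(1000, 10_000)))
        assert parts == pytest.approx(band_power(psd, Band(1, 10_000)),
                                      rel=1e-9)

    def test_white_noise_band_integral(self):
        fs = 200_000.0
        psd = welch_psd(_white(int(4 * fs), fs, seed=2), fs,
                        window_len=int(fs / 4))
        expected = (2.0 / fs) * 9000.0
        assert band_power(psd, Band(1000, 10_000)) == pytest.approx(
            expected, rel=0.10)

    def test_band_above_nyquist_rejected(self):
        psd = welch_psd(_white(8000, 1000.0), 1000.0)
        with pytest.raises(ValueError):
            band_power(psd, Band(400, 600))


class TestOneOverF:
    def test_exact_synthetic_spectrum(self):
        """Noiseless s = A/f recovers alpha = 1 to 0.01."""
        f = np.arange(0.0, 201.0)
        s = np.zeros_like(f)
        s[1:] = 2e-3 / f[1:]
        psd = PSDEstimate(f, s, 400.0, 400, 0.5, 1)
        fit = fit_one_over_f(psd, Band(1, 100))
        assert fit.alpha == pytest.approx(1.0, abs=0.01)
        assert fit.amplitude_a == pytest.approx(2e-3, rel=0.05)
        assert fit.fit_ok

    def test_exponent_recovery_from_synthesis(self):
        """Seeded 1/f^1.5 noise fits back to alpha = 1.5 +- 0.1 on the
        ensemble-averaged PSD."""
        fs, dur = 2000.0, 10.0
        psds = []
        for seed in range(10):
            x = synth_colored_noise(int(fs * dur), fs,
                                    NoiseSpec(white_sd=1e-3,
                                              flicker_alpha=1.5,
                                              flicker_amp=1e-3), seed=seed)
            psds.append(welch_psd(x, fs).s)
        mean_psd = PSDEstimate(welch_psd(x, fs).freqs, np.mean(psds, axis=0),
                               fs, int(fs), 0.5, 10)
        fit = fit_one_over_f(mean_psd, Band(1, 100))
        assert fit.alpha == pytest.approx(1.5, abs=0.1)

    def test_pure_white_noise_flagged_not_ok(self):
        fs = 2000.0
        psd = welch_psd(_white(int(30 * fs), fs, sd=0.5, seed=5), fs)
        fit = fit_one_over_f(psd, Band(1, 100))
        assert not fit.fit_ok
        assert fit.c == pytest.approx(2 * 0.25 / fs, rel=0.15)

    def test_too_few_bins_rejected(self):
        f = np.arange(0.0, 6.0)
        psd = PSDEstimate(f, np.ones_like(f), 10.0, 10, 0.5, 1)
        with pytest.raises(SpectralUnavailableError):
            fit_one_over_f(psd, Band(1, 5))


class TestNIF:
    def test_identity_on_same_segment(self):
        fs = 25_000.0
        psd = welch_psd(_white(int(4 * fs), fs, seed=6), fs)
        nifs = compute_nif(psd, psd)
        assert nifs.as_tuple() == pytest.approx((1.0, 1.0, 1.0), abs=1e-9)

    def test_scale_invariance(self):
        fs = 25_000.0
        x = _white(int(4 * fs), fs, seed=7)
        y = _white(int(4 * fs), fs, seed=8)
        a = compute_nif(welch_psd(2.0 * y, fs), welch_psd(2.0 * x, fs))
        b = compute_nif(welch_psd(y, fs), welch_psd(x, fs))
        np.testing.assert_allclose(a.as_tuple(), b.as_tuple(), rtol=1e-9)

    def test_added_independent_equal_power_doubles_band(self):
        """gated = open-statistics noise + an independent equal-variance
        white process gives NIF ~ 2 where white noise dominates."""
        fs = 25_000.0
        x = _white(int(6 * fs), fs, seed=9)
        y = x + _white(int(6 * fs), fs, seed=10)
        nifs = compute_nif(welch_psd(y, fs), welch_psd(x, fs))
        assert nifs.nif_mid == pytest.approx(2.0, rel=0.15)
        assert nifs.nif_high == pytest.approx(2.0, rel=0.15)

    def test_zero_open_power_rejected(self):
        fs = 25_000.0
        silent = welch_psd(np.zeros(int(4 * fs)), fs)
        noisy = welch_psd(_white(int(4 * fs), fs, seed=11), fs)
        with pytest.raises(ValueError, match="open"):
            compute_nif(noisy, silent)
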