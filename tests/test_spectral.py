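import numpy as np
import pytest

from cortexdyn import (
    AperiodicFit,
    PeakFit,
    PowerSpectrum,
    extract_alpha,
    fit_spectral_model,
    interpolate_line_noise,
    summarize_spectrum,
    welch_psd,
)
from cortexdyn.spectral import mean_reference_spectrum, n_welch_epochs

from conftest import freq_grid


class TestWelchPsd:
    def test_single_tone_peak(self):
        fs = 200.0
        t = np.arange(0, 60.0, 1 / fs)
        spec = welch_psd(np.sin(2 * np.pi * 10.0 * t), fs)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(10.0)

    def test_epoch_count_formula(self):
        # floor((300 - 10)/5) + 1 = 59
        assert n_welch_epochs(300 * 100, 100.0) == 59

    def test_grid_resolution(self):
        spec = welch_psd(np.random.default_rng(0).standard_normal(3000), 100.0)
        np.testing.assert_allclose(np.diff(spec.freqs), 0.1, atol=1e-9)

    def test_white_noise_flat(self):
        x = np.random.default_rng(1).standard_normal(300 * 200)
        spec = welch_psd(x, 200.0)
        m = spec.band(1, 65)
        slope = np.polyfit(np.log10(spec.freqs[m]), np.log10(spec.power[m]), 1)[0]
        assert abs(slope) < 0.1

    def test_amplitude_mode_halves_exponent(self):
        rng = np.random.default_rng(2)
        # brown noise: power slope -2, amplitude slope -1
        x = np.cumsum(rng.standard_normal(200 * 100))
        sp_p = welch_psd(x, 100.0, mode="power")
        sp_a = welch_psd(x, 100.0, mode="amplitude")
        m = sp_p.band(1, 30)
        sl_p = np.polyfit(np.log10(sp_p.freqs[m]), np.log10(sp_p.power[m]), 1)[0]
        sl_a = np.polyfit(np.log10(sp_a.freqs[m]), np.log10(sp_a.power[m]), 1)[0]
        assert sl_a == pytest.approx(sl_p / 2, abs=0.1)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="1000"):
            welch_psd(np.zeros(999), 100.0)


class TestInterpolateLineNoise:
    def test_idempotent_on_linear(self):
        f = freq_grid(40.0, 60.0)
        power = 2.0 + 0.1 * f
        out = interpolate_line_noise(PowerSpectrum(f, power), line_freqs=(50.0,))
        np.testing.assert_allclose(out.power, power, atol=1e-12)

    def test_spike_removed(self):
        f = freq_grid(40.0, 60.0)
        power = np.ones_like(f)
        power[np.argmin(np.abs(f - 50.0))] = 10.0
        out = interpolate_line_noise(PowerSpectrum(f, power), line_freqs=(50.0,))
        assert out.power[np.argmin(np.abs(f - 50.0))] == pytest.approx(1.0)

    def test_outside_band_bit_identical(self):
        f = freq_grid(40.0, 60.0)
        rng = np.random.default_rng(3)
        power = rng.uniform(0.5, 2.0, len(f))
        out = interpolate_line_noise(PowerSpectrum(f, power), line_freqs=(50.0,))
        outside = np.abs(f - 50.0) > 2.0 + 1e-9
        np.testing.assert_array_equal(out.power[outside], power[outside])
        assert not np.allclose(out.power[~outside], power[~outside])

    def test_unsupported_band_raises(self):
        f = freq_grid(49.0, 60.0)
        with pytest.raises(ValueError):
            interpolate_line_noise(PowerSpectrum(f, np.ones_like(f)),
                                   line_freqs=(50.0,))

    def test_repeat_application_idempotent(self):
        f = freq_grid(40.0, 160.0)
        rng = np.random.default_rng(4)
        power = rng.uniform(0.5, 2.0, len(f))
        once = interpolate_line_noise(PowerSpectrum(f, power))
        twice = interpolate_line_noise(once)
        np.testing.assert_allclose(twice.power, once.power, atol=1e-12)


class TestFitSpectralModel:
    def test_pure_powerlaw(self):
        f = freq_grid()
        ap, peaks = fit_spectral_model(PowerSpectrum(f, 1.0 / f**2))
        assert ap.exponent == pytest.approx(2.0, abs=0.05)
        assert peaks == []

    def test_knee_plus_peak_recovery(self):
        f = freq_grid()
        rng = np.random.default_rng(5)
        logp = (1.0 - np.log10(100.0 + f**2)
                + 0.5 * np.exp(-0.5 * ((f - 10.0) / 1.5) ** 2)
                + rng.normal(0, 0.01, len(f)))
        ap, peaks = fit_spectral_model(PowerSpectrum(f, 10.0**logp))
        assert ap.mode == "with_knee"
        assert ap.exponent == pytest.approx(2.0, abs=0.1)
        alpha = [p for p in peaks if 7 <= p.center_frequency <= 13]
        assert len(alpha) == 1
        assert alpha[0].center_frequency == pytest.approx(10.0, abs=0.2)

    def test_near_powerlaw_falls_back_to_fixed(self):
        # k ~ 0: the knee fit returns a non-positive knee -> mode fixed
        f = freq_grid()
        ap, _ = fit_spectral_model(PowerSpectrum(f, 10.0 / f**1.5))
        assert ap.mode == "fixed"
        assert np.isnan(ap.knee_frequency)

    def test_nonpositive_power_raises(self):
        f = freq_grid()
        p = 1.0 / f
        p[100] = 0.0
        with pytest.raises(ValueError):
            fit_spectral_model(PowerSpectrum(f, p))

    def test_alpha_power_positive_when_returned(self):
        f = freq_grid()
        logp = -np.log10(50.0 + f**2) + 0.4 * np.exp(-0.5 * ((f - 9.0) / 1.0) ** 2)
        _, peaks = fit_spectral_model(PowerSpectrum(f, 10.0**logp))
        assert all(p.peak_power > 0 for p in peaks)


class TestExtractAlpha:
    @staticmethod
    def _ref_psd(center=10.0, sd=1.0, height=0.6):
        f = freq_grid()
        logp = -np.log10(30.0 + f**2) + height * np.exp(
            -0.5 * ((f - center) / sd) ** 2)
        return PowerSpectrum(f, 10.0**logp)

    def test_highest_power_wins(self):
        peaks = [[PeakFit(9.0, 0.3, 2.0), PeakFit(10.5, 0.5, 2.0)]]
        out = extract_alpha(peaks, self._ref_psd())
        assert out[0, 0] == pytest.approx(10.5)
        assert out[0, 1] == pytest.approx(0.5)

    def test_missing_propagated(self):
        peaks = [[], [PeakFit(25.0, 0.9, 3.0)]]  # none in any alpha window
        out = extract_alpha(peaks, self._ref_psd())
        assert np.isnan(out).all()

    def test_window_membership(self):
        # reference peak at 10 Hz with bandwidth 2 -> window
        # center +/- (bw/2 + 2) = [7, 13]: 11.5 in, 13.5 out
        ref = self._ref_psd(center=10.0, sd=1.0)  # fitted bandwidth ~2 Hz
        inside = extract_alpha([[PeakFit(11.5, 0.4, 2.0)]], ref)
        outside = extract_alpha(
            [[PeakFit(13.5, 0.4, 2.0), PeakFit(20.0, 0.6, 2.0)]], ref)
        assert inside[0, 0] == pytest.approx(11.5)
        assert np.isnan(outside[0, 0])  # 13.5 out of window, 20 Hz not alpha

    def test_fallback_to_traditional_range(self):
        # reference without an alpha peak: highest-power peak in 7-13 Hz
        f = freq_grid()
        flat_ref = PowerSpectrum(f, 1.0 / f**2)
        peaks = [[PeakFit(8.0, 0.2, 2.0), PeakFit(12.0, 0.7, 2.0)]]
        out = extract_alpha(peaks, flat_ref)
        assert out[0, 0] == pytest.approx(12.0)

    def test_empty_reference_set_raises(self):
        with pytest.raises(ValueError):
            mean_reference_spectrum([])


class TestSummarize:
    def test_constant_power_auc(self):
        # chi -> 0 makes the model constant at c = 10^b over [1, 65]:
        # the 641-bin sum must be 641 c
        ap = AperiodicFit(offset=np.log10(3.0), knee=0.0, exponent=1e-9,
                          mode="fixed")
        assert summarize_spectrum(ap).auc == pytest.approx(641 * 3.0, rel=1e-6)

    def test_auc_equals_grid_sum_of_model(self):
        ap = AperiodicFit(offset=0.5, knee=50.0, exponent=1.7, mode="with_knee")
        f = 1.0 + 0.1 * np.arange(641)
        expected = np.sum(10.0**0.5 / (50.0 + f**1.7))
        assert summarize_spectrum(ap).auc == pytest.approx(expected, rel=1e-12)

    def test_knee_frequency_conversion(self):
        ap = AperiodicFit(offset=0.0, knee=100.0, exponent=2.0, mode="with_knee")
        assert ap.knee_frequency == pytest.approx(10.0)
        assert summarize_spectrum(ap).knee_frequency == pytest.approx(10.0)

    def test_fixed_mode_missing_knee(self):
        ap = AperiodicFit(offset=0.0, knee=0.0, exponent=2.0, mode="fixed")
        assert np.isnan(summarize_spectrum(ap).knee_frequency)


class TestParameterRecoveryProperty:
    def test_median_errors_small_sample(self):
        # light version of the acceptance criterion (20 spectra)
        rng = np.random.default_rng(10)
        f = freq_grid()
        chi_err, alpha_err = [], []
        for _ in range(20):
            chi = rng.uniform(1.0, 3.0)
            k = rng.uniform(10.0, 400.0)
            height = rng.uniform(0.25, 0.9)
            center = rng.uniform(8.0, 12.0)
            logp = (rng.uniform(-1, 1) - np.log10(k + f**chi)
                    + height * np.exp(-0.5 * ((f - center) / 1.2) ** 2)
                    + rng.normal(0, 0.02, len(f)))
            ap, peaks = fit_spectral_model(PowerSpectrum(f, 10.0**logp))
            chi_err.append(abs(ap.exponent - chi))
            alpha = [p for p in peaks if 7 <= p.center_frequency <= 13]
            alpha_err.append(
                min(abs(p.center_frequency - center) for p in alpha)
                if alpha else np.inf)
        assert np.median(chi_err) <= 0.1
        assert np.median(alpha_err) <= 0.2
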