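import math

import numpy as np
import pytest

from tremorkit import SimConfig, simulate_tremor
from tremorkit.preprocess import run_preprocess
from tremorkit.spectral import (
    AXES,
    BAND_GRID,
    Spectra,
    SpectralConfig,
    analyze_test,
    band_avg_amplitude,
    compute_spectra,
    dominant_frequency,
    energy_band,
    summarize,
    tone_amplitude,
    total_energy,
)

from conftest import make_tone_series, series_from_arrays

FS = 55.56


def brute_force_peak(series, axis, band=(1.0, 12.0), step=0.0005):
    """Oracle: exhaustive windowed-DTFT magnitude scan over a fine grid."""
    v = getattr(series, axis)
    v = v - v.mean()
    n = len(v)
    w = np.hanning(n)
    t = np.arange(n) / series.nominal_rate_hz
    grid = np.arange(band[0], band[1] + step, step)
    mags = np.abs(np.exp(-2j * np.pi * grid[:, None] * t[None, :]) @ (w * v))
    return float(grid[int(np.argmax(mags))])


def preprocessed_tone(f0, amplitude=1.0, noise=0.0, seed=0, weights=(0.0, 0.0, 1.0)):
    s = make_tone_series(f0, amplitude, noise_sigma=noise, seed=seed,
                         tremor_axis_weights=weights)
    return run_preprocess(s)


class TestComputeSpectra:
    def test_zero_signal_zero_spectra(self):
        s = series_from_arrays(*(np.zeros((3, 400))))
        spectra = compute_spectra(s, min_duration_s=1.0)
        assert np.all(spectra.amplitude == 0)
        assert np.all(spectra.psd == 0)

    def test_tone_peak_amplitude_near_A(self):
        s = preprocessed_tone(5.0)
        spectra = compute_spectra(s)
        k = int(np.argmax(spectra.amplitude[2]))
        assert spectra.freqs[k] == pytest.approx(5.0, abs=2 * spectra.df)
        assert spectra.amplitude[2, k] == pytest.approx(1.0, rel=0.01)

    def test_parseval_identity_noise(self):
        from scipy.signal import get_window

        rng = np.random.default_rng(5)
        s = series_from_arrays(*rng.normal(size=(3, 2000)))
        spectra = compute_spectra(s)
        w = get_window("hann", 2000, fftbins=True)
        # windowed mean-square power, normalized by the window's power
        for ai, axis in enumerate(AXES):
            v = getattr(s, axis)
            lhs = float(spectra.psd[ai].sum() * spectra.df)
            rhs = float(((w * v) ** 2).sum() / (w**2).sum())
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_unresolved_gaps_rejected(self):
        s = series_from_arrays(*(np.zeros((3, 400))))
        s = s.replace(gap_mask=np.arange(400) == 3)
        with pytest.raises(ValueError, match="unresolved gaps"):
            compute_spectra(s, min_duration_s=1.0)

    def test_too_short_rejected(self):
        s = series_from_arrays(*(np.zeros((3, 50))))
        with pytest.raises(ValueError, match="at least"):
            compute_spectra(s)


class TestDominantFrequency:
    def test_tone_on_z_vs_brute_force_oracle(self):
        s = preprocessed_tone(4.35)
        spectra = compute_spectra(s)
        freqs, axis = dominant_frequency(spectra)
        assert axis == "z"
        oracle = brute_force_peak(s, "z")
        assert freqs["z"] == pytest.approx(oracle, abs=0.005)
        assert freqs["z"] == pytest.approx(4.35, abs=0.01)

    def test_two_tones_axis_selection(self):
        n = int(60 * FS)
        t = np.arange(n) / FS
        x = 1.0 * np.sin(2 * np.pi * 4.0 * t)
        y = 0.3 * np.sin(2 * np.pi * 8.0 * t)
        s = series_from_arrays(x, y, np.zeros(n))
        spectra = compute_spectra(s)
        freqs, axis = dominant_frequency(spectra)
        assert axis == "x"
        assert freqs["x"] == pytest.approx(4.0, abs=0.01)
        assert freqs["y"] == pytest.approx(8.0, abs=0.01)

    def test_white_noise_undefined(self):
        rng = np.random.default_rng(17)
        s = series_from_arrays(*rng.normal(0, 0.05, size=(3, int(60 * FS))))
        spectra = compute_spectra(s)
        freqs, axis = dominant_frequency(spectra)
        assert axis is None
        assert all(math.isnan(v) for v in freqs.values())

    def test_axis_permutation_equivariance(self):
        s = preprocessed_tone(5.0, weights=(0.0, 0.0, 1.0))
        permuted = s.replace(x=s.z.copy(), y=s.x.copy(), z=s.y.copy())
        _, axis = dominant_frequency(compute_spectra(s))
        _, axis_p = dominant_frequency(compute_spectra(permuted))
        assert axis == "z" and axis_p == "x"

    def test_empty_band_rejected(self):
        s = preprocessed_tone(5.0)
        spectra = compute_spectra(s)
        with pytest.raises(ValueError, match="no frequency bins"):
            dominant_frequency(spectra, analysis_band=(12.001, 12.002))


class TestEnergyBand:
    def test_tone_bin_membership(self):
        spectra = compute_spectra(preprocessed_tone(4.35))
        assert energy_band(spectra) == (3.0, 5.0)

    def test_preset_5p5_hz(self):
        spectra = compute_spectra(preprocessed_tone(5.5, noise=0.05, seed=2))
        assert energy_band(spectra) == (5.0, 7.0)

    def test_tie_breaks_low(self):
        freqs = np.arange(0, 14, 0.02)
        psd = np.zeros((3, len(freqs)))
        k1 = np.argmin(np.abs(freqs - 4.0))
        k2 = np.argmin(np.abs(freqs - 6.0))
        psd[0, k1] = psd[0, k2] = 1.0
        spectra = Spectra(freqs=freqs, amplitude=np.sqrt(psd), psd=psd, df=0.02, fs=FS)
        assert energy_band(spectra) == (3.0, 5.0)

    def test_contains_global_psd_max(self):
        # oracle: exhaustive band scan around the tri-axial argmax
        for seed in range(5):
            cfg = SimConfig(
                tremor_frequency_hz=2.0 + 2.1 * seed,
                tremor_amplitude=1.0,
                noise_sigma=0.05,
                seed=seed,
            )
            spectra = compute_spectra(run_preprocess(simulate_tremor(cfg)))
            band = energy_band(spectra)
            total = spectra.psd.sum(axis=0)
            in_grid = (spectra.freqs >= BAND_GRID[0][0]) & (spectra.freqs < BAND_GRID[-1][1])
            fmax = spectra.freqs[in_grid][np.argmax(total[in_grid])]
            assert band[0] <= fmax < band[1]


class TestBandAvgAmplitude:
    def test_constant_spectrum(self):
        freqs = np.arange(0, 14, 0.5)
        amp = np.full((3, len(freqs)), 0.7)
        spectra = Spectra(freqs=freqs, amplitude=amp, psd=amp**2, df=0.5, fs=FS)
        assert band_avg_amplitude(spectra, (3.0, 5.0)) == pytest.approx(0.7)

    def test_single_bin_tone_arithmetic(self):
        # one bin at amplitude A on one axis, k bins in band -> A / (3k)
        freqs = np.arange(0, 14, 0.5)
        amp = np.zeros((3, len(freqs)))
        k_bin = int(np.argmin(np.abs(freqs - 4.0)))
        A = 1.2
        amp[2, k_bin] = A
        spectra = Spectra(freqs=freqs, amplitude=amp, psd=amp**2, df=0.5, fs=FS)
        k = int(((freqs >= 3.0) & (freqs < 5.0)).sum())
        assert band_avg_amplitude(spectra, (3.0, 5.0)) == pytest.approx(A / (3 * k))

    def test_zero_spectrum(self):
        freqs = np.arange(0, 14, 0.5)
        amp = np.zeros((3, len(freqs)))
        spectra = Spectra(freqs=freqs, amplitude=amp, psd=amp, df=0.5, fs=FS)
        assert band_avg_amplitude(spectra, (3.0, 5.0)) == 0.0

    def test_band_outside_grid_rejected(self):
        freqs = np.arange(0, 5, 0.5)
        amp = np.zeros((3, len(freqs)))
        spectra = Spectra(freqs=freqs, amplitude=amp, psd=amp, df=0.5, fs=FS)
        with pytest.raises(ValueError, match="outside"):
            band_avg_amplitude(spectra, (11.0, 13.0))


class TestTotalEnergy:
    def test_constant_magnitude(self):
        n = 110
        s = series_from_arrays(np.full(n, 2.0), np.zeros(n), np.zeros(n))
        e = total_energy(s, window_s=1.0)  # 55 samples per window
        assert len(e) == 2
        np.testing.assert_allclose(e, 55 * 4.0)

    def test_homogeneity(self, tone_5hz):
        e1 = total_energy(tone_5hz)
        doubled = tone_5hz.replace(x=2 * tone_5hz.x, y=2 * tone_5hz.y, z=2 * tone_5hz.z)
        np.testing.assert_allclose(total_energy(doubled), 4 * e1)

    def test_window_count_integer_arithmetic(self):
        s = make_tone_series(5.0, 1.0, duration_s=60.0)
        e = total_energy(s, window_s=1.0)
        assert len(s) == 3333
        assert len(e) == 3333 // 55 == 60

    def test_window_longer_than_recording(self):
        s = series_from_arrays(*(np.zeros((3, 50))))
        with pytest.raises(ValueError, match="does not fit"):
            total_energy(s, window_s=10.0)


class TestToneAmplitude:
    @pytest.mark.parametrize("A", [0.5, 1.0, 3.0])
    def test_amplitude_recovery(self, A):
        s = preprocessed_tone(5.0, amplitude=A, noise=0.01, seed=4)
        assert tone_amplitude(s, 5.0) == pytest.approx(A, rel=0.02)

    def test_split_across_axes(self):
        w = (0.6, 0.0, 0.8)
        s = preprocessed_tone(5.0, amplitude=1.0, weights=w)
        assert tone_amplitude(s, 5.0) == pytest.approx(1.0, rel=0.02)


class TestAnalyzeTest:
    def test_missing_input_gives_missing_row(self):
        rec = analyze_test(None, patient_id=3, test_id=4, age=60, years_diagnosed=4)
        assert not rec.performed
        assert math.isnan(rec.dominant_freq_x_hz)
        assert rec.energy_band_hz is None
        assert math.isnan(rec.band_avg_amplitude)

    def test_end_to_end_preset(self):
        s = make_tone_series(4.5, 1.0, noise_sigma=0.05, seed=8)
        rec = analyze_test(s, patient_id=1, test_id=1)
        assert rec.performed
        assert rec.energy_band_hz == (3.0, 5.0)
        assert rec.dominant_freq_z_hz == pytest.approx(4.5, abs=0.02)
        assert rec.band_avg_amplitude > 0

    def test_deterministic(self):
        s = make_tone_series(4.5, 1.0, noise_sigma=0.05, seed=8)
        r1 = analyze_test(s, patient_id=1, test_id=1)
        r2 = analyze_test(s, patient_id=1, test_id=1)
        assert r1 == r2

    def test_summarize_bundle(self):
        s = run_preprocess(make_tone_series(5.5, 1.0, noise_sigma=0.05, seed=2))
        summary = summarize(s)
        assert summary.dominant_axis == "z"
        assert summary.energy_band_hz == (5.0, 7.0)
        assert len(summary.total_energy_per_window) == 60
        assert summary.analysis_band == (1.0, 12.0)
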