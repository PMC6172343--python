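"""Least-squares spectral estimation, baselines and feature construction."""

import numpy as np
import pytest
from scipy.signal import lombscargle

from lspdbn import (RemovalSpec, SubbandSpec, apply_minmax, default_freq_grid,
                    fft_periodogram, fit_minmax, lsp_power_at, lsp_spectrum,
                    normalize_power_by_retention, remove_points,
                    subband_features, welch_periodogram)
from lspdbn.spectral import SpectrumEstimate, lsp_spectra_batch

from conftest import make_segment


class TestLspPowerAt:
    def test_zero_signal_zero_power(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 10, 100))
        assert lsp_power_at(t, np.zeros(100), 2 * np.pi * 3.0) == 0.0

    def test_agrees_with_classical_lomb(self):
        # scipy's tau-shifted Lomb periodogram equals the least-squares
        # power up to the 2/N normalization -- an independent code path.
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 10, 257))
        x = np.sin(2 * np.pi * 3.3 * t) + 0.5 * rng.standard_normal(257)
        for f in (0.7, 3.3, 11.2):
            w = 2 * np.pi * f
            ours = lsp_power_at(t, x, w)
            classical = float(lombscargle(t, x, np.asarray([w]), normalize=False))
            assert ours == pytest.approx(2 / len(t) * classical, rel=1e-9)

    def test_agrees_with_lstsq_oracle(self):
        # Brute-force route: solve the sinusoid fit with numpy's SVD-based
        # lstsq and evaluate the fitted power directly.
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 5, 400))
        x = 0.8 * np.cos(2 * np.pi * 6 * t + 0.4) + rng.standard_normal(400)
        w = 2 * np.pi * 6.0
        design = np.column_stack([np.cos(w * t), np.sin(w * t)])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        oracle = float((design @ coef) @ (design @ coef)) / len(t)
        assert lsp_power_at(t, x, w) == pytest.approx(oracle, rel=1e-9)

    def test_dense_uniform_sinusoid_converges_to_half_amp_squared(self):
        fs, amp = 200.0, 1.3
        t = np.arange(4000) / fs
        x = amp * np.cos(2 * np.pi * 7 * t + 0.9)
        p = lsp_power_at(t, x, 2 * np.pi * 7.0)
        assert p == pytest.approx(amp**2 / 2, rel=1e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lsp_power_at(np.array([0.0, 1.0]), np.array([1.0, 2.0]), 1.0)


class TestLspSpectrum:
    def test_two_tone_peaks(self, two_tone_segment):
        spec = lsp_spectrum(two_tone_segment)
        top2 = spec.freqs[np.argsort(spec.power[0])[-2:]]
        assert set(np.round(top2, 1)) == {4.0, 8.0}

    def test_peaks_survive_80pct_removal(self, two_tone_segment):
        inc = remove_points(two_tone_segment, RemovalSpec(proportion=0.8, seed=5))
        spec = lsp_spectrum(inc)
        i4 = np.argmin(np.abs(spec.freqs - 4))
        i8 = np.argmin(np.abs(spec.freqs - 8))
        assert spec.power[0, i4] > 10 * np.median(spec.power[0])
        assert spec.power[0, i8] > 10 * np.median(spec.power[0])

    def test_zero_channel_gives_zero_row(self, two_tone_segment):
        seg = make_segment(np.zeros((1, 500)), sampling_rate=100.0)
        spec = lsp_spectrum(seg)
        assert np.all(spec.power == 0.0)

    def test_empty_or_invalid_grid_rejected(self, two_tone_segment):
        with pytest.raises(ValueError):
            lsp_spectrum(two_tone_segment, np.array([]))
        with pytest.raises(ValueError):
            lsp_spectrum(two_tone_segment, np.array([60.0]))  # above Nyquist

    def test_batch_path_matches_per_segment_path(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((4, 3, 200))
        masks = rng.random((4, 200)) < 0.7
        masks[:, :3] = True  # keep at least a few samples
        grid = default_freq_grid(2.0, 30.0, 1.0)
        batch = lsp_spectra_batch(values, masks, 250.0, grid)
        from lspdbn import IncompleteSegment
        for i in range(4):
            seg = IncompleteSegment(values=values[i][:, masks[i]],
                                    timestamps=np.flatnonzero(masks[i]) / 250.0,
                                    sampling_rate=250.0, original_length=200,
                                    label=0, source_trial=0, segment_index=0)
            single = lsp_spectrum(seg, grid)
            np.testing.assert_allclose(batch[i], single.power, rtol=1e-8)

    def test_nonnegative_power(self):
        rng = np.random.default_rng(4)
        seg = make_segment(rng.standard_normal((2, 300)))
        spec = lsp_spectrum(seg)
        assert np.all(spec.power >= 0)

    def test_normal_matrix_trace_equals_sample_count(self):
        # cos^2 + sin^2 sums to one per sample, for any timestamp set
        from lspdbn.spectral import _lsp_components
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 3, 173))
        omegas = 2 * np.pi * np.array([0.5, 4.0, 19.7])
        _, _, scc, sss, _ = _lsp_components(t, omegas)
        np.testing.assert_allclose(scc + sss, len(t), rtol=1e-12)


class TestUniformBaselines:
    def test_peaks_on_intact_two_tone(self, two_tone_segment):
        from scipy.signal import find_peaks
        for est in (fft_periodogram, welch_periodogram):
            spec = est(two_tone_segment)
            keep = spec.freqs <= 20
            freqs, power = spec.freqs[keep], spec.power[0, keep]
            peaks, _ = find_peaks(power)
            top2 = freqs[peaks[np.argsort(power[peaks])[-2:]]]
            assert set(np.round(top2, 1)) == {4.0, 8.0}

    def test_welch_full_window_equals_single_windowed_periodogram(self, two_tone_segment):
        from scipy import signal as sps
        welch = welch_periodogram(two_tone_segment,
                                  window_length=two_tone_segment.n_retained)
        freqs, power = sps.periodogram(two_tone_segment.values, fs=100.0,
                                       window="hann", detrend=False, axis=1)
        np.testing.assert_allclose(welch.power, power[:, freqs > 0], rtol=1e-10)

    def test_lsp_beats_uniform_estimators_on_gappy_data(self, two_tone_segment):
        # the headline mechanism, on one seed; the acceptance suite runs
        # the full Monte-Carlo version
        from lspdbn import peak_background_ratio
        from dataclasses import replace as drep
        inc = remove_points(two_tone_segment, RemovalSpec(proportion=0.8, seed=9))
        ratios = {}
        for name, fn in [("lsp", lambda s: lsp_spectrum(s, np.arange(1, 20.05, 0.1))),
                         ("fft", fft_periodogram), ("welch", welch_periodogram)]:
            spec = normalize_power_by_retention(fn(inc))
            keep = spec.freqs <= 20
            spec = drep(spec, freqs=spec.freqs[keep], power=spec.power[:, keep])
            ratios[name], _ = peak_background_ratio(spec, (4.0, 8.0))
        assert ratios["lsp"] > ratios["fft"]
        assert ratios["lsp"] > ratios["welch"]

    def test_too_few_samples_rejected(self):
        seg = make_segment(np.ones((1, 5)))
        with pytest.raises(ValueError):
            fft_periodogram(seg)


class TestRetentionNormalization:
    def test_scales_by_retained_fraction(self):
        spec = SpectrumEstimate(freqs=np.arange(1.0, 5.0), power=np.ones((2, 4)),
                                estimator="lsp", retained_fraction=0.5)
        out = normalize_power_by_retention(spec)
        assert np.all(out.power == 2.0)
        assert out.normalized_by_retention

    def test_identity_at_full_retention(self):
        spec = SpectrumEstimate(freqs=np.arange(1.0, 5.0), power=np.ones((1, 4)),
                                estimator="fft", retained_fraction=1.0)
        assert np.all(normalize_power_by_retention(spec).power == 1.0)

    def test_double_application_rejected(self):
        spec = SpectrumEstimate(freqs=np.arange(1.0, 5.0), power=np.ones((1, 4)),
                                estimator="lsp", retained_fraction=0.5)
        with pytest.raises(ValueError):
            normalize_power_by_retention(normalize_power_by_retention(spec))


class TestSubbandFeatures:
    def test_dimensionality_64_channels(self):
        grid = default_freq_grid()
        spec = SpectrumEstimate(freqs=grid, power=np.ones((64, len(grid))),
                                estimator="lsp", retained_fraction=1.0)
        assert subband_features(spec).shape == (256,)

    def test_flat_spectrum_gives_constant_features(self):
        grid = default_freq_grid()
        spec = SpectrumEstimate(freqs=grid, power=np.full((3, len(grid)), 2.5),
                                estimator="lsp", retained_fraction=1.0)
        assert np.allclose(subband_features(spec), 2.5)

    def test_alpha_only_spectrum_hits_alpha_slots(self):
        grid = default_freq_grid()
        power = np.zeros((4, len(grid)))
        alpha = (grid >= 8) & (grid < 13)
        power[:, alpha] = 1.0
        spec = SpectrumEstimate(freqs=grid, power=power, estimator="lsp",
                                retained_fraction=1.0)
        v = subband_features(spec)
        expected_nonzero = {4 * c for c in range(4)}
        assert set(np.flatnonzero(v)) == expected_nonzero

    def test_band_without_grid_points_rejected(self):
        spec = SpectrumEstimate(freqs=np.array([1.0, 2.0]), power=np.ones((1, 2)),
                                estimator="lsp", retained_fraction=1.0)
        with pytest.raises(ValueError):
            subband_features(spec, SubbandSpec())

    def test_linearity_in_the_spectrum(self):
        grid = default_freq_grid()
        rng = np.random.default_rng(5)
        p1 = rng.random((2, len(grid)))
        p2 = rng.random((2, len(grid)))
        mk = lambda p: SpectrumEstimate(freqs=grid, power=p, estimator="lsp",
                                        retained_fraction=1.0)
        lhs = subband_features(mk(3 * p1 + 2 * p2))
        rhs = 3 * subband_features(mk(p1)) + 2 * subband_features(mk(p2))
        np.testing.assert_allclose(lhs, rhs)


class TestMinMax:
    def test_training_data_maps_into_unit_interval(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 8)) * 5 + 2
        stats = fit_minmax(X)
        Z = apply_minmax(X, stats)
        assert Z.min() == pytest.approx(0.0)
        assert Z.max() == pytest.approx(1.0)
        assert np.allclose(Z.min(axis=0), 0.0) and np.allclose(Z.max(axis=0), 1.0)

    def test_test_data_may_exceed_one_without_clipping(self):
        X = np.array([[0.0], [1.0]])
        stats = fit_minmax(X)
        assert apply_minmax(np.array([[2.0]]), stats)[0, 0] == pytest.approx(2.0)

    def test_constant_dimension_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        stats = fit_minmax(X)
        Z = apply_minmax(X, stats)
        assert np.all(Z[:, 1] == 0.0)

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            fit_minmax(np.ones((1, 4)))
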