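"""Frequency-domain measures: normalization identities, the transfer-matrix
oracle, the direct-vs-total causality dissociation, PSD and IAF, band math."""

import numpy as np
import pytest

from conftest import chain_model, random_stable_model
from motorconn.mvar import MVARModel, simulate_mvar
from motorconn.series import MultichannelSeries
from motorconn.spectral import (BandDefinition, FrequencyGrid, band_average,
                                coefficient_spectrum, compute_iaf,
                                directed_coherence_squared, gpdc_squared,
                                welch_psd)


def ma_truncation_transfer(model: MVARModel, freqs, n_terms=4096):
    """Brute-force H(f): FFT of the impulse-response (MA) coefficients.

    Iterates h(n) = sum_k A(k) h(n-k) from h(0) = I and evaluates
    H(f) = sum_n h(n) e^{-j 2 pi f n T} on FFT bins; ``freqs`` must align
    with multiples of fs / n_terms.
    """
    p, m = model.order, model.n_channels
    h = np.zeros((n_terms, m, m))
    h[0] = np.eye(m)
    for n in range(1, n_terms):
        for k in range(1, min(p, n) + 1):
            h[n] += model.coeffs[k - 1] @ h[n - k]
    hf = np.fft.rfft(h, axis=0)  # bins at fs * i / n_terms
    step = model.fs / n_terms
    idx = np.round(np.asarray(freqs) / step).astype(int)
    assert np.allclose(idx * step, freqs, atol=1e-9)
    return hf[idx]


class TestCoefficientSpectrum:
    def test_zero_coefficients_give_identity(self):
        model = MVARModel(np.zeros((2, 3, 3)), np.eye(3), fs=128.0)
        spec = coefficient_spectrum(model, FrequencyGrid.default(128.0))
        expected = np.broadcast_to(np.eye(3), (513, 3, 3))
        np.testing.assert_allclose(spec.abar, expected, atol=0)
        np.testing.assert_allclose(spec.h, expected, atol=0)

    def test_zero_frequency_is_real_coefficient_sum(self):
        model = random_stable_model(seed=1, m=4, p=3, radius=0.8)
        spec = coefficient_spectrum(model, np.array([0.0, 1.0]))
        expected = np.eye(4) - model.coeffs.sum(axis=0)
        np.testing.assert_allclose(spec.abar[0], expected, atol=1e-14)
        assert np.abs(spec.abar[0].imag).max() == 0.0

    def test_inverse_identity_on_grid(self):
        model = random_stable_model(seed=2, m=5, p=8, radius=0.9)
        spec = coefficient_spectrum(model, FrequencyGrid.default(128.0))
        prod = spec.abar @ spec.h
        assert np.abs(prod - np.eye(5)[None]).max() < 1e-8

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_transfer_matches_ma_truncation_oracle(self, seed):
        model = random_stable_model(seed=seed, m=2, p=3, radius=0.95, fs=128.0)
        freqs = np.arange(0.0, 64.0 + 0.125 / 2, 0.125)
        spec = coefficient_spectrum(model, freqs)
        oracle = ma_truncation_transfer(model, freqs)
        assert np.abs(spec.h - oracle).max() < 1e-6


class TestDirectedCoherence:
    def test_uncoupled_model_is_diagonal(self):
        model = MVARModel(np.zeros((1, 4, 4)), np.diag([1.0, 2.0, 0.5, 3.0]),
                          fs=128.0)
        dc = directed_coherence_squared(model, FrequencyGrid.default(128.0))
        diag = np.einsum("fii->fi", dc.values)
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)
        assert dc.values.sum() == pytest.approx(dc.values.shape[0] * 4)

    def test_rows_sum_to_one_everywhere(self):
        model = random_stable_model(seed=6, m=5, p=8, radius=0.9)
        dc = directed_coherence_squared(model, FrequencyGrid.default(128.0))
        assert np.abs(dc.values.sum(axis=2) - 1.0).max() < 1e-10

    def test_chain_passes_indirect_path(self):
        """DC sees 1 -> 3 through the mediated chain; verified against the
        MA-truncation oracle."""
        model = chain_model(strength=0.5)
        freqs = np.arange(8.0, 12.0 + 1e-9, 0.125)
        dc = directed_coherence_squared(model, freqs)
        band = band_average(dc, (8.0, 12.0))
        assert band[2, 0] > 0.01
        oracle = ma_truncation_transfer(model, freqs)
        assert np.abs(oracle[:, 2, 0]).max() > 0.1  # nonzero H_31 confirmed

    def test_denominator_equals_parametric_psd_under_strict_causality(self):
        model = random_stable_model(seed=7, m=4, p=5, radius=0.85,
                                    diag_sigma=True)
        grid = FrequencyGrid.default(128.0)
        spec = coefficient_spectrum(model, grid)
        s = spec.h @ model.sigma @ np.conj(np.transpose(spec.h, (0, 2, 1)))
        psd = np.einsum("fii->fi", s).real
        sigma2 = np.diag(model.sigma)
        denom = (np.abs(spec.h) ** 2 * sigma2[None, None, :]).sum(axis=2)
        assert np.abs(psd - denom).max() < 1e-10


class TestGPDC:
    def test_uncoupled_model_is_diagonal(self):
        model = MVARModel(np.zeros((1, 3, 3)), np.diag([1.0, 4.0, 0.25]),
                          fs=128.0)
        gp = gpdc_squared(model, FrequencyGrid.default(128.0))
        diag = np.einsum("fii->fi", gp.values)
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)

    def test_columns_sum_to_one_everywhere(self):
        model = random_stable_model(seed=8, m=5, p=8, radius=0.9)
        gp = gpdc_squared(model, FrequencyGrid.default(128.0))
        assert np.abs(gp.values.sum(axis=1) - 1.0).max() < 1e-10

    def test_chain_direct_only(self):
        """gPDC is exactly zero on the mediated pair 1 -> 3."""
        model = chain_model(strength=0.5)
        gp = gpdc_squared(model, FrequencyGrid.default(128.0))
        assert np.all(gp.values[:, 2, 0] == 0.0)
        assert band_average(gp, (8.0, 12.0))[1, 0] > 0.01

    def test_zero_pair_stays_zero_for_any_sigma_scale(self):
        model = chain_model(strength=0.3)
        model.sigma = np.diag([0.5, 2.0, 7.0])
        gp = gpdc_squared(model, FrequencyGrid.default(128.0))
        assert np.all(gp.values[:, 2, 0] == 0.0)
        assert np.abs(gp.values.sum(axis=1) - 1.0).max() < 1e-10


class TestWelchAndIAF:
    def test_sinusoid_peak_located(self):
        fs, t = 128.0, np.arange(0, 60 * 128) / 128.0
        rng = np.random.default_rng(0)
        vals = np.sin(2 * np.pi * 10.0 * t) + 0.01 * rng.standard_normal(t.size)
        ser = MultichannelSeries(vals[None], fs, ("x",))
        freqs, psd = welch_psd(ser)
        assert abs(freqs[np.argmax(psd[0])] - 10.0) <= freqs[1] - freqs[0]

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(1)
        ser = MultichannelSeries(rng.standard_normal((1, 128 * 400)), 128.0, ("x",))
        freqs, psd = welch_psd(ser)
        inner = psd[0][(freqs > 2) & (freqs < 62)]
        assert inner.max() / inner.min() < 3.0

    def test_zero_signal_gives_zero_psd(self):
        ser = MultichannelSeries(np.zeros((1, 1280)), 128.0, ("x",))
        _, psd = welch_psd(ser)
        assert np.all(psd == 0.0)

    def test_total_power_matches_variance(self):
        rng = np.random.default_rng(2)
        ser = MultichannelSeries(rng.standard_normal((2, 128 * 60)), 128.0,
                                 ("x", "y"))
        freqs, psd = welch_psd(ser)
        power = np.trapezoid(psd, freqs, axis=1)
        np.testing.assert_allclose(power, ser.values.var(axis=1), rtol=0.05)

    def test_iaf_degenerate_average(self):
        freqs = np.arange(0, 64.1, 0.25)
        psd = np.exp(-0.5 * (freqs - 9.0) ** 2)[None].repeat(5, axis=0)
        assert compute_iaf(freqs, psd) == 9.0

    def test_iaf_mean_of_two_channels(self):
        freqs = np.arange(0, 64.1, 0.25)
        p1 = np.exp(-0.5 * (freqs - 8.0) ** 2)
        p2 = np.exp(-0.5 * (freqs - 10.0) ** 2)
        assert compute_iaf(freqs, np.vstack([p1, p2])) == 9.0

    def test_iaf_monotone_psd_warns_and_uses_edge(self):
        freqs = np.arange(0, 64.1, 0.25)
        psd = (1.0 / (1.0 + freqs))[None]
        with pytest.warns(UserWarning, match="monotone"):
            iaf = compute_iaf(freqs, psd)
        assert iaf == 7.5


class TestBandDefinition:
    def test_iaf_relative_edges(self):
        b = BandDefinition(9.07)
        assert b.alpha == (7.07, 11.07)
        assert b.beta == (11.57, 29.07)

    def test_bands_disjoint(self):
        b = BandDefinition(10.0)
        assert b.alpha[1] < b.beta[0]

    def test_beta_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            BandDefinition(50.0).validate(128.0)


class TestBandAverage:
    def test_constant_spectrum(self):
        model = MVARModel(np.zeros((1, 3, 3)), np.eye(3), fs=128.0)
        dc = directed_coherence_squared(model, FrequencyGrid.default(128.0))
        band = band_average(dc, (5.0, 20.0))
        np.testing.assert_array_equal(band, np.eye(3))

    def test_full_grid_band_preserves_row_normalization(self):
        model = random_stable_model(seed=9, m=5, p=8, radius=0.9)
        dc = directed_coherence_squared(model, FrequencyGrid.default(128.0))
        band = band_average(dc, (0.0, 64.0))
        np.testing.assert_allclose(band.sum(axis=1), 1.0, atol=1e-10)

    def test_single_bin_band(self):
        model = random_stable_model(seed=10, m=4, p=3, radius=0.8)
        grid = FrequencyGrid.default(128.0)
        dc = directed_coherence_squared(model, grid)
        k = 80
        band = band_average(dc, (grid.freqs[k], grid.freqs[k]))
        np.testing.assert_array_equal(band, dc.values[k])

    def test_empty_band_raises(self):
        model = random_stable_model(seed=11, m=3, p=2, radius=0.8)
        dc = directed_coherence_squared(model, FrequencyGrid.default(128.0))
        with pytest.raises(ValueError, match="no grid bins"):
            band_average(dc, (10.01, 10.05))
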