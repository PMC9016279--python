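"""Frequency-domain connectivity: DC, gPDC, Welch PSD, IAF and band averages.

From a fitted MVAR model, the coefficient spectrum is
``Abar(f) = I - sum_k A(k) exp(-j 2 pi f k T)`` and the transfer matrix is
``H(f) = Abar(f)^{-1}``. Two squared-modulus causality measures are derived:

* Directed Coherence (DC): ``|DC_ij(f)|^2 = sigma_j^2 |H_ij(f)|^2 /
  sum_m sigma_m^2 |H_im(f)|^2`` -- the fraction of channel i's spectral power
  causally driven by channel j through *all* (direct and mediated) paths.
  Rows sum to 1 over sources at every frequency.
* Generalized Partial Directed Coherence (gPDC):
  ``|gPDC_ij(f)|^2 = sigma_i^{-2} |Abar_ij(f)|^2 /
  sum_m sigma_m^{-2} |Abar_mj(f)|^2`` -- nonzero only for *direct* couplings;
  columns sum to 1 over receivers at every frequency (normalization with
  respect to the outflow from source j).

Band edges are anchored to the Individual Alpha Frequency (IAF): the alpha
band is [IAF-2, IAF+2] Hz and the beta band is [IAF+2.5, IAF+20] Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .mvar import MVARModel
from .series import MultichannelSeries

IAF_SEARCH_RANGE = (7.5, 12.5)


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency grid from 0 to the Nyquist frequency inclusive."""

    freqs: np.ndarray

    @classmethod
    def default(cls, fs: float, n_points: int = 513) -> "FrequencyGrid":
        """513 points on [0, fs/2]: 0.125 Hz resolution at fs = 128 Hz."""
        return cls(np.linspace(0.0, fs / 2.0, n_points))

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BandDefinition:
    """IAF-relative alpha and beta band edges (closed intervals, Hz)."""

    iaf: float

    @property
    def alpha(self):
        return (self.iaf - 2.0, self.iaf + 2.0)

    @property
    def beta(self):
        return (self.iaf + 2.5, self.iaf + 20.0)

    def band(self, name: str):
        if name == "alpha":
            return self.alpha
        if name == "beta":
            return self.beta
        raise KeyError(f"unknown band {name!r}")

    def validate(self, fs: float) -> None:
        if self.beta[1] > fs / 2.0:
            raise ValueError(
                f"beta band upper edge {self.beta[1]:.2f} Hz exceeds the "
                f"Nyquist frequency {fs / 2.0:.2f} Hz"
            )


@dataclass
class SpectralMatrices:
    """Coefficient spectrum Abar(f) and transfer matrix H(f) per frequency."""

    abar: np.ndarray   # (F, M, M) complex
    h: np.ndarray      # (F, M, M) complex
    freqs: np.ndarray  # (F,)


@dataclass
class ConnectivitySpectrum:
    """Squared-modulus DC or gPDC values on a frequency grid.

    ``values[f, i, j]`` is the squared modulus of the measure from source j
    to receiver i at ``freqs[f]``; all entries lie in [0, 1].
    """

    measure: str       # "DC" | "gPDC"
    values: np.ndarray  # (F, M, M) real in [0, 1]
    freqs: np.ndarray
    sigma2: np.ndarray  # diagonal innovation variances used


def _abar(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    p, m = model.order, model.n_channels
    t = 1.0 / model.fs
    k = np.arange(1, p + 1)
    # phase[f, k] = exp(-j 2 pi f k T)
    phase = np.exp(-2j * np.pi * np.outer(freqs * t, k))
    a_f = np.einsum("fk,kij->fij", phase, model.coeffs, optimize=True)
    return np.eye(m) - a_f


def coefficient_spectrum(model: MVARModel, grid) -> SpectralMatrices:
    """Evaluate Abar(f) = I - A(f) and H(f) = Abar(f)^(-1) on a grid.

    Raises a ValueError naming the first offending frequency if the
    inversion fails (model on the stability boundary).
    """
    freqs = grid.freqs if isinstance(grid, FrequencyGrid) else np.asarray(grid, float)
    abar = _abar(model, freqs)
    try:
        h = np.linalg.inv(abar)
    except np.linalg.LinAlgError:
        for f, mat in zip(freqs, abar):
            if abs(np.linalg.det(mat)) < 1e-300:
                raise ValueError(
                    f"coefficient spectrum singular at f = {f:.4f} Hz"
                ) from None
        raise
    return SpectralMatrices(abar=abar, h=h, freqs=freqs)


def directed_coherence_squared(model: MVARModel, grid) -> ConnectivitySpectrum:
    """Squared-modulus Directed Coherence spectrum of an MVAR model."""
    sigma2 = np.diag(model.sigma).copy()
    if np.any(sigma2 <= 0):
        raise ValueError("DC requires strictly positive innovation variances")
    spec = coefficient_spectrum(model, grid)
    habs2 = np.abs(spec.h) ** 2                      # (F, M, M)
    num = habs2 * sigma2[None, None, :]              # sigma_j^2 |H_ij|^2
    denom = num.sum(axis=2, keepdims=True)           # sum over sources m
    if np.any(denom <= 0):
        raise ValueError("degenerate DC spectrum: zero row power")
    return ConnectivitySpectrum("DC", num / denom, spec.freqs, sigma2)


def gpdc_squared(model: MVARModel, grid) -> ConnectivitySpectrum:
    """Squared-modulus generalized PDC spectrum of an MVAR model."""
    sigma2 = np.diag(model.sigma).copy()
    if np.any(sigma2 <= 0):
        raise ValueError("gPDC requires strictly positive innovation variances")
    freqs = grid.freqs if isinstance(grid, FrequencyGrid) else np.asarray(grid, float)
    abar = _abar(model, freqs)
    return ConnectivitySpectrum(
        "gPDC", _gpdc_from_abar(abar, sigma2), freqs, sigma2
    )


def _gpdc_from_abar(abar: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """gPDC squared from (..., M, M) Abar arrays; broadcasts over batch axes."""
    inv_s2 = 1.0 / sigma2
    num = (np.abs(abar) ** 2) * inv_s2[..., :, None]   # sigma_i^-2 |Abar_ij|^2
    denom = num.sum(axis=-2, keepdims=True)            # sum over receivers m
    if np.any(denom <= 0):
        raise ValueError("degenerate gPDC spectrum: zero column outflow")
    return num / denom


def welch_psd(
    series: MultichannelSeries,
    segment_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
):
    """Per-channel Welch PSD (Hann window, mean-detrended segments).

    Returns ``(freqs, psd)`` with ``psd`` of shape (M, F). Segments are
    zero-padded twofold, so 4 s segments at 128 Hz give a 0.125 Hz grid
    (matching the connectivity grid resolution) while the spectral
    resolution itself remains that of the 4 s window.
    """
    nperseg = int(round(segment_seconds * series.fs))
    if nperseg > series.n_samples:
        raise ValueError(
            f"Welch segment of {nperseg} samples exceeds the series length "
            f"{series.n_samples}"
        )
    freqs, psd = signal.welch(
        series.values,
        fs=series.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_fraction)),
        nfft=2 * nperseg,
        detrend="constant",
        axis=1,
    )
    return freqs, psd


def compute_iaf(freqs: np.ndarray, psd: np.ndarray,
                search_range=IAF_SEARCH_RANGE) -> float:
    """Individual Alpha Frequency: mean per-channel PSD peak in 7.5-12.5 Hz.

    The peak is the discrete argmax of each channel's PSD restricted to the
    closed search range, averaged across channels. If a channel's PSD is
    monotone over the range (no interior peak) a warning is issued and the
    range-edge argmax is used for that channel.
    """
    psd = np.atleast_2d(psd)
    lo, hi = search_range
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError("frequency grid does not cover the IAF search range")
    f_in = freqs[mask]
    peaks = []
    for ch in psd:
        seg = ch[mask]
        k = int(np.argmax(seg))
        if k in (0, len(seg) - 1):
            d = np.diff(seg)
            if np.all(d >= 0) or np.all(d <= 0):
                warnings.warn(
                    "PSD is monotone over the IAF search range; "
                    "using the range-edge argmax",
                    stacklevel=2,
                )
        peaks.append(f_in[k])
    return float(np.mean(peaks))


def band_average(spectrum: ConnectivitySpectrum, band) -> np.ndarray:
    """Mean of the squared-modulus values over grid bins inside a band.

    A bin belongs to the band if its center frequency lies in the closed
    interval [f_lo, f_hi]. Returns an (M, M) matrix.
    """
    f_lo, f_hi = band
    mask = (spectrum.freqs >= f_lo) & (spectrum.freqs <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no grid bins inside band [{f_lo}, {f_hi}] Hz")
    return spectrum.values[mask].mean(axis=0)
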