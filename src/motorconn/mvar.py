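"""Multivariate autoregressive (MVAR) model fitting and order selection.

The model is X(n) = sum_{k=1..p} A(k) X(n-k) + W(n), with A(k) an MxM
coefficient matrix at lag k and W(n) multivariate white Gaussian noise with
covariance Sigma. Coefficients are estimated by ordinary least squares on the
lag-stacked regression, the standard choice for short EEG epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .series import EpochSet, MultichannelSeries


@dataclass
class MVARModel:
    """Order-p MVAR model: coefficients, innovation covariance, sampling rate.

    Attributes
    ----------
    coeffs : ndarray, shape (p, M, M)
        ``coeffs[k-1, i, j]`` is A_ij(k): the dependence of channel i at
        time n on channel j at time n-k.
    sigma : ndarray, shape (M, M)
        Innovation covariance Sigma (symmetric positive semi-definite).
    fs : float
        Sampling rate in Hz; the sampling period is T = 1/fs.
    """

    coeffs: np.ndarray
    sigma: np.ndarray
    fs: float

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must have shape (p, M, M)")
        if self.order < 1:
            raise ValueError("model order must be >= 1")
        m = self.n_channels
        if self.sigma.shape != (m, m):
            raise ValueError("sigma shape does not match channel count")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """Companion-form transition matrix, shape (M*p, M*p)."""
        p, m = self.order, self.n_channels
        comp = np.zeros((m * p, m * p))
        comp[:m] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            comp[m:, :-m] = np.eye(m * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        """Largest eigenvalue modulus of the companion matrix."""
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol


def _lag_design(values: np.ndarray, p: int):
    """Lag-stacked regression arrays from an (M, N) series.

    Returns Y of shape (N-p, M) and Z of shape (N-p, M*p), where row n of Z
    is [X(n-1); X(n-2); ...; X(n-p)] flattened channel-fastest per lag.
    """
    m, n = values.shape
    # windows[t] = values[:, t:t+p]; reversed so lag 1 comes first
    win = sliding_window_view(values, p, axis=1)          # (M, N-p+1, p)
    z = win[:, :-1, ::-1]                                 # (M, N-p, p) lag1..p
    z = np.transpose(z, (1, 2, 0)).reshape(n - p, p * m)  # (N-p, p*M)
    y = values[:, p:].T                                   # (N-p, M)
    return y, z


def fit_mvar(epoch: MultichannelSeries, p: int) -> MVARModel:
    """Least-squares MVAR fit of one epoch at fixed order ``p``.

    The residual covariance uses denominator N - p (the effective sample
    count after lag truncation).

    Raises
    ------
    ValueError
        If the epoch is too short for an overdetermined regression or the
        lag matrix is rank deficient (e.g. duplicated channels).
    """
    m, n = epoch.values.shape
    if n <= p * m + m:
        raise ValueError(
            f"epoch of {n} samples cannot identify an order-{p} model on "
            f"{m} channels (need N > p*M + M = {p * m + m})"
        )
    y, z = _lag_design(epoch.values, p)
    b, _, rank, _ = np.linalg.lstsq(z, y, rcond=None)
    if rank < z.shape[1]:
        raise ValueError(
            f"lag design matrix is rank deficient (rank {rank} < {z.shape[1]}); "
            "channels may be duplicated or constant"
        )
    resid = y - z @ b
    sigma = resid.T @ resid / (n - p)
    sigma = 0.5 * (sigma + sigma.T)
    coeffs = b.T.reshape(m, p, m).transpose(1, 0, 2)
    return MVARModel(coeffs=coeffs, sigma=sigma, fs=epoch.fs)


def fit_mvar_batch(values: np.ndarray, p: int, fs: float):
    """Vectorized least-squares MVAR fit of a batch of equal-length epochs.

    Parameters
    ----------
    values : ndarray, shape (B, M, N)
    p : model order
    fs : sampling rate

    Returns
    -------
    coeffs : ndarray, shape (B, p, M, M)
    sigma : ndarray, shape (B, M, M)

    Notes
    -----
    Solves the normal equations with a batched Cholesky-backed solve, which
    is what makes per-epoch surrogate ensembles (hundreds of refits)
    affordable. Falls back to per-epoch ``lstsq`` if any normal matrix is
    singular.
    """
    bsz, m, n = values.shape
    if n <= p * m + m:
        raise ValueError("epochs too short for requested order")
    win = sliding_window_view(values, p, axis=2)             # (B, M, N-p+1, p)
    z = win[:, :, :-1, ::-1]                                 # (B, M, N-p, p)
    z = np.transpose(z, (0, 2, 3, 1)).reshape(bsz, n - p, p * m)
    y = np.transpose(values[:, :, p:], (0, 2, 1))            # (B, N-p, M)
    ztz = np.einsum("bti,btj->bij", z, z, optimize=True)
    zty = np.einsum("bti,btm->bim", z, y, optimize=True)
    try:
        b = np.linalg.solve(ztz, zty)                        # (B, p*M, M)
    except np.linalg.LinAlgError:
        b = np.stack(
            [np.linalg.lstsq(z[i], y[i], rcond=None)[0] for i in range(bsz)]
        )
    resid = y - np.einsum("bti,bim->btm", z, b, optimize=True)
    sigma = np.einsum("bti,btj->bij", resid, resid, optimize=True) / (n - p)
    sigma = 0.5 * (sigma + np.transpose(sigma, (0, 2, 1)))
    coeffs = np.transpose(b.reshape(bsz, p, m, m), (0, 1, 3, 2))
    return coeffs, sigma


def select_order_bic(epochs: EpochSet, p_max: int):
    """Select the MVAR order minimizing the epoch-averaged BIC.

    BIC(p) = ln det(Sigma_hat_p) + p * M^2 * ln(N_eff) / N_eff with
    N_eff = N - p, averaged over epochs; ties break toward the smaller
    order (parsimony).

    Returns
    -------
    (p_star, scores) : selected order and the dict {p: mean BIC}.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    scores = {}
    for p in range(1, p_max + 1):
        vals = []
        for ep in epochs:
            model = fit_mvar(ep, p)
            n_eff = ep.n_samples - p
            sign, logdet = np.linalg.slogdet(model.sigma)
            if sign <= 0 or not np.isfinite(logdet):
                raise ValueError(
                    f"BIC undefined at order {p}: singular residual covariance"
                )
            m = ep.n_channels
            vals.append(logdet + p * m * m * np.log(n_eff) / n_eff)
        scores[p] = float(np.mean(vals))
    return _argmin_order(scores), scores


def _argmin_order(scores: dict) -> int:
    """Order with the smallest score; exact ties go to the smaller order."""
    return min(scores, key=lambda p: (scores[p], p))


def simulate_mvar(
    model: MVARModel,
    n_samples: int,
    seed,
    burn_in: int = 1000,
    labels=None,
) -> MultichannelSeries:
    """Forward-iterate X(n) = sum_k A(k) X(n-k) + W(n) from zero initial state.

    Innovations are multivariate Gaussian with covariance ``model.sigma``.
    The first ``burn_in`` samples are discarded so the returned series is
    (approximately) a draw from the stationary distribution. Identical seeds
    produce identical output.
    """
    if n_samples < 10 * model.order:
        raise ValueError("n_samples must be at least 10 * order")
    rho = model.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"refusing to simulate an unstable model (spectral radius {rho:.4f})"
        )
    rng = np.random.default_rng(seed)
    p, m = model.order, model.n_channels
    total = n_samples + burn_in
    # eigh-based factor: PSD-safe even when sigma is singular
    evals, evecs = np.linalg.eigh(model.sigma)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    w = rng.standard_normal((total, m)) @ factor.T
    # stacked (M, M*p) coefficients acting on [X(n-1); ...; X(n-p)]
    a_stack = np.concatenate(list(model.coeffs), axis=1)
    x = np.zeros((total + p, m))
    for t in range(total):
        past = x[t:t + p][::-1].ravel()
        x[t + p] = w[t] + a_stack @ past
    out = x[p + burn_in:].T
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(m))
    return MultichannelSeries(out, model.fs, labels)


def check_stability(model: MVARModel, context: str = "model") -> None:
    """Raise with the offending spectral radius if the model is unstable."""
    rho = model.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"{context} is unstable: companion spectral radius {rho:.4f} >= 1"
        )
    if rho > 0.999:
        warnings.warn(
            f"{context} is near the stability boundary (radius {rho:.4f})",
            stacklevel=2,
        )
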