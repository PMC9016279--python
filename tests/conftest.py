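import numpy as np
import pytest

from motorconn.mvar import MVARModel, simulate_mvar
from motorconn.series import MultichannelSeries


def random_stable_model(seed, m=5, p=8, radius=0.9, fs=128.0,
                        diag_sigma=True) -> MVARModel:
    """Random MVAR model rescaled to an exact companion spectral radius.

    Scaling lag-k coefficients by gamma**k scales every companion eigenvalue
    by gamma, so the target radius is hit exactly.
    """
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(scale=0.3, size=(p, m, m))
    model = MVARModel(coeffs=coeffs, sigma=np.eye(m), fs=fs)
    rho = model.spectral_radius()
    gamma = radius / rho
    coeffs = coeffs * gamma ** np.arange(1, p + 1)[:, None, None]
    if diag_sigma:
        sigma = np.diag(rng.uniform(0.5, 2.0, size=m))
    else:
        a = rng.normal(size=(m, m))
        sigma = a @ a.T + m * np.eye(m)
    return MVARModel(coeffs=coeffs, sigma=sigma, fs=fs)


def chain_model(strength=0.5, f0=10.0, rho=0.9, fs=128.0, p=2) -> MVARModel:
    """Three oscillators coupled in a causal chain 1 -> 2 -> 3 (0-indexed 0->1->2)
    with no direct 1 -> 3 coefficient."""
    theta = 2 * np.pi * f0 / fs
    coeffs = np.zeros((p, 3, 3))
    for i in range(3):
        coeffs[0, i, i] = 2 * rho * np.cos(theta)
        coeffs[1, i, i] = -rho ** 2
    coeffs[0, 1, 0] = strength   # 1 -> 2
    coeffs[0, 2, 1] = strength   # 2 -> 3
    return MVARModel(coeffs=coeffs, sigma=np.eye(3), fs=fs)


@pytest.fixture(scope="session")
def oscillator_epoch() -> MultichannelSeries:
    """One 10 s, 128 Hz epoch of a 10 Hz AR(2) oscillator pair (2 channels)."""
    theta = 2 * np.pi * 10.0 / 128.0
    coeffs = np.zeros((2, 2, 2))
    for i in range(2):
        coeffs[0, i, i] = 2 * 0.9 * np.cos(theta)
        coeffs[1, i, i] = -0.81
    model = MVARModel(coeffs=coeffs, sigma=np.eye(2), fs=128.0)
    ser = simulate_mvar(model, 1280, seed=123, labels=("a", "b"))
    return ser
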