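import numpy as np
import pytest


def data_with_exact_cov(S, n, seed=0, means=None):
    """Sample of size n whose *sample* covariance (ddof=1) equals S exactly."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(0)
    C = np.cov(Z, rowvar=False, ddof=1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(C)).T @ np.linalg.cholesky(S).T
    if means is not None:
        Z += np.asarray(means)
    return Z


@pytest.fixture
def exact_cov_data():
    return data_with_exact_cov


def one_factor_sample(loadings, n, rng, shift=0.0, factor_sd=1.0,
                      missing_rate=0.0):
    """Standardized one-factor indicator sample."""
    lam = np.asarray(loadings, dtype=float)
    F = rng.standard_normal(n) * factor_sd
    X = F[:, None] * lam + rng.standard_normal((n, len(lam))) * np.sqrt(1 - lam ** 2)
    X += shift
    if missing_rate:
        X[rng.random(X.shape) < missing_rate] = np.nan
    return X


@pytest.fixture
def one_factor_data():
    return one_factor_sample
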