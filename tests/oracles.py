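"""Independent brute-force oracles used across the test suite.

Each oracle is coded from the defining formula, deliberately without
reusing the package's optimized implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import poisson


def brute_gi_star(values: np.ndarray, coords: np.ndarray, d_km: float,
                  pooled: tuple[float, float] | None = None) -> np.ndarray:
    """O(N^2) double-loop Getis-Ord Gi* with binary weights, self included."""
    x = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if pooled is None:
        xbar, s = x.mean(), x.std(ddof=0)
    else:
        xbar, s = pooled
    z = np.empty(n)
    for i in range(n):
        w = np.zeros(n)
        for j in range(n):
            if np.hypot(*(coords[i] - coords[j])) <= d_km:
                w[j] = 1.0
        big_w = w.sum()
        num = (w * x).sum() - xbar * big_w
        den = s * np.sqrt((n * (w**2).sum() - big_w**2) / (n - 1))
        z[i] = num / den
    return z


def brute_morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Double-sum Moran's I straight from the definition."""
    x = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float)
    n = x.size
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
    return n / w.sum() * num / ((x - xbar) ** 2).sum()


def tweedie_logpdf_oracle(y: float, mu: float, p: float, phi: float, n_max: int = 500) -> float:
    """Compound Poisson-gamma density by direct enumeration over the
    Poisson count using scipy's pmf/pdf (independent of the package's
    series evaluation)."""
    lam = mu ** (2 - p) / (phi * (2 - p))
    alpha = (2 - p) / (p - 1)
    scale = phi * (p - 1) * mu ** (p - 1)
    if y == 0:
        return float(-lam)
    total = 0.0
    for n in range(1, n_max):
        total += poisson.pmf(n, lam) * gamma_dist.pdf(y, n * alpha, scale=scale)
    return float(np.log(total))


def tweedie_nll_oracle(y: np.ndarray, mu: float, p: float, phi: float, n_max: int = 200) -> float:
    """Vectorized negative log-likelihood of iid Tweedie data by direct
    enumeration over the Poisson count (independent of the package's
    Dunn-Smyth series)."""
    y = np.asarray(y, dtype=float)
    lam = mu ** (2 - p) / (phi * (2 - p))
    alpha = (2 - p) / (p - 1)
    scale = phi * (p - 1) * mu ** (p - 1)
    nll = float((y == 0).sum()) * lam  # each zero contributes -log P(0) = lam
    pos = y[y > 0]
    counts = np.arange(1, n_max)
    pmf = poisson.pmf(counts, lam)  # (n_max-1,)
    dens = gamma_dist.pdf(pos[:, None], counts[None, :] * alpha, scale=scale)
    nll -= np.log(dens @ pmf).sum()
    return nll


def brute_rda(y: np.ndarray, x: np.ndarray) -> dict:
    """Explicit hat-matrix projection + full eigendecomposition RDA.

    Y and X are centered and standardized columns; returns eigenvalues
    of Yhat' Yhat / (n-1) and the constrained-variance proportion.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    yc = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    xc = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    hat = xc @ np.linalg.inv(xc.T @ xc) @ xc.T
    yhat = hat @ yc
    cov = yhat.T @ yhat / (n - 1)
    evals = np.linalg.eigvalsh(cov)[::-1]
    evals = evals[evals > 1e-12 * max(evals.max(), 1.0)]
    total = (yc**2).sum() / (n - 1)
    return {"eigenvalues": evals, "prop_constrained": evals.sum() / total}


def pca_eigenvalues(y: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation-scaled covariance of Y."""
    yc = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    cov = yc.T @ yc / (y.shape[0] - 1)
    evals = np.linalg.eigvalsh(cov)[::-1]
    return evals[evals > 1e-12 * max(evals.max(), 1.0)]
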