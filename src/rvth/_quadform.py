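"""Tail probabilities of positive quadratic forms in Gaussian variables.

Computes ``P(Q > x)`` for ``Q = sum_k lambda_k * chi2_1`` by numerical
inversion of the characteristic function (Imhof's integral, the same quantity
Davies' algorithm evaluates), with the Liu et al. moment-matching
approximation as a fallback when the inversion misbehaves.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

__all__ = ["chi2_mixture_sf"]


def _imhof_sf(x: float, lam: np.ndarray, tol: float = 1e-9) -> float:
    lam = np.asarray(lam, dtype=float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(
            integrand, 0.0, np.inf, epsabs=tol, epsrel=tol, limit=500
        )
    return 0.5 + val / np.pi


def _liu_sf(x: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching to a (non)central chi-square."""
    lam = np.asarray(lam, dtype=float)
    c = np.array([np.sum(lam**k) for k in (1, 2, 3, 4)])
    s1 = c[2] / c[1] ** 1.5
    s2 = c[3] / c[1] ** 2
    mu_q = c[0]
    sigma_q = np.sqrt(2.0 * c[1])
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2.0 * ncp
    else:
        ncp = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_x = df + ncp
    sigma_x = np.sqrt(2.0 * (df + 2.0 * ncp))
    t = (x - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, ncp) if ncp > 0 else stats.chi2.sf(t, df))


def chi2_mixture_sf(x: float, weights: np.ndarray, tol: float = 1e-9) -> float:
    """Upper-tail probability of a weighted sum of 1-df chi-squares at ``x``.

    Non-positive weights are dropped (numerical zeros from the eigensolve).
    """
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > max(1e-12 * lam.max(initial=0.0), 0.0)]
    if lam.size == 0:
        return 1.0
    if x <= 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12):
        # equal weights: exactly a scaled chi-square; also avoids the slowly
        # decaying one-component Imhof integrand
        return float(stats.chi2.sf(x / lam[0], df=lam.size))
    try:
        with np.errstate(all="ignore"):
            p = _imhof_sf(float(x), lam, tol)
    except Exception:
        p = np.nan
    if not np.isfinite(p) or not 0.0 <= p <= 1.0:
        p = _liu_sf(float(x), lam)
    return float(min(max(p, 0.0), 1.0))
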