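"""Gene-level rare-variant association tests for binary traits.

Implements four families of tests compared on the same carriage data:

* ``th_test`` — trend-and-heterogeneity (TH): the sum of squared Pearson
  residuals of rare-variant carriers, with significance by resampling
  carrier-sized subsets from the whole sample.  Because E[X^2] = mu^2 +
  sigma^2, the statistic responds to both a mean shift (trend) and a
  variance inflation (heterogeneity) among carriers.
* ``rcs_test`` — collapsing logistic regression of the trait on carriage
  status (RCS), optionally with covariates (RCS-C); likelihood-ratio
  inference.
* ``calpha_test`` — C-alpha: a test of extra-binomial variance in the
  proportion of cases among the carriers of each variant; asymptotic normal
  or permutation p-values.
* ``skat_test`` — the sequence kernel association score test with a linear
  (optionally beta(1,25) MAF-weighted) kernel; asymptotic
  mixture-of-chi-squares or parametric-bootstrap p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._quadform import chi2_mixture_sf

__all__ = [
    "TestResult",
    "NullModel",
    "fit_null",
    "th_statistic",
    "th_test",
    "rcs_test",
    "calpha_statistic",
    "calpha_test",
    "skat_test",
]

# relative tolerance when counting resampled statistics >= observed, so that
# exact ties (degenerate resampling distributions) are counted as ties
_TIE_RTOL = 1e-9


def _chunks(total: int, size: int):
    while total > 0:
        take = min(total, size)
        yield take
        total -= take


@dataclass(frozen=True)
class TestResult:
    """Outcome of one gene-level association test."""

    method: str
    statistic: float
    p_value: float
    mode: str
    n_resamples: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class NullModel:
    """Logistic null model of the trait on covariates (intercept-only if none).

    ``residuals`` are Pearson residuals ``(y - mu) / sqrt(mu (1 - mu))``.
    """

    fitted_probs: np.ndarray
    residuals: np.ndarray
    design: np.ndarray  # intercept + covariates, n x (1 + k)


def _as_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    return np.column_stack([np.ones(n), cov])


def fit_null(y: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Fit the logistic null model and return fitted probabilities + residuals.

    Raises ``ValueError`` if ``y`` is single-class or the fit does not
    converge (including perfect separation).
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("phenotype must contain both cases and controls")
    x = _as_design(y.shape[0], covariates)

    if x.shape[1] == 1:
        # intercept-only MLE in closed form
        mu = np.full(y.shape[0], y.mean())
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            try:
                res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100)
            except Exception as exc:  # separation or IRLS failure
                raise ValueError(f"logistic null model did not converge: {exc}") from exc
        if not res.converged:
            raise ValueError("logistic null model did not converge within 100 iterations")
        mu = np.asarray(res.fittedvalues)
    eps = np.finfo(float).tiny
    if np.any(mu <= eps) or np.any(mu >= 1 - 1e-12):
        raise ValueError("fitted probabilities degenerate (separation?)")
    resid = (y - mu) / np.sqrt(mu * (1.0 - mu))
    return NullModel(fitted_probs=mu, residuals=resid, design=x)


def th_statistic(residuals: np.ndarray, carrier_index: np.ndarray) -> float:
    """Sum of squared mean-centered residuals over the carrier set."""
    r = np.asarray(residuals, dtype=float)
    idx = np.asarray(carrier_index)
    if idx.size == 0:
        raise ValueError("carrier set is empty")
    centered = r - r.mean()
    return float(np.sum(centered[idx] ** 2))


def th_test(
    y: np.ndarray,
    covariates: np.ndarray | None,
    carriage: np.ndarray,
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    with_replacement: bool = False,
    null: NullModel | None = None,
) -> TestResult:
    """Trend-and-heterogeneity test of the trait on rare-variant carriage.

    Pearson residuals from the logistic null model are treated as a
    quantitative trait; the observed statistic is the sum of their squares
    over the ``m`` carriers, and the reference distribution resamples ``m``
    residuals from all ``n`` (without replacement by default).  One-sided:
    large values indicate association.
    """
    rng = rng if rng is not None else np.random.default_rng()
    g = np.asarray(carriage).astype(bool)
    n = g.shape[0]
    m = int(g.sum())
    if m == 0:
        return TestResult("TH", 0.0, 1.0, "resampling", n_resamples, degenerate=True)
    model = null if null is not None else fit_null(y, covariates)
    r = model.residuals - model.residuals.mean()
    r2 = r**2
    obs = float(r2[g].sum())
    if m == n:
        return TestResult("TH", obs, 1.0, "resampling", n_resamples, degenerate=True)

    thresh = obs - _TIE_RTOL * max(1.0, abs(obs))
    k = 0
    # chunked so large resample counts stay within a few tens of MB
    for chunk in _chunks(n_resamples, max(1, 2**21 // max(n, 1))):
        if with_replacement:
            idx = rng.integers(0, n, size=(chunk, m))
        else:
            u = rng.random((chunk, n), dtype=np.float32)
            idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        star = r2[idx].sum(axis=1)
        k += int(np.count_nonzero(star >= thresh))
    p = (1.0 + k) / (n_resamples + 1.0)
    return TestResult("TH", obs, p, "resampling", n_resamples)


def _logistic_llf(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Fit a logistic model, returning (log-likelihood, params, clean_fit).

    On separation or non-convergence the best achieved finite log-likelihood
    is returned with ``clean_fit=False`` and a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100)
            return float(res.llf), np.asarray(res.params), bool(res.converged)
        except Exception:
            pass
    warnings.warn(
        "separation or non-convergence in logistic fit; using the largest "
        "finite-likelihood iterate",
        RuntimeWarning,
        stacklevel=3,
    )
    res = sm.Logit(y, x).fit(method="lbfgs", maxiter=200, disp=0)
    return float(res.llf), np.asarray(res.params), False


def rcs_test(
    y: np.ndarray,
    carriage: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    null: NullModel | None = None,
) -> TestResult:
    """Collapsing logistic regression on carriage status (RCS / RCS-C).

    Likelihood-ratio test, 1 df, of the model with carriage against the
    nested model without it.  ``method`` is RCS-C when covariates are given.
    A pre-fitted ``null`` (of y on the same covariates) supplies the reduced
    model's likelihood.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("phenotype must contain both cases and controls")
    g = np.asarray(carriage, dtype=float)
    tag = "RCS" if covariates is None else "RCS-C"
    x0 = _as_design(y.shape[0], covariates)
    if g.min() == g.max():
        return TestResult(tag, 0.0, 1.0, "asymptotic", degenerate=True)
    x1 = np.column_stack([x0, g])
    if null is not None and null.design.shape == x0.shape:
        mu0 = null.fitted_probs
        llf0 = float(y @ np.log(mu0) + (1.0 - y) @ np.log1p(-mu0))
    else:
        llf0, _, _ = _logistic_llf(y, x0)
    llf1, _, _ = _logistic_llf(y, x1)
    lrt = max(0.0, 2.0 * (llf1 - llf0))
    p = float(stats.chi2.sf(lrt, df=1))
    return TestResult(tag, lrt, p, "asymptotic")


def calpha_statistic(
    case_counts: np.ndarray, copy_counts: np.ndarray, p0: float
) -> tuple[float, float]:
    """C-alpha overdispersion statistic ``T`` and its null variance ``c``.

    For variant ``j`` with ``n_j`` minor-allele copies, ``y_j`` of them in
    cases, and null case fraction ``p0``:

        T = sum_j (y_j - n_j p0)^2 - n_j p0 (1 - p0)

    ``c`` sums the exact per-variant variances of the bracketed term under
    ``y_j ~ Binomial(n_j, p0)``, enumerated over all copy configurations.
    Both are additive over variants; singletons contribute nothing at
    ``p0 = 0.5``.
    """
    yj = np.asarray(case_counts, dtype=float)
    nj = np.asarray(copy_counts, dtype=float)
    if np.any(yj < 0) or np.any(yj > nj):
        raise ValueError("need 0 <= case_counts <= copy_counts")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    t = float(np.sum((yj - nj * p0) ** 2 - nj * p0 * (1.0 - p0)))

    c = 0.0
    for n in np.unique(nj[nj > 0]).astype(int):
        u = np.arange(n + 1)
        f = (u - n * p0) ** 2 - n * p0 * (1.0 - p0)
        pmf = stats.binom.pmf(u, n, p0)
        mean = float(pmf @ f)  # zero analytically; kept for exactness
        var = float(pmf @ (f - mean) ** 2)
        c += var * int(np.sum(nj == n))
    return t, c


def calpha_test(
    genotypes: np.ndarray,
    y: np.ndarray,
    mode: str = "asymptotic",
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """C-alpha test of extra-binomial variance in per-variant case counts.

    ``p0`` is the sample case fraction.  The permutation mode permutes
    case/control labels and recomputes ``T`` only: both ``p0`` and the
    variance term ``c`` depend on the per-variant copy counts alone and are
    permutation-invariant, so holding them fixed is exact, not an
    approximation.
    """
    if mode not in ("asymptotic", "permutation"):
        raise ValueError("mode must be 'asymptotic' or 'permutation'")
    geno = np.asarray(genotypes)
    y = np.asarray(y)
    nj = geno.sum(axis=0).astype(float)
    if not np.any(nj > 0):
        raise ValueError("need at least one variant with at least one copy")
    n = y.shape[0]
    n1 = int(y.sum())
    p0 = n1 / n
    yj = (y.astype(float) @ geno).astype(float)
    t, c = calpha_statistic(yj, nj, p0)
    tag = "CA" if mode == "asymptotic" else "CA-P"

    if mode == "asymptotic":
        if c <= 0:
            return TestResult(tag, t, 1.0, "asymptotic", degenerate=True)
        z = t / np.sqrt(c)
        return TestResult(tag, z, float(stats.norm.sf(z)), "asymptotic")

    rng = rng if rng is not None else np.random.default_rng()
    # Only subjects carrying >=1 variant contribute to the y_j; under a label
    # permutation their labels are a without-replacement sample from y.
    rows = np.flatnonzero(geno.any(axis=1))
    m = rows.size
    xc = geno[rows].astype(float)
    k = rng.hypergeometric(n1, n - n1, m, size=n_permutations)
    ranks = np.argsort(rng.random((n_permutations, m)), axis=1)
    labels = (np.argsort(ranks, axis=1) < k[:, None]).astype(float)
    yj_star = labels @ xc
    t_star = np.sum((yj_star - nj * p0) ** 2 - nj * p0 * (1.0 - p0), axis=1)
    kk = int(np.count_nonzero(t_star >= t - _TIE_RTOL * max(1.0, abs(t))))
    p = (1.0 + kk) / (n_permutations + 1.0)
    return TestResult(tag, t, p, "permutation", n_permutations)


def _beta_maf_weights(geno: np.ndarray) -> np.ndarray:
    """Squared beta(1,25)-density weights of each variant's sample MAF."""
    maf = geno.mean(axis=0) / 2.0
    maf = np.clip(maf, 1e-12, 0.5)
    w = stats.beta.pdf(maf, 1, 25)
    return w**2


def skat_test(
    y: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray | None = None,
    weights: str = "beta",
    mode: str = "asymptotic",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    null: NullModel | None = None,
) -> TestResult:
    """Sequence kernel association (variance-component score) test.

    ``Q = (y - mu)' G W G' (y - mu)`` with ``mu`` from the logistic null
    model and ``W`` the squared beta(1,25)-density weights of each variant's
    sample MAF (identity when ``weights='unweighted'``).  The asymptotic null
    is the matching mixture of 1-df chi-squares (numerical characteristic
    function inversion, moment-matching fallback); the bootstrap mode
    redraws ``y* ~ Bernoulli(mu)`` and recomputes the score with a one-step
    covariate-projection correction in place of a per-replicate refit.
    """
    if mode not in ("asymptotic", "bootstrap"):
        raise ValueError("mode must be 'asymptotic' or 'bootstrap'")
    if weights not in ("beta", "unweighted"):
        raise ValueError("weights must be 'beta' or 'unweighted'")
    y = np.asarray(y, dtype=float)
    geno = np.asarray(genotypes, dtype=float)
    poly = geno.std(axis=0) > 0
    tag = "SK" if mode == "asymptotic" else "SK-R"
    if not poly.any():
        return TestResult(tag, 0.0, 1.0, mode, degenerate=True)
    geno = geno[:, poly]

    model = null if null is not None else fit_null(y, covariates)
    mu = model.fitted_probs
    x = model.design
    w = _beta_maf_weights(geno) if weights == "beta" else np.ones(geno.shape[1])
    a = geno * np.sqrt(w)  # n x v, columns already weight-scaled
    r = y - mu
    q = float(np.sum((a.T @ r) ** 2))

    v = mu * (1.0 - mu)
    xtvx_inv = np.linalg.inv(x.T @ (x * v[:, None]))
    # Z' P0 Z with P0 = V - V X (X'VX)^-1 X' V
    va = a * v[:, None]
    m_mat = a.T @ va - (va.T @ x) @ xtvx_inv @ (x.T @ va)
    lam = np.linalg.eigvalsh(m_mat)

    if mode == "asymptotic":
        p = chi2_mixture_sf(q, lam)
        return TestResult(tag, q, p, "asymptotic")

    rng = rng if rng is not None else np.random.default_rng()
    n = y.shape[0]
    # Q* = || a' P r* ||^2 with the one-step refit correction
    # P = I - V X (X'VX)^-1 X', expressed through the p x v matrix below
    corr = xtvx_inv @ ((x * v[:, None]).T @ a)  # p x v
    mu32 = mu.astype(np.float32)
    a32 = a.astype(np.float32)
    x32 = x.astype(np.float32)
    mua = mu32 @ a32
    mux = mu32 @ x32
    corr32 = corr.astype(np.float32)
    thresh = q - _TIE_RTOL * max(1.0, abs(q))
    k = 0
    for chunk in _chunks(n_boot, max(1, 2**22 // max(n, 1))):
        ystar = (rng.random((chunk, n), dtype=np.float32) < mu32).astype(np.float32)
        t1 = ystar @ a32 - mua  # a'(y* - mu)
        xs = ystar @ x32 - mux  # X'(y* - mu)
        qstar = np.sum((t1 - xs @ corr32) ** 2, axis=1, dtype=np.float64)
        k += int(np.count_nonzero(qstar >= thresh))
    p = (1.0 + k) / (n_boot + 1.0)
    return TestResult(tag, q, p, "bootstrap", n_boot)
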