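"""Univariate variance-component score test and quadratic-form null laws.

The region statistic is the SKAT-type quadratic form

    Q = r' G W G' r / sigma2_hat,

where r are the residuals of the phenotype regressed on covariates, G the
N x v dosage matrix of the region, and W = diag(w) the variant weights.
Under the null hypothesis of no association, Q is distributed as a weighted
mixture of independent 1-df chi-squares whose weights are the eigenvalues of
W^{1/2} G' P G W^{1/2} with P the residual-projection matrix of the
covariate design.  Tail probabilities of that mixture are computed exactly
by Imhof-style numerical inversion of the characteristic function, with a
four-moment (Liu-type) approximation as a recorded fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "MixtureSpec",
    "UnivariateNullModel",
    "fit_null_univariate",
    "skat_q",
    "skat_test",
    "mixture_chisq_p",
    "mixture_chisq_quantile",
    "adjusted_univariate_p",
    "single_variant_wald",
]

#: relative threshold below which eigenvalues are treated as numerically zero
EIG_RTOL = 1e-10


@dataclass
class MixtureSpec:
    """Eigenvalue weights of a sum-of-chi-squares null distribution."""

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float).ravel()
        lam = lam[lam > 0]
        if lam.size:
            lam = lam[lam >= EIG_RTOL * lam.max()]
        self.eigenvalues = np.sort(lam)[::-1]

    @property
    def rank(self) -> int:
        return int(self.eigenvalues.size)


@dataclass
class UnivariateNullModel:
    """OLS null fit of one trait on the covariate design (with intercept)."""

    design: np.ndarray        # N x p design including intercept
    q_basis: np.ndarray       # orthonormal column basis of the design
    coefficients: np.ndarray  # length p
    residuals: np.ndarray     # length N
    sigma2: float             # residual variance, r'r / (N - p)

    @property
    def n_samples(self) -> int:
        return self.design.shape[0]

    def project_out(self, M: np.ndarray) -> np.ndarray:
        """P @ M with P = I - X (X'X)^-1 X' (covariate projection)."""
        return M - self.q_basis @ (self.q_basis.T @ M)


def _check_full_rank(X: np.ndarray, names=None) -> np.ndarray:
    """QR basis of X, raising with the offending columns if rank-deficient."""
    qx, rx = np.linalg.qr(X)
    diag = np.abs(np.diag(rx))
    bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        labels = (
            [names[i] for i in bad]
            if names is not None
            else [f"column {i}" for i in bad]
        )
        raise ValueError(f"covariate design is rank deficient: {', '.join(labels)}")
    return qx


def fit_null_univariate(y: np.ndarray, X: np.ndarray, names=None) -> UnivariateNullModel:
    """Least-squares fit of y on X (X must already include an intercept)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    qx = _check_full_rank(X, names)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    sigma2 = float(r @ r) / (n - p)
    # a numerically perfect fit leaves no residual variation to test against
    if sigma2 <= 1e-12 * max(float(np.var(y)), np.finfo(float).tiny):
        sigma2 = 0.0
    return UnivariateNullModel(
        design=X, q_basis=qx, coefficients=coef, residuals=r, sigma2=sigma2
    )


def _drop_null_columns(G: np.ndarray, w: np.ndarray):
    """Remove all-zero (monomorphic in-sample) genotype columns."""
    keep = np.ptp(G, axis=0) > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} genotype column(s) with no "
            "dosage variation",
            stacklevel=3,
        )
    return G[:, keep], w[keep]


def skat_q(null: UnivariateNullModel, G: np.ndarray, w=None):
    """Variance-component score statistic and its null mixture for one trait.

    Returns ``(Q, MixtureSpec)``.  ``w`` defaults to identical weights.
    If every genotype column is monomorphic the mixture is empty and the
    caller should report p = 1.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != null.n_samples:
        raise ValueError("genotype rows must match the null model's samples")
    v = G.shape[1]
    if v < 1:
        raise ValueError("need at least one variant")
    if null.sigma2 <= 0:
        raise ValueError("null model has zero residual variance (degenerate fit)")
    w = np.ones(v) if w is None else np.asarray(w, dtype=float).ravel()
    if w.shape[0] != v:
        raise ValueError("weight vector length must match variant count")
    G, w = _drop_null_columns(G, w)
    if G.shape[1] == 0:
        return 0.0, MixtureSpec(np.array([]))
    Gw = G * np.sqrt(w)
    score = Gw.T @ null.residuals
    q = float(score @ score) / null.sigma2
    PGw = null.project_out(Gw)
    C = PGw.T @ PGw
    lam = np.linalg.eigvalsh(C)
    return q, MixtureSpec(lam)


def skat_test(null: UnivariateNullModel, G: np.ndarray, w=None) -> float:
    """Convenience wrapper returning the SKAT p-value (1.0 if no variation)."""
    q, spec = skat_q(null, G, w)
    if spec.rank == 0:
        return 1.0
    return mixture_chisq_p(spec, q)


def adjusted_univariate_p(p_per_trait) -> float:
    """Minimum of the per-trait univariate p-values (no extra correction)."""
    p = np.asarray(p_per_trait, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one per-trait p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.min())


def single_variant_wald(y: np.ndarray, X: np.ndarray, g: np.ndarray):
    """Wald test of a single variant: regress y on [X, g], test g's slope.

    Returns ``(beta_hat, p_value)``.
    """
    import statsmodels.api as sm

    g = np.asarray(g, dtype=float).ravel()
    if np.ptp(g) == 0:
        raise ValueError("variant has no dosage variation")
    design = np.column_stack([np.atleast_2d(np.asarray(X, float)), g])
    _check_full_rank(design)
    fit = sm.OLS(np.asarray(y, float).ravel(), design).fit()
    return float(fit.params[-1]), float(fit.pvalues[-1])


# ---------------------------------------------------------------------------
# mixture-of-chi-squares tail probabilities
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


def _imhof_theta_rho(u: np.ndarray, lam: np.ndarray, q: float):
    lu = np.multiply.outer(u, lam)
    theta = 0.5 * np.arctan(lu).sum(axis=-1) - 0.5 * q * u
    log_rho = 0.25 * np.log1p(lu * lu).sum(axis=-1)
    return theta, log_rho


def _imhof_cutoff(lam: np.ndarray, eps: float):
    """Upper integration limit U with integrand envelope < eps beyond it.

    Solves 0.25 * sum(log1p(lam^2 u^2)) = log(1/eps) by doubling plus
    bisection.  Returns None when the envelope decays too slowly (fewer
    than ~3 effective eigenvalues at the cutoff), signalling that adaptive
    quadrature should be used instead.
    """
    target = np.log(1.0 / eps)
    # vectorized coarse search on a geometric grid, then log-log interpolation;
    # a slight overshoot of U only costs a few extra panels
    u_grid = np.exp2(np.arange(-6.0, 42.0))
    log_rho = 0.25 * np.log1p(np.multiply.outer(u_grid, lam) ** 2).sum(axis=1)
    idx = np.searchsorted(log_rho, target)
    if idx >= u_grid.size:
        return None
    if idx == 0:
        u_cut = float(u_grid[0])
    else:
        frac = (target - log_rho[idx - 1]) / (log_rho[idx] - log_rho[idx - 1])
        u_cut = float(u_grid[idx - 1] * 2.0 ** (frac * 1.1))
    lu2 = (lam * u_cut) ** 2
    s = 0.5 * np.sum(lu2 / (1.0 + lu2))  # local decay exponent of 1/(u rho)
    if s < 1.5:
        return None
    return u_cut


def _imhof_fixed_panels(q: float, lam: np.ndarray, eps: float = 1e-13):
    """Composite Gauss-Legendre evaluation of the Imhof integral.

    Valid (fast) when the integrand decays quickly, i.e. for spectra with
    enough eigenvalues; panel width is chosen so the oscillation phase
    advances by at most ~pi per panel.  Returns None when the spectrum is
    too small/spread for the cutoff bound, signalling the caller to use
    adaptive quadrature instead.
    """
    u_cut = _imhof_cutoff(lam, eps)
    if u_cut is None:
        return None
    h = 2.0 * np.pi / (q + lam.sum())
    n_panels = int(np.ceil(u_cut / h))
    if n_panels > 200_000:
        return None
    half = 0.5 * h
    starts = h * np.arange(n_panels)
    u = (starts[:, None] + half + half * _GL_NODES).ravel()
    theta, log_rho = _imhof_theta_rho(u, lam, q)
    vals = np.sin(theta) * np.exp(-log_rho) / u
    return half * float(np.sum(vals.reshape(n_panels, 16) @ _GL_WEIGHTS))


def _ruben_tail(q: float, lam: np.ndarray, eps: float = 1e-14, max_terms: int = 20_000):
    """P(Q >= q) by Ruben's series: Q written as an exact nonnegative
    mixture of central chi-squares with n, n+2, n+4, ... degrees of
    freedom, scale beta = min(lam).

    All mixture weights are nonnegative, so truncation error is bounded by
    the un-accumulated weight and relative accuracy holds even far in the
    tail.  Returns None when the series converges too slowly (very spread
    eigenvalues).
    """
    n = lam.size
    beta = lam.min()
    r = 1.0 - beta / lam  # in [0, 1)
    c = np.empty(max_terms)
    c[0] = np.exp(0.5 * np.sum(np.log(beta / lam)))
    if c[0] == 0.0:
        return None
    g = np.empty(max_terms)
    mass = c[0]
    k_used = max_terms
    for k in range(1, max_terms):
        g[k] = np.sum(r**k)
        c[k] = 0.5 / k * float(g[1 : k + 1][::-1] @ c[:k])
        mass += c[k]
        if 1.0 - mass < eps:
            k_used = k + 1
            break
    else:
        return None
    ks = np.arange(k_used)
    tail = float(c[:k_used] @ stats.chi2.sf(q / beta, n + 2 * ks))
    # the neglected mixture mass contributes at most (1 - mass) to the tail
    return min(tail + max(1.0 - mass, 0.0), 1.0)


def _imhof_quad(q: float, lam: np.ndarray):
    def f(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        log_rho = 0.25 * np.sum(np.log1p((lam * u) ** 2))
        return np.sin(theta) * np.exp(-log_rho) / u

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            f, 0.0, np.inf, epsabs=1e-12, epsrel=1e-10, limit=500
        )
    return val, err


def _liu_params(lam: np.ndarray):
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q, sigma_q = c1, np.sqrt(2.0 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    return df, delta, mu_q, sigma_q, mu_x, sigma_x


def _liu_p(q: float, lam: np.ndarray) -> float:
    df, delta, mu_q, sigma_q, mu_x, sigma_x = _liu_params(lam)
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def mixture_chisq_p(spec, q: float, return_method: bool = False):
    """P(sum_l lambda_l Z_l^2 >= q) for independent standard normals Z_l.

    Exact characteristic-function inversion (Imhof) with chi-square special
    cases; falls back to the Liu four-moment approximation when inversion
    is unreliable (far tails).  With ``return_method=True`` also returns
    which method produced the value (``"exact"`` or ``"liu"``).
    """
    lam = spec.eigenvalues if isinstance(spec, MixtureSpec) else MixtureSpec(spec).eigenvalues
    if lam.size == 0:
        raise ValueError("mixture has no positive eigenvalues")
    if q <= 0:
        return (1.0, "exact") if return_method else 1.0
    # scale invariance: normalize so the largest eigenvalue is 1; this keeps
    # p-values bit-stable under rescaling of (q, lambda)
    lmax = lam[0]
    lam = lam / lmax
    q = q / lmax

    method = "exact"
    if lam.size == 1:
        p = float(stats.chi2.sf(q, 1))
    elif np.all(lam == lam[0]):
        p = float(stats.chi2.sf(q / lam[0], lam.size))
    else:
        p = None
        if lam.size >= 6:
            val = _imhof_fixed_panels(q, lam)
            if val is not None:
                p = 0.5 + val / np.pi
        if p is None:
            p = _ruben_tail(q, lam)
        if p is None:
            val, err = _imhof_quad(q, lam)
            if np.isfinite(val) and err <= max(1e-7, 0.5 * abs(val)):
                p = 0.5 + val / np.pi
        if p is None or not np.isfinite(p) or p <= 1e-12 or p > 1 + 1e-9:
            p = _liu_p(q, lam)
            method = "liu"
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return (p, method) if return_method else p


def mixture_chisq_quantile(spec, p: float) -> float:
    """q such that ``mixture_chisq_p(spec, q) == p`` (upper-tail quantile)."""
    lam = spec.eigenvalues if isinstance(spec, MixtureSpec) else MixtureSpec(spec).eigenvalues
    if lam.size == 0:
        raise ValueError("mixture has no positive eigenvalues")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    df, delta, mu_q, sigma_q, mu_x, sigma_x = _liu_params(lam)
    x = stats.ncx2.isf(p, df, delta) if delta > 0 else stats.chi2.isf(p, df)
    guess = max((x - mu_x) / sigma_x * sigma_q + mu_q, 1e-8 * lam[0])

    def g(q):
        return mixture_chisq_p(lam, q) - p

    # g is decreasing in q: lo must sit where g >= 0, hi where g <= 0
    lo = hi = guess
    for _ in range(200):
        if g(lo) >= 0:
            break
        lo *= 0.5
    for _ in range(200):
        if g(hi) <= 0:
            break
        hi *= 2.0
    if g(lo) * g(hi) > 0:
        raise RuntimeError("failed to bracket the mixture quantile")
    # quantiles feed Monte-Carlo exceedance thresholds; 1e-7 relative
    # accuracy on q keeps the induced p error far below Monte-Carlo noise
    return float(optimize.brentq(g, lo, hi, xtol=1e-10 * max(hi, 1.0), rtol=1e-7))
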