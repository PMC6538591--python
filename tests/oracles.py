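"""Independent numerical oracles used to validate the analytic Bayes factors.

Nothing here touches the package's own Bayes-factor code paths: the
fractional marginal likelihoods are evaluated by brute-force quadrature,
and orthant probabilities come from closed-form results for elliptical
distributions.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate


def centered_orthant2(rho: float) -> float:
    """Pr(X1 > 0, X2 > 0) for a centred bivariate elliptical distribution.

    Depends only on the correlation: 1/4 + arcsin(rho) / (2 pi).
    """
    return 0.25 + np.arcsin(rho) / (2.0 * np.pi)


def _log_integral_sigma2(logf, u_lo: float, u_hi: float) -> float:
    """log of integral f(sigma2) d sigma2 via the substitution sigma2 = e^u."""
    us = np.linspace(u_lo, u_hi, 401)
    logvals = np.array([logf(np.exp(u)) + u for u in us])
    peak = float(np.max(logvals))
    u_peak = float(us[np.argmax(logvals)])
    val, _ = integrate.quad(
        lambda u: np.exp(logf(np.exp(u)) + u - peak),
        u_lo,
        u_hi,
        limit=400,
        points=[u_peak - 2.0, u_peak, u_peak + 2.0],
    )
    return peak + np.log(val)


def fractional_bf_null_oracle(y: np.ndarray, x: np.ndarray) -> float:
    """Brute-force Bayes factor for H0: beta = 0 in y = beta x + noise.

    The default Bayes factor is the ratio of fractional marginal
    likelihoods p*_0(y) / p*_u(y), each defined as the full marginal
    likelihood under the noninformative prior sigma^-2 divided by the
    marginal of the fraction-b likelihood whose quadratic has been
    relocated to the null value (b = (k + 1)/n, here 2/n).  All four
    marginals are computed by direct quadrature over (beta, sigma2).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    a = float(x @ x)
    beta_hat = float(x @ y) / a
    ss0 = float(y @ y)
    s2 = ss0 - a * beta_hat**2
    b = 2.0 / n

    def loglik(beta, v, power=1.0, relocate=False):
        center = 0.0 if relocate else beta_hat
        quad = s2 + a * (beta - center) ** 2
        return power * (-0.5 * n * np.log(2 * np.pi * v) - 0.5 * quad / v)

    u_mid = np.log(ss0 / n)
    # the fraction-b marginals have heavy (Cauchy-like) upper tails in
    # sigma2, so the integration range is deliberately very wide
    u_lo, u_hi = u_mid - 25.0, u_mid + 45.0

    def log_marg_2d(power, relocate):
        def logf(v):
            center = 0.0 if relocate else beta_hat
            # conditional on v the integrand is Gaussian with sd
            # sqrt(v / (a * power)); widen the limits accordingly
            blim = 40.0 * np.sqrt(v / (a * power))
            peak = loglik(center, v, power, relocate)
            val, _ = integrate.quad(
                lambda beta: np.exp(
                    loglik(beta, v, power, relocate) - peak
                ),
                center - blim,
                center + blim,
                limit=200,
            )
            return peak + np.log(val) - np.log(v)  # sigma^-2 prior

        return _log_integral_sigma2(logf, u_lo, u_hi)

    def log_marg_null(power, relocate):
        def logf(v):
            return loglik(0.0, v, power, relocate) - np.log(v)

        return _log_integral_sigma2(logf, u_lo, u_hi)

    log_m_u = log_marg_2d(1.0, relocate=False)
    log_m_0 = log_marg_null(1.0, relocate=False)
    log_mb_u = log_marg_2d(b, relocate=True)
    log_mb_0 = log_marg_null(b, relocate=True)
    return float(np.exp((log_m_0 - log_mb_0) - (log_m_u - log_mb_u)))


def conditional_t_moments(mu, S, df, idx_cond, value):
    """Generic conditional location/scale of a multivariate Student-t.

    For xi ~ t(mu, S, df) partitioned into conditioning block ``idx_cond``
    (set to ``value``) and the rest, returns the standard conditional
    location and the conditional scale including the quadratic-form
    inflation (df + d(value)) / (df + q).
    """
    mu = np.asarray(mu, float)
    S = np.asarray(S, float)
    d = mu.size
    idx_cond = list(idx_cond)
    idx_free = [i for i in range(d) if i not in idx_cond]
    S11 = S[np.ix_(idx_cond, idx_cond)]
    S21 = S[np.ix_(idx_free, idx_cond)]
    S22 = S[np.ix_(idx_free, idx_free)]
    dev = np.asarray(value, float) - mu[idx_cond]
    sol = np.linalg.solve(S11, dev)
    loc = mu[idx_free] + S21 @ sol
    mahal = float(dev @ sol)
    q = len(idx_cond)
    scale = (df + mahal) / (df + q) * (S22 - S21 @ np.linalg.solve(S11, S21.T))
    return loc, scale
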