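"""Deterministic regression-data generators for tests and examples.

Two generators are provided.  :func:`generate_regression` draws a small
regression dataset with controllable true coefficients, error scale, and
predictor correlation — the sampling model behind the consistency
properties of the test.  :func:`generate_exact_mle` constructs a dataset
whose OLS statistics *exactly* equal prescribed targets, which makes
analytic expectations seed-independent: the Bayes factors depend on the
data only through ``(beta_hat, s2, X'X, n)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimSpec", "generate_regression", "generate_exact_mle"]


@dataclass(frozen=True)
class SimSpec:
    """Study design for one simulated regression dataset.

    ``beta_true`` lists the intercept first, then one coefficient per
    predictor.  ``predictor_corr`` is the correlation matrix of the
    predictors (unit diagonal, positive definite); predictors are drawn
    zero-mean multivariate normal.  ``sigma`` is the error standard
    deviation.
    """

    n: int
    beta_true: tuple
    sigma: float = 1.0
    predictor_corr: np.ndarray | None = None
    seed: int = 0
    standardize_predictors: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "beta_true", tuple(float(b) for b in self.beta_true)
        )
        p = len(self.beta_true) - 1
        if p < 1:
            raise ValueError("beta_true must list the intercept plus >= 1 slope")
        if self.n <= len(self.beta_true):
            raise ValueError("need n > number of coefficients")
        corr = self.predictor_corr
        if corr is None:
            corr = np.eye(p)
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"predictor_corr must be {p}x{p}")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix needs a unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ValueError("correlation matrix must be positive definite") from None
        object.__setattr__(self, "predictor_corr", corr)
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.sigma == 0:
            warnings.warn(
                "sigma=0 produces a perfect fit; model fitting will reject s2=0",
                stacklevel=2,
            )


def generate_regression(spec: SimSpec) -> pd.DataFrame:
    """Simulate ``y = b0 + X b + sigma * noise`` with correlated predictors.

    Fully reproducible from ``spec.seed``; columns are ``y, x1, ..., xp``.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.beta_true) - 1
    L = np.linalg.cholesky(spec.predictor_corr)
    X = rng.standard_normal((spec.n, p)) @ L.T
    if spec.standardize_predictors:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    beta = np.asarray(spec.beta_true)
    y = beta[0] + X @ beta[1:] + spec.sigma * rng.standard_normal(spec.n)
    table = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    table.insert(0, "y", y)
    return table


def generate_exact_mle(
    beta_hat_target,
    s2_target: float,
    xtx_target,
    n: int,
    seed: int = 0,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Construct data whose OLS fit reproduces the targets exactly.

    The design is ``X = Q L'`` with ``L L' = xtx_target`` (Cholesky) and
    ``Q`` a random n-by-k orthonormal frame, so ``X'X = xtx_target`` to
    machine precision.  The response is ``y = X beta_hat_target + e`` with
    ``e`` in the orthogonal complement of the columns of ``X`` and
    ``||e||^2 = s2_target``, so refitting returns exactly the prescribed
    ``(beta_hat, s2, X'X, n)``.  Different seeds give different raw data
    but identical sufficient statistics — and therefore identical Bayes
    factors.

    The returned columns are the literal design columns; fit them with an
    intercept-suppressing formula (``"y ~ x1 + x2 - 1"``), since the
    construction does not produce a column of ones.
    """
    beta = np.atleast_1d(np.asarray(beta_hat_target, dtype=float))
    xtx = np.atleast_2d(np.asarray(xtx_target, dtype=float))
    k = beta.size
    if xtx.shape != (k, k):
        raise ValueError(f"xtx_target must be {k}x{k}")
    if n - k < 1:
        raise ValueError("need n - k >= 1 residual directions")
    if not s2_target > 0:
        raise ValueError("s2_target must be positive")
    L = np.linalg.cholesky(xtx)
    rng = np.random.default_rng(seed)
    # orthonormal frame spanning k+1 directions: k for X, one for the residual
    G = rng.standard_normal((n, k + 1))
    Q, _ = np.linalg.qr(G)
    X = Q[:, :k] @ L.T
    e = Q[:, k] * np.sqrt(s2_target)
    y = X @ beta + e
    if names is None:
        names = [f"x{j + 1}" for j in range(k)]
    table = pd.DataFrame(X, columns=names)
    table.insert(0, "y", y)
    return table
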