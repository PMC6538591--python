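"""Linear-model ingestion: sufficient statistics for the Bayes factor test.

The whole testing procedure depends on the data only through the OLS
sufficient statistics ``(beta_hat, s2, X'X, n, k)``, where ``s2`` is the
residual *sum of squares* (not a variance estimate).  Two entry points are
provided: :func:`fit_linear_model`, which fits a formula to a data table,
and :func:`fit_from_summaries`, which accepts precomputed statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LinearModelFit", "fit_linear_model", "fit_from_summaries", "ModelError"]

logger = logging.getLogger(__name__)

INTERCEPT_NAME = "(Intercept)"


class ModelError(ValueError):
    """Raised when a design matrix or summary statistics are unusable."""


@dataclass(frozen=True)
class LinearModelFit:
    """Sufficient statistics of an ordinary least-squares fit.

    Attributes
    ----------
    coef_names : list of str
        Names of the design columns, intercept first when present.
    beta_hat : ndarray, shape (k,)
        OLS estimates ``(X'X)^{-1} X'y``.
    xtx : ndarray, shape (k, k)
        Cross-product matrix ``X'X`` (symmetric positive definite).
    s2 : float
        Residual sum of squares ``(y - X beta_hat)'(y - X beta_hat)``.
    n : int
        Number of observations used in the fit.
    k : int
        Number of design columns (including any intercept).
    fraction_b : float
        Minimal training fraction ``(k + 1) / n`` used to build the
        implicit default prior (one variance plus k coefficients).
    """

    coef_names: list[str]
    beta_hat: np.ndarray
    xtx: np.ndarray
    s2: float
    n: int
    k: int
    fraction_b: float = field(default=0.0)

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta_hat, dtype=float))
        xtx = np.atleast_2d(np.asarray(self.xtx, dtype=float))
        object.__setattr__(self, "beta_hat", beta)
        object.__setattr__(self, "xtx", xtx)
        k = beta.size
        if len(self.coef_names) != k:
            raise ModelError(
                f"{len(self.coef_names)} coefficient names for {k} coefficients"
            )
        if xtx.shape != (k, k):
            raise ModelError(f"X'X has shape {xtx.shape}, expected ({k}, {k})")
        if not np.allclose(xtx, xtx.T, rtol=1e-10, atol=1e-10):
            raise ModelError("X'X must be symmetric")
        # positive definiteness == full column rank of the design
        try:
            np.linalg.cholesky(xtx)
        except np.linalg.LinAlgError:
            raise ModelError(
                "X'X is not positive definite (rank-deficient design)"
            ) from None
        if self.k != k:
            raise ModelError(f"k={self.k} inconsistent with beta_hat of length {k}")
        if self.n <= self.k:
            raise ModelError(
                f"n={self.n} observations cannot support k={self.k} coefficients "
                "(need n > k for positive residual degrees of freedom)"
            )
        if not self.s2 > 0:
            raise ModelError(
                "residual sum of squares must be positive: a perfect fit leaves "
                "no scale for the default prior"
            )
        object.__setattr__(self, "fraction_b", (self.k + 1) / self.n)

    @property
    def sigma(self) -> np.ndarray:
        """``(X'X)^{-1}``, the unscaled coefficient covariance."""
        return np.linalg.inv(self.xtx)

    def name_index(self, name: str) -> int:
        try:
            return self.coef_names.index(name)
        except ValueError:
            raise ModelError(
                f"unknown coefficient {name!r}; model has {self.coef_names}"
            ) from None


def _parse_formula(formula: str) -> tuple[str, list[str], bool]:
    """Split ``"y ~ x1 + x2 [- 1]"`` into (response, predictors, intercept).

    Only the additive subset of the formula language is supported: ``~``,
    ``+`` and the intercept-suppression tokens ``-1`` / leading ``0 +``.
    """
    if formula.count("~") != 1:
        raise ModelError(f"formula must contain exactly one '~': {formula!r}")
    lhs, rhs = (side.strip() for side in formula.split("~"))
    if not lhs:
        raise ModelError("formula has no response variable")
    intercept = True
    rhs = rhs.replace("-1", "+ __NOINT__").replace("- 1", "+ __NOINT__")
    terms = []
    for tok in rhs.split("+"):
        tok = tok.strip()
        if tok in ("", "1"):
            continue
        if tok in ("0", "__NOINT__"):
            intercept = False
            continue
        if any(ch in tok for ch in "*:^()-"):
            raise ModelError(
                f"unsupported formula term {tok!r}: only additive terms "
                "'y ~ x1 + x2' (optionally '-1') are accepted"
            )
        terms.append(tok)
    if not terms and not intercept:
        raise ModelError("formula names no predictor columns and no intercept")
    return lhs, terms, intercept


def fit_linear_model(
    table: pd.DataFrame, formula: str, standardize: bool = False
) -> LinearModelFit:
    """Fit a linear regression and return its sufficient statistics.

    Parameters
    ----------
    table : DataFrame
        Data with labelled columns.
    formula : str
        ``"y ~ x1 + x2"``; append ``-1`` to suppress the intercept.
    standardize : bool
        Replace every used column (response and predictors, never the
        intercept) by ``(value - mean) / sd`` before fitting, so that the
        coefficients are on a common standardized scale.

    Rows with missing values in any used column are dropped with a logged
    warning.
    """
    response, predictors, intercept = _parse_formula(formula)
    missing = [c for c in [response, *predictors] if c not in table.columns]
    if missing:
        raise ModelError(f"columns {missing} not found in table")
    used = table[[response, *predictors]].apply(pd.to_numeric, errors="coerce")
    complete = used.dropna()
    dropped = len(used) - len(complete)
    if dropped:
        logger.warning("dropped %d rows with missing values (listwise)", dropped)
    if standardize:
        sds = complete.std(ddof=1)
        degenerate = sds.index[~(sds > 0)].tolist()
        if degenerate:
            raise ModelError(
                f"cannot standardize zero-variance columns: {degenerate}"
            )
        complete = (complete - complete.mean()) / sds
    y = complete[response].to_numpy(dtype=float)
    X = complete[predictors].to_numpy(dtype=float)
    names = list(predictors)
    if intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = [INTERCEPT_NAME, *names]
    n, k = X.shape
    if n <= k:
        raise ModelError(f"n={n} rows after dropping NAs cannot support k={k} columns")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name a minimal set of columns that are linear combinations of
        # earlier ones, via greedy rank inspection in column order
        culprits, kept = [], np.empty((n, 0))
        for j, name in enumerate(names):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                culprits.append(name)
            else:
                kept = cand
        raise ModelError(f"design is rank deficient; collinear columns: {culprits}")
    xtx = X.T @ X
    beta_hat = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta_hat
    s2 = float(resid @ resid)
    return LinearModelFit(
        coef_names=names, beta_hat=beta_hat, xtx=xtx, s2=s2, n=n, k=k
    )


def fit_from_summaries(
    beta_hat, xtx, s2: float, n: int, names: list[str] | None = None
) -> LinearModelFit:
    """Build a :class:`LinearModelFit` from precomputed statistics.

    Downstream Bayes factors are identical to those from
    :func:`fit_linear_model` on any dataset with the same ``(beta_hat,
    s2, X'X, n)`` — the statistics are sufficient.
    """
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    k = beta_hat.size
    if names is None:
        names = [f"b{i + 1}" for i in range(k)]
    return LinearModelFit(
        coef_names=list(names), beta_hat=beta_hat, xtx=xtx, s2=float(s2),
        n=int(n), k=k,
    )
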