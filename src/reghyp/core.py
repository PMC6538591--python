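"""Fit/complexity components and default Bayes factors.

Each constrained hypothesis is compared against the unconstrained model
through a fit term (posterior density or probability of the constraints)
and a complexity term (the same quantity under the implicit default
prior).  The default prior is the fraction-``b`` posterior, ``b = (k+1)/n``,
relocated to the boundary of the constrained space; it is a multivariate
Cauchy (Student-t with one degree of freedom) with scale ``s2 (X'X)^{-1}``.

* Equality constraints: Savage-Dickey density ratio of posterior over
  relocated prior at the null value.
* Order constraints: ratio of posterior to prior probability that the
  constraints hold.
* Both kinds: the equality ratio times a conditional probability ratio in
  the transformed xi-coordinates.

Bayes factors against the unconstrained model combine through
transitivity into a full Bayes-factor matrix and, with prior hypothesis
probabilities, into posterior hypothesis probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hypotheses import ConstraintSystem
from .model import LinearModelFit
from .mvt import DEFAULT_MCREP, ProbEstimate, StudentTSpec, mvt_density, mvt_polytope_prob
from .transform import TransformedSystem, transform_system

__all__ = [
    "ConditionalMoments",
    "BFTerms",
    "TestResult",
    "bf_equality",
    "bf_order",
    "conditional_moments",
    "bf_combined",
    "bf_complement",
    "compute_bf",
    "posterior_probabilities",
    "bf_matrix",
    "bf_interval",
]


@dataclass(frozen=True)
class ConditionalMoments:
    """Moments of the conditional posterior and prior of the free directions.

    Conditioning the coefficient posterior (and relocated prior) on the
    equality constraints leaves Student-t distributions for ``xi_I`` whose
    location/scale are standard conditional-t expressions: ``mu_I_N`` is
    the conditional posterior mean, ``S_I_N`` the conditional posterior
    scale inflated by the Mahalanobis distance of ``r_E`` from ``R_E
    beta_hat``, and ``S_I_0`` the conditional prior scale.  ``r_star_I =
    Rtilde_I xi_hat_I`` is the boundary threshold at which the prior
    probability is evaluated, which centres the prior probability on its
    own boundary.
    """

    mu_I_N: np.ndarray
    S_I_N: np.ndarray
    S_I_0: np.ndarray
    r_star_I: np.ndarray
    xi_hat_I: np.ndarray
    post_df: int
    prior_df: int = 1


@dataclass
class BFTerms:
    """Fit/complexity decomposition of one hypothesis against H_u.

    Absent components (``None``) act as factors of 1 in
    ``B = (fE/cE) * (fI/cI)``.  ``ci90`` is present only when a Monte
    Carlo probability entered the computation.
    """

    label: str
    fE: float | None = None
    cE: float | None = None
    fI: ProbEstimate | None = None
    cI: ProbEstimate | None = None
    B: float = 1.0
    ci90: tuple[float, float] | None = None
    source: str = ""

    @property
    def uses_monte_carlo(self) -> bool:
        return any(
            p is not None and p.method == "monte_carlo" for p in (self.fI, self.cI)
        )

    @property
    def f(self) -> float | None:
        """Combined fit f = fE * fI (None when no equality part exists)."""
        if self.fE is None:
            return None
        return self.fE * (self.fI.value if self.fI is not None else 1.0)

    @property
    def c(self) -> float | None:
        if self.cE is None:
            return None
        return self.cE * (self.cI.value if self.cI is not None else 1.0)


@dataclass
class TestResult:
    """Joint outcome of a multiple-hypothesis test."""

    hypotheses: list[BFTerms]
    posterior_probs: np.ndarray
    prior_probs: np.ndarray
    bf_matrix: np.ndarray
    complement_added: bool = False
    seed: int | None = None
    mcrep: int = DEFAULT_MCREP

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.hypotheses]


def _assemble(label, fE=None, cE=None, fI=None, cI=None, source="") -> BFTerms:
    B = 1.0
    if fE is not None:
        if cE == 0:
            raise ZeroDivisionError("prior density at the null value is zero")
        B *= fE / cE
    if fI is not None:
        if cI.value == 0:
            raise ZeroDivisionError(
                "prior probability of the order constraints is numerically zero; "
                "increase mcrep"
            )
        B *= fI.value / cI.value
    terms = BFTerms(label=label, fE=fE, cE=cE, fI=fI, cI=cI, B=B, source=source)
    if terms.uses_monte_carlo:
        terms.ci90 = bf_interval(terms)
    return terms


def bf_equality(fit: LinearModelFit, sys: ConstraintSystem) -> BFTerms:
    """Savage-Dickey Bayes factor for a purely equality-constrained hypothesis.

    fit  = t(r_E; R_E beta_hat, s2 (n-k)^-1 R_E (X'X)^-1 R_E', n-k)
    comp = t(r_E; r_E,          s2          R_E (X'X)^-1 R_E', 1)
    """
    if sys.q_E < 1:
        raise ValueError("hypothesis has no equality constraints")
    Sigma = fit.sigma
    H = sys.R_E @ Sigma @ sys.R_E.T
    post = StudentTSpec(
        location=sys.R_E @ fit.beta_hat,
        scale=fit.s2 / (fit.n - fit.k) * H,
        df=fit.n - fit.k,
    )
    prior = StudentTSpec(location=sys.r_E, scale=fit.s2 * H, df=1)
    fE = mvt_density(sys.r_E, post)
    cE = mvt_density(sys.r_E, prior)
    return _assemble(sys.label, fE=fE, cE=cE, source=sys.source)


def bf_order(
    fit: LinearModelFit,
    sys: ConstraintSystem,
    mcrep: int = DEFAULT_MCREP,
    seed: int | None = None,
) -> BFTerms:
    """Bayes factor for a purely order-constrained hypothesis.

    Fit is the posterior probability of ``R_I beta > r_I`` under
    ``t(beta_hat, s2 (X'X)^-1/(n-k), n-k)``; complexity is the same
    probability under the relocated default prior
    ``t(R_I^- r_I, s2 (X'X)^-1, 1)`` centred on the constraint boundary.
    Monte Carlo streams for the two probabilities are independent.
    """
    if sys.q_I < 1 or sys.q_E:
        raise ValueError("hypothesis must contain only inequality constraints")
    Sigma = fit.sigma
    post = StudentTSpec(
        location=fit.beta_hat,
        scale=fit.s2 * Sigma / (fit.n - fit.k),
        df=fit.n - fit.k,
    )
    prior = StudentTSpec(
        location=np.linalg.pinv(sys.R_I) @ sys.r_I, scale=fit.s2 * Sigma, df=1
    )
    seed_f, seed_c = _child_seeds(seed)
    fI = mvt_polytope_prob(sys.R_I, sys.r_I, post, mcrep=mcrep, seed=seed_f)
    cI = mvt_polytope_prob(sys.R_I, sys.r_I, prior, mcrep=mcrep, seed=seed_c)
    return _assemble(sys.label, fI=fI, cI=cI, source=sys.source)


def conditional_moments(
    fit: LinearModelFit, tsys: TransformedSystem, sys: ConstraintSystem
) -> ConditionalMoments:
    """Conditional Student-t moments for the combined-constraint case."""
    if not 1 <= sys.q_E < fit.k:
        raise ValueError("requires 1 <= q_E < k")
    Sigma = fit.sigma
    D = tsys.D
    H = sys.R_E @ Sigma @ sys.R_E.T
    Hinv = np.linalg.inv(H)
    dev = sys.r_E - sys.R_E @ fit.beta_hat
    cross = D @ Sigma @ sys.R_E.T
    schur = D @ Sigma @ D.T - cross @ Hinv @ cross.T
    mu_I_N = D @ fit.beta_hat + cross @ (Hinv @ dev)
    inflation = 1.0 + float(dev @ Hinv @ dev) / fit.s2
    S_I_N = inflation * fit.s2 / (fit.n - fit.k + sys.q_E) * schur
    S_I_0 = fit.s2 / (1.0 + sys.q_E) * schur
    xi_hat_I = D @ fit.beta_hat
    r_star_I = tsys.Rtilde_I @ xi_hat_I
    return ConditionalMoments(
        mu_I_N=mu_I_N,
        S_I_N=S_I_N,
        S_I_0=S_I_0,
        r_star_I=r_star_I,
        xi_hat_I=xi_hat_I,
        post_df=fit.n - fit.k,
    )


def bf_combined(
    fit: LinearModelFit,
    sys: ConstraintSystem,
    mcrep: int = DEFAULT_MCREP,
    seed: int | None = None,
    tsys: TransformedSystem | None = None,
) -> BFTerms:
    """Bayes factor for a hypothesis with equality *and* order constraints.

    The equality part is the Savage-Dickey ratio of :func:`bf_equality`;
    the order part compares the conditional posterior probability of
    ``Rtilde_I xi_I > rtilde_I`` with the conditional prior probability of
    ``Rtilde_I xi_I > r_star_I``, the latter centred on its own boundary
    (for a single surviving inequality it is exactly 0.5 whatever the
    data).
    """
    if sys.q_E < 1 or sys.q_I < 1:
        raise ValueError("hypothesis must contain equality and order constraints")
    if sys.q_E >= fit.k:
        # saturated: the equalities already pin beta down to a point
        return bf_equality(fit, sys)
    eq = bf_equality(fit, sys)
    if tsys is None:
        tsys = transform_system(sys)
    cm = conditional_moments(fit, tsys, sys)
    post = StudentTSpec(location=cm.mu_I_N, scale=cm.S_I_N, df=cm.post_df)
    prior = StudentTSpec(location=cm.xi_hat_I, scale=cm.S_I_0, df=cm.prior_df)
    seed_f, seed_c = _child_seeds(seed)
    fI = mvt_polytope_prob(tsys.Rtilde_I, tsys.rtilde_I, post, mcrep=mcrep, seed=seed_f)
    cI = mvt_polytope_prob(tsys.Rtilde_I, cm.r_star_I, prior, mcrep=mcrep, seed=seed_c)
    return _assemble(sys.label, fE=eq.fE, cE=eq.cE, fI=fI, cI=cI, source=sys.source)


def compute_bf(
    fit: LinearModelFit,
    sys: ConstraintSystem,
    mcrep: int = DEFAULT_MCREP,
    seed: int | None = None,
) -> BFTerms:
    """Route a constraint system to the appropriate Bayes factor."""
    if sys.k != fit.k:
        raise ValueError("hypothesis and model disagree on the number of coefficients")
    if sys.q_E >= fit.k or (sys.q_E and not sys.q_I):
        return bf_equality(fit, sys)
    if sys.q_E:
        return bf_combined(fit, sys, mcrep=mcrep, seed=seed)
    return bf_order(fit, sys, mcrep=mcrep, seed=seed)


def bf_complement(
    order_terms: list[BFTerms], label: str = "Hc"
) -> BFTerms | None:
    """Bayes factor of the complement of all order-constrained hypotheses.

    Hypotheses with equality constraints occupy measure-zero sets and do
    not reduce the complement: only pure order hypotheses contribute,
    f_c = 1 - sum f_I and c_c = 1 - sum c_I (regions must be pairwise
    disjoint; the caller verifies this).  Returns ``None`` when the order
    regions already exhaust the space (c_c ~ 0), in which case no
    complement is added.
    """
    fs = [t.fI for t in order_terms if t.fI is not None and t.fE is None]
    cs = [t.cI for t in order_terms if t.cI is not None and t.cE is None]
    f_c = 1.0 - sum(p.value for p in fs)
    c_c = 1.0 - sum(p.value for p in cs)
    if c_c <= 1e-10:
        return None
    f_c = max(f_c, 0.0)
    any_mc = any(p.method == "monte_carlo" for p in fs + cs)
    se_f = float(np.sqrt(sum(p.std_error**2 for p in fs)))
    se_c = float(np.sqrt(sum(p.std_error**2 for p in cs)))
    method = "monte_carlo" if any_mc else "analytic"
    fI = ProbEstimate(f_c, se_f if any_mc else 0.0, method,
                      max((p.draws_used for p in fs), default=0))
    cI = ProbEstimate(c_c, se_c if any_mc else 0.0, method,
                      max((p.draws_used for p in cs), default=0))
    return _assemble(label, fI=fI, cI=cI, source="complement")


def posterior_probabilities(bfs, priors=None) -> np.ndarray:
    """Posterior hypothesis probabilities: normalised ``B_tu * Pr(H_t)``."""
    bfs = np.asarray(bfs, dtype=float)
    if not np.all(np.isfinite(bfs)) or np.any(bfs < 0):
        raise ValueError("Bayes factors must be finite and nonnegative")
    if priors is None:
        priors = np.ones_like(bfs)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != bfs.shape:
        raise ValueError("prior probabilities and Bayes factors disagree in length")
    if np.any(priors < 0) or not priors.sum() > 0:
        raise ValueError("prior probabilities must be nonnegative and not all zero")
    w = bfs * priors
    return w / w.sum()


def bf_matrix(bfs) -> np.ndarray:
    """Pairwise Bayes factors ``M[t, s] = B_tu / B_su`` via transitivity."""
    bfs = np.asarray(bfs, dtype=float)
    if np.any(bfs <= 0):
        raise ValueError("all Bayes factors must be positive")
    return bfs[:, None] / bfs[None, :]


def bf_interval(terms: BFTerms, level: float = 0.90) -> tuple[float, float]:
    """Credibility interval for B propagating Monte Carlo uncertainty.

    Log-normal error propagation: ``var(log B) ~ (se_f/f)^2 + (se_c/c)^2``
    over the Monte Carlo components, with quantiles at ``(1 +/- level)/2``.
    Only meaningful when at least one component was estimated by draws.
    """
    if not terms.uses_monte_carlo:
        raise ValueError("Bayes factor is fully analytic; no interval applies")
    var = 0.0
    for p in (terms.fI, terms.cI):
        if p is not None and p.method == "monte_carlo":
            if p.value == 0:
                return (0.0, np.inf)
            var += (p.std_error / p.value) ** 2
    sd = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (float(terms.B * np.exp(-z * sd)), float(terms.B * np.exp(z * sd)))


def _child_seeds(seed: int | None) -> tuple[int | None, int | None]:
    """Two independent child seeds (fit and complexity draws never share)."""
    if seed is None:
        return None, None
    children = np.random.SeedSequence(seed).spawn(2)
    return (
        int(children[0].generate_state(1)[0] % (2**31)),
        int(children[1].generate_state(1)[0] % (2**31)),
    )
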