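# Methods

## Model and hypotheses

`reghyp` operates on the normal linear regression model

    y = X b + e,   e ~ N(0, s^2 I_n),

with `n` observations and `k` design columns (intercept included unless
suppressed). Everything downstream depends on the data only through the
OLS sufficient statistics `(b_hat, s2, X'X, n)`, where `s2` denotes the
residual **sum of squares**, not a variance estimate; the two
construction paths (`fit_linear_model` on raw data, `fit_from_summaries`
on precomputed statistics) are interchangeable.

A hypothesis is a conjunction of equality and strict-inequality
constraints, `R_E b = r_E` and `R_I b > r_I`, written in a small
constraint language: chains (`b1 > b2 > b3 > 0`, comparisons binding
adjacent terms only), groups (`(b2, b3) = 0`, expanding member-wise),
name differences (`b1 - b2 > 0.2`), `&`-conjunctions, and numeric
right-hand sides. `<` is normalised to `>` by mirroring. Redundant
equality rows are removed at parse time; redundant inequality rows (which
group expansion can produce) are deliberately kept, and rank handling
downstream routes rank-deficient systems to Monte Carlo — semantic
fidelity over premature simplification. Every hypothesis must have a
strictly feasible interior point, verified by a linear program that
maximises the minimal inequality slack subject to the equalities.

## The default Bayes factor

The test compares each hypothesis against the unconstrained model `H_u`
through a fractional marginal likelihood: a minimal fraction
`b = (k + 1)/n` of the likelihood (one observation's worth of information
per parameter — `k` coefficients and one variance) implicitly defines a
proper prior, and the prior's quadratic form is relocated from `b_hat` to
the boundary of the constrained space. Operationally each marginal
likelihood is the full-data marginal under the noninformative `1/s^2`
prior divided by the marginal of the relocated fraction-`b` likelihood.
This yields Student-t posteriors and priors and three analytic cases:

* **Equality only** (`q_E >= 1, q_I = 0`): Savage–Dickey ratio

      B = t(r_E; R_E b_hat, s2 (n-k)^-1 R_E (X'X)^-1 R_E', n-k)
        / t(r_E; r_E,       s2         R_E (X'X)^-1 R_E', 1)

  The prior (denominator) is a multivariate Cauchy centred at the null
  value itself.

* **Order only** (`q_E = 0`): ratio of the posterior probability of
  `R_I b > r_I` under `t(b_hat, s2 (X'X)^-1/(n-k), n-k)` to the prior
  probability under `t(R_I^- r_I, s2 (X'X)^-1, 1)`, whose centre
  `R_I^- r_I` (minimum-norm pseudo-inverse solution) lies on the
  constraint boundary. Centring is what makes complexity an honest
  measure of a hypothesis's size: "both coefficients positive" has prior
  probability exactly 1/4 under an orthogonal design.

* **Both kinds**: the coefficients are transformed to `xi = T b` with
  `T = [R_E; D]`, where `D` holds `k - q_E` linearly independent rows of
  the projector `I - R_E'(R_E R_E')^-1 R_E`, selected greedily in row
  order. (The row choice is a labelling convention only; an explicit test
  asserts the Bayes factor is invariant to any full-rank selection.) The
  Bayes factor is the equality ratio above times a conditional
  probability ratio for `Rtilde_I xi_I` with `Rtilde_I = R_I D^-`:
  numerator under the conditional posterior `t(mu_I_N, S_I_N, n-k)`
  against `rtilde_I = r_I - R_I R_E^- r_E`, denominator under the
  conditional prior `t(xi_hat_I, S_I_0, 1)` against
  `r*_I = Rtilde_I xi_hat_I`. Evaluating the prior probability at the
  image of its own centre makes the conditional complexity exactly 0.5
  for a single surviving inequality, for any dataset. `S_I_N` and `S_I_0`
  are the standard conditional-t Schur complements, the former inflated
  by `(1 + d/s2)` with `d` the Mahalanobis distance of `r_E` from
  `R_E b_hat`, and scaled by `(n - k + q_E)^-1 s2` and `s2/(1 + q_E)`
  respectively. When the equalities saturate all `k` coordinates the
  transform is skipped and the equality-only ratio is used.

A brute-force oracle in the test suite validates this construction for
`k = 1`: the analytic null-hypothesis Bayes factor matches direct
quadrature of the four marginal-likelihood integrals to a relative
tolerance of 1e-3 for `n <= 20`.

## Complement, posterior probabilities, uncertainty

When the specified order hypotheses do not already exhaust coefficient
space, a complement hypothesis is added automatically with
`f_c = 1 - sum f_I` and `c_c = 1 - sum c_I` over the *purely*
order-constrained hypotheses (hypotheses carrying equality constraints
occupy measure-zero sets and do not shrink the complement). This requires
the order regions to be pairwise disjoint, which is verified exactly by a
linear-program feasibility check on each merged pair; overlapping
formulations are rejected with an error rather than approximated, since
union probabilities are not estimated in this version. When `c_c` is
numerically zero the complement is suppressed.

Posterior probabilities are `Pr(H_t | y) ∝ B_tu Pr(H_t)` with equal prior
probabilities by default, and the full Bayes-factor matrix follows from
transitivity, `B_ts = B_tu / B_su`.

Rectangle probabilities of full-row-rank systems are evaluated by scipy's
deterministic quasi-Monte-Carlo Student-t routine with a fixed internal
randomisation (error below 1e-6 at the configured effort, treated as
exact with zero standard error); dimension one uses the exact univariate
survival function. Rank-deficient systems fall back to the proportion of
`mcrep` seeded draws (default 1e6) from the unconstrained t, with
binomial standard error `sqrt(p(1-p)/mcrep)`; fit and complexity always
use independent draw streams so their errors are independent. Monte Carlo
uncertainty propagates to the Bayes factor through a log-normal
approximation, `var(log B) ≈ (se_f/f)^2 + (se_c/c)^2`, giving a 90%
credibility interval that is reported only when draws were actually used;
a 500-replication coverage study in the test suite confirms the interval
covers the analytic value at close to its nominal rate.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `mcrep` | 1e6 | draws for rank-deficient order constraints; halving the MC interval width costs 4x draws |
| `seed` | none | seeds all Monte Carlo paths; child seeds are spawned per hypothesis and per fit/complexity stream |
| `prior_probs` | `"equal"` | prior hypothesis probabilities, including the complement when added |
| `standardize` | off | z-score response and predictors before fitting, for hypotheses comparing coefficients across predictors on different scales |
| fraction `b` | `(k+1)/n` | fixed by the construction, not tunable |

Displayed values are rounded half-even to three decimals; JSON output
retains full precision, and the text report is a deterministic function
of the JSON payload.

## Synthetic data

`generate_regression` draws predictors from a correlated Gaussian and
adds Gaussian noise — it emulates the small, well-conditioned
observational designs of typical regression applications with
controllable truth, error scale, and predictor correlation. It does not
emulate heavy-tailed or heteroscedastic errors, discrete or skewed
predictors, or missingness, so passing tests speak to the method's
behaviour under its own model assumptions, not to robustness against
their violation. `generate_exact_mle` builds a design with
`X'X` equal to a prescribed matrix (via a random orthonormal frame times
a Cholesky factor) and a residual vector of prescribed squared norm lying
exactly in the design's orthogonal complement; since the Bayes factors
are functions of the sufficient statistics alone, fixtures built this way
give seed-independent analytic targets.

The consistency check simulates a strictly ordered positive truth
`(b1, b2, b3) = (0.6, 0.4, 0.2)` with unit error standard deviation and
tracks the median posterior probability of the true ordering over 50
replications at `n = 30, 100, 300` — sizes chosen to show the
accumulation of evidence while keeping the default suite quick.

## Numerical choices and degenerate inputs

* Pseudo-inverses use SVD with numpy's default cutoff
  (`max(dim) * eps * sigma_max`).
* The prior centre `mu0 = T R^- r` uses the minimum-norm least-squares
  solution of the stacked constraint system; for the all-zero right-hand
  sides of typical hypotheses it is exactly the origin.
* Perfect fits (`s2 = 0`) are rejected — the prior scale matrices would
  be singular. Rank-deficient designs are rejected with the collinear
  columns named. Rows with missing values are dropped listwise with a
  logged count.
* A zero Monte Carlo complexity estimate raises an error suggesting a
  larger `mcrep` instead of returning an infinite Bayes factor.

## Limitations

* The constraint language covers names, groups, name differences, and
  numeric bounds; arbitrary linear-combination arithmetic (`2*b1 + b2`)
  is not parsed.
* Only linear Gaussian regression: no GLMs, weighted or robust fits.
* Overlapping order hypotheses are rejected rather than handled by union
  estimation.
* Evidence cannot be updated sequentially by Bayes' theorem — fractional
  priors are data-dependent — so new data require recomputation (cheap,
  as everything is analytic).
* The two-predictor illustration shipped in the test suite checks the
  *assembly* of printed fit/complexity components into Bayes factors and
  posterior probabilities; the underlying simulated dataset of that
  illustration is not publicly available, so its components are not
  end-to-end reproduction targets.
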