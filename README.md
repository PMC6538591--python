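# reghyp

Default Bayes factors for testing equality- and order-constrained
hypotheses on the coefficients of a linear regression model.

Scientific expectations about relative effects are often naturally
expressed as constraints on regression coefficients: "the effect of the
strong treatment exceeds the medium one, which exceeds the mild one, and
all are positive" is `b1 > b2 > b3 > 0`; "all treatments work equally
well" is `b1 = b2 = b3 > 0`. `reghyp` quantifies the relative evidence in
the data for several such hypotheses at once — including the complement
"none of the above" — and reports Bayes factors and posterior hypothesis
probabilities, without requiring the user to specify prior distributions
for the effects.

## The method

For the normal linear model `y = X b + e`, `e ~ N(0, s^2 I)`, each
hypothesis has the form

```
H_t:  R_E b = r_E   and   R_I b > r_I
```

Evidence against the unconstrained model `H_u` is a ratio of *fit* to
*complexity*:

* **Equality constraints** — a Savage–Dickey density ratio: the posterior
  density of `R_E b` at `r_E` (a multivariate Student t with `n - k`
  degrees of freedom) over the density of the implicit default prior at
  the same point.
* **Order constraints** — the posterior probability that `R_I b > r_I`
  over the same probability under the default prior.
* **Both kinds** — the equality ratio times a conditional probability
  ratio in transformed coordinates `xi = T b` that separate the
  equality-constrained directions from the free ones.

The default prior is constructed from a minimal fraction `b = (k + 1)/n`
of the data (one observation's worth of information per parameter) and
relocated to the boundary of the constrained region; it is a multivariate
Cauchy centred so that, e.g., "both coefficients positive" has prior
probability exactly 1/4 under an orthogonal design. All quantities are
analytic (deterministic Student-t rectangle probabilities) except when
the reduced constraint matrix is rank deficient, in which case seeded
Monte Carlo proportions with 90% credibility intervals are used.

Bayes factors of the hypotheses against `H_u` combine by transitivity
into a Bayes-factor matrix and, with prior hypothesis probabilities
(equal by default), into posterior probabilities
`Pr(H_t | y) ∝ B_tu Pr(H_t)`.

## Worked example

```python
import reghyp as rh

table = rh.generate_regression(
    rh.SimSpec(n=60, beta_true=(0.2, 0.7, 0.4, 0.1), seed=21)
)
res = rh.run_test(rh.TestRequest(
    table=table, formula="y ~ x1 + x2 + x3",
    hyp="x1 > x2 > x3 > 0; x1 = x2 = x3 > 0",
))
print(rh.format_output(res, "text"))
```

```
Hypotheses:

  H1: "x1>x2>x3>0"
  H2: "x1=x2=x3>0"
  Hc: "Not H1-H2"

Posterior probability of each hypothesis (rounded):

  H1: 0.984
  H2: 0.001
  Hc: 0.015

BF_matrix:
              H1        H2        Hc
H1         1.000  1144.194    63.851
H2         0.001     1.000     0.056
Hc         0.016    17.920     1.000

BF_computation:
           c(E)   c(I|E)        c     f(E)   f(I|E)        f   B(t,u)    PP(t)
H1           NA    0.016       NA       NA    0.512       NA   31.645    0.984
H2        0.084    0.500    0.042    0.001    1.000    0.001    0.028    0.001
Hc           NA    0.984       NA       NA    0.488       NA    0.496    0.015
```

The data were simulated with a strictly ordered positive truth, and the
ordered hypothesis H1 wins decisively: its posterior probability is 0.984
and it is favoured over the equal-effects hypothesis H2 by a Bayes factor
of about 1144. The `BF_computation` block decomposes each Bayes factor
into complexity (`c`) and fit (`f`): H1 occupies only 1.6% of coefficient
space a priori (`c(I|E) = 0.016`) but 51% a posteriori, a 31.6-fold gain;
`NA` cells mark components that do not exist for a hypothesis (an
order-only hypothesis has probabilities but no density at a null value).
The complement row `Hc` guards against all stated hypotheses fitting
badly. A one-line `reghyp test`/`reghyp exploratory` command-line
interface wraps the same pipeline for CSV/TSV files, and
`hyp="exploratory"` tests zero/positive/negative for every coefficient.

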