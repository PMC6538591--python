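import numpy as np
import pytest

import reghyp as rh
from oracles import conditional_t_moments
from reghyp.core import BFTerms, _assemble
from reghyp.mvt import ProbEstimate


def _scaled_fit(fit, c):
    """The fit obtained from the same design after y -> c * y."""
    return rh.fit_from_summaries(
        c * fit.beta_hat, fit.xtx, c**2 * fit.s2, fit.n, names=fit.coef_names
    )


class TestEqualityBF:
    def test_hand_computed_intercept_example(self):
        """beta_hat=0, s2=2, X'X=3, n=3, H: b=0 -> B = pi/2 exactly."""
        fit = rh.fit_from_summaries([0.0], [[3.0]], 2.0, 3, names=["b1"])
        (sys,) = rh.parse_hypotheses("b1 = 0", ["b1"])
        t = rh.bf_equality(fit, sys)
        assert t.fE == pytest.approx(0.6123724357, rel=1e-9)
        assert t.cE == pytest.approx(1 / (np.pi * np.sqrt(2 / 3)), rel=1e-12)
        assert t.B == pytest.approx(np.pi / 2, rel=1e-12)

    def test_null_at_mle_maximizes_evidence(self, small_fit):
        """fE is the posterior mode value when r_E = R_E beta_hat."""
        names = small_fit.coef_names
        at_mle = rh.fit_from_summaries(
            small_fit.beta_hat, small_fit.xtx, small_fit.s2, small_fit.n,
            names=names,
        )
        target = at_mle.beta_hat[1]
        (sys0,) = rh.parse_hypotheses(f"x1 = {target:.17g}", names)
        b0 = rh.bf_equality(at_mle, sys0).B
        for shift in (0.1, -0.25, 0.6):
            (sys,) = rh.parse_hypotheses(f"x1 = {target + shift:.17g}", names)
            assert rh.bf_equality(at_mle, sys).B < b0

    def test_scale_invariance_when_null_is_zero(self, small_fit):
        (sys,) = rh.parse_hypotheses("x1 = x2 = 0", small_fit.coef_names)
        b1 = rh.bf_equality(small_fit, sys).B
        b2 = rh.bf_equality(_scaled_fit(small_fit, 2.0), sys).B
        assert b2 == pytest.approx(b1, rel=1e-9)


class TestOrderBF:
    def test_boundary_mle_gives_unit_bayes_factor(self):
        fit = rh.fit_from_summaries([0.0], [[3.0]], 2.0, 10, names=["b1"])
        (sys,) = rh.parse_hypotheses("b1 > 0", ["b1"])
        t = rh.bf_order(fit, sys)
        assert t.fI.value == 0.5 and t.cI.value == 0.5
        assert t.B == 1.0

    def test_orthogonal_predictors_prior_probability_quarter(self, orthogonal_fit):
        """Complexity of 'both positive' is 0.25 under the centred prior."""
        (sys,) = rh.parse_hypotheses("(x1,x2) > 0", orthogonal_fit.coef_names)
        t = rh.bf_order(orthogonal_fit, sys)
        assert t.cI.value == pytest.approx(0.25, abs=1e-7)
        # ... regardless of the observed response
        other = rh.fit_from_summaries(
            [-1.2, 4.0], orthogonal_fit.xtx, 7.7, orthogonal_fit.n,
            names=orthogonal_fit.coef_names,
        )
        t2 = rh.bf_order(other, sys)
        assert t2.cI.value == pytest.approx(0.25, abs=1e-7)

    def test_scale_invariance(self, small_fit):
        (sys,) = rh.parse_hypotheses("x1 > x2 > 0", small_fit.coef_names)
        b1 = rh.bf_order(small_fit, sys).B
        b2 = rh.bf_order(_scaled_fit(small_fit, 3.0), sys).B
        assert b2 == pytest.approx(b1, rel=1e-9)

    def test_assembly_contract_from_printed_components(self):
        t = _assemble(
            "H2",
            fI=ProbEstimate(0.546, 0.0, "analytic", 0),
            cI=ProbEstimate(0.250, 0.0, "analytic", 0),
        )
        assert t.B == pytest.approx(2.184, abs=1e-12)


class TestConditionalMoments:
    def test_matches_generic_conditional_t_formula(self, small_fit):
        (sys,) = rh.parse_hypotheses("x1 = 0.2 & x2 > x3", small_fit.coef_names)
        tsys = rh.transform_system(sys)
        cm = rh.conditional_moments(small_fit, tsys, sys)
        # oracle: condition the joint posterior of xi = T beta directly
        nu = small_fit.n - small_fit.k
        S_xi = small_fit.s2 / nu * tsys.T @ small_fit.sigma @ tsys.T.T
        mu_xi = tsys.T @ small_fit.beta_hat
        loc, scale = conditional_t_moments(
            mu_xi, S_xi, nu, idx_cond=range(sys.q_E), value=sys.r_E
        )
        np.testing.assert_allclose(cm.mu_I_N, loc, atol=1e-10)
        np.testing.assert_allclose(cm.S_I_N, scale, atol=1e-10)

    def test_inflation_vanishes_when_null_at_mle(self, small_fit):
        names = small_fit.coef_names
        val = small_fit.beta_hat[1]
        (sys,) = rh.parse_hypotheses(f"x1 = {val:.17g} & x2 > 0", names)
        tsys = rh.transform_system(sys)
        cm = rh.conditional_moments(small_fit, tsys, sys)
        nu, qE = small_fit.n - small_fit.k, sys.q_E
        D = tsys.D
        Sg = small_fit.sigma
        cross = D @ Sg @ sys.R_E.T
        H = sys.R_E @ Sg @ sys.R_E.T
        schur = D @ Sg @ D.T - cross @ np.linalg.solve(H, cross.T)
        np.testing.assert_allclose(
            cm.S_I_N, small_fit.s2 / (nu + qE) * schur, atol=1e-12
        )

    def test_prior_scale_schur_complement_diagonal_design(self):
        fit = rh.fit_from_summaries(
            [0.4, -0.1, 0.2], np.diag([2.0, 4.0, 8.0]), 3.0, 25
        )
        (sys,) = rh.parse_hypotheses("b1 = 0 & b2 > 0", fit.coef_names)
        tsys = rh.transform_system(sys)
        cm = rh.conditional_moments(fit, tsys, sys)
        # diagonal X'X and a coordinate equality: Schur complement is just
        # the remaining diagonal block, D = coordinate selector rows
        expect = fit.s2 / 2.0 * tsys.D @ np.diag([0.5, 0.25, 0.125]) @ tsys.D.T
        np.testing.assert_allclose(cm.S_I_0, expect, atol=1e-12)


class TestCombinedBF:
    def test_single_conditional_inequality_prior_half(self, small_fit):
        """c(I|E) = 0.500 exactly, whatever the data."""
        for fit in (small_fit, _scaled_fit(small_fit, 0.1)):
            (sys,) = rh.parse_hypotheses(
                "x1 > x2 = x3 = 0", fit.coef_names
            )
            t = rh.bf_combined(fit, sys)
            assert t.cI.value == 0.5
            assert t.cI.method == "analytic"

    def test_saturated_equalities_reduce_to_equality_bf(self, small_fit):
        names = small_fit.coef_names
        spec = "(Intercept) = 0 & x1 = 0 & x2 = 0 & x3 = 0 & x1 > -1"
        (sys,) = rh.parse_hypotheses(spec, names)
        (eq_sys,) = rh.parse_hypotheses(
            "(Intercept) = 0 & x1 = 0 & x2 = 0 & x3 = 0", names
        )
        assert rh.compute_bf(small_fit, sys).B == pytest.approx(
            rh.bf_equality(small_fit, eq_sys).B, rel=1e-12
        )

    def test_scale_invariance(self, small_fit):
        (sys,) = rh.parse_hypotheses("x1 > x2 = x3 = 0", small_fit.coef_names)
        b1 = rh.bf_combined(small_fit, sys).B
        b2 = rh.bf_combined(_scaled_fit(small_fit, 5.0), sys).B
        assert b2 == pytest.approx(b1, rel=1e-9)

    def test_redundant_rows_route_to_monte_carlo_and_agree(self, small_fit):
        """Grouped and chained forms of one hypothesis give the same B."""
        names = small_fit.coef_names
        (chain,) = rh.parse_hypotheses("x1 > x2 = x3 = 0", names)
        (group,) = rh.parse_hypotheses("x1 > (x2,x3) = 0", names)
        t_chain = rh.bf_combined(small_fit, chain)
        t_group = rh.bf_combined(small_fit, group, mcrep=10**5, seed=7)
        assert t_chain.fI.method == "analytic"
        assert t_group.fI.method == "monte_carlo"
        se = np.sqrt(
            (t_group.fI.std_error / t_group.fI.value) ** 2
            + (t_group.cI.std_error / t_group.cI.value) ** 2
        )
        assert np.log(t_group.B) == pytest.approx(
            np.log(t_chain.B), abs=4 * se + 1e-9
        )


class TestComplement:
    def test_printed_component_example(self):
        order = BFTerms(
            label="H2",
            fI=ProbEstimate(0.546, 0.0, "analytic", 0),
            cI=ProbEstimate(0.250, 0.0, "analytic", 0),
            B=2.184,
        )
        c = rh.bf_complement([order])
        assert c.fI.value == pytest.approx(0.454)
        assert c.cI.value == pytest.approx(0.750)
        assert c.B == pytest.approx(0.454 / 0.750, rel=1e-12)

    def test_exhaustive_regions_suppress_complement(self):
        halves = [
            BFTerms(label=f"H{i}",
                    fI=ProbEstimate(f, 0.0, "analytic", 0),
                    cI=ProbEstimate(0.5, 0.0, "analytic", 0))
            for i, f in enumerate((0.7, 0.3))
        ]
        assert rh.bf_complement(halves) is None

    def test_no_order_hypotheses_gives_unit_complement(self):
        eq = BFTerms(label="H1", fE=0.5, cE=0.25, B=2.0)
        c = rh.bf_complement([eq])
        assert c is not None and c.B == 1.0

    def test_complement_region_probability_verified_by_draws(self, small_fit):
        """f_c matches a direct Monte Carlo estimate of the leftover region."""
        names = small_fit.coef_names
        systems = rh.parse_hypotheses("x1 > x2 > 0; x1 < x2 & x2 < 0", names)
        terms = [rh.bf_order(small_fit, s) for s in systems]
        c = rh.bf_complement(terms)
        from scipy import stats

        nu = small_fit.n - small_fit.k
        draws = stats.multivariate_t.rvs(
            loc=small_fit.beta_hat,
            shape=small_fit.s2 * small_fit.sigma / nu,
            df=nu, size=10**5, random_state=np.random.default_rng(17),
        )
        in_any = np.zeros(len(draws), dtype=bool)
        for s in systems:
            in_any |= np.all(draws @ s.R_I.T > s.r_I, axis=1)
        est = np.mean(~in_any)
        se = np.sqrt(est * (1 - est) / 10**5)
        assert c.fI.value == pytest.approx(est, abs=4 * se)
        # fit and complexity each conserve total probability
        assert sum(t.fI.value for t in terms) + c.fI.value == pytest.approx(1.0)
        assert sum(t.cI.value for t in terms) + c.cI.value == pytest.approx(1.0)


class TestPosteriorProbabilities:
    def test_printed_worked_examples(self):
        pp = rh.posterior_probabilities([0.383, 2.183, 10.061, 0.606])
        np.testing.assert_allclose(
            np.round(pp, 3), [0.029, 0.165, 0.760, 0.046]
        )
        pp2 = rh.posterior_probabilities([58.265, 32.525, 0.036, 0.357])
        assert round(float(pp2[0]), 3) == 0.639

    def test_sum_to_one_and_single_hypothesis(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            bfs = rng.lognormal(size=rng.integers(1, 7))
            priors = rng.uniform(0.1, 1.0, size=bfs.size)
            pp = rh.posterior_probabilities(bfs, priors)
            assert pp.sum() == pytest.approx(1.0, abs=1e-12)
        assert rh.posterior_probabilities([123.4]) == pytest.approx([1.0])

    def test_nonfinite_bf_rejected(self):
        with pytest.raises(ValueError):
            rh.posterior_probabilities([1.0, np.inf])


class TestBFMatrix:
    def test_transitivity_and_diagonal(self):
        M = rh.bf_matrix([0.383, 2.183, 10.061, 0.606])
        assert M[2, 0] == pytest.approx(10.061 / 0.383, rel=1e-12)
        np.testing.assert_allclose(np.diag(M), 1.0)
        for t in range(4):
            for s in range(4):
                for r in range(4):
                    assert M[t, s] * M[s, r] == pytest.approx(M[t, r], rel=1e-12)

    def test_zero_bf_rejected(self):
        with pytest.raises(ValueError):
            rh.bf_matrix([1.0, 0.0])


class TestIntervals:
    def test_analytic_terms_have_no_interval(self, small_fit):
        (sys,) = rh.parse_hypotheses("x1 > x2", small_fit.coef_names)
        t = rh.bf_order(small_fit, sys)
        assert t.ci90 is None
        with pytest.raises(ValueError, match="analytic"):
            rh.bf_interval(t)

    def test_width_shrinks_with_root_mcrep(self, small_fit):
        (sys,) = rh.parse_hypotheses("x1 > (x2,x3) = 0", small_fit.coef_names)
        widths = {}
        for mcrep in (10**4, 10**5, 10**6):
            t = rh.bf_combined(small_fit, sys, mcrep=mcrep, seed=3)
            lb, ub = t.ci90
            widths[mcrep] = np.log(ub) - np.log(lb)
        assert widths[10**4] / widths[10**5] == pytest.approx(
            np.sqrt(10), rel=0.2
        )
        assert widths[10**5] / widths[10**6] == pytest.approx(
            np.sqrt(10), rel=0.2
        )

    def test_interval_coverage_near_nominal(self):
        """~90% of seeded MC intervals should contain the analytic value."""
        spec_fit = rh.fit_from_summaries(
            [0.5, 0.3], [[4.0, 1.0], [1.0, 3.0]], 2.5, 20
        )
        (chain,) = rh.parse_hypotheses("b1 > b2 = 0", spec_fit.coef_names)
        truth = rh.bf_combined(spec_fit, chain).B
        (group,) = rh.parse_hypotheses("(b1, b1) > b2 = 0", spec_fit.coef_names)
        hits = 0
        reps = 500
        for i in range(reps):
            t = rh.bf_combined(spec_fit, group, mcrep=10**4, seed=1000 + i)
            lb, ub = t.ci90
            hits += lb <= truth <= ub
        assert 0.85 <= hits / reps <= 0.95
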