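"""Margins, Xi2, Delta2, M2, RMSEA, and the incremental index."""

import numpy as np
import pytest
from scipy import linalg, stats

from tlirt import (
    FitStatistics,
    ItemParameters,
    QuadratureGrid,
    ResponseData,
    enumerate_pattern_distribution,
    fit_grm_em,
    fit_null_model,
    generate_responses,
    m2_statistic,
    margin_covariance,
    margin_jacobian,
    misspec1_parameters,
    model_margins,
    n_moments,
    observed_margins,
    rmsea_confidence_interval,
    rmsea_from_chi2,
    generating_parameters,
    tlirt,
)
from tlirt.limited_info import _margin_structure


def reduction_operator(params, grid):
    """Full-cell enumeration oracle: moments = L @ pi with indicator rows."""
    n, K = params.n_items, params.K
    dist = enumerate_pattern_distribution(params, grid)
    pats = dist.patterns
    st = _margin_structure(n, K)
    m = K - 1
    L = np.zeros((st.s, dist.n_cells))
    for i in range(n):
        for k in range(1, K):
            L[i * m + k - 1] = pats[:, i] >= k
    for r in range(st.s2):
        i, j = st.item_a[r], st.item_b[r]
        ki = st.row_a[r] - i * m + 1
        lj = st.row_b[r] - j * m + 1
        L[st.s1 + r] = (pats[:, i] >= ki) & (pats[:, j] >= lj)
    return L, dist.probs


def random_grm(rng, n, K):
    icpts = np.sort(rng.uniform(-1.8, 1.8, (n, K - 1)), axis=1)[:, ::-1]
    icpts -= np.arange(K - 1) * 0.4  # enforce strict ordering
    return ItemParameters(slopes=rng.uniform(0.4, 2.0, (n, 1)), intercepts=icpts, K=K)


class TestMoments:
    def test_moment_vector_lengths(self):
        assert n_moments(30, 2) == 465
        assert n_moments(30, 5) == 7080

    def test_toy_counting_example(self):
        data = ResponseData(codes=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]), K=2)
        mom = observed_margins(data)
        np.testing.assert_allclose(mom.uni, [0.5, 0.5])
        np.testing.assert_allclose(mom.bi, [0.25])

    def test_zero_slope_bivariate_moments_factorize(self, grid):
        p = ItemParameters(slopes=np.zeros((3, 1)), intercepts=[[0.4], [-0.2], [1.0]], K=2)
        mom = model_margins(p, grid)
        st = _margin_structure(3, 2)
        np.testing.assert_allclose(
            mom.bi, mom.uni[st.row_a] * mom.uni[st.row_b], atol=1e-12
        )

    def test_identical_items_have_identical_univariate_moments(self, grid):
        p = ItemParameters(slopes=[[1.3], [1.3]], intercepts=[[0.5], [0.5]], K=2)
        mom = model_margins(p, grid)
        assert mom.uni[0] == pytest.approx(mom.uni[1], abs=1e-14)

    @pytest.mark.parametrize("n,K", [(5, 2), (4, 3), (3, 3)])
    def test_model_margins_match_full_enumeration(self, grid, rng, n, K):
        p = random_grm(rng, n, K)
        L, pi = reduction_operator(p, grid)
        np.testing.assert_allclose(model_margins(p, grid).vector, L @ pi, atol=1e-12)


class TestJacobian:
    def test_matches_central_finite_differences(self, grid, rng):
        n, K = 3, 3
        p = random_grm(rng, n, K)
        J = margin_jacobian(p, grid, free="all")

        def vec(theta):
            sl = theta[0::K].reshape(n, 1)
            ic = np.column_stack([theta[d::K] for d in range(1, K)])
            return model_margins(ItemParameters(slopes=sl, intercepts=ic, K=K), grid).vector

        theta0 = np.column_stack([p.slopes, p.intercepts]).ravel()
        h = 1e-5
        for c in range(theta0.size):
            e = np.zeros_like(theta0)
            e[c] = h
            fd = (vec(theta0 + e) - vec(theta0 - e)) / (2 * h)
            np.testing.assert_allclose(J[:, c], fd, atol=1e-5)

    def test_cross_item_univariate_derivatives_vanish(self, grid, rng):
        p = random_grm(rng, 4, 2)
        J = margin_jacobian(p, grid, free="all")
        # univariate moment of item 0 w.r.t. parameters of items 1..3
        assert np.abs(J[0, 2:]).max() == 0.0

    def test_null_model_jacobian_has_intercept_columns_only(self, grid, rng):
        p = ItemParameters(slopes=np.zeros((4, 1)), intercepts=rng.uniform(-1, 1, (4, 1)), K=2)
        J = margin_jacobian(p, grid, free="intercepts")
        assert J.shape == (n_moments(4, 2), 4)
        assert np.linalg.matrix_rank(J) == 4


class TestCovariance:
    def test_univariate_diagonal_is_bernoulli_variance(self, grid, rng):
        p = random_grm(rng, 4, 2)
        xi = margin_covariance(p, grid)
        mu = model_margins(p, grid).uni
        np.testing.assert_allclose(np.diag(xi)[:4], mu * (1 - mu), atol=1e-12)

    @pytest.mark.parametrize("n,K", [(6, 2), (4, 3)])
    def test_matches_full_enumeration(self, grid, rng, n, K):
        p = random_grm(rng, n, K)
        L, pi = reduction_operator(p, grid)
        xi_enum = L @ (np.diag(pi) - np.outer(pi, pi)) @ L.T
        np.testing.assert_allclose(margin_covariance(p, grid), xi_enum, atol=1e-10)

    def test_zero_slope_disjoint_moments_uncorrelated(self, grid):
        p = ItemParameters(slopes=np.zeros((4, 1)), intercepts=[[0.2], [-0.3], [0.8], [0.0]], K=2)
        xi = margin_covariance(p, grid)
        # univariate moments of items 0 and 1 are independent
        assert xi[0, 1] == pytest.approx(0.0, abs=1e-12)
        # pair (0,1) vs pair (2,3): disjoint item sets
        st = _margin_structure(4, 2)
        r01 = st.s1 + int(np.nonzero((st.item_a == 0) & (st.item_b == 1))[0][0])
        r23 = st.s1 + int(np.nonzero((st.item_a == 2) & (st.item_b == 3))[0][0])
        assert xi[r01, r23] == pytest.approx(0.0, abs=1e-12)

    def test_positive_definite_for_nondegenerate_model(self, grid, rng):
        xi = margin_covariance(random_grm(rng, 5, 3), grid)
        assert np.linalg.eigvalsh(xi).min() > 0


@pytest.fixture(scope="module")
def fitted_small(grid):
    gen = random_grm(np.random.default_rng(8), 4, 2)
    data = generate_responses(gen, np.eye(1), 600, 8)
    return data, fit_grm_em(data, grid=grid)


class TestM2:
    def test_matches_orthogonal_complement_form(self, grid, fitted_small):
        data, fit = fitted_small
        stat = m2_statistic(data, fit, grid)
        e = observed_margins(data).vector - model_margins(fit.params, grid).vector
        xi = margin_covariance(fit.params, grid)
        delta = margin_jacobian(fit.params, grid, free="all")
        dc = linalg.null_space(delta.T)
        m2c = data.n_respondents * e @ dc @ np.linalg.solve(dc.T @ xi @ dc, dc.T @ e)
        assert stat.value == pytest.approx(m2c, abs=1e-6)

    def test_invariant_to_nonsingular_basis_transform(self, grid, fitted_small):
        data, fit = fitted_small
        e = observed_margins(data).vector - model_margins(fit.params, grid).vector
        xi = margin_covariance(fit.params, grid)
        delta = margin_jacobian(fit.params, grid, free="all")

        def quad_form(e, xi, delta):
            xi_inv = np.linalg.inv(xi)
            a = delta.T @ xi_inv @ delta
            w = xi_inv - xi_inv @ delta @ np.linalg.solve(a, delta.T @ xi_inv)
            return data.n_respondents * e @ w @ e

        base = quad_form(e, xi, delta)
        t = np.random.default_rng(3).uniform(-1, 1, (e.size, e.size)) + 2 * np.eye(e.size)
        transformed = quad_form(t @ e, t @ xi @ t.T, t @ delta)
        assert transformed == pytest.approx(base, rel=1e-8)

    def test_nonnegative_and_item_order_invariant(self, grid, fitted_small):
        data, fit = fitted_small
        stat = m2_statistic(data, fit, grid)
        assert stat.value >= 0
        perm = [2, 0, 3, 1]
        from tlirt.fiml import FittedModel

        pdata = ResponseData(codes=data.codes[:, perm], K=2)
        pfit = FittedModel(
            params=ItemParameters(
                slopes=fit.params.slopes[perm],
                intercepts=fit.params.intercepts[perm],
                K=2,
            ),
            loglik=fit.loglik,
            n_iterations=fit.n_iterations,
            converged=True,
            model_kind="substantive",
            dim_theta=fit.dim_theta,
        )
        assert m2_statistic(pdata, pfit, grid).value == pytest.approx(stat.value, abs=1e-6)

    def test_degrees_of_freedom_bookkeeping(self, grid, fitted_small):
        data, fit = fitted_small
        assert m2_statistic(data, fit, grid).df == n_moments(4, 2) - 8
        null = fit_null_model(data)
        assert m2_statistic(data, null, grid).df == n_moments(4, 2) - 4

    def test_null_distribution_calibrated(self, grid):
        """Under a correct model M2 follows chi-square(df) (KS at alpha=.01)."""
        gen = random_grm(np.random.default_rng(55), 6, 2)
        vals = []
        for r in range(500):
            data = generate_responses(gen, np.eye(1), 2000, [55, r])
            fit = fit_grm_em(data, grid=grid)
            vals.append(m2_statistic(data, fit, grid).value)
        df = n_moments(6, 2) - 12
        ks = stats.kstest(vals, stats.chi2(df).cdf)
        assert ks.pvalue > 0.01

    def test_null_model_fits_worse_on_associated_data(self, grid):
        params, cov = misspec1_parameters(2, n_items=6)
        data = generate_responses(params, cov, 1000, 13)
        sub = fit_grm_em(data, grid=grid)
        null = fit_null_model(data)
        assert m2_statistic(data, null, grid).value > m2_statistic(data, sub, grid).value


class TestRmsea:
    def test_truncation_at_zero(self):
        stat = FitStatistics.from_value(300.0, 405, 1000, "M2")
        assert rmsea_from_chi2(stat) == 0.0

    def test_arithmetic(self):
        stat = FitStatistics.from_value(810.0, 405, 1000, "M2")
        assert rmsea_from_chi2(stat) == pytest.approx(np.sqrt(405 / 405000), abs=1e-10)

    def test_ci_lower_bound_zero_when_value_at_df(self):
        stat = FitStatistics.from_value(405.0, 405, 1000, "M2")
        lo, hi = rmsea_confidence_interval(stat)
        assert lo == 0.0

    def test_ci_brackets_point_estimate(self):
        stat = FitStatistics.from_value(900.0, 405, 1000, "M2")
        lo, hi = rmsea_confidence_interval(stat)
        point = rmsea_from_chi2(stat)
        assert lo < point < hi

    def test_interval_collapses_to_median_noncentrality_as_level_shrinks(self):
        stat = FitStatistics.from_value(900.0, 405, 1000, "M2")
        lo, hi = rmsea_confidence_interval(stat, level=1e-9)
        assert hi - lo < 1e-5
        assert lo == pytest.approx(rmsea_from_chi2(stat), abs=2e-3)

    def test_level_monotonicity(self):
        stat = FitStatistics.from_value(900.0, 405, 1000, "M2")
        lo90, hi90 = rmsea_confidence_interval(stat, level=0.90)
        lo99, hi99 = rmsea_confidence_interval(stat, level=0.99)
        assert lo99 <= lo90 and hi99 >= hi90


class TestTlirt:
    def test_ideal_model_scores_one(self):
        m = FitStatistics.from_value(100.0, 100, 500, "M2")
        n0 = FitStatistics.from_value(2000.0, 100, 500, "M2")
        assert tlirt(m, n0) == pytest.approx(1.0)

    def test_null_equivalent_model_scores_zero(self):
        m = FitStatistics.from_value(400.0, 100, 500, "M2")
        n0 = FitStatistics.from_value(800.0, 200, 500, "M2")
        assert tlirt(m, n0) == pytest.approx(0.0)

    def test_ratio_arithmetic(self):
        m = FitStatistics.from_value(150.0, 100, 500, "M2")
        n0 = FitStatistics.from_value(2000.0, 100, 500, "M2")
        assert tlirt(m, n0) == pytest.approx((20 - 1.5) / 19, abs=1e-10)

    def test_not_clamped_above_one(self):
        m = FitStatistics.from_value(50.0, 100, 500, "M2")
        n0 = FitStatistics.from_value(2000.0, 100, 500, "M2")
        assert tlirt(m, n0) > 1.0

    def test_fitting_null_is_an_error(self):
        m = FitStatistics.from_value(150.0, 100, 500, "M2")
        n0 = FitStatistics.from_value(100.0, 100, 500, "M2")
        with pytest.raises(ZeroDivisionError):
            tlirt(m, n0)
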