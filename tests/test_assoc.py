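"""Univariate score test, mixture-of-chi-squares law, Wald regression."""

import numpy as np
import pytest
from scipy import stats

from murat.assoc import (
    MixtureSpec,
    _imhof_quad,
    _ruben_tail,
    adjusted_univariate_p,
    fit_null_univariate,
    mixture_chisq_p,
    mixture_chisq_quantile,
    single_variant_wald,
    skat_q,
    skat_test,
)


class TestNullFit:
    def test_intercept_only_mean_centering(self):
        null = fit_null_univariate(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)))
        assert null.coefficients[0] == pytest.approx(2.0)
        np.testing.assert_allclose(null.residuals, [-1, 0, 1], atol=1e-12)
        assert null.sigma2 == pytest.approx(1.0)

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(11)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        alpha = np.array([1.0, 0.5, -0.3, 0.2])
        y = X @ alpha + rng.standard_normal(n)
        null = fit_null_univariate(y, X)
        se = np.sqrt(null.sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(null.coefficients - alpha) < 3 * se)
        # residuals orthogonal to the design
        np.testing.assert_allclose(X.T @ null.residuals, 0, atol=1e-8)

    def test_rank_deficient_design_named(self):
        X = np.column_stack([np.ones(4), [1.0, 2, 3, 4], [2.0, 4, 6, 8]])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_null_univariate(np.zeros(4), X, names=["icpt", "a", "2a"])

    def test_degenerate_fit_errors_downstream(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = X[:, 1].copy()  # perfectly explained -> sigma2 == 0
        null = fit_null_univariate(y, X)
        with pytest.raises(ValueError, match="residual variance"):
            skat_q(null, np.ones((5, 1)) + np.eye(5)[:, :1])


class TestMixtureChisq:
    def test_chi_square_special_cases(self):
        assert mixture_chisq_p([1.0], 3.841459) == pytest.approx(0.05, abs=1e-6)
        assert mixture_chisq_p([1.0, 1.0], 5.991465) == pytest.approx(0.05, abs=1e-6)

    def test_negative_q_gives_one(self):
        assert mixture_chisq_p([1.0, 2.0], -1.0) == 1.0

    def test_three_eigenvalue_tail_vs_monte_carlo(self):
        lam = np.array([2.0, 1.0, 0.5])
        rng = np.random.default_rng(0)
        draws = rng.chisquare(1, (1_000_000, 3)) @ lam
        mc = float((draws >= 10.0).mean())
        se = np.sqrt(mc * (1 - mc) / 1e6)
        assert mixture_chisq_p(lam, 10.0) == pytest.approx(mc, abs=3 * se)

    @pytest.mark.parametrize("n_eig", [2, 3, 5, 8, 15, 40])
    def test_methods_cross_agree(self, n_eig):
        """Panel quadrature, Ruben's series and adaptive quadrature are
        independent evaluations of the same distribution."""
        rng = np.random.default_rng(n_eig)
        lam = np.sort(rng.uniform(0.05, 1.0, n_eig))[::-1]
        lam[0] = 1.0
        for target in (0.4, 0.02):
            q = mixture_chisq_quantile(lam, target)
            assert mixture_chisq_p(lam, q) == pytest.approx(target, rel=1e-6)
            p_ruben = _ruben_tail(q, lam)
            assert p_ruben == pytest.approx(target, rel=1e-6)
            val, err = _imhof_quad(q, lam)
            assert 0.5 + val / np.pi == pytest.approx(target, rel=2e-3)

    def test_quantile_round_trip_far_tail(self):
        lam = np.array([1.0, 0.6, 0.2, 0.1])
        for p in (0.05, 1e-4, 1e-8):
            q = mixture_chisq_quantile(lam, p)
            assert mixture_chisq_p(lam, q) == pytest.approx(p, rel=1e-5)

    def test_eigenvalue_truncation(self):
        spec = MixtureSpec([1.0, 1e-14, 0.0, -1e-16])
        assert spec.rank == 1

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="eigenvalues"):
            mixture_chisq_p(MixtureSpec([]), 1.0)


class TestSkatQ:
    @staticmethod
    def _data(seed=5, n=200, v=10):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        G = rng.binomial(2, 0.1, (n, v)).astype(float)
        y = X @ [0.5, 0.2, -0.1] + rng.standard_normal(n)
        return fit_null_univariate(y, X), G, X

    def test_single_variant_rank_one_reduction(self):
        null, G, X = self._data(v=1)
        g = G[:, :1]
        q, spec = skat_q(null, g)
        expected_q = float(g[:, 0] @ null.residuals) ** 2 / null.sigma2
        assert q == pytest.approx(expected_q, rel=1e-12)
        Pg = null.project_out(g)
        assert spec.eigenvalues[0] == pytest.approx(float(Pg[:, 0] @ Pg[:, 0]), rel=1e-10)

    def test_weight_scale_invariance(self):
        null, G, _ = self._data()
        p1 = skat_test(null, G, np.ones(10))
        p2 = skat_test(null, G, 37.5 * np.ones(10))
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_default_weights_bitwise_identity(self):
        null, G, _ = self._data()
        q1, s1 = skat_q(null, G)
        q2, s2 = skat_q(null, G, np.ones(10))
        assert q1 == q2
        np.testing.assert_array_equal(s1.eigenvalues, s2.eigenvalues)

    def test_affine_rescaling_of_phenotype(self):
        rng = np.random.default_rng(6)
        n, v = 150, 6
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        G = rng.binomial(2, 0.15, (n, v)).astype(float)
        y = rng.standard_normal(n)
        p1 = skat_test(fit_null_univariate(y, X), G)
        p2 = skat_test(fit_null_univariate(5.0 - 2.3 * y, X), G)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_null_tail_matches_monte_carlo(self):
        """Analytic p for an observed Q agrees with simulating the
        quadratic form from its eigenvalue representation."""
        null, G, _ = self._data(seed=9)
        q, spec = skat_q(null, G)
        p = mixture_chisq_p(spec, q)
        rng = np.random.default_rng(1)
        draws = rng.chisquare(1, (200_000, spec.rank)) @ spec.eigenvalues
        mc = float((draws >= q).mean())
        se = np.sqrt(max(mc * (1 - mc), 1e-12) / 200_000)
        assert p == pytest.approx(mc, abs=3 * se)

    def test_monomorphic_columns_dropped(self):
        null, G, _ = self._data()
        G2 = np.column_stack([G, np.zeros(len(G))])
        with pytest.warns(UserWarning, match="dropping"):
            q2, s2 = skat_q(null, G2, np.ones(11))
        q1, s1 = skat_q(null, G)
        assert q1 == q2
        np.testing.assert_array_equal(s1.eigenvalues, s2.eigenvalues)

    def test_all_monomorphic_reports_p_one(self):
        null, _, _ = self._data(n=50)
        with pytest.warns(UserWarning):
            assert skat_test(null, np.zeros((50, 3))) == 1.0


class TestAdjustedP:
    def test_minimum(self):
        assert adjusted_univariate_p([0.02, 0.5]) == 0.02
        assert adjusted_univariate_p([1.0, 1.0]) == 1.0
        assert adjusted_univariate_p([0.37]) == 0.37

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            adjusted_univariate_p([])
        with pytest.raises(ValueError):
            adjusted_univariate_p([0.0, 0.5])


class TestSingleVariantWald:
    def test_effect_recovery(self):
        rng = np.random.default_rng(21)
        n = 1000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.2, n).astype(float)
        y = X @ [1.0, 0.3] + 0.5 * g + rng.standard_normal(n)
        beta, p = single_variant_wald(y, X, g)
        se = 1.0 / np.sqrt(np.sum((g - g.mean()) ** 2))
        assert beta == pytest.approx(0.5, abs=3 * se)
        assert p < 1e-10

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        n = 120
        X = np.ones((n, 1))
        ps = []
        for _ in range(300):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = rng.standard_normal(n)
            ps.append(single_variant_wald(y, X, g)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_score_wald_asymptotic_equivalence(self):
        """-log10 p from the Wald test and the one-variant score test agree
        closely across many simulated variants."""
        rng = np.random.default_rng(13)
        n = 500
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        lw, ls = [], []
        for _ in range(500):
            g = rng.binomial(2, rng.uniform(0.05, 0.4), n).astype(float)
            y = 0.15 * g * rng.choice([0, 1]) + rng.standard_normal(n)
            _, pw = single_variant_wald(y, X, g)
            null = fit_null_univariate(y, X)
            ps = skat_test(null, g[:, None])
            lw.append(-np.log10(pw))
            ls.append(-np.log10(ps))
        assert np.corrcoef(lw, ls)[0, 1] > 0.99

    def test_collinear_variant_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError):
            single_variant_wald(np.zeros(6), X, 2.0 * np.arange(6.0))
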