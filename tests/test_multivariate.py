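"""Multivariate score test: null fit, factorized spectrum, omnibus."""

import numpy as np
import pytest

from murat.assoc import fit_null_univariate, mixture_chisq_p, skat_q
from murat.multivariate import (
    MuratResult,
    RhoGrid,
    fit_null_multivariate,
    murat_omnibus,
    murat_q,
)


def make_instance(seed=1, n=150, v=8, k=2, m=3, trait_corr=0.68, weights=True):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, m))])
    G = rng.binomial(2, rng.uniform(0.02, 0.2, v), (n, v)).astype(float)
    R = (1 - trait_corr) * np.eye(k) + trait_corr * np.ones((k, k))
    Y = X @ rng.standard_normal((m + 1, k)) + rng.standard_normal((n, k)) @ np.linalg.cholesky(R).T
    w = rng.uniform(0.5, 2.0, v) if weights else None
    return X, G, Y, w


def dense_independent_effects_p(X, G, Y, w):
    """Independently coded multivariate score test at rho = 0.

    Builds the full stacked (trait-major) system with explicit Kronecker
    products: S = (I_K x GW^.5)' V^-1 r, Q = S'S, spectrum from the dense
    projected information matrix.  Shares no code with murat_q.
    """
    n, k = Y.shape
    coef = np.linalg.solve(X.T @ X, X.T @ Y)
    E = Y - X @ coef
    sigma = E.T @ E / (n - X.shape[1])
    sigma_inv = np.linalg.inv(sigma)
    Gw = G * np.sqrt(w)
    Gt = np.kron(np.eye(k), Gw)                      # KN x Kv
    Xt = np.kron(np.eye(k), X)
    Vinv = np.kron(sigma_inv, np.eye(n))
    rt = E.T.reshape(-1)                             # trait-major stack
    S = Gt.T @ Vinv @ rt
    q = float(S @ S)
    Pt = Vinv - Vinv @ Xt @ np.linalg.solve(Xt.T @ Vinv @ Xt, Xt.T @ Vinv)
    Lam = Gt.T @ Pt @ Gt
    lam = np.linalg.eigvalsh(Lam)
    return q, mixture_chisq_p(lam[lam > 1e-10 * lam.max()], q)


class TestNullFit:
    def test_k1_reduces_to_univariate(self):
        X, G, Y, _ = make_instance(k=1)
        mnull = fit_null_multivariate(Y, X)
        unull = fit_null_univariate(Y[:, 0], X)
        assert mnull.sigma[0, 0] == pytest.approx(unull.sigma2, rel=1e-12)
        np.testing.assert_allclose(mnull.residuals[:, 0], unull.residuals, atol=1e-10)

    def test_independent_traits_near_zero_covariance(self):
        rng = np.random.default_rng(4)
        n = 2000
        X = np.ones((n, 1))
        Y = rng.standard_normal((n, 2))
        mnull = fit_null_multivariate(Y, X)
        assert abs(mnull.sigma[0, 1]) < 3 / np.sqrt(n)

    def test_trait_correlation_recovery(self):
        rng = np.random.default_rng(5)
        n, r = 2000, 0.68
        X = np.ones((n, 1))
        L = np.linalg.cholesky([[1, r], [r, 1]])
        Y = rng.standard_normal((n, 2)) @ L.T
        mnull = fit_null_multivariate(Y, X)
        corr = mnull.sigma[0, 1] / np.sqrt(mnull.sigma[0, 0] * mnull.sigma[1, 1])
        assert corr == pytest.approx(r, abs=0.05)

    def test_collinear_traits_rejected(self):
        X = np.ones((20, 1))
        y = np.random.default_rng(0).standard_normal(20)
        with pytest.raises(ValueError, match="positive definite"):
            fit_null_multivariate(np.column_stack([y, 2 * y]), X)

    def test_residuals_orthogonal_to_design(self):
        X, G, Y, _ = make_instance(seed=3)
        mnull = fit_null_multivariate(Y, X)
        np.testing.assert_allclose(X.T @ mnull.residuals, 0, atol=1e-8)


class TestMuratQ:
    def test_matches_dense_kronecker_construction(self):
        """The factorized spectrum (outer product of the K x K and v x v
        eigenproblems) equals the dense (R x I)^.5 Lam (R x I)^.5 one."""
        import scipy.linalg as sla

        X, G, Y, w = make_instance(seed=7)
        mnull = fit_null_multivariate(Y, X)
        n, k = Y.shape
        Gw = G * np.sqrt(w)
        rho = 0.4
        R = (1 - rho) * np.eye(k) + rho * np.ones((k, k))
        Gt = np.kron(np.eye(k), Gw)
        Xt = np.kron(np.eye(k), X)
        Vinv = np.kron(mnull.sigma_inv, np.eye(n))
        rt = mnull.residuals.T.reshape(-1)
        S = Gt.T @ Vinv @ rt
        M = np.kron(R, np.eye(G.shape[1]))
        q_dense = float(S @ M @ S)
        Pt = Vinv - Vinv @ Xt @ np.linalg.solve(Xt.T @ Vinv @ Xt, Xt.T @ Vinv)
        Lam = Gt.T @ Pt @ Gt
        Mh = sla.sqrtm(M).real
        lam_dense = np.sort(np.linalg.eigvalsh(Mh @ Lam @ Mh))[::-1]
        q, spec = murat_q(mnull, G, w, rho)
        assert q == pytest.approx(q_dense, rel=1e-10)
        np.testing.assert_allclose(
            spec.eigenvalues, lam_dense[: spec.rank], rtol=1e-8
        )

    def test_rho_zero_equals_independent_effects_oracle(self):
        for seed in range(5):
            X, G, Y, w = make_instance(seed=seed)
            mnull = fit_null_multivariate(Y, X)
            q, spec = murat_q(mnull, G, w, rho=0.0)
            p = mixture_chisq_p(spec, q)
            q_oracle, p_oracle = dense_independent_effects_p(X, G, Y, w)
            assert q == pytest.approx(q_oracle, rel=1e-10)
            assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_k1_p_equals_skat_p(self):
        for seed in range(10):
            X, G, Y, w = make_instance(seed=100 + seed, k=1)
            mnull = fit_null_multivariate(Y, X)
            qm, sm = murat_q(mnull, G, w, rho=0.6)
            pm = mixture_chisq_p(sm, qm)
            unull = fit_null_univariate(Y[:, 0], X)
            qu, su = skat_q(unull, G, w)
            pu = mixture_chisq_p(su, qu)
            assert pm == pytest.approx(pu, rel=1e-10)

    def test_tail_matches_monte_carlo(self):
        X, G, Y, w = make_instance(seed=11)
        mnull = fit_null_multivariate(Y, X)
        q, spec = murat_q(mnull, G, w, rho=0.3)
        p = mixture_chisq_p(spec, q)
        rng = np.random.default_rng(2)
        draws = rng.chisquare(1, (200_000, spec.rank)) @ spec.eigenvalues
        mc = float((draws >= q).mean())
        se = np.sqrt(max(mc * (1 - mc), 1e-12) / 200_000)
        assert p == pytest.approx(mc, abs=3 * se)

    def test_invalid_rho(self):
        X, G, Y, w = make_instance()
        mnull = fit_null_multivariate(Y, X)
        with pytest.raises(ValueError, match="rho"):
            murat_q(mnull, G, w, rho=1.5)


class TestRhoGrid:
    def test_default_grid(self):
        g = RhoGrid()
        assert len(g.values) == 11
        assert g.values[0] == 0.0 and g.values[-1] == 1.0

    def test_from_string(self):
        assert RhoGrid.from_string("0:1:0.1").values == RhoGrid().values
        assert RhoGrid.from_string("0,0.5,1").values == (0.0, 0.5, 1.0)

    def test_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            RhoGrid((0.0, 0.5, 0.5))
        with pytest.raises(ValueError, match="contain 0"):
            RhoGrid((0.1, 0.5))
        with pytest.raises(ValueError, match="<= 1"):
            RhoGrid((0.0, 1.2))


class TestOmnibus:
    def test_single_point_grid_is_exact(self):
        X, G, Y, w = make_instance(seed=17)
        mnull = fit_null_multivariate(Y, X)
        res = murat_omnibus(mnull, G, w, grid=RhoGrid((0.0,)), seed=0)
        q, spec = murat_q(mnull, G, w, 0.0)
        assert res.omnibus_p == pytest.approx(mixture_chisq_p(spec, q), rel=1e-12)
        assert res.optimal_rho == 0.0

    def test_k1_omnibus_equals_univariate_p(self):
        X, G, Y, w = make_instance(seed=19, k=1)
        mnull = fit_null_multivariate(Y, X)
        res = murat_omnibus(mnull, G, w, seed=0)
        unull = fit_null_univariate(Y[:, 0], X)
        qu, su = skat_q(unull, G, w)
        assert res.omnibus_p == pytest.approx(mixture_chisq_p(su, qu), rel=1e-10)

    def test_selection_penalty_and_bonferroni_envelope(self):
        for seed in (23, 29, 31):
            X, G, Y, w = make_instance(seed=seed)
            mnull = fit_null_multivariate(Y, X)
            res = murat_omnibus(mnull, G, w, seed=5, mc_draws=20_000)
            assert res.omnibus_p >= res.min_p
            assert res.omnibus_p <= min(1.0, len(res.rho_grid) * res.min_p) + 1e-12

    def test_optimal_rho_in_grid_and_tie_break(self):
        X, G, Y, w = make_instance(seed=37)
        mnull = fit_null_multivariate(Y, X)
        res = murat_omnibus(mnull, G, w, seed=5, mc_draws=10_000)
        assert res.optimal_rho in res.rho_grid
        assert res.min_p == min(res.p_by_rho.values())

    def test_seed_reproducibility_bitwise(self):
        X, G, Y, w = make_instance(seed=41)
        mnull = fit_null_multivariate(Y, X)
        r1 = murat_omnibus(mnull, G, w, seed=99, mc_draws=10_000)
        r2 = murat_omnibus(mnull, G, w, seed=99, mc_draws=10_000)
        assert r1.omnibus_p == r2.omnibus_p

    def test_trait_permutation_leaves_grid_invariant(self):
        """R_rho is exchangeable, so swapping traits leaves Q(rho) and
        p(rho) unchanged exactly; the Monte-Carlo omnibus agrees to MC
        accuracy (its latent draws rotate with the trait basis)."""
        X, G, Y, w = make_instance(seed=43)
        m1 = fit_null_multivariate(Y, X)
        m2 = fit_null_multivariate(Y[:, ::-1], X)
        r1 = murat_omnibus(m1, G, w, seed=7, mc_draws=100_000)
        r2 = murat_omnibus(m2, G, w, seed=7, mc_draws=100_000)
        for rho in r1.rho_grid:
            assert r1.q_by_rho[rho] == pytest.approx(r2.q_by_rho[rho], rel=1e-10)
            assert r1.p_by_rho[rho] == pytest.approx(r2.p_by_rho[rho], rel=1e-8)
        se = np.sqrt(r1.omnibus_p * (1 - r1.omnibus_p) / 100_000)
        assert abs(r1.omnibus_p - r2.omnibus_p) <= max(4 * se, 0.01 * r1.omnibus_p)

    def test_too_few_draws_rejected(self):
        X, G, Y, w = make_instance()
        mnull = fit_null_multivariate(Y, X)
        with pytest.raises(ValueError, match="10,000"):
            murat_omnibus(mnull, G, w, mc_draws=500)

    def test_untestable_region_flagged(self):
        X, _, Y, _ = make_instance(seed=47)
        mnull = fit_null_multivariate(Y, X)
        with pytest.warns(UserWarning):
            res = murat_omnibus(mnull, np.zeros((Y.shape[0], 2)), seed=0)
        assert res.omnibus_p == 1.0
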