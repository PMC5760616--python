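"""Reproducible simulation studies validating the test machinery.

Each function runs a self-contained experiment on synthetic data drawn
from the generative model in :mod:`murat.simulate` and returns summary
numbers: null calibration of the tests, Monte-Carlo verification of the
mixture-of-chi-squares tail, exactness of the K=1 and rho=0 reductions,
the multivariate-vs-univariate power comparison, structural checks of the
region builders, and recovery of the effective number of tests by
permutation.  They are used by the test suite and by the acceptance
script; all are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .assoc import (
    adjusted_univariate_p,
    fit_null_univariate,
    mixture_chisq_p,
    mixture_chisq_quantile,
    skat_q,
    skat_test,
)
from .datamodel import Region
from .multivariate import fit_null_multivariate, murat_omnibus, murat_q
from .regions import assign_variants, make_gene_pieces, make_windows
from .simulate import SimConfig, simulate_genotypes, simulate_phenotypes
from .thresholds import extrapolate_threshold, permute_min_p
from .weights import WeightScheme

__all__ = [
    "null_calibration",
    "power_study",
    "mixture_mc_agreement",
    "reduction_checks",
    "region_builder_checks",
    "threshold_extrapolation_study",
]

#: residual trait correlation used throughout (the BMD regime)
TRAIT_CORR = 0.6775


def _one_dataset(tau, rho_sim, seed, n, v):
    cfg = SimConfig(n_samples=n, n_variants=v, tau=tau, rho_sim=rho_sim, seed=seed)
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(cfg, rng)
    phen, cov, _ = simulate_phenotypes(G, cfg, rng)
    Gd = G.dosages[:, G.sample_maf() > 0]
    return Gd, phen.values, cov.design(), rng


def _both_tests(tau, rho_sim, seed, n, v, mc_draws):
    Gd, Y, X, rng = _one_dataset(tau, rho_sim, seed, n, v)
    p_uni = [skat_test(fit_null_univariate(Y[:, k], X), Gd) for k in range(Y.shape[1])]
    mres = murat_omnibus(fit_null_multivariate(Y, X), Gd, mc_draws=mc_draws, seed=rng)
    return p_uni, mres.omnibus_p


def null_calibration(
    n_reps: int = 2000,
    n: int = 500,
    v: int = 20,
    alpha: float = 0.05,
    mc_draws: int = 20_000,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the omnibus multivariate test and the
    per-trait univariate test on pure-null data (tau = 0, K = 2 traits
    with residual correlation 0.6775)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rej_m = 0
    rej_u = 0
    n_uni = 0
    for s in seeds:
        p_uni, p_m = _both_tests(0.0, 0.0, int(s), n, v, mc_draws)
        rej_m += p_m < alpha
        rej_u += sum(p < alpha for p in p_uni)
        n_uni += len(p_uni)
    return {
        "type1_murat": rej_m / n_reps,
        "type1_skat": rej_u / n_uni,
        "n_reps": n_reps,
        "alpha": alpha,
    }


def power_study(
    n_reps: int = 400,
    n: int = 500,
    v: int = 20,
    tau: float = 0.2,
    rho_sim: float = 0.7,
    alpha: float = 0.01,
    mc_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Power of the multivariate omnibus test versus the adjusted (min-p)
    univariate test, with all variants causal and pleiotropic effects.

    Both tests are compared at the same nominal alpha; the paired
    discordant counts feed a one-sided binomial test of the direction.
    The FWER-matched univariate power (min-p against alpha / K, the
    Bonferroni charge for testing K traits separately) is also reported.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rej = np.zeros((n_reps, 3), dtype=bool)  # murat, adj@alpha, adj@alpha/K
    for i, s in enumerate(seeds):
        p_uni, p_m = _both_tests(tau, rho_sim, int(s), n, v, mc_draws)
        p_adj = adjusted_univariate_p(p_uni)
        rej[i] = (p_m < alpha, p_adj < alpha, p_adj < alpha / len(p_uni))
    a = int(np.sum(rej[:, 0] & ~rej[:, 1]))
    b = int(np.sum(~rej[:, 0] & rej[:, 1]))
    binom_p = (
        float(stats.binomtest(a, a + b, alternative="greater").pvalue)
        if a + b
        else 1.0
    )
    return {
        "power_murat": float(rej[:, 0].mean()),
        "power_adjusted_skat": float(rej[:, 1].mean()),
        "power_adjusted_skat_fwer": float(rej[:, 2].mean()),
        "discordant_murat_only": a,
        "discordant_skat_only": b,
        "binomial_p_one_sided": binom_p,
        "n_reps": n_reps,
        "alpha": alpha,
    }


def mixture_mc_agreement(
    n_specs: int = 20, draws: int = 1_000_000, seed: int = 0
) -> dict:
    """Analytic mixture tails versus Monte-Carlo over random eigenvalue
    spectra; returns the largest |z| (deviation in MC standard errors)."""
    rng = np.random.default_rng(seed)
    max_z = 0.0
    for _ in range(n_specs):
        n_eig = int(rng.integers(2, 30))
        lam = rng.uniform(0.05, 3.0, n_eig)
        target = float(10 ** rng.uniform(-3, np.log10(0.5)))
        q = mixture_chisq_quantile(lam, target)
        p = mixture_chisq_p(lam, q)
        mc = float((rng.chisquare(1, (draws, n_eig)) @ lam >= q).mean())
        se = np.sqrt(max(mc * (1 - mc), 1e-12) / draws)
        max_z = max(max_z, abs(p - mc) / se)
    return {"max_abs_z": max_z, "n_specs": n_specs, "draws": draws}


def _sig_digit_agreement(a: float, b: float) -> float:
    """Relative difference; 1e-10 corresponds to ~10 significant digits."""
    return abs(a - b) / max(abs(a), abs(b), 1e-300)


def reduction_checks(n_instances: int = 50, seed: int = 0) -> dict:
    """Exactness of the two analytic reductions of the multivariate test:
    K=1 equals the univariate test; rho=0 equals an independently coded
    independent-effects test built from dense Kronecker matrices."""
    rng = np.random.default_rng(seed)
    worst_k1 = 0.0
    for _ in range(n_instances):
        n, v = int(rng.integers(80, 200)), int(rng.integers(2, 12))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        G = rng.binomial(2, rng.uniform(0.02, 0.3, v), (n, v)).astype(float)
        G = G[:, np.ptp(G, axis=0) > 0]
        if G.shape[1] == 0:
            continue
        w = rng.uniform(0.5, 2.0, G.shape[1])
        y = rng.standard_normal(n)
        mnull = fit_null_multivariate(y[:, None], X)
        qm, sm = murat_q(mnull, G, w, rho=float(rng.uniform(0, 1)))
        pm = mixture_chisq_p(sm, qm)
        qu, su = skat_q(fit_null_univariate(y, X), G, w)
        pu = mixture_chisq_p(su, qu)
        worst_k1 = max(worst_k1, _sig_digit_agreement(pm, pu))

    worst_rho0 = 0.0
    for _ in range(10):
        n, v, k = 120, int(rng.integers(2, 8)), 2
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        G = rng.binomial(2, rng.uniform(0.05, 0.3, v), (n, v)).astype(float)
        G = G[:, np.ptp(G, axis=0) > 0]
        if G.shape[1] == 0:
            continue
        w = rng.uniform(0.5, 2.0, G.shape[1])
        R = (1 - TRAIT_CORR) * np.eye(k) + TRAIT_CORR * np.ones((k, k))
        Y = rng.standard_normal((n, k)) @ np.linalg.cholesky(R).T
        mnull = fit_null_multivariate(Y, X)
        q0, s0 = murat_q(mnull, G, w, rho=0.0)
        p0 = mixture_chisq_p(s0, q0)
        # independently coded dense construction
        Gw = G * np.sqrt(w)
        Gt = np.kron(np.eye(k), Gw)
        Xt = np.kron(np.eye(k), X)
        Vinv = np.kron(mnull.sigma_inv, np.eye(n))
        S = Gt.T @ Vinv @ mnull.residuals.T.reshape(-1)
        q_dense = float(S @ S)
        Pt = Vinv - Vinv @ Xt @ np.linalg.solve(Xt.T @ Vinv @ Xt, Xt.T @ Vinv)
        lam = np.linalg.eigvalsh(Gt.T @ Pt @ Gt)
        p_dense = mixture_chisq_p(lam[lam > 1e-10 * lam.max()], q_dense)
        worst_rho0 = max(worst_rho0, _sig_digit_agreement(p0, p_dense))
    return {
        "k1_max_rel_diff": worst_k1,
        "rho0_max_rel_diff": worst_rho0,
        "n_instances": n_instances,
    }


def region_builder_checks(
    n_genes: int = 1000, n_window_regions: int = 1000, seed: int = 0
) -> dict:
    """Structural violations of the gene-piece and window partitions over
    random gene lengths and region sizes (should be zero)."""
    rng = np.random.default_rng(seed)
    gene_violations = 0
    for _ in range(n_genes):
        start = int(rng.integers(1, 10**8))
        length = int(rng.integers(1, 2_000_000))
        pieces = make_gene_pieces([("1", start, start + length - 1, "g")])
        fstart, fend = max(1, start - 5_000), start + length - 1 + 5_000
        ok = pieces[0].start == fstart and pieces[-1].end == fend
        ok &= all(a.end + 1 == b.start for a, b in zip(pieces, pieces[1:]))
        span = fend - fstart + 1
        if span > 150_000:
            ok &= all(50_000 <= p.length <= 100_000 for p in pieces)
        else:
            ok &= len(pieces) == 1
        gene_violations += not ok

    window_violations = 0
    for _ in range(n_window_regions):
        v = int(rng.integers(1, 300))
        cfg = SimConfig(n_samples=2, n_variants=v, maf=("uniform", 0.2, 0.5), seed=int(rng.integers(2**31)))
        G = simulate_genotypes(cfg)
        reg = Region("1", 1, 10**9, variant_indices=np.arange(v))
        wins = make_windows(reg, G, 30)
        sizes = [wi.n_variants for wi in wins]
        ok = max(sizes) <= 30 and (max(sizes) - min(sizes) <= 1)
        concat = np.concatenate([wi.variant_indices for wi in wins])
        ok &= np.array_equal(concat, reg.variant_indices)
        window_violations += not ok
    return {
        "gene_piece_violations": gene_violations,
        "window_violations": window_violations,
        "n_genes": n_genes,
        "n_window_regions": n_window_regions,
    }


def threshold_extrapolation_study(
    n_perm: int = 500,
    n_regions: int = 25,
    v_per: int = 4,
    n: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Permutation min-p extrapolation on independent null tests.

    Regions hold disjoint, LD-free variants and a single trait is
    scanned, so the tests are independent and the nominal count is
    n_regions; the extrapolated threshold should sit near alpha divided
    by that count.  (With multiple correlated traits the effective count
    would legitimately drop below the nominal one.)"""
    cfg = SimConfig(
        n_samples=n,
        n_variants=n_regions * v_per,
        maf=("uniform", 0.05, 0.3),
        ld=0.0,
        tau=0.0,
        n_traits=1,
        sigma=np.array([[1.0]]),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    G = simulate_genotypes(cfg, rng)
    phen, cov, _ = simulate_phenotypes(G, cfg, rng)
    pos = G.variants["pos"].to_numpy()
    regions = assign_variants(
        [
            Region("1", int(pos[i * v_per]), int(pos[(i + 1) * v_per - 1]), label=f"r{i}")
            for i in range(n_regions)
        ],
        G,
    )
    run = permute_min_p(
        G, phen, cov, regions, [WeightScheme("identical")],
        test="skat", n_perm=n_perm, seed=seed,
    )
    m_nominal = n_regions * phen.n_traits
    m_eff, threshold = extrapolate_threshold(run, alpha)
    return {
        "m_eff": m_eff,
        "m_nominal": m_nominal,
        "threshold": threshold,
        "threshold_over_bonferroni": threshold / (alpha / m_nominal),
        "n_perm": n_perm,
    }
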