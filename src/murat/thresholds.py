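"""Genome-wide significance thresholds.

Two routes are provided:

* a Bonferroni threshold ``alpha / (n_weights * n_phenotype_tests *
  n_regions)``, counting every weighting scheme and separately-tested
  phenotype as a test; and
* a permutation-based estimate of the *effective* number of independent
  tests: phenotype-genotype links are broken by permuting the genotype
  sample order, the full region x weight scan is re-run per permutation,
  and the per-scan minimum p-value is recorded.  Under M independent
  tests the minimum p is Beta(1, M); fitting M by maximum likelihood and
  inverting gives the family-wise threshold 1 - (1 - alpha)^(1/M_eff).
  Correlated tests yield M_eff below the nominal count, hence a *less*
  stringent threshold than Bonferroni; the converse (estimated threshold
  more stringent than Bonferroni) indicates estimation noise and is
  surfaced as a warning so callers can fall back to Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .assoc import fit_null_univariate, skat_test
from .multivariate import RhoGrid, fit_null_multivariate, murat_omnibus
from .weights import compute_weights

__all__ = [
    "PermutationRun",
    "bonferroni_threshold",
    "permute_min_p",
    "extrapolate_threshold",
]


@dataclass
class PermutationRun:
    """Per-permutation scan minima plus the scope that produced them."""

    min_p: np.ndarray
    n_permutations: int
    seed: int | None
    scope: str

    def __post_init__(self) -> None:
        self.min_p = np.asarray(self.min_p, dtype=float)
        if self.min_p.size != self.n_permutations:
            raise ValueError("one minimum p-value per permutation required")
        if np.any(self.min_p <= 0) or np.any(self.min_p > 1):
            raise ValueError("minimum p-values must lie in (0, 1]")


def bonferroni_threshold(
    alpha: float, n_weights: int, n_phenotype_tests: int, n_regions: int
) -> float:
    """alpha divided by the total test count (weights x phenotypes x regions)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    for label, n in (
        ("n_weights", n_weights),
        ("n_phenotype_tests", n_phenotype_tests),
        ("n_regions", n_regions),
    ):
        if n < 1:
            raise ValueError(f"{label} must be >= 1")
    return alpha / (n_weights * n_phenotype_tests * n_regions)


def _scan_min_p(genotypes_dosages, regions, weight_vectors, test, nulls, mnull,
                grid, mc_draws, rng):
    best = 1.0
    for reg_idx, region in enumerate(regions):
        idx = region.variant_indices
        if idx.size == 0:
            continue
        G = genotypes_dosages[:, idx]
        for w in weight_vectors[reg_idx]:
            if w is None:
                continue
            if test == "skat":
                for null in nulls:
                    best = min(best, skat_test(null, G, w))
            else:
                res = murat_omnibus(mnull, G, w, grid=grid, mc_draws=mc_draws, seed=rng)
                best = min(best, res.omnibus_p)
    return best


def permute_min_p(
    genotypes,
    phenotypes,
    covariates,
    regions,
    weight_schemes,
    test: str = "skat",
    n_perm: int = 100,
    seed: int | None = None,
    rho_grid: RhoGrid | None = None,
    mc_draws: int = 10_000,
) -> PermutationRun:
    """Minimum scan p-value under n_perm genotype-order permutations.

    The genotype matrix rows are shuffled while phenotypes and covariates
    stay aligned to each other, so the phenotype-covariate model (and any
    genotype-derived covariates already in it) is preserved while every
    genotype-phenotype association is broken.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if test not in ("skat", "murat"):
        raise ValueError(f"unknown test {test!r}")
    active = [r for r in regions if r.n_variants > 0]
    if not active or not weight_schemes:
        raise ValueError("permutation scope is empty (no testable regions/weights)")
    X = covariates.design()
    Y = phenotypes.values
    nulls = [fit_null_univariate(Y[:, k], X) for k in range(Y.shape[1])]
    mnull = fit_null_multivariate(Y, X) if test == "murat" else None
    grid = rho_grid or RhoGrid()

    # weights depend on MAF only, which is invariant under row permutation
    maf = genotypes.sample_maf()
    weight_vectors = []
    for region in active:
        per_scheme = []
        for scheme in weight_schemes:
            m = maf[region.variant_indices]
            keep = m > 0
            per_scheme.append(compute_weights(m[keep], scheme) if keep.any() else None)
        weight_vectors.append(per_scheme)
    # pre-drop monomorphic columns so weight vectors stay aligned
    active = [
        r.with_variants(r.variant_indices[maf[r.variant_indices] > 0])
        for r in active
    ]

    rng = np.random.default_rng(seed)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(genotypes.n_samples)
        dosages = genotypes.dosages[perm]
        minima[b] = _scan_min_p(
            dosages, active, weight_vectors, test, nulls, mnull, grid, mc_draws, rng
        )
    scope = f"{len(active)} regions x {len(weight_schemes)} weights, test={test}"
    return PermutationRun(minima, n_perm, seed, scope)


def extrapolate_threshold(
    run: PermutationRun, alpha: float = 0.05, n_nominal_tests: int | None = None
):
    """Effective test count and family-wise threshold from scan minima.

    Fits min-p ~ Beta(1, M) by maximum likelihood:
    M_hat = n / sum(-log(1 - p_min)).  Returns ``(m_eff, threshold)`` with
    threshold = 1 - (1 - alpha)^(1 / M_eff).  If ``n_nominal_tests`` is
    given and the estimate is *more* stringent than Bonferroni, a warning
    is emitted (correlation can only reduce the effective count).
    """
    p = run.min_p
    if p.size == 0:
        raise ValueError("empty permutation run")
    if np.allclose(p, p[0]):
        raise ValueError("all permutation minima identical; cannot fit Beta(1, M)")
    m_eff = p.size / float(np.sum(-np.log1p(-p)))
    threshold = 1.0 - (1.0 - alpha) ** (1.0 / m_eff)
    if n_nominal_tests is not None:
        bonf = alpha / n_nominal_tests
        if threshold < bonf:
            warnings.warn(
                f"extrapolated threshold {threshold:.3g} is more stringent than "
                f"Bonferroni {bonf:.3g}; this indicates estimation noise - "
                "consider using the Bonferroni threshold",
                stacklevel=2,
            )
    return float(m_eff), float(threshold)
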