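"""Synthetic genotypes, covariates and correlated phenotypes.

The generator draws data from the same mixed model the tests assume:
haplotypes come from a first-order Markov chain on {0, 1} with a chosen
per-site allele-frequency spectrum and adjacent-site correlation (a crude
but controllable stand-in for local LD); genotypes are haplotype sums.
Phenotypes follow

    Y_i = alpha_0 + alpha' X_i + beta' G_i + eps_i,
    beta ~ N(0, tau^2 * R_rho (x) W_sim)  on the causal variants,
    eps_i ~ i.i.d. N(0, Sigma_sim),

so a variant's effects on the K traits share correlation ``rho_sim``
(pleiotropy) and the residuals carry the trait correlation.  Covariates
mimic the usual epidemiological set (age, age^2, sex, weight) with fixed
coefficients.  Defaults target the regime of the motivating BMD study:
two traits with residual correlation 0.6775, 500 samples, 20 rare
variants with MAF in (0.005, 0.05).

The effect-size scale ``tau`` is per standardized weight unit: beta_kj has
standard deviation tau * sqrt(w_sim_j).  ``tau = 0`` gives pure null data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes", "simulate_dataset"]

#: residual trait correlation observed between the two log-BMD measures
DEFAULT_TRAIT_CORR = 0.6775

#: fixed covariate coefficients (age, age^2, sex, weight) per trait; the
#: second trait gets slightly different loadings so traits are not clones
COVARIATE_COEF = np.array(
    [
        [-0.004, -0.005],
        [-0.00002, -0.00002],
        [0.08, 0.06],
        [0.003, 0.004],
    ]
)


def _default_sigma() -> np.ndarray:
    return np.array([[1.0, DEFAULT_TRAIT_CORR], [DEFAULT_TRAIT_CORR, 1.0]])


@dataclass
class SimConfig:
    """Knobs of the generative model (see module docstring for the model)."""

    n_samples: int = 500
    n_variants: int = 20
    maf: tuple = ("uniform", 0.005, 0.05)  # or ("fixed", [maf_1, ..., maf_v])
    ld: float = 0.0                        # adjacent-haplotype correlation in [0, 1)
    n_traits: int = 2
    sigma: np.ndarray = field(default_factory=_default_sigma)
    causal_idx: np.ndarray | None = None   # default: all variants
    tau: float = 0.0                       # sqrt of the effect variance component
    rho_sim: float = 0.0                   # effect correlation across traits
    w_sim: np.ndarray | None = None        # per-variant effect variance weights
    seed: int | None = None
    chrom: str = "1"
    pos_start: int = 10_000
    pos_step: int = 150

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.n_traits, self.n_traits):
            raise ValueError("sigma must be K x K")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("sigma must be positive definite")
        if not 0.0 <= self.rho_sim <= 1.0:
            raise ValueError("rho_sim must lie in [0, 1]")
        if not 0.0 <= self.ld < 1.0:
            raise ValueError("ld must lie in [0, 1)")
        if self.causal_idx is not None:
            self.causal_idx = np.asarray(self.causal_idx, dtype=int)
            if self.causal_idx.size and (
                self.causal_idx.min() < 0 or self.causal_idx.max() >= self.n_variants
            ):
                raise ValueError("causal indices out of range")

    def site_frequencies(self, rng: np.random.Generator) -> np.ndarray:
        kind = self.maf[0]
        if kind == "uniform":
            lo, hi = float(self.maf[1]), float(self.maf[2])
            if hi > 0.5 or lo <= 0:
                raise ValueError("uniform MAF bounds must lie in (0, 0.5]")
            return rng.uniform(lo, hi, self.n_variants)
        if kind == "fixed":
            p = np.asarray(self.maf[1], dtype=float)
            if p.size != self.n_variants:
                raise ValueError("fixed MAF list length must equal n_variants")
            if p.max() > 0.5 or p.min() <= 0:
                raise ValueError("fixed MAFs must lie in (0, 0.5]")
            return p
        raise ValueError(f"unknown MAF spectrum {kind!r}")


def _markov_haplotypes(p: np.ndarray, ld: float, n_hap: int, rng) -> np.ndarray:
    """n_hap haplotypes over sites with frequencies p and adjacent corr ld."""
    v = p.size
    H = np.empty((n_hap, v), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < p[0]
    sd = np.sqrt(p * (1.0 - p))
    for j in range(1, v):
        cond = p[j] + ld * sd[j] / sd[j - 1] * (H[:, j - 1] - p[j - 1])
        H[:, j] = rng.random(n_hap) < np.clip(cond, 0.0, 1.0)
    return H


def simulate_genotypes(cfg: SimConfig, rng=None) -> GenotypeMatrix:
    """Genotypes as sums of two Markov-chain haplotypes; seed-deterministic."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = cfg.site_frequencies(rng)
    H = _markov_haplotypes(p, cfg.ld, 2 * cfg.n_samples, rng)
    dosages = (H[::2] + H[1::2]).astype(float)
    variants = {
        "chrom": [cfg.chrom] * cfg.n_variants,
        "pos": cfg.pos_start + cfg.pos_step * np.arange(cfg.n_variants),
        "id": [f"sim{j + 1}" for j in range(cfg.n_variants)],
    }
    import pandas as pd

    return GenotypeMatrix(
        samples=[f"S{i + 1}" for i in range(cfg.n_samples)],
        dosages=dosages,
        variants=pd.DataFrame(variants),
    )


def _draw_covariates(n: int, rng) -> CovariateMatrix:
    age = rng.normal(70.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    weight = rng.normal(75.0, 13.0, n)
    values = np.column_stack([age, age**2, sex, weight])
    return CovariateMatrix(
        samples=[f"S{i + 1}" for i in range(n)],
        values=values,
        names=["age", "age2", "sex", "weight"],
    )


def simulate_phenotypes(G: GenotypeMatrix, cfg: SimConfig, rng=None):
    """Phenotypes, covariates and the true effect matrix for one dataset.

    The variant effects are redrawn per call (the random-effects view the
    test itself takes).  Returns ``(PhenotypeMatrix, CovariateMatrix,
    betas)`` with ``betas`` of shape v x K, zero off the causal set.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, v, k = G.n_samples, G.n_variants, cfg.n_traits
    if n != cfg.n_samples:
        raise ValueError("genotype sample count does not match the config")
    cov = _draw_covariates(n, rng)
    coef = COVARIATE_COEF[:, :k] if k <= 2 else np.tile(COVARIATE_COEF[:, :1], (1, k))

    betas = np.zeros((v, k))
    causal = np.arange(v) if cfg.causal_idx is None else cfg.causal_idx
    if cfg.tau > 0 and causal.size:
        R = (1.0 - cfg.rho_sim) * np.eye(k) + cfg.rho_sim * np.ones((k, k))
        # symmetric square root (exact even at rho = 1, where R is rank 1)
        d, U = np.linalg.eigh(R)
        Rh = (U * np.sqrt(np.clip(d, 0.0, None))) @ U.T
        w = np.ones(v) if cfg.w_sim is None else np.asarray(cfg.w_sim, dtype=float)
        raw = rng.standard_normal((causal.size, k)) @ Rh
        betas[causal] = cfg.tau * np.sqrt(w[causal])[:, None] * raw

    eps = rng.standard_normal((n, k)) @ np.linalg.cholesky(cfg.sigma).T
    values = cov.values @ coef + G.dosages @ betas + eps
    phen = PhenotypeMatrix(
        samples=list(G.samples),
        values=values,
        trait_names=[f"trait{i + 1}" for i in range(k)],
    )
    return phen, cov, betas


def simulate_dataset(cfg: SimConfig):
    """One seed-reproducible dataset: (genotypes, phenotypes, covariates, betas)."""
    rng = np.random.default_rng(cfg.seed)
    G = simulate_genotypes(cfg, rng)
    phen, cov, betas = simulate_phenotypes(G, cfg, rng)
    return G, phen, cov, betas
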