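"""Study workflow: phenotype preprocessing, ancestry PCs, region scan.

The scan couples the pieces: for every region x weight scheme it runs the
per-trait univariate variance-component test (plus their minimum, the
'adjusted' univariate p-value) and the multivariate omnibus test, and
emits a results table plus QQ-plot-ready summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import adjusted_univariate_p, fit_null_univariate, skat_test
from .datamodel import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix, Region, TestResult
from .multivariate import RhoGrid, fit_null_multivariate, murat_omnibus
from .weights import WeightScheme, compute_weights

__all__ = [
    "preprocess_phenotypes",
    "compute_pcs",
    "run_scan",
    "qq_summary",
    "inflation_lambda",
]

log = logging.getLogger(__name__)


def preprocess_phenotypes(
    raw: PhenotypeMatrix, study_labels=None
) -> PhenotypeMatrix:
    """Natural-log transform each trait; optionally z-standardize per study.

    All raw values must be positive.  When ``study_labels`` (one label per
    sample) is given, each trait is centered and scaled to unit variance
    within each study after the log transform, the usual guard when
    combining cohorts measured on different instruments.
    """
    values = np.array(raw.values, dtype=float)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive phenotype for sample {raw.samples[i]!r}, trait "
            f"{raw.trait_names[j]!r}: cannot log-transform"
        )
    values = np.log(values)
    if study_labels is not None:
        labels = np.asarray(study_labels)
        if labels.shape[0] != values.shape[0]:
            raise ValueError("one study label per sample required")
        for lab in np.unique(labels):
            mask = labels == lab
            mu = values[mask].mean(axis=0)
            sd = values[mask].std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError(f"constant trait within study {lab!r}")
            values[mask] = (values[mask] - mu) / sd
    return PhenotypeMatrix(
        samples=list(raw.samples),
        values=values,
        trait_names=list(raw.trait_names),
        log_transformed=[True] * len(raw.trait_names),
    )


def compute_pcs(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.48,
    ld_r2_max: float = 0.1,
    n_pcs: int = 5,
):
    """Ancestry principal components from common, LD-pruned variants.

    Variants with in-sample MAF > ``maf_min`` are greedily LD-pruned
    (each candidate kept only if its squared correlation with every
    already-kept variant stays below ``ld_r2_max``), standardized, and
    decomposed by SVD.  Returns ``(scores, variance_fractions)`` where
    scores is N x n_pcs and variance_fractions covers all components of
    the pruned set (for a scree plot).  ``n_pcs = 0`` returns an empty
    score matrix.
    """
    if n_pcs == 0:
        return np.empty((genotypes.n_samples, 0)), np.empty(0)
    maf = genotypes.sample_maf()
    eligible = np.flatnonzero(maf > maf_min)
    if eligible.size < n_pcs:
        raise ValueError(
            f"only {eligible.size} variants with MAF > {maf_min}; "
            f"cannot compute {n_pcs} PCs"
        )
    D = genotypes.dosages[:, eligible]
    Z = (D - D.mean(axis=0)) / D.std(axis=0)
    kept: list[int] = []
    for j in range(Z.shape[1]):
        if kept:
            r = Z[:, kept].T @ Z[:, j] / Z.shape[0]
            if np.max(r**2) >= ld_r2_max:
                continue
        kept.append(j)
    if len(kept) < n_pcs:
        raise ValueError(
            f"only {len(kept)} variants survive LD pruning; "
            f"cannot compute {n_pcs} PCs"
        )
    Zk = Z[:, kept]
    U, s, _ = np.linalg.svd(Zk - Zk.mean(axis=0), full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    scores = U[:, :n_pcs] * s[:n_pcs]
    return scores, fractions


def qq_summary(pvalues) -> pd.DataFrame:
    """Sorted observed -log10 p against uniform expected quantiles."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)  # most significant first, matching expected order
    return pd.DataFrame({"expected": expected, "observed": observed})


def inflation_lambda(pvalues) -> float:
    """Genomic-control lambda: median test chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / stats.chi2.isf(0.5, 1))


def run_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates: CovariateMatrix,
    regions: list[Region],
    weight_schemes: list[WeightScheme],
    tests=("skat", "murat"),
    rho_grid: RhoGrid | None = None,
    mc_draws: int = 100_000,
    seed: int | None = None,
    maf_source: str = "sample",
    rare_maf_cutoff: float = 0.05,
    out_prefix: str | None = None,
):
    """Evaluate every region x weight scheme; optionally write TSV outputs.

    Returns ``(results, table, qq_tables)``: the list of TestResult
    objects, the tidy results DataFrame, and a dict of QQ summaries per
    p-value column.  With ``out_prefix`` the table is written to
    ``<prefix>_results.tsv`` and the QQ summaries to
    ``<prefix>_qq_<column>.tsv``.
    """
    if genotypes.samples != phenotypes.samples or genotypes.samples != covariates.samples:
        raise ValueError("genotypes, phenotypes and covariates must share sample order")
    grid = rho_grid or RhoGrid()
    X = covariates.design()
    Y = phenotypes.values
    k = Y.shape[1]
    do_skat = "skat" in tests
    do_murat = "murat" in tests
    nulls = [fit_null_univariate(Y[:, t], X) for t in range(k)] if do_skat else []
    mnull = fit_null_multivariate(Y, X) if do_murat else None
    maf_all = genotypes.maf(maf_source)
    sample_maf = genotypes.sample_maf()
    rng = np.random.default_rng(seed)

    results: list[TestResult] = []
    n_dropped = 0
    for region in regions:
        idx = region.variant_indices
        usable = idx[sample_maf[idx] > 0] if idx.size else idx
        pct_rare = (
            100.0 * float(np.mean(maf_all[idx] < rare_maf_cutoff)) if idx.size else float("nan")
        )
        for scheme in weight_schemes:
            res = TestResult(
                region=region,
                weight_name=scheme.name,
                n_variants=int(idx.size),
                pct_rare=pct_rare,
            )
            if usable.size == 0:
                res.notes = "no polymorphic variants"
                n_dropped += 1
                results.append(res)
                continue
            G = genotypes.dosages[:, usable]
            w = compute_weights(maf_all[usable], scheme)
            if do_skat:
                res.univariate_p = [skat_test(null, G, w) for null in nulls]
                res.adjusted_p = adjusted_univariate_p(res.univariate_p)
            if do_murat:
                mres = murat_omnibus(mnull, G, w, grid=grid, mc_draws=mc_draws, seed=rng)
                res.q_by_rho = mres.q_by_rho
                res.p_by_rho = mres.p_by_rho
                res.optimal_rho = mres.optimal_rho
                res.omnibus_p = mres.omnibus_p
            results.append(res)

    log.info(
        "scan: %d regions x %d weights = %d rows (%d untestable)",
        len(regions), len(weight_schemes), len(results), n_dropped,
    )

    rows = []
    for r in results:
        row = {
            "chrom": r.region.chrom,
            "start": r.region.start,
            "end": r.region.end,
            "gene": r.region.label,
            "piece": r.region.piece_index,
            "n_variants": r.n_variants,
            "pct_rare": r.pct_rare,
            "weight": r.weight_name,
        }
        for t in range(k):
            row[f"p_{phenotypes.trait_names[t]}"] = (
                r.univariate_p[t] if r.univariate_p else np.nan
            )
        row["p_adj_univariate"] = r.adjusted_p if r.adjusted_p is not None else np.nan
        row["p_murat"] = r.omnibus_p if r.omnibus_p is not None else np.nan
        row["optimal_rho"] = r.optimal_rho if r.optimal_rho is not None else np.nan
        row["note"] = r.notes
        rows.append(row)
    table = pd.DataFrame(rows)

    qq_tables = {}
    p_cols = [c for c in table.columns if c.startswith("p_")]
    for col in p_cols:
        vals = table[col].dropna()
        if len(vals):
            qq_tables[col] = qq_summary(vals)

    if out_prefix is not None:
        table.to_csv(f"{out_prefix}_results.tsv", sep="\t", index=False)
        for col, qq in qq_tables.items():
            qq.to_csv(f"{out_prefix}_qq_{col}.tsv", sep="\t", index=False)
    return results, table, qq_tables
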