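"""Readers and writers for genotypes, tables, regions and results.

Supported external formats:

* genotypes: VCF v4.x (``DS`` dosage field preferred, ``GT`` otherwise;
  multi-allelic sites are rejected) or a plain TSV dosage matrix with one
  row per sample and one ``chrom:pos:id`` column per variant;
* phenotypes/covariates: whitespace- or tab-delimited tables with a header
  and a sample-id first column;
* gene intervals: 4-column TSV (chrom, start, end, name; 1-based
  inclusive) or BED (0-based half-open, converted on read);
* results: TSV, one row per region x weight scheme.

All coordinates are 1-based inclusive internally (VCF convention).
Missing dosages are mean-imputed to 2*MAF and counted; sites whose ALT
allele is the major allele are re-oriented so dosages count minor alleles,
with the flip recorded per variant.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CovariateMatrix,
    GenotypeMatrix,
    PhenotypeMatrix,
    Region,
    TestResult,
)

__all__ = [
    "read_genotypes",
    "read_table",
    "read_gene_intervals",
    "write_results",
    "write_vcf",
    "write_regions",
]

log = logging.getLogger(__name__)


def _fold_and_impute(dosages: np.ndarray):
    """Impute missing entries to 2*AF, then orient each column to the
    minor allele.  Returns (dosages, flipped, n_imputed) per variant."""
    n, v = dosages.shape
    n_imputed = np.zeros(v, dtype=int)
    for j in range(v):
        col = dosages[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            fill = 2.0 * (col[~miss].mean() / 2.0) if (~miss).any() else 0.0
            col[miss] = fill
            n_imputed[j] = int(miss.sum())
    af = dosages.mean(axis=0) / 2.0
    flipped = af > 0.5
    dosages[:, flipped] = 2.0 - dosages[:, flipped]
    return dosages, flipped, n_imputed


def _variants_frame(chroms, poss, ids, dosages, flipped, n_imputed) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "id": ids,
            "maf": dosages.mean(axis=0) / 2.0,
            "flipped": flipped,
            "n_imputed": n_imputed,
        }
    )


def _read_vcf(path: str, region: Region | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols, chroms, poss, ids = [], [], [], []
    for i, var in enumerate(vcf):
        if region is not None and not (
            var.CHROM == region.chrom and region.start <= var.POS <= region.end
        ):
            continue
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path} record {i + 1} ({var.CHROM}:{var.POS}): multi-allelic "
                "sites are not supported; decompose the VCF first"
            )
        ds = None
        try:
            fmt = var.FORMAT
        except Exception:
            fmt = []
        if "DS" in fmt:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            ds = np.asarray(var.gt_types, dtype=float)
            ds[ds == 3] = np.nan  # unknown genotype
        if ds.shape[0] != len(samples):
            raise ValueError(
                f"{path} record {i + 1} ({var.CHROM}:{var.POS}): "
                f"{ds.shape[0]} genotype entries for {len(samples)} samples"
            )
        cols.append(ds)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError(f"no usable variant records in {path}")
    dosages = np.column_stack(cols)
    dosages, flipped, n_imputed = _fold_and_impute(dosages)
    if n_imputed.sum():
        log.info("imputed %d missing dosages to 2*MAF", int(n_imputed.sum()))
    variants = _variants_frame(chroms, poss, ids, dosages, flipped, n_imputed)
    return GenotypeMatrix(samples=samples, dosages=dosages, variants=variants)


def _read_matrix(path: str, region: Region | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample ids in {path}")
    chroms, poss, ids, keep = [], [], [], []
    for k, col in enumerate(df.columns):
        parts = str(col).split(":")
        if len(parts) < 2:
            raise ValueError(
                f"{path}: column {col!r} is not of the form chrom:pos[:id]"
            )
        chrom, pos = parts[0], int(parts[1])
        if region is not None and not (
            chrom == region.chrom and region.start <= pos <= region.end
        ):
            continue
        chroms.append(chrom)
        poss.append(pos)
        ids.append(parts[2] if len(parts) > 2 else f"{chrom}:{pos}")
        keep.append(k)
    if not keep:
        raise ValueError(f"no variants selected from {path}")
    dosages = df.iloc[:, keep].to_numpy(dtype=float)
    dosages, flipped, n_imputed = _fold_and_impute(dosages)
    variants = _variants_frame(chroms, poss, ids, dosages, flipped, n_imputed)
    return GenotypeMatrix(samples=samples, dosages=dosages, variants=variants)


def read_genotypes(path, region: Region | None = None) -> GenotypeMatrix:
    """Load a dosage matrix from a VCF (.vcf/.vcf.gz) or TSV matrix file.

    ``GT`` calls are converted to {0, 1, 2}; ``DS`` dosages are used
    verbatim when present.  An optional region restricts to variants
    within it.  After loading, every variant satisfies MAF <= 0.5 (alleles
    re-oriented as needed) and no entry is missing.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path, region)
    return _read_matrix(path, region)


def _load_aligned_table(path, samples):
    df = pd.read_csv(path, sep=None, engine="python")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"duplicate sample id(s) in {path}: {', '.join(dupes)}")
    df = df.set_index(ids).drop(columns=[id_col])
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value in {path}, sample {row!r}, column {col!r}"
            )
        df[col] = coerced
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        log.info("dropped %d incomplete row(s) from %s", n_before - len(df), path)
    if samples is not None:
        missing = [s for s in samples if s not in df.index]
        if missing:
            raise ValueError(
                f"{path} lacks rows for {len(missing)} genotyped sample(s), "
                f"e.g. {missing[:3]}"
            )
        df = df.loc[list(samples)]
    return df


def read_table(path, kind: str = "phenotype", samples=None):
    """Load a phenotype or covariate table, aligned to a sample order.

    The first column is the sample id.  Rows with any missing value are
    dropped (complete-case) and logged; when ``samples`` is given the rows
    are re-ordered to match it and every requested sample must survive.
    """
    df = _load_aligned_table(path, samples)
    ids = [str(s) for s in df.index]
    values = df.to_numpy(dtype=float)
    names = [str(c) for c in df.columns]
    if kind == "phenotype":
        return PhenotypeMatrix(samples=ids, values=values, trait_names=names)
    if kind == "covariate":
        return CovariateMatrix(samples=ids, values=values, names=names)
    raise ValueError(f"unknown table kind {kind!r}")


def read_gene_intervals(path) -> list[tuple]:
    """Gene intervals as (chrom, start, end, name), 1-based inclusive.

    ``.bed`` files (0-based, half-open) are converted; anything else is
    read as a 4-column TSV already in 1-based inclusive coordinates.
    """
    path = str(path)
    is_bed = path.endswith(".bed")
    df = pd.read_csv(
        path, sep=None, engine="python", header=None,
        names=["chrom", "start", "end", "name"], comment="#",
    )
    out = []
    for _, row in df.iterrows():
        start = int(row["start"]) + (1 if is_bed else 0)
        out.append((str(row["chrom"]), start, int(row["end"]), str(row["name"])))
    return out


RESULT_COLUMNS_FIXED = ["chrom", "start", "end", "gene", "n_variants", "pct_rare", "weight"]


def write_results(results: list[TestResult], path, trait_names=None) -> None:
    """Write one TSV row per region x weight scheme.

    P-values are printed in scientific notation with 4 significant digits;
    regions that could not be tested carry NA p-values and a reason.
    """
    if trait_names is None:
        k = max((len(r.univariate_p) for r in results), default=2)
        trait_names = [f"trait{i + 1}" for i in range(k)]
    p_cols = [f"p_{t}" for t in trait_names]
    columns = RESULT_COLUMNS_FIXED + p_cols + [
        "p_adj_univariate", "p_murat", "optimal_rho", "note",
    ]

    def fmt_p(p):
        return "NA" if p is None or not np.isfinite(p) else f"{p:.3e}"

    rows = []
    for r in results:
        row = {
            "chrom": r.region.chrom,
            "start": r.region.start,
            "end": r.region.end,
            "gene": r.region.label,
            "n_variants": r.n_variants,
            "pct_rare": "NA" if not np.isfinite(r.pct_rare) else f"{r.pct_rare:.1f}",
            "weight": r.weight_name,
            "p_adj_univariate": fmt_p(r.adjusted_p),
            "p_murat": fmt_p(r.omnibus_p),
            "optimal_rho": "NA" if r.optimal_rho is None else f"{r.optimal_rho:g}",
            "note": r.notes or "",
        }
        for name, p in zip(p_cols, list(r.univariate_p) + [None] * len(p_cols)):
            row[name] = fmt_p(p)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_regions(regions: list[Region], path) -> None:
    """Audit TSV of regions: coordinates, label, piece index, variant count."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "gene": r.label,
            "piece": r.piece_index,
            "n_variants": r.n_variants,
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf(genotypes: GenotypeMatrix, path, dosage_field: bool = True) -> None:
    """Write a minimal single-allelic VCF v4.2 with GT (and optionally DS).

    Hard genotypes are emitted as 0/0, 0/1, 1/1; fractional dosages fall
    back to the best-guess GT plus the exact DS value.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(genotypes.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Estimated alternate allele dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:DS" if dosage_field else "GT"
        for j in range(genotypes.n_variants):
            var = genotypes.variants.iloc[j]
            fields = [
                str(var["chrom"]), str(int(var["pos"])), str(var["id"]),
                "A", "C", ".", "PASS", ".", fmt,
            ]
            for d in genotypes.dosages[:, j]:
                gt = gt_codes[int(round(d))]
                fields.append(f"{gt}:{d:.4g}" if dosage_field else gt)
            fh.write("\t".join(fields) + "\n")
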