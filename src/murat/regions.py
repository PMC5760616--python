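"""Region builders: gene pieces, bounded-size windows, single variants.

Three granularities of analysis region are supported:

* *gene pieces* — each gene interval extended by a 5 kb flank on both
  ends; genes whose flanked extent exceeds 150 kb are partitioned into
  contiguous, non-overlapping pieces of 50-100 kb covering the flanked
  interval exactly;
* *windows* — a region's ordered variant list chunked into consecutive
  non-overlapping windows of at most 30 variants, sizes as equal as
  possible;
* *single variants* — one region per variant, dropping variants whose
  minor allele is carried by fewer than 4 individuals.

A rare-variant filter restricts region variant lists to MAF < 0.05, using
either the in-sample allele frequency or an externally supplied one.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import GenotypeMatrix, Region

__all__ = [
    "make_gene_pieces",
    "make_windows",
    "single_variant_regions",
    "filter_rare",
    "assign_variants",
]

log = logging.getLogger(__name__)


def make_gene_pieces(
    gene_intervals,
    flank_bp: int = 5_000,
    split_threshold_bp: int = 150_000,
    piece_min_bp: int = 50_000,
    piece_max_bp: int = 100_000,
) -> list[Region]:
    """Flank each gene and split long ones into near-equal pieces.

    ``gene_intervals`` is an iterable of ``(chrom, start, end, name)`` with
    1-based inclusive coordinates.  Genes whose flanked span is at most
    ``split_threshold_bp`` become a single region; longer ones are cut into
    ``ceil(L / piece_max_bp)`` contiguous pieces of near-equal length,
    which keeps every piece within [piece_min_bp, piece_max_bp] whenever
    the span permits.  Piece indices increment along the gene.
    """
    pieces: list[Region] = []
    for chrom, start, end, name in gene_intervals:
        start, end = int(start), int(end)
        if end < start:
            raise ValueError(f"gene {name}: end {end} < start {start}")
        fstart = max(1, start - flank_bp)
        fend = end + flank_bp
        length = fend - fstart + 1
        if length <= split_threshold_bp:
            pieces.append(Region(str(chrom), fstart, fend, label=str(name)))
            continue
        n_pieces = -(-length // piece_max_bp)  # ceil
        base, extra = divmod(length, n_pieces)
        cursor = fstart
        for i in range(n_pieces):
            plen = base + (1 if i < extra else 0)
            pieces.append(
                Region(str(chrom), cursor, cursor + plen - 1, label=str(name), piece_index=i)
            )
            cursor += plen
    return pieces


def assign_variants(regions: list[Region], genotypes: GenotypeMatrix) -> list[Region]:
    """Attach to each region the indices of the variants inside it."""
    chrom = genotypes.variants["chrom"].to_numpy(dtype=str)
    pos = genotypes.variants["pos"].to_numpy(dtype=int)
    out = []
    for reg in regions:
        mask = (chrom == reg.chrom) & (pos >= reg.start) & (pos <= reg.end)
        out.append(reg.with_variants(np.flatnonzero(mask)))
    return out


def make_windows(
    region: Region, genotypes: GenotypeMatrix, max_variants: int = 30
) -> list[Region]:
    """Chunk a region's variants into balanced windows of <= max_variants.

    The ordered variant list is split into ``ceil(v / max_variants)``
    consecutive, non-overlapping windows whose sizes differ by at most one
    (avoiding a trailing near-empty window).  Window coordinates are the
    first and last variant positions.  An empty region yields no windows.
    """
    idx = region.variant_indices
    v = idx.size
    if v == 0:
        return []
    n_win = -(-v // max_variants)
    pos = genotypes.variants["pos"].to_numpy(dtype=int)
    out = []
    for i, chunk in enumerate(np.array_split(idx, n_win)):
        out.append(
            Region(
                chrom=region.chrom,
                start=int(pos[chunk[0]]),
                end=int(pos[chunk[-1]]),
                label=region.label,
                piece_index=i,
                variant_indices=chunk,
            )
        )
    return out


def carrier_counts(genotypes: GenotypeMatrix) -> np.ndarray:
    """Number of samples carrying at least one minor allele, per variant.

    On fractional dosages a carrier is a sample with dosage > 0.5 (the
    best-guess genotype has at least one copy); on hard genotypes this is
    the count of samples with genotype >= 1.
    """
    return (genotypes.dosages > 0.5).sum(axis=0)


def single_variant_regions(
    genotypes: GenotypeMatrix, min_carriers: int = 4
) -> list[Region]:
    """One region per variant, dropping those with < min_carriers carriers."""
    counts = carrier_counts(genotypes)
    chrom = genotypes.variants["chrom"].to_numpy(dtype=str)
    pos = genotypes.variants["pos"].to_numpy(dtype=int)
    ids = genotypes.variants["id"].to_numpy(dtype=str)
    out = []
    for j in np.flatnonzero(counts >= min_carriers):
        out.append(
            Region(
                chrom=str(chrom[j]),
                start=int(pos[j]),
                end=int(pos[j]),
                label=str(ids[j]),
                variant_indices=np.array([j]),
            )
        )
    return out


def filter_rare(
    genotypes: GenotypeMatrix,
    regions: list[Region],
    maf_cutoff: float = 0.05,
    maf_source: str = "sample",
) -> list[Region]:
    """Restrict each region's variant list to rare variants (MAF < cutoff).

    The comparison is strict: a variant at exactly the cutoff is dropped.
    ``maf_source`` selects in-sample frequencies or an external column
    (e.g. frequencies estimated in a larger reference cohort).  Regions
    left empty are kept (with zero variants) and logged.
    """
    maf = genotypes.maf(maf_source)
    out = []
    for reg in regions:
        idx = reg.variant_indices
        kept = idx[maf[idx] < maf_cutoff]
        if kept.size == 0 and idx.size > 0:
            log.info(
                "region %s piece %d: no variants below MAF %.3g",
                reg.label, reg.piece_index, maf_cutoff,
            )
        out.append(reg.with_variants(kept))
    return out
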