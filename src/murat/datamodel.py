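"""Core domain containers for rare-variant region-based association testing.

The analysis operates on four aligned objects: an N x v genotype dosage
matrix, an N x K matrix of continuous phenotypes, an N x m covariate matrix,
and a collection of genomic regions, each holding an ordered subset of the
genotype matrix's variants.  Sample order is the contract that ties them
together: every matrix in one analysis must carry samples in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "CovariateMatrix",
    "Region",
    "TestResult",
]

#: columns every variant table carries, in order
VARIANT_COLUMNS = ["chrom", "pos", "id", "maf"]


@dataclass
class GenotypeMatrix:
    """N samples x v variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length N).
    dosages
        N x v float array; entry (i, j) is the expected count of minor
        alleles of variant j carried by sample i, in [0, 2].  Hard
        genotypes are exactly {0, 1, 2}.
    variants
        DataFrame with one row per variant and columns ``chrom`` (str),
        ``pos`` (1-based int), ``id`` (str) and ``maf`` (float in
        [0, 0.5]).  An optional ``maf_external`` column carries allele
        frequencies estimated outside the analyzed sample (e.g. from a
        larger reference set); an optional boolean ``flipped`` column
        records sites whose alleles were re-oriented at load time so that
        the dosage counts the minor allele.
    """

    samples: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        n, v = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(
                f"{len(self.samples)} sample ids but {n} dosage rows"
            )
        if len(self.variants) != v:
            raise ValueError(
                f"{len(self.variants)} variant records but {v} dosage columns"
            )
        if v and (np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if "maf" not in self.variants.columns:
            self.variants = self.variants.copy()
            self.variants["maf"] = self.sample_maf()

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def sample_maf(self) -> np.ndarray:
        """Minor-allele frequency from the dosage columns, folded to <= 0.5."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def maf(self, source: str = "sample") -> np.ndarray:
        """Per-variant MAF from the requested source.

        ``source='sample'`` recomputes from dosages; ``source='external'``
        requires a ``maf_external`` column (frequencies estimated outside
        the analyzed cohort, as used for rare/common classification).
        """
        if source == "sample":
            return self.sample_maf()
        if source == "external":
            if "maf_external" not in self.variants.columns:
                raise ValueError(
                    "external MAF requested but the variant table has no "
                    "'maf_external' column"
                )
            return self.variants["maf_external"].to_numpy(dtype=float)
        raise ValueError(f"unknown MAF source {source!r}")

    def subset(self, variant_indices) -> "GenotypeMatrix":
        """New matrix restricted to the given variant columns (order kept)."""
        idx = np.asarray(variant_indices, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )


@dataclass
class PhenotypeMatrix:
    """N x K matrix of continuous traits (K >= 1), complete cases only."""

    samples: list[str]
    values: np.ndarray
    trait_names: list[str]
    log_transformed: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.samples):
            raise ValueError("phenotype rows must match sample ids")
        if self.values.shape[1] != len(self.trait_names):
            raise ValueError("trait_names must match phenotype columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotypes contain missing or non-finite values")
        if not self.log_transformed:
            self.log_transformed = [False] * len(self.trait_names)

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateMatrix:
    """N x m covariate matrix (intercept excluded; added by the null fit)."""

    samples: list[str]
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.samples):
            raise ValueError("covariate rows must match sample ids")
        if self.values.shape[1] != len(self.names):
            raise ValueError("names must match covariate columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariates contain missing or non-finite values")

    def design(self) -> np.ndarray:
        """N x (m+1) design matrix with a leading intercept column."""
        n = self.values.shape[0]
        return np.column_stack([np.ones(n), self.values])


@dataclass
class Region:
    """A genomic interval plus the ordered variants it contains.

    Coordinates are 1-based inclusive throughout (VCF convention).
    ``piece_index`` distinguishes multiple pieces of one split gene and is 0
    for unsplit regions.  ``variant_indices`` index into the columns of the
    GenotypeMatrix the region was built against, strictly increasing.
    """

    chrom: str
    start: int
    end: int
    label: str = ""
    piece_index: int = 0
    variant_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"region {self.label or self.chrom}: end {self.end} < start {self.start}"
            )
        self.variant_indices = np.asarray(self.variant_indices, dtype=int)
        if self.variant_indices.size > 1 and np.any(np.diff(self.variant_indices) <= 0):
            raise ValueError("variant indices must be strictly increasing")

    @property
    def n_variants(self) -> int:
        return int(self.variant_indices.size)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_variants(self, indices) -> "Region":
        return Region(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            label=self.label,
            piece_index=self.piece_index,
            variant_indices=np.asarray(indices, dtype=int),
        )


@dataclass
class TestResult:
    """Outcome of one region x weight-scheme analysis.

    ``univariate_p`` holds the per-trait variance-component score-test
    p-values; ``adjusted_p`` is their minimum (the 'adjusted' univariate
    p-value used when several traits are tested separately).  The
    multivariate fields hold the statistic and p-value per grid value of
    the effect correlation rho, the rho minimizing the p-value, and the
    omnibus (selection-corrected) p-value.
    """

    region: Region
    weight_name: str
    q_by_rho: dict = field(default_factory=dict)
    p_by_rho: dict = field(default_factory=dict)
    optimal_rho: float | None = None
    omnibus_p: float | None = None
    univariate_p: list = field(default_factory=list)
    adjusted_p: float | None = None
    n_variants: int = 0
    pct_rare: float = float("nan")
    notes: str = ""

    __test__ = False  # despite the name, not a pytest test class
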