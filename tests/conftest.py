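import numpy as np
import pandas as pd
import pytest

from murat.datamodel import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix


@pytest.fixture
def toy_genotypes():
    """5 samples x 4 hard-called variants with known MAFs."""
    dosages = np.array(
        [
            [0, 1, 2, 0],
            [1, 0, 2, 0],
            [0, 0, 2, 1],
            [0, 1, 1, 0],
            [1, 0, 2, 0],
        ],
        dtype=float,
    )
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * 4,
            "pos": [100, 200, 300, 400],
            "id": [f"v{i}" for i in range(1, 5)],
        }
    )
    return GenotypeMatrix(samples=[f"S{i}" for i in range(1, 6)], dosages=dosages, variants=variants)


@pytest.fixture
def small_null_data():
    """N=200 samples: independent-trait phenotypes, covariates, genotypes."""
    rng = np.random.default_rng(42)
    n, v = 200, 12
    dosages = rng.binomial(2, 0.08, (n, v)).astype(float)
    variants = pd.DataFrame(
        {"chrom": ["1"] * v, "pos": 1000 + 50 * np.arange(v), "id": [f"v{j}" for j in range(v)]}
    )
    samples = [f"S{i}" for i in range(n)]
    G = GenotypeMatrix(samples=samples, dosages=dosages, variants=variants)
    cov = CovariateMatrix(
        samples=samples,
        values=np.column_stack([rng.normal(70, 8, n), rng.integers(0, 2, n)]),
        names=["age", "sex"],
    )
    L = np.linalg.cholesky(np.array([[1.0, 0.6775], [0.6775, 1.0]]))
    values = cov.values @ np.array([[0.01, 0.012], [0.1, 0.08]]) + rng.standard_normal((n, 2)) @ L.T
    phen = PhenotypeMatrix(samples=samples, values=values, trait_names=["fn", "ls"])
    return G, phen, cov
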