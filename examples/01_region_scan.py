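"""Region-based association scan on a simulated cohort.

Builds a synthetic dataset of 500 people with two correlated bone-density-
like traits and one gene's worth of rare variants carrying pleiotropic
effects, then runs the univariate (per-trait) variance-component score
test and the multivariate omnibus test for three variant weightings.
"""

import numpy as np

from murat import Region, assign_variants, make_windows, run_scan
from murat.simulate import SimConfig, simulate_dataset
from murat.weights import DEFAULT_SCHEMES

cfg = SimConfig(
    n_samples=500, n_variants=40, tau=0.15, rho_sim=0.7, ld=0.2, seed=7
)
G, phen, cov, betas = simulate_dataset(cfg)

pos = G.variants["pos"].to_numpy()
gene = Region("1", int(pos[0]), int(pos[-1]), label="GENE1")
(gene,) = assign_variants([gene], G)
windows = make_windows(gene, G, max_variants=30)

results, table, qq = run_scan(
    G, phen, cov, windows, list(DEFAULT_SCHEMES), seed=1, mc_draws=50_000
)
cols = ["gene", "piece", "n_variants", "weight", "p_trait1", "p_trait2",
        "p_adj_univariate", "p_murat", "optimal_rho"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\np_adj_univariate is the smaller of the two per-trait p-values; "
    "p_murat is the omnibus multivariate p-value after searching the "
    "effect-correlation grid (optimal_rho is the grid value that "
    "minimized it). With pleiotropic effects the multivariate p-values "
    "tend to undercut the univariate minima."
)
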