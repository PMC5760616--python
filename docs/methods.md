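# Methods

## Model and statistics

The package tests association between a region's v variant dosages and K
correlated continuous phenotypes on N unrelated samples.  Univariately,
each trait follows the linear mixed model y_k = α₀k + Xα_k + Gβ_k + ε_k
with β_k ~ N(0, τ²W) and the score test of τ² = 0 is the quadratic form
Q = rᵀGWGᵀr/σ̂², where r are OLS residuals of y on the covariate design
(intercept included) and σ̂² = rᵀr/(N−m−1).  Under the null, Q is
distributed as Σ_l λ_l χ²₁ with λ the eigenvalues of W½GᵀPGW½ and
P = I − X(XᵀX)⁻¹Xᵀ.  The residual variance is estimated rather than
fixed at 1: phenotypes are only assumed Gaussian after covariate
adjustment, not standardized.

Multivariately, the traits are stacked trait-major and the variant
effects β (length Kv) carry covariance τ²·R_ρ⊗W with
R_ρ = (1−ρ)I_K + ρ11ᵀ: a variant's effects across traits share the
correlation ρ, different variants' effects are independent.  Residuals
are i.i.d. N(0, Σ) with Σ estimated by equation-wise OLS (efficient here
because the design is common to all traits) and plugged in as known —
appropriate for N ≫ K.  For fixed ρ the score statistic is

    Q(ρ) = Sᵀ(R_ρ⊗I_v)S,   S = (I_K ⊗ W½Gᵀ) (Σ̂⁻¹⊗I_N) r̃,

whose null spectrum factorizes: with C = W½GᵀPGW½ and
A_ρ = Σ̂^{-1/2}R_ρΣ̂^{-1/2}, the mixture weights are the outer product
eig(A_ρ) × eig(C).  This reduces a Kv×Kv eigenproblem to one v×v problem
shared across the ρ grid plus a K×K problem per ρ, and is verified in the
test suite against the dense Kronecker construction.

### Omnibus over the ρ grid

ρ is unknown; Q(ρ) is evaluated on the grid {0, 0.1, …, 1.0} (11 points,
both endpoints included) and the reported statistic is the smallest
per-ρ p-value, with the grid value attaining it reported as the optimal ρ
(ties broken toward the smallest ρ).  The selection over the grid is
corrected by evaluating P(min_ρ p(Q(ρ)) ≤ observed min) under the joint
null law: all Q(ρ) are quadratic forms in one shared standard-normal
vector (one i.i.d. N(0, I_K) row per positive eigenvalue of C), so the
joint law is simulated exactly up to Monte-Carlo error by drawing that
vector (default 100,000 draws, seedable; at least 10,000 enforced) and
checking per draw whether any Q(ρ) exceeds the per-ρ quantile matched to
the observed minimum p-value.  The estimate is clamped to the analytic
envelope [min_p, n_grid·min_p], which the true law always satisfies.
Degenerate grids — a single grid point, or K = 1 where every Q(ρ) is
identical — return the per-ρ p-value exactly, making the K = 1 reduction
to the univariate test exact rather than Monte-Carlo-noisy.  An analytic
one-dimensional-integration omnibus is a possible future method slot; the
Monte-Carlo omnibus defines the current behavior.

Exchangeability of R_ρ makes Q(ρ) and p(ρ) exactly invariant to trait
reordering; the Monte-Carlo omnibus is invariant in distribution but not
bit-wise (its latent draws rotate with the eigenbasis of Σ̂), which the
tests check at Monte-Carlo tolerance.

### Mixture-of-chi-squares tails

P(Σλ_l χ²₁ ≥ q) is computed by a chain of exact methods with two
chi-square special cases (single eigenvalue; all eigenvalues equal):

1. *Imhof characteristic-function inversion* with vectorized composite
   Gauss–Legendre panels (width chosen so the oscillation phase advances
   ≤ π per panel; upper cutoff where the integrand envelope falls below
   1e−13).  Used for spectra with ≥6 eigenvalues, where the integrand
   decays fast.
2. *Ruben's series*: the mixture rewritten as an exact nonnegative
   mixture of central chi-squares with scale β = min λ.  All terms are
   positive, so relative accuracy survives far into the tail; used for
   small spectra (e.g. K=2 single-variant tests) and as the second
   attempt generally.  Truncated when the un-accumulated mixture mass is
   < 1e−14 (the mass bounds the error); abandoned if 20,000 terms do not
   converge (very spread eigenvalues).
3. *Adaptive quadrature* (scipy) of the Imhof integral, accepted when its
   error estimate is small.
4. *Liu four-moment approximation* as a recorded fallback (`method`
   flag "liu"), reached only when inversion is unreliable (p below
   ~1e−12 numerically).

Methods 1–3 agree to ~13 significant digits where they overlap and are
validated against Monte-Carlo in the tests.  Eigenvalues below
1e−10 × max are truncated (numerical rank control).  P-values are
computed on the spectrum normalized by its largest eigenvalue, making
them bit-stable under joint rescaling of (q, λ) — this is what renders
the K=1 and weight-rescaling invariances exact.  Quantiles invert the
same tail function by bracketed root finding from a Liu initial guess
(relative accuracy 1e−7 on q, far below Monte-Carlo noise in the
omnibus).

## Weights, regions, thresholds

Weight schemes: identical (W = I); Beta(a₁,a₂) with √w_j the Beta density
at the variant's MAF (default pair 1, 25); and the inverse-allele-SD form
√w_j = 1/√(MAF_j(1−MAF_j)), which is the Beta(0.5, 0.5) density weighting
up to the constant 1/π — constants cancel in the score test (verified as
a property), so the unnormalized form is used and the scheme string
`beta:0.5,0.5` maps to it.  Weighting uses in-sample MAF unless an
external per-variant frequency column is supplied (external frequencies
are the natural choice for the *rare/common classification* when they
come from a larger reference cohort; the rare filter accepts either
source).  Monomorphic variants must be dropped before divergent schemes.

Gene pieces: each gene interval is extended by 5 kb on both ends (floored
at position 1); if the flanked span exceeds 150 kb it is cut into
⌈L/100 kb⌉ contiguous pieces of near-equal length, which keeps every
piece within [50 kb, 100 kb] for all spans above the split threshold.
The equal-split rule is one admissible deterministic choice (greedy
100-kb cuts would also satisfy the bounds); flanks are applied before the
size check.  Windows chunk a region's ordered variant list into
⌈v/30⌉ consecutive windows with sizes differing by ≤1 (balanced rather
than greedy, avoiding a trailing near-empty window).  Single-variant
regions keep variants whose minor allele is carried by ≥4 samples;
carriers on fractional dosages are samples with dosage > 0.5 (best-guess
genotype).  The rare-variant filter keeps MAF < 0.05 strictly.

Thresholds: Bonferroni divides α by (weights × separately tested
phenotypes × regions).  The permutation route shuffles the genotype
matrix's sample order — phenotypes and covariates stay aligned to each
other, preserving the phenotype–covariate model including
genotype-derived PCs — re-runs the scan, and records the per-permutation
minimum p.  The effective number of tests is the maximum-likelihood fit
of min-p ~ Beta(1, M): M̂ = n/Σ(−log(1−p)); the family-wise threshold is
1−(1−α)^{1/M̂}.  Correlation between tests can only lower M̂, so an
extrapolated threshold *more* stringent than Bonferroni indicates
estimation noise and triggers a warning suggesting the Bonferroni value.
The Beta(1, M) fit is a documented surrogate for more elaborate
extrapolation schemes and is pluggable.

## Preprocessing and PCs

Phenotypes are natural-log transformed (values must be positive; the
offending sample is named otherwise) and optionally z-standardized within
study after the transform when per-study labels are supplied (the guard
used when combining cohorts measured on different instruments).  Ancestry
PCs come from variants with in-sample MAF > 0.48, greedily LD-pruned at
r² < 0.1 against the retained set, standardized and decomposed by SVD;
the default 5 components plus per-component variance fractions (for a
scree plot) are returned.  PCs are computed on the analysis samples.

## Data model and I/O

Coordinates are 1-based inclusive everywhere (VCF convention); BED input
is converted at the boundary.  VCF reading uses cyvcf2 (`DS` dosages
verbatim when present, otherwise `GT` as 0/1/2); multi-allelic sites are
rejected with a message rather than decomposed.  Missing dosages are
mean-imputed to 2·MAF (keeping N constant, the usual score-test
convention — how the motivating study handled them is not recorded) and
counted per variant; sites whose ALT allele is the major allele are
re-oriented so dosages count minor alleles, with the flip flagged.
Tables are whitespace/TSV with a sample-id first column; rows with
missing values are dropped (complete case) and rows are aligned to the
genotype sample order.  Results are TSV with p-values in scientific
notation.

## Simulator

`SimConfig` defines the generative model used for calibration, power and
recovery studies.  Haplotypes follow a first-order Markov chain on {0,1}
with per-site frequency from the configured MAF spectrum and
adjacent-site correlation `ld` (a controllable stand-in for local LD —
no recombination map, demography or population structure); genotypes are
haplotype sums.  Phenotypes follow the mixed model exactly: β is redrawn
per dataset from N(0, τ²R_ρ⊗W_sim) on the causal set (the random-effects
view the test itself takes, which makes power well-defined), residuals
are i.i.d. N(0, Σ_sim), and covariates mimic age, age², sex and weight
with fixed small coefficients.  Defaults target the motivating regime:
N = 500, v = 20 rare variants with MAF ∈ (0.005, 0.05), K = 2 traits with
residual correlation 0.6775, τ = 0 (null).  W_sim defaults to identity
and is deliberately decoupled from the analysis weights so
misspecification experiments are possible.  What passing tests on these
data do *not* show: robustness to population stratification, relatedness,
non-Gaussian phenotypes, genotyping/imputation error, or realistic LD.

## Validation protocol (sizes and rationale)

All experiments live in `murat.experiments`, are seed-deterministic, and
back both the test suite and `scripts/acceptance.py`:

* **Null calibration** — 2000 null datasets (N=500, v=20, K=2,
  correlation 0.6775); type-I error of the omnibus test and the
  per-trait univariate test at α = 0.05 must fall in the binomial 99%
  band [0.037, 0.063].  Omnibus draws 20,000 per dataset.
* **Mixture tails vs Monte-Carlo** — 20 random spectra (2–29
  eigenvalues), targets log-uniform in [1e−3, 0.5], 10⁶ draws each;
  agreement within 3 MC standard errors.
* **Reductions** — 50 random K=1 instances (multivariate p = univariate
  p) and 10 dense-Kronecker ρ=0 instances, both to ≥10 significant
  digits.
* **Power direction** — N=500, v=20, all variants causal, effect
  correlation ρ_sim = 0.7, trait correlation 0.6775, τ = 0.2 (chosen once
  to give mid-range power ≈ 0.7, where a directional comparison is
  informative), 400 replicates, both tests at α = 0.01.  The multivariate
  power must exceed the min-p univariate power with a one-sided binomial
  test on the paired discordant counts at 0.05.  The FWER-matched
  comparison (min-p charged α/K for testing K traits separately, the
  Bonferroni convention) is also reported; the multivariate advantage is
  larger there.
* **Region builders** — 1000 random gene lengths and 1000 random window
  regions; zero structural violations allowed.
* **Threshold extrapolation** — 25 disjoint LD-free regions, one trait
  (so the tests are independent), 500 permutations; the extrapolated
  threshold must lie within 20% of α/25.

## Known limitations

Binary phenotypes, relatedness/kinship adjustment, small-sample moment
corrections, BGEN/PLINK input, multi-allelic decomposition and
annotation-based weighting are out of scope.  The omnibus p-value is
Monte-Carlo (exact in the limit of draws) rather than the analytic
one-dimensional integral; its resolution is bounded below by 1/draws.
The permutation threshold machinery exposes its scope explicitly and
leaves genome-scale extrapolation factors to the caller.
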