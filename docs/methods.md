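# Methods

## Model and hypotheses

The unit of analysis is one pre-specified genomic region (a gene or
pathway) with *m* variants genotyped in *n* unrelated individuals. The
trait *y* (quantitative, or binary coded 0/1) is modeled by a generalized
linear model on covariates **X**, the environmental factor *E*, genotype
main effects **G** and the GE interaction terms **S** (S_ij = E_i·g_ij).
The null hypothesis is that all interaction coefficients vanish; main
effects and covariates are nuisance.

All tests in this package are *residual permutation score tests*: the
trait and every interaction column are replaced by their least-squares
residuals on the adjustment design X̃ = [1, **X**, E, **G**], the statistic
is computed from those residuals, and its null distribution is estimated by
shuffling the residualized trait across individuals. Because the genotype
main-effect block is part of X̃, any trait signal that lives in the span of
the design — including the main effects themselves — is removed exactly,
which is why the with/without-main-effect null settings give identical
residuals on identical noise draws.

### TOW-GE

With ỹ and s̃_j the residuals, U_j = Σ(ỹ−ȳ̃)(s̃_j−s̄̃_j) and
V_j = Σ(s̃_j−s̄̃_j)², the statistic is T = Σ_j U_j²/V_j ≥ 0, the score of
the weighted combination Σ w_j⁰ s̃_j at the analytically optimal weights
w_j⁰ = U_j/V_j. Optimality holds under a diagonal approximation of the
interaction covariance; the `score_statistic` function keeps the exact
(cross-term) denominator so the approximation is testable. The weights are
data-dependent, so they are re-derived inside every permutation; only V_j
is permutation-invariant, which is what makes the vectorized permutation
path cheap (one B×n by n×p matrix product per test).

### VW-TOW-GE

Columns are split at the rare/common MAF boundary (strict < 0.05,
configurable); the two TOW-GE statistics are combined as
T_λ = λ·T_r/var(T_r) + (1−λ)·T_c/var(T_c) over the grid λ_k = k/K and the
p-value of the best λ is calibrated by the nested rank transformation:
a single shared permutation stream produces the joint ensemble
(T_r^(b), T_c^(b)), b = 0..B with b = 0 the observed data; variances are
sample variances (ddof = 1) over the full ensemble including b = 0; each
T_λk^(b) is converted to p_λk^(b) = #{d : T_λk^(d) > T_λk^(b)}/B; and the
final p-value is the rank of min_k p_λk^(0) among the per-permutation
minima. Sharing one stream across the two sides preserves their dependence
— a regression test shows that independent streams change the answer on a
dependence fixture. K defaults to 10 (λ resolution 0.1; the ensembles are
reused across k so the cost of a finer grid is negligible); the reported
λ* is the observed minimizer and is descriptive only.

### Comparators

The modified WSS aggregates the residualized interaction columns with
Madsen–Browning weights 1/√(n·q̂_j(1−q̂_j)) (q̂_j the whole-sample MAF — no
case/control split exists for a quantitative trait) and squares the signed
score of the sum, so opposite-direction effects cancel by construction.
The modified CMC collapses the rare interactions to a single
environment-times-carrier-indicator column (residualized on X̃ like every
other interaction column), keeps common interaction columns marginally,
and uses the multivariate score form UᵀV⁻¹U with V the column covariance
scaled by Σỹ²/n (pseudo-inverse on singularity). The originals of both
tests were published for main effects with different inference (rank-sum;
Hotelling T²); the forms here are this package's reconstructions as
residual score tests, and only their aggregation schemes are inherited.
Any permutation-consistent normalization yields a valid test; the choice
affects power only.

## p-value conventions

Two conventions are implemented everywhere:

- **add-one** (default): p = (1 + #{T^(b) ≥ T⁰})/(B+1); always positive,
  finite-sample valid. For VW the final comparison is
  (1 + #{p^(b) ≤ p^(0)})/(B+1), tie-inclusive and therefore conservative.
- **raw**: the strict-greater / divide-by-B form, p = #{T^(b) > T⁰}/B
  (VW: #{p^(b) < p^(0)}/B), which can return 0.

At small B the two differ materially for VW: the rank transformation makes
ties at the minimum common (roughly one per grid point), so the
tie-inclusive add-one final comparison deflates rejection by about K/B —
noticeable at B = 500, negligible at B = 10,000. The simulation-table
recomputations in `scripts/acceptance.py` therefore use the raw convention,
which is the convention those tables were produced with; interactive
analyses keep the guaranteed-valid add-one default.

The permutation target is the residualized trait; a `permute_raw` option
residualizes the shuffled raw trait inside every permutation instead
(identical null, B extra regressions). Both quantitative and binary traits
are residualized by OLS by default — validity rests on the permutation
null, not on the linear model — with logistic-link Pearson residuals
available via `binary_link="logistic"`.

## Synthetic data generator

`simulate_genotypes` draws dosages independently as Binomial(2, MAF) per
variant — emulating a small sequenced gene panel of 10 variants (8 rare,
2 common) without linkage disequilibrium, the regime in which rare-variant
interaction columns are essentially uncorrelated. Default rare MAFs are
drawn once per scenario from Uniform(0.001, 0.04) and common MAFs from
Uniform(0.08, 0.5): the margins around the 0.05 boundary keep each
variant's *sample*-MAF classification stable at n = 2000 (a variant drawn
at 0.048 would flip sides by sampling noise in a substantial fraction of
replicates, changing the tested design mid-study).

`simulate_trait` follows
y = 0.5·X₁ + 0.5·X₂ + 0.015·E + **G**ᵀα₂ + **S**ᵀβ + ε, with X₁ ~ N(0,1),
X₂ ~ Bernoulli(0.5), E ~ N(0,1), ε ~ N(0,1); main effects, when enabled,
have magnitude 0.3 with independent random signs on all panel variants.
Under alternatives, `causal_count` rare variants (chosen uniformly at
random per scenario) receive coefficients of magnitude c, a fraction
`pct_positive` positive; a common-variant effect, when enabled, is +2c.
A logistic binary-trait analogue exists as an extension but the simulation
study proper is quantitative-trait.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, relatedness, population stratification, genotype
missingness and call errors, covariate–environment dependence. Passing
calibration and power checks on these synthetic panels therefore
demonstrates correctness of the statistics and their permutation
machinery under the stated sampling model, not robustness to the
correlation structure of real sequence data.

## Numerical choices

- Residualization uses a minimum-norm least-squares solve; residuals are
  unique under rank deficiency (near-collinear rare-variant columns), so
  no column pruning of the design is needed. n ≤ rank(X̃) and a constant
  trait are errors.
- Residualized interaction columns with variance below 1e-12 × max(1, raw
  variance) are dropped with a warning (typically zero-carrier or
  design-collinear columns); dropped columns receive no weight and are
  excluded from all statistics.
- Missing genotype calls are mean-imputed per variant before MAF
  computation; raw allele frequencies above 0.5 flip the dosage coding to
  the minor allele and are flagged. Phenotype rows with any missing value
  are listwise-deleted.
- Means ȳ̃, s̄̃_j are recomputed from the residuals (they are ≈ 0 with an
  intercept in X̃) for exactness of the printed formulas.
- All randomness flows from a single integer seed per test or scenario;
  experiment replicates use spawned, collision-free seed sequences and
  results are bit-reproducible for a fixed scenario.

## Problem sizes

The packaged experiment defaults are 500 replicates × 500 permutations for
null calibration and 300 replicates for power comparisons at n = 2000 —
sizes chosen so the whole study re-runs in minutes on one CPU while leaving
Monte-Carlo standard errors (≈ 0.01 at a rate of 0.05) small against the
effects being checked. The full-scale study settings (10,000 null
replicates; 1,000 power replicates × 10,000 permutations) are available via
`paper_scale()` and the CLI `--paper-scale` flag.

## Known limitations

- Permuting regression residuals is exact only asymptotically. At the
  study scale (n = 2000) the null is calibrated to Monte-Carlo accuracy,
  but at much smaller n (a few hundred) with single-carrier variants the
  high-leverage residual structure inflates the type-I error measurably
  (≈ 0.06–0.09 at nominal 0.05 for n = 300 in internal checks). For small
  samples, `permute_raw` does not remove this; exact conditional
  approaches would be needed.
- One environmental factor; multiple-exposure extensions are out of scope.
- No asymptotic p-values: the optimally weighted statistic has no tractable
  null distribution, so cost scales with B. The CLI's `--step-up` flag
  (screen at B = 1000, escalate ×10 when p < 0.1 — thresholds are this
  package's convention) mitigates this for multi-gene scans.
- The rare/common split of VW-TOW-GE requires both sides non-empty; the
  CLI falls back to plain TOW-GE with a warning otherwise.
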