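# towge

Permutation score tests for **gene–environment (GE) interactions** of rare
and/or common genetic variants in sequencing association studies.

Most region-based tests target the *main* effects of rare variants; methods
built for common-variant GE interaction lose power when applied naively to
rare variants. `towge` implements two tests designed for the interaction
problem, plus two burden-style comparators, a model-style API, a simulation
harness and a command-line interface:

- **TOW-GE** — the score test of an *optimally weighted* combination of
  per-variant interaction terms, aimed at rare variants;
- **VW-TOW-GE** — a *variable-weight* extension that balances a rare-variant
  side and a common-variant side through a grid of mixing weights and a
  nested permutation min-p calibration;
- modified **WSS** (Madsen–Browning weighted burden) and modified **CMC**
  (carrier-indicator collapsing) interaction tests, recast as permutation
  score tests on the same residualized data.

## The statistic

For individual *i* with trait *y_i*, covariates **X**_i, environmental factor
*E_i* and dosages **G**_i = (g_i1, …, g_ip), the interaction terms are
**S**_i = (E_i g_i1, …, E_i g_ip). Under the generalized linear model

&nbsp;&nbsp;g(E[y_i]) = **X**_iᵀα₁ + E_i α₂ + **G**_iᵀα₃ + **S**_iᵀβ,

testing H₀: β = 0 proceeds by residualizing both *y* and every column of
**S** on [1, **X**, E, **G**] (ordinary least squares), then forming, with
ỹ and s̃_j the residuals,

&nbsp;&nbsp;U_j = Σᵢ (ỹ_i − ȳ̃)(s̃_ij − s̄̃_j), &nbsp; V_j = Σᵢ (s̃_ij − s̄̃_j)²,

&nbsp;&nbsp;**T_TOW-GE = Σ_j U_j² / V_j**,

the score of the combination Σ_j w_j⁰ s̃_j with the analytically optimal
weights w_j⁰ = U_j / V_j (derived under a diagonal approximation of the
interaction covariance, appropriate because rare-variant interactions are
essentially uncorrelated). The weights are signed by the trait–interaction
correlation and scaled by 1/V_j, so the test is robust to effect direction
and up-weights rare variants. T has no tractable null distribution;
p-values come from permuting ỹ, re-deriving the weights inside every
permutation.

VW-TOW-GE splits columns at MAF 0.05 into rare/common sides with statistics
T_r, T_c and scans T_λ = λ·T_r/var(T_r) + (1−λ)·T_c/var(T_c) over
λ = k/K; the minimized p-value is calibrated by a nested rank
transformation over one shared permutation stream.

## Worked example

```python
import numpy as np
from towge import GEInteractionModel, Scenario, simulate_genotypes, simulate_trait

# a 2000-individual region: 8 rare + 2 common variants, 4 rare variants
# carrying interaction effects of magnitude 0.3 with mixed signs
scen = Scenario(seed=8, n=2000, causal_count=4, pct_positive=0.5, c=0.3)
g = simulate_genotypes(scen.n, scen.resolve_panel(), seed=8)
pheno = simulate_trait(g, scen, seed=9)

model = GEInteractionModel(pheno, g, method="tow-ge", scope="rare")
results = model.fit(n_permutations=10_000, seed=1)
print(results.summary())
```

```
Gene-Environment Interaction Permutation Test
======================================================
Method:                     tow-ge
No. individuals:            2000
No. variants:               10 (8 rare, 2 common at MAF < 0.05)
Trait type:                 quantitative
Interaction columns:        8 retained, 0 dropped
Permutations:               10000
Seed:                       1
------------------------------------------------------
Statistic:                  37.3289
Permutation p-value:        9.999e-05
------------------------------------------------------
Optimal weights (U_j / V_j):
  v1                   0.01398
  v2                   -0.3042
  v3                    0.1802
  v4                    0.5249
  v5                  -0.08372
  v6                    0.1678
  v7                   -0.3347
  v8                  -0.09892
======================================================
```

The statistic T = 37.33 is the sum over the 8 rare interaction columns of
U_j²/V_j; none of the 10,000 permuted traits reached it, so the add-one
p-value is 1/10001 ≈ 1e-4 — strong evidence of GE interaction despite the
mixed effect signs (note the weights' signs track the per-variant
correlation). The variable-weight test on the same data agrees:

```python
vw = GEInteractionModel(pheno, g, method="vw-tow-ge").fit(n_permutations=10_000, seed=1)
print(f"VW-TOW-GE: p = {vw.pvalue:.4g} (lambda* = {vw.lambda_star})")
# VW-TOW-GE: p = 0.0003 (lambda* = 0.9)
```

λ* = 0.9 says the minimized p-value put nearly all weight on the rare side,
as expected when only rare variants are causal.

From the shell, against a VCF (or dosage TSV) and a phenotype TSV:

```
towge test   --genotypes region.vcf --pheno pheno.tsv \
             --trait fev1 --covariates age,sex,bmi --environment packyears \
             -B 10000 --seed 1 --out results.tsv
towge vw-test --genotypes region.vcf --pheno pheno.tsv --trait fev1 \
             --covariates age,sex,bmi --environment packyears --out vw.tsv
towge simulate --config scenario.yaml --methods tow-ge,wss --out rates.tsv
```

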