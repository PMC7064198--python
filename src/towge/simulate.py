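"""Synthetic genotype/trait generation and the simulation harness.

Emulates a small sequenced gene region of 10 variants (8 rare with
MAF < 0.05, 2 common) and a quantitative trait driven by

    Y = 0.5 X1 + 0.5 X2 + α1 E + Gᵀα2 + Sᵀβ + S_c β_c + ε,

with X1 ~ N(0,1), X2 ~ Bernoulli(0.5), E ~ N(0,1), ε ~ N(0,1), the
environment coefficient α1 = 0.015, optional genotype main effects of
magnitude 0.3 with random signs, and interaction coefficients β (rare)
and β_c (one common variant) that are zero under the null.  Genotype
dosages are drawn independently as Binomial(2, MAF) — rare-variant
interactions in such regions are essentially uncorrelated, which is the
regime the optimal-weight argument assumes.

The harness runs repeated null (type-I error) and alternative (power)
simulations through the full residualize-then-test pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .comparators import cmc_ge_test, wss_ge_test
from .data import GenotypeMatrix, PhenoTable, classify_variants
from .residualize import residualize
from .tow import permutation_pvalue
from .vw import vw_tow_ge_test

__all__ = [
    "Scenario",
    "ExperimentResult",
    "default_maf_panel",
    "simulate_genotypes",
    "simulate_trait",
    "run_type1_experiment",
    "run_power_experiment",
    "binomial_ci",
]

MAF_THRESHOLD = 0.05


@dataclass(frozen=True)
class Scenario:
    """One simulation cell.

    Defaults are the study conditions of the quantitative-trait design:
    n = 2000 individuals, a 10-variant panel (8 rare, 2 common),
    environment coefficient 0.015, main-effect magnitude 0.3 with random
    signs when enabled, and no interaction effects (the null).
    """

    n: int = 2000
    maf_panel: tuple[float, ...] | None = None  # drawn from seed if None
    n_rare: int = 8
    n_common: int = 2
    include_main: bool = True
    alpha1: float = 0.015
    alpha2_mag: float = 0.3
    causal_count: int = 0
    pct_positive: float = 1.0
    c: float = 0.0
    common_causal: bool = False
    replicates: int = 500
    n_permutations: int = 500
    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001)
    seed: int = 0
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_positive <= 1.0:
            raise ValueError("pct_positive must lie in [0, 1]")
        if self.c < 0:
            raise ValueError("effect magnitude c must be >= 0")
        if self.maf_panel is not None:
            panel = np.asarray(self.maf_panel)
            if np.any(panel <= 0) or np.any(panel > 0.5):
                raise ValueError("MAFs must lie in (0, 0.5]")

    def resolve_panel(self) -> np.ndarray:
        """The per-variant MAF panel, drawn once from the scenario seed."""
        if self.maf_panel is not None:
            return np.asarray(self.maf_panel, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
        return default_maf_panel(self.n_rare, self.n_common, rng)

    @property
    def is_null(self) -> bool:
        return self.c == 0 or (self.causal_count == 0 and not self.common_causal)


@dataclass
class ExperimentResult:
    """Per-method rejection rates with Monte-Carlo uncertainty."""

    rates: pd.DataFrame  # index: method, columns: alpha levels
    mcse: pd.DataFrame
    replicates: int
    pvalues: dict[str, np.ndarray] = field(default_factory=dict)
    scenario: Scenario | None = None

    def to_frame(self, label: str = "") -> pd.DataFrame:
        rows = []
        for method in self.rates.index:
            for alpha in self.rates.columns:
                rows.append(
                    {
                        "scenario": label,
                        "method": method,
                        "alpha": alpha,
                        "rate": self.rates.loc[method, alpha],
                        "mcse": self.mcse.loc[method, alpha],
                        "replicates": self.replicates,
                    }
                )
        return pd.DataFrame(rows)


def default_maf_panel(
    n_rare: int, n_common: int, rng: np.random.Generator
) -> np.ndarray:
    """Rare MAFs ~ Uniform(0.001, 0.04), common ~ Uniform(0.08, 0.5).

    The margins around the 0.05 rare/common boundary keep each variant's
    sample-MAF classification stable at the default sample size, so the
    emulated panel reliably presents 8 rare and 2 common variants.
    """
    rare = rng.uniform(0.001, 0.04, size=n_rare)
    common = rng.uniform(0.08, 0.5, size=n_common)
    return np.concatenate([rare, common])


def simulate_genotypes(
    n: int, maf_panel: Sequence[float], seed: int | np.random.Generator | None = None
) -> GenotypeMatrix:
    """Independent Binomial(2, MAF) dosages per variant and individual."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    panel = np.asarray(maf_panel, dtype=float)
    dos = rng.binomial(2, panel[None, :], size=(n, panel.size)).astype(float)
    # keep the panel's orientation even if a very common allele drifts past 0.5
    freq = dos.sum(axis=0) / (2 * n)
    return GenotypeMatrix(
        dosages=dos,
        variant_ids=[f"v{j + 1}" for j in range(panel.size)],
        maf=np.minimum(freq, 1 - freq),
        flipped=np.zeros(panel.size, dtype=bool),
    )


def _interaction_coefficients(
    scen: Scenario, g: GenotypeMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Per-variant interaction coefficients under the scenario.

    ``causal_count`` rare variants (chosen uniformly at random) receive
    coefficients of magnitude c, a fraction ``pct_positive`` of them
    positive; with ``common_causal`` one common variant receives +2c.
    """
    beta = np.zeros(g.n_variants)
    part = classify_variants(g, MAF_THRESHOLD)
    if scen.causal_count > 0 and scen.c > 0:
        if scen.causal_count > part.rare_idx.size:
            raise ValueError("causal_count exceeds the number of rare variants")
        causal = rng.choice(part.rare_idx, size=scen.causal_count, replace=False)
        n_pos = int(round(scen.pct_positive * scen.causal_count))
        signs = np.concatenate(
            [np.ones(n_pos), -np.ones(scen.causal_count - n_pos)]
        )
        beta[causal] = scen.c * rng.permutation(signs)
    if scen.common_causal and scen.c > 0:
        if part.common_idx.size == 0:
            raise ValueError("common_causal requires a common variant in the panel")
        beta[rng.choice(part.common_idx)] = 2.0 * scen.c
    return beta


def simulate_trait(
    g: GenotypeMatrix,
    scen: Scenario,
    seed: int | np.random.Generator | None = None,
) -> PhenoTable:
    """Draw covariates, environment and the trait for one replicate."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = g.n
    X1 = rng.standard_normal(n)
    X2 = rng.binomial(1, 0.5, size=n).astype(float)
    E = rng.standard_normal(n)
    eps = rng.standard_normal(n)

    y = 0.5 * X1 + 0.5 * X2 + scen.alpha1 * E + eps
    if scen.include_main:
        alpha2 = scen.alpha2_mag * rng.choice([-1.0, 1.0], size=g.n_variants)
        y = y + g.dosages @ alpha2
    beta = _interaction_coefficients(scen, g, rng)
    if np.any(beta):
        y = y + (g.dosages * E[:, None]) @ beta

    pheno = PhenoTable(
        y=y, X=np.column_stack([X1, X2]), E=E, trait_type="quantitative"
    )
    if scen.trait_type == "binary":
        # logistic analogue: the linear predictor becomes a log-odds scale
        prob = 1.0 / (1.0 + np.exp(-(y - y.mean())))
        pheno = PhenoTable(
            y=rng.binomial(1, prob).astype(float),
            X=pheno.X,
            E=E,
            trait_type="binary",
        )
    return pheno


def _run_methods(
    g: GenotypeMatrix,
    pheno: PhenoTable,
    methods: Sequence[str],
    scope: str,
    B: int,
    rng_seeds: dict[str, int],
    convention: str,
) -> dict[str, float]:
    part = classify_variants(g, MAF_THRESHOLD)
    with warnings.catch_warnings():
        # occasional zero-carrier columns are expected across thousands of
        # replicates; their removal is routine here
        warnings.filterwarnings("ignore", message=".*degenerate residual variance.*")
        r_full = residualize(pheno, g)
    if scope == "rare":
        keep = np.array(
            [i for i, v in enumerate(r_full.kept_idx) if v in set(part.rare_idx)],
            dtype=int,
        )
        r = r_full.subset_columns(keep)
    elif scope == "all":
        r = r_full
    else:
        raise ValueError("scope must be 'rare' or 'all'")

    out: dict[str, float] = {}
    for method in methods:
        seed = rng_seeds[method]
        if method == "tow-ge":
            out[method] = permutation_pvalue(
                r, B=B, seed=seed, convention=convention
            ).p_value
        elif method == "vw-tow-ge":
            out[method] = vw_tow_ge_test(
                r_full, part, B=B, seed=seed, convention=convention
            ).p_value
        elif method == "wss":
            out[method] = wss_ge_test(
                r, g, B=B, seed=seed, convention=convention
            ).p_value
        elif method == "cmc":
            out[method] = cmc_ge_test(
                r_full, part, pheno.E, g, B=B, seed=seed, convention=convention
            ).p_value
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def _run_experiment(
    scen: Scenario, methods: Sequence[str], scope: str, convention: str
) -> ExperimentResult:
    panel = scen.resolve_panel()
    ss = np.random.SeedSequence([scen.seed, 11])
    children = ss.spawn(scen.replicates)
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        g = simulate_genotypes(scen.n, panel, rng)
        pheno = simulate_trait(g, scen, rng)
        # independent, reproducible seed per method per replicate
        method_seeds = {
            m: int(np.random.default_rng(child.spawn(1)[0]).integers(2**31))
            + k
            for k, m in enumerate(methods)
        }
        res = _run_methods(
            g, pheno, methods, scope, scen.n_permutations, method_seeds, convention
        )
        for m, p in res.items():
            pvals[m].append(p)

    alphas = list(scen.alpha_levels)
    rates = pd.DataFrame(index=list(methods), columns=alphas, dtype=float)
    mcse = rates.copy()
    pv = {m: np.asarray(v) for m, v in pvals.items()}
    for m in methods:
        for a in alphas:
            r = float(np.mean(pv[m] <= a))
            rates.loc[m, a] = r
            mcse.loc[m, a] = float(np.sqrt(r * (1 - r) / scen.replicates))
    return ExperimentResult(
        rates=rates, mcse=mcse, replicates=scen.replicates, pvalues=pv, scenario=scen
    )


def run_type1_experiment(
    scen: Scenario,
    methods: Sequence[str] = ("tow-ge",),
    scope: str = "rare",
    convention: str = "add-one",
) -> ExperimentResult:
    """Empirical rejection rates under the null (all interaction effects zero)."""
    if not scen.is_null:
        raise ValueError("type-I experiment requires a null scenario (c = 0)")
    return _run_experiment(scen, methods, scope, convention)


def run_power_experiment(
    scenarios: Sequence[Scenario] | Scenario,
    methods: Sequence[str] = ("tow-ge",),
    scope: str = "rare",
    convention: str = "add-one",
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Empirical power per scenario cell; tidy rows (scenario, method, alpha)."""
    if isinstance(scenarios, Scenario):
        scenarios = [scenarios]
    frames = []
    for i, scen in enumerate(scenarios):
        label = labels[i] if labels is not None else f"c={scen.c}"
        res = _run_experiment(scen, methods, scope, convention)
        frames.append(res.to_frame(label))
    return pd.concat(frames, ignore_index=True)


def binomial_ci(
    level: float, replicates: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation confidence interval for an empirical rate at a
    nominal level, e.g. the band an empirical type-I error should fall in."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(level * (1.0 - level) / replicates)
    return (level - half, level + half)


def paper_scale(scen: Scenario, power: bool = False) -> Scenario:
    """The full-scale study conditions: 10,000 null replicates, or
    1,000 power replicates with 10,000 permutations each."""
    if power:
        return replace(scen, replicates=1000, n_permutations=10_000)
    return replace(scen, replicates=10_000, n_permutations=10_000)
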