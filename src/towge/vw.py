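"""VW-TOW-GE: variable-weight combination of rare- and common-variant tests.

TOW-GE concentrates weight on rare-variant interactions; when common
variants also carry interaction effects, their contribution is diluted.
VW-TOW-GE splits the interaction columns into a rare side and a common
side, computes the TOW-GE statistic on each, and combines them as

    T_λ = λ T_r / var(T_r) + (1 − λ) T_c / var(T_c),   λ ∈ [0, 1],

minimizing the p-value of T_λ over a grid λ_k = k/K.  Because the minimum
of p-values is not itself a p-value, a nested permutation transformation
calibrates it: one shared permutation stream yields the joint ensemble
(T_r^(b), T_c^(b)) for b = 0..B (b = 0 observed), the variances are
estimated from these ensembles, each T_{λk}^(b) is rank-transformed to
p_{λk}^(b) against its own column, and the final p-value is the rank of
p^(0) = min_k p_{λk}^(0) among the per-permutation minima p^(b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import VariantPartition
from .residualize import ResidualSet
from .tow import TestResult, TowStatistic, _centered, permuted_rows

__all__ = ["VWGrid", "split_by_partition", "t_lambda", "vw_tow_ge_test"]


@dataclass
class VWGrid:
    """Full nested-permutation bookkeeping for one VW-TOW-GE run."""

    K: int
    lambdas: np.ndarray  # (K+1,)
    T_r_ensemble: np.ndarray  # (B+1,), index 0 = observed
    T_c_ensemble: np.ndarray
    var_r: float
    var_c: float
    p_lambda_matrix: np.ndarray  # (K+1, B+1)
    p_min: np.ndarray  # (B+1,)
    lambda_star: float


def split_by_partition(
    r: ResidualSet, part: VariantPartition
) -> tuple[ResidualSet, ResidualSet]:
    """Split retained interaction columns into rare-variant and
    common-variant ResidualSets sharing the same residualized trait."""
    rare = set(part.rare_idx.tolist())
    common = set(part.common_idx.tolist())
    loc_rare = np.array([i for i, v in enumerate(r.kept_idx) if v in rare], dtype=int)
    loc_common = np.array(
        [i for i, v in enumerate(r.kept_idx) if v in common], dtype=int
    )
    if loc_rare.size == 0:
        raise ValueError(
            "no rare-variant interaction columns retained; "
            "use the plain TOW-GE test on the common side"
        )
    if loc_common.size == 0:
        raise ValueError(
            "no common-variant interaction columns retained; "
            "use the plain TOW-GE test on the rare side"
        )
    return r.subset_columns(loc_rare), r.subset_columns(loc_common)


def t_lambda(T_r: float, T_c: float, var_r: float, var_c: float, lam: float) -> float:
    """λ T_r/var(T_r) + (1−λ) T_c/var(T_c) — variance, not SD, in the denominator."""
    if var_r <= 0 or var_c <= 0:
        raise ValueError("ensemble variances must be positive")
    return lam * T_r / var_r + (1.0 - lam) * T_c / var_c


def _rank_transform(t: np.ndarray) -> np.ndarray:
    """p^(b) = #{d : t_d > t_b} / B over the ensemble of size B+1 (strict >)."""
    B = t.size - 1
    order = np.sort(t)
    n_greater = t.size - np.searchsorted(order, t, side="right")
    return n_greater / B


def vw_tow_ge_test(
    r: ResidualSet,
    part: VariantPartition,
    B: int = 10_000,
    K: int = 10,
    seed: int | None = None,
    convention: str = "add-one",
    return_grid: bool = False,
) -> TestResult:
    """VW-TOW-GE permutation test combining rare and common interactions.

    One permutation stream drives both sides: for each b the same shuffled
    trait residual vector yields T_r^(b) and T_c^(b), preserving their
    dependence.  ``convention`` selects the final comparison: "add-one"
    gives (1 + #{b ≥ 1 : p^(b) ≤ p^(0)})/(B+1); "raw" gives the literal
    #{b = 0..B : p^(b) < p^(0)}/B (which can return 0).
    """
    if B < 1 or K < 1:
        raise ValueError("B and K must be >= 1")
    r_rare, r_common = split_by_partition(r, part)
    rng = np.random.default_rng(seed)
    yc, _ = _centered(r)

    stat_r = TowStatistic(r_rare.S_res - r_rare.S_res.mean(axis=0))
    stat_c = TowStatistic(r_common.S_res - r_common.S_res.mean(axis=0))

    Yperm = permuted_rows(yc, B, rng)
    T_r = np.concatenate([[stat_r.observed(yc)], stat_r.batch(Yperm)])
    T_c = np.concatenate([[stat_c.observed(yc)], stat_c.batch(Yperm)])

    # variances over the full ensembles b = 0..B
    var_r = float(np.var(T_r, ddof=1))
    var_c = float(np.var(T_c, ddof=1))
    if var_r <= 0:
        raise ValueError("degenerate rare side: statistic constant under permutation")
    if var_c <= 0:
        raise ValueError("degenerate common side: statistic constant under permutation")

    lambdas = np.arange(K + 1) / K
    p_lambda = np.empty((K + 1, B + 1))
    for k, lam in enumerate(lambdas):
        t_k = lam * T_r / var_r + (1.0 - lam) * T_c / var_c
        p_lambda[k] = _rank_transform(t_k)
    p_min = p_lambda.min(axis=0)
    lambda_star = float(lambdas[int(np.argmin(p_lambda[:, 0]))])

    if convention == "add-one":
        p = float((1 + np.sum(p_min[1:] <= p_min[0])) / (B + 1))
    elif convention == "raw":
        p = float(np.sum(p_min < p_min[0]) / B)
    else:
        raise ValueError(f"unknown p-value convention: {convention!r}")

    result = TestResult(
        statistic=float(p_min[0]),
        p_value=p,
        n_perm=B,
        method="vw-tow-ge",
        seed=seed,
        lambda_star=lambda_star,
        notes={
            "K": K,
            "n_rare_columns": r_rare.n_columns,
            "n_common_columns": r_common.n_columns,
            "dropped_columns": list(map(int, r.dropped_idx)),
        },
    )
    if return_grid:
        result.notes["grid"] = VWGrid(
            K=K,
            lambdas=lambdas,
            T_r_ensemble=T_r,
            T_c_ensemble=T_c,
            var_r=var_r,
            var_c=var_c,
            p_lambda_matrix=p_lambda,
            p_min=p_min,
            lambda_star=lambda_star,
        )
    return result
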