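"""Burden-style comparator tests on the residualized interactions.

The weighted-sum (WSS) and collapsing (CMC) burden tests were designed for
main effects of rare variants; here both are recast as permutation score
tests on the residualized trait and residualized interaction columns, so
they target the same null hypothesis as TOW-GE.  The original WSS rank-sum
and CMC Hotelling-T² ingredients are replaced by residual-based scores;
the aggregation schemes (Madsen–Browning inverse-frequency weights; the
carrier-indicator collapse) are kept.  These forms are reconstructions of
the named comparators, not published statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, VariantPartition
from .residualize import ResidualSet, _lstsq_residuals
from .tow import TestResult, _centered, permuted_rows, pvalue_from_ensemble

__all__ = ["CollapsedDesign", "wss_ge_test", "cmc_ge_test"]


@dataclass
class CollapsedDesign:
    """Columns entering the collapsed (CMC-style) score test."""

    columns: np.ndarray  # (n, 1 + #common), centered
    description: list[str]


class WssStatistic:
    """Squared score of the Madsen–Browning weighted interaction sum.

    The combination s̃^W = Σ_j s̃_j / sqrt(n q̂_j (1 − q̂_j)) aggregates
    columns with their signs, so opposite-direction effects cancel —
    the statistic (Σ_i (ỹ_i − ȳ̃)(s̃^W_i − s̄̃^W))² is direction-sensitive.
    """

    name = "wss-ge"

    def __init__(self, Sc: np.ndarray, maf: np.ndarray, n: int):
        q = np.asarray(maf, dtype=float)
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("WSS weights need MAFs strictly inside (0, 1)")
        w = 1.0 / np.sqrt(n * q * (1.0 - q))
        comb = Sc @ w
        self.cc = comb - comb.mean()
        if self.cc @ self.cc <= 0:
            raise ValueError("degenerate weighted combination")

    def observed(self, yc: np.ndarray) -> float:
        return float((yc @ self.cc) ** 2)

    def batch(self, Yperm: np.ndarray) -> np.ndarray:
        return (Yperm @ self.cc) ** 2


class CmcStatistic:
    """Multivariate score form Uᵀ V⁻¹ U on the collapsed design.

    V is the sample covariance of the collapsed columns scaled by
    Σ ỹ² / n; it is permutation-invariant, so the exact normalization
    affects power only — validity comes from the permutation null.
    """

    name = "cmc-ge"

    def __init__(self, Cc: np.ndarray, y_ss: float):
        n = Cc.shape[0]
        V = (Cc.T @ Cc / n) * (y_ss / n)
        try:
            self.Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            warnings.warn("singular score covariance; using pseudo-inverse", stacklevel=3)
            self.Vinv = np.linalg.pinv(V)
        self.Cc = Cc

    def observed(self, yc: np.ndarray) -> float:
        U = self.Cc.T @ yc
        return float(U @ self.Vinv @ U)

    def batch(self, Yperm: np.ndarray) -> np.ndarray:
        U = Yperm @ self.Cc  # (B, k)
        return np.einsum("bi,ij,bj->b", U, self.Vinv, U)


def _run_permutation(stat, yc, B, rng, convention, method, notes=None) -> TestResult:
    t_obs = stat.observed(yc)
    t_perm = stat.batch(permuted_rows(yc, B, rng))
    if np.ptp(np.concatenate([[t_obs], t_perm])) == 0:
        warnings.warn("statistic is constant under permutation; p = 1", stacklevel=3)
        p = 1.0
    else:
        p = pvalue_from_ensemble(t_obs, t_perm, convention)
    return TestResult(
        statistic=t_obs, p_value=p, n_perm=B, method=method, notes=notes or {}
    )


def wss_ge_test(
    r: ResidualSet,
    g: GenotypeMatrix,
    B: int = 10_000,
    seed: int | None = None,
    convention: str = "add-one",
) -> TestResult:
    """Modified-WSS permutation test of the interaction effects.

    Madsen–Browning weights use the whole-sample MAF of each retained
    variant (no case/control split exists for a quantitative trait).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    yc, Sc = _centered(r)
    stat = WssStatistic(Sc, g.maf[r.kept_idx], r.n)
    res = _run_permutation(
        stat, yc, B, rng, convention, "wss-ge",
        notes={"dropped_columns": list(map(int, r.dropped_idx))},
    )
    res.seed = seed
    return res


def build_collapsed_design(
    r: ResidualSet,
    part: VariantPartition,
    E: np.ndarray,
    g: GenotypeMatrix,
) -> CollapsedDesign:
    """One residualized carrier-indicator column for the rare interactions
    plus the residualized common-variant interaction columns."""
    rare_kept = [v for v in r.kept_idx if v in set(part.rare_idx.tolist())]
    cols: list[np.ndarray] = []
    desc: list[str] = []
    if rare_kept:
        carrier = (g.dosages[:, rare_kept] > 0).any(axis=1).astype(float)
        collapsed = np.asarray(E, dtype=float) * carrier
        collapsed_res = _lstsq_residuals(r.design, collapsed[:, None]).ravel()
        if collapsed_res.var() > 1e-12 * max(1.0, collapsed.var()):
            cols.append(collapsed_res)
            desc.append(f"rare collapse of variants {list(map(int, rare_kept))}")
        else:
            warnings.warn(
                "collapsed rare column degenerate after residualization; dropped",
                stacklevel=2,
            )
    common = set(part.common_idx.tolist())
    for i, v in enumerate(r.kept_idx):
        if v in common:
            cols.append(r.S_res[:, i])
            desc.append(f"common interaction column {int(v)}")
    if not cols:
        raise ValueError("collapsed design has no usable columns")
    C = np.column_stack(cols)
    return CollapsedDesign(columns=C - C.mean(axis=0), description=desc)


def cmc_ge_test(
    r: ResidualSet,
    part: VariantPartition,
    E: np.ndarray,
    g: GenotypeMatrix,
    B: int = 10_000,
    seed: int | None = None,
    convention: str = "add-one",
) -> TestResult:
    """Modified-CMC permutation test: rare interactions collapsed to a
    carrier-indicator-times-environment column, common interactions kept
    marginally, combined through a multivariate score statistic."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    design = build_collapsed_design(r, part, E, g)
    if r.n <= design.columns.shape[1]:
        raise ValueError("more collapsed columns than individuals")
    yc, _ = _centered(r)
    stat = CmcStatistic(design.columns, float(yc @ yc))
    res = _run_permutation(
        stat, yc, B, rng, convention, "cmc-ge",
        notes={"collapsed_design": design.description},
    )
    res.seed = seed
    return res
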