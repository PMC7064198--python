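"""TOW-GE: the optimally weighted interaction score test.

For residualized trait values ỹ and residualized interaction columns s̃_j,
define the per-column score U_j = Σ_i (ỹ_i − ȳ̃)(s̃_ij − s̄̃_j) and sum of
squares V_j = Σ_i (s̃_ij − s̄̃_j)².  Under a diagonal approximation of the
interaction covariance (interactions of rare variants are essentially
uncorrelated) the score statistic of the weighted combination Σ_j w_j s̃_j
is maximized at w_j⁰ = U_j / V_j, and the test statistic reduces to

    T = Σ_i (ỹ_i − ȳ̃)(s̃_i⁰ − s̄̃⁰) = Σ_j U_j² / V_j ≥ 0,

with s̃⁰ the optimally weighted combination.  T has no tractable null
distribution, so its p-value is evaluated by permuting the residualized
trait across individuals, re-deriving the (data-dependent) weights inside
every permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .residualize import ResidualSet

__all__ = [
    "WeightVector",
    "TestResult",
    "score_statistic",
    "optimal_weights",
    "tow_ge_statistic",
    "permutation_pvalue",
]


@dataclass
class WeightVector:
    """Optimal per-column weights w_j = U_j / V_j and their components."""

    w: np.ndarray
    per_column_score: np.ndarray  # U_j
    per_column_ss: np.ndarray  # V_j


@dataclass
class TestResult:
    """Outcome of one permutation test."""

    statistic: float
    p_value: float
    n_perm: int
    method: str
    seed: int | None = None
    weights: WeightVector | None = None
    lambda_star: float | None = None
    notes: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, result-style
        return (
            f"TestResult(method={self.method!r}, statistic={self.statistic:.6g}, "
            f"p_value={self.p_value:.6g}, n_perm={self.n_perm})"
        )


def _centered(r: ResidualSet) -> tuple[np.ndarray, np.ndarray]:
    # residuals have mean ~0 already; re-center for exactness
    yc = r.y_res - r.y_res.mean()
    Sc = r.S_res - r.S_res.mean(axis=0)
    return yc, Sc


def score_statistic(r: ResidualSet, w: np.ndarray) -> float:
    """Score statistic of the weighted combination s̃ = Σ_j w_j s̃_j.

    Uses the exact denominator Σ(ỹ−ȳ̃)² · Σ(s̃−s̄̃)² with all covariance
    cross terms (no diagonal approximation):

        S(w) = n (Σ_i (ỹ_i−ȳ̃)(s̃_i−s̄̃))² / (Σ_i (ỹ_i−ȳ̃)² Σ_i (s̃_i−s̄̃)²)
    """
    w = np.asarray(w, dtype=float).ravel()
    yc, Sc = _centered(r)
    if w.size != Sc.shape[1]:
        raise ValueError("weight vector length does not match retained columns")
    if not np.any(w):
        raise ValueError("degenerate weight vector: all weights zero")
    s = Sc @ w
    sc = s - s.mean()
    denom = (yc @ yc) * (sc @ sc)
    if sc @ sc <= 0:
        raise ValueError("degenerate weight vector: combination has zero variance")
    return float(r.n * (yc @ sc) ** 2 / denom)


def optimal_weights(r: ResidualSet) -> WeightVector:
    """Analytic maximizer w_j⁰ = U_j / V_j of the (diagonalized) score statistic."""
    yc, Sc = _centered(r)
    U = Sc.T @ yc
    V = np.einsum("ij,ij->j", Sc, Sc)
    if np.any(V <= 0):
        raise ValueError("zero-variance interaction column; residualize first")
    return WeightVector(w=U / V, per_column_score=U, per_column_ss=V)


def tow_ge_statistic(r: ResidualSet) -> float:
    """T = Σ_i (ỹ_i−ȳ̃)(s̃_i⁰−s̄̃⁰), the score of the optimally weighted
    combination; algebraically Σ_j U_j²/V_j, hence non-negative."""
    if r.n_columns == 0:
        raise ValueError("no retained interaction columns")
    wv = optimal_weights(r)
    yc, Sc = _centered(r)
    s0 = Sc @ wv.w
    return float(yc @ (s0 - s0.mean()))


class TowStatistic:
    """TOW-GE statistic with a vectorized batch path for permutations.

    Weights are re-derived from each permuted trait: T(b) = Σ_j U_j(b)²/V_j
    where U(b) uses the permuted residuals and V is permutation-invariant.
    """

    name = "tow-ge"

    def __init__(self, Sc: np.ndarray):
        self.Sc = Sc
        self.V = np.einsum("ij,ij->j", Sc, Sc)
        if Sc.shape[1] == 0:
            raise ValueError("no retained interaction columns")
        if np.any(self.V <= 0):
            raise ValueError("zero-variance interaction column")

    def observed(self, yc: np.ndarray) -> float:
        U = self.Sc.T @ yc
        return float(np.sum(U * U / self.V))

    def batch(self, Yperm: np.ndarray) -> np.ndarray:
        U = Yperm @ self.Sc  # (B, p)
        return np.sum(U * U / self.V, axis=1)


def permuted_rows(yc: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B independent uniform shuffles of yc, stacked as a (B, n) matrix."""
    out = np.tile(yc, (B, 1))
    return rng.permuted(out, axis=1)


def pvalue_from_ensemble(
    t_obs: float, t_perm: np.ndarray, convention: str = "add-one"
) -> float:
    """Permutation p-value under the add-one (default) or raw convention.

    add-one: (1 + #{T(b) >= T(0)}) / (B + 1)  — strictly positive, valid.
    raw:     #{T(b) > T(0)} / B               — can return 0.
    """
    B = t_perm.size
    if convention == "add-one":
        return float((1 + np.sum(t_perm >= t_obs)) / (B + 1))
    if convention == "raw":
        return float(np.sum(t_perm > t_obs) / B)
    raise ValueError(f"unknown p-value convention: {convention!r}")


def permutation_pvalue(
    r: ResidualSet,
    statistic: str | TowStatistic = "tow-ge",
    B: int = 10_000,
    seed: int | None = None,
    convention: str = "add-one",
    permute_raw: bool = False,
) -> TestResult:
    """Permutation test of H0: no interaction effect.

    The residualized trait is shuffled across individuals (interaction
    residuals fixed) and the statistic recomputed per permutation, weights
    included.  ``permute_raw`` instead shuffles the raw trait and
    re-residualizes it on the adjustment design inside every permutation
    (a literal reading of trait shuffling; identical null, O(B) regressions).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    yc, Sc = _centered(r)

    if isinstance(statistic, str):
        if statistic != "tow-ge":
            raise ValueError(f"unknown statistic {statistic!r}")
        stat = TowStatistic(Sc)
    else:
        stat = statistic

    t_obs = stat.observed(yc)
    if permute_raw:
        from .residualize import _lstsq_residuals

        t_perm = np.empty(B)
        for b in range(B):
            yp = rng.permutation(r.y_raw)
            yres = _lstsq_residuals(r.design, yp[:, None]).ravel()
            t_perm[b] = stat.observed(yres - yres.mean())
    else:
        t_perm = stat.batch(permuted_rows(yc, B, rng))

    notes: dict = {"dropped_columns": list(map(int, r.dropped_idx))}
    if np.allclose(t_perm, t_obs) and np.ptp(t_perm) == 0:
        warnings.warn("statistic is constant under permutation; p = 1", stacklevel=2)
        p = 1.0
    else:
        p = pvalue_from_ensemble(t_obs, t_perm, convention)
    weights = None
    if isinstance(stat, TowStatistic):
        U = Sc.T @ yc
        weights = WeightVector(w=U / stat.V, per_column_score=U, per_column_ss=stat.V)
    return TestResult(
        statistic=t_obs,
        p_value=p,
        n_perm=B,
        method=getattr(stat, "name", "custom"),
        seed=seed,
        weights=weights,
        notes=notes,
    )
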