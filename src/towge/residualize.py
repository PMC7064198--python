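"""Adjustment of trait and interaction columns for nuisance effects.

The interaction score tests condition out covariates, the environmental
main effect and the genotype main effects by replacing the trait y and
every interaction column S[:, j] with their least-squares residuals on the
design [1, X, E, G].  All downstream statistics operate on these residuals
only; inference comes from permuting them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, PhenoTable, build_interactions

__all__ = ["ResidualSet", "residualize"]


@dataclass
class ResidualSet:
    """Residualized trait and interaction columns.

    Attributes
    ----------
    y_res : ndarray, shape (n,)
        Trait residuals on the adjustment design.
    S_res : ndarray, shape (n, p)
        Residuals of the retained interaction columns.
    kept_idx : ndarray
        Indices (into the original interaction matrix) of retained columns.
    dropped_idx : ndarray
        Columns removed because their residual variance was degenerate.
    design_rank : int
        Numerical rank of the adjustment design.
    """

    y_res: np.ndarray
    S_res: np.ndarray
    kept_idx: np.ndarray
    dropped_idx: np.ndarray
    design_rank: int
    design: np.ndarray = field(repr=False)
    y_raw: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.y_res.size

    @property
    def n_columns(self) -> int:
        return self.S_res.shape[1]

    def subset_columns(self, local_idx: np.ndarray) -> "ResidualSet":
        """A ResidualSet sharing y_res but keeping only the given retained columns."""
        local_idx = np.asarray(local_idx, dtype=int)
        return ResidualSet(
            y_res=self.y_res,
            S_res=self.S_res[:, local_idx],
            kept_idx=self.kept_idx[local_idx],
            dropped_idx=self.dropped_idx,
            design_rank=self.design_rank,
            design=self.design,
            y_raw=self.y_raw,
        )


def _lstsq_residuals(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    # minimum-norm solution: residuals are unique even when the design is
    # rank deficient (near-collinear genotype columns are common)
    beta, *_ = np.linalg.lstsq(design, targets, rcond=None)
    return targets - design @ beta


def residualize(
    pheno: PhenoTable,
    g: GenotypeMatrix,
    S: np.ndarray | None = None,
    include_main_effects: bool = True,
    binary_link: str = "linear",
    var_tol: float = 1e-12,
) -> ResidualSet:
    """Residualize the trait and interaction columns on [1, X, E, G].

    Parameters
    ----------
    pheno, g : aligned phenotype table and genotype matrix.
    S : optional precomputed interaction matrix; built as E * g if omitted.
    include_main_effects : include the genotype main-effect block G in the
        adjustment design (all variants of the region).
    binary_link : {"linear", "logistic"} — how a binary trait is
        residualized.  The default follows the linear-regression adjustment
        used for both trait types; "logistic" substitutes Pearson residuals
        from a logistic fit.  Validity of the permutation test does not
        depend on the link.
    var_tol : relative variance tolerance below which a residualized
        interaction column is treated as degenerate and dropped.
    """
    if S is None:
        S = build_interactions(g, pheno.E)
    S = np.asarray(S, dtype=float)
    n = pheno.n
    if g.n != n or S.shape[0] != n:
        raise ValueError("phenotype, genotype and interaction row counts differ")

    blocks = [np.ones((n, 1)), pheno.X, pheno.E[:, None]]
    if include_main_effects:
        blocks.append(g.dosages)
    design = np.column_stack(blocks)
    rank = int(np.linalg.matrix_rank(design))
    if n <= rank:
        raise ValueError(
            f"n = {n} individuals cannot support an adjustment design of rank {rank}"
        )
    if np.var(pheno.y) == 0:
        raise ValueError("trait is constant; nothing to test")

    if pheno.trait_type == "binary" and binary_link == "logistic":
        y_res = _logistic_pearson_residuals(pheno.y, design)
        S_res_full = _lstsq_residuals(design, S)
    else:
        resid = _lstsq_residuals(design, np.column_stack([pheno.y, S]))
        y_res, S_res_full = resid[:, 0], resid[:, 1:]

    raw_var = np.maximum(1.0, S.var(axis=0))
    keep = S_res_full.var(axis=0) > var_tol * raw_var
    dropped = np.where(~keep)[0]
    if dropped.size:
        warnings.warn(
            f"dropped {dropped.size} interaction column(s) with degenerate "
            f"residual variance: {list(dropped)}",
            stacklevel=2,
        )
    return ResidualSet(
        y_res=y_res,
        S_res=S_res_full[:, keep],
        kept_idx=np.where(keep)[0],
        dropped_idx=dropped,
        design_rank=rank,
        design=design,
        y_raw=np.asarray(pheno.y, dtype=float),
    )


def _logistic_pearson_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    mu = fit.fittedvalues
    return (y - mu) / np.sqrt(mu * (1.0 - mu))
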