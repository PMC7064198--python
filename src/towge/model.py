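"""Model-style front end: build once from data, fit by permutation.

`GEInteractionModel` assembles the adjustment design, interaction columns
and rare/common partition from a genotype matrix and a phenotype table;
`fit()` runs the requested permutation test and returns a
`GEInteractionResults` object carrying the statistic, p-value, per-variant
weights and diagnostics, with a `summary()` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparators import cmc_ge_test, wss_ge_test
from .data import GenotypeMatrix, PhenoTable, classify_variants
from .residualize import ResidualSet, residualize
from .tow import TestResult, permutation_pvalue
from .vw import split_by_partition, vw_tow_ge_test

__all__ = ["GEInteractionModel", "GEInteractionResults"]

_METHODS = ("tow-ge", "vw-tow-ge", "wss", "cmc")


class GEInteractionModel:
    """Permutation score test of gene-environment interaction in a region.

    Parameters
    ----------
    pheno : PhenoTable
        Trait, covariates and environmental factor (aligned to genotypes).
    genotypes : GenotypeMatrix
        Minor-allele dosages for the region's variants.
    method : {"tow-ge", "vw-tow-ge", "wss", "cmc"}
        "tow-ge" — optimally weighted combination of the (residualized)
        interaction columns; "vw-tow-ge" — rare/common variable-weight
        combination; "wss" — Madsen-Browning weighted burden; "cmc" —
        collapsing burden.
    maf_threshold : rare/common boundary (strict `<` means rare).
    scope : {"all", "rare"} — which interaction columns are tested
        ("vw-tow-ge" and "cmc" always use the full rare/common structure).
    include_main_effects : adjust for the genotype main effects of every
        variant in the region.
    min_maf : variants with MAF below this are excluded before testing
        (0 disables the filter).

    Examples
    --------
    >>> model = GEInteractionModel(pheno, genotypes, method="tow-ge")
    >>> results = model.fit(n_permutations=10_000, seed=1)
    >>> print(results.summary())
    """

    def __init__(
        self,
        pheno: PhenoTable,
        genotypes: GenotypeMatrix,
        method: str = "tow-ge",
        maf_threshold: float = 0.05,
        scope: str = "all",
        include_main_effects: bool = True,
        min_maf: float = 0.0,
        binary_link: str = "linear",
    ):
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if scope not in ("all", "rare"):
            raise ValueError("scope must be 'all' or 'rare'")
        if min_maf > 0:
            keep = np.where(genotypes.maf >= min_maf)[0]
            if keep.size == 0:
                raise ValueError("no variants survive the minimum-MAF filter")
            genotypes = GenotypeMatrix(
                dosages=genotypes.dosages[:, keep],
                variant_ids=[genotypes.variant_ids[j] for j in keep],
                maf=genotypes.maf[keep],
                flipped=genotypes.flipped[keep],
                sample_ids=genotypes.sample_ids,
            )
        self.pheno = pheno
        self.genotypes = genotypes
        self.method = method
        self.scope = scope
        self.maf_threshold = maf_threshold
        self.partition = classify_variants(genotypes, maf_threshold)
        self.residuals: ResidualSet = residualize(
            pheno, genotypes, include_main_effects=include_main_effects,
            binary_link=binary_link,
        )
        if self.residuals.n_columns == 0:
            raise ValueError("no interaction columns survive residualization")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        genotypes: GenotypeMatrix | pd.DataFrame | np.ndarray,
        trait: str,
        environment: str,
        covariates: tuple[str, ...] = (),
        trait_type: str = "auto",
        **kwargs,
    ) -> "GEInteractionModel":
        """Build from a phenotype DataFrame plus genotypes (matrix-like or
        GenotypeMatrix).  Rows with missing values are listwise-deleted;
        genotype rows must already correspond to the DataFrame rows."""
        if isinstance(genotypes, pd.DataFrame):
            g_raw = genotypes.to_numpy(dtype=float)
            ids = [str(c) for c in genotypes.columns]
        elif isinstance(genotypes, GenotypeMatrix):
            g_raw = None
            ids = None
        else:
            g_raw = np.asarray(genotypes, dtype=float)
            ids = None
        cols = [trait, environment, *covariates]
        sub = data[cols].apply(pd.to_numeric, errors="coerce")
        keep = ~sub.isna().any(axis=1)
        pheno = PhenoTable.from_dataframe(
            data, trait=trait, environment=environment, covariates=covariates,
            trait_type=trait_type,
        )
        if isinstance(genotypes, GenotypeMatrix):
            g = GenotypeMatrix.from_dosages(
                genotypes.dosages[keep.to_numpy()],
                variant_ids=genotypes.variant_ids,
            )
        else:
            g = GenotypeMatrix.from_dosages(g_raw[keep.to_numpy()], variant_ids=ids)
        return cls(pheno, g, **kwargs)

    def _rare_scope_residuals(self) -> ResidualSet:
        rare = set(self.partition.rare_idx.tolist())
        keep = np.array(
            [i for i, v in enumerate(self.residuals.kept_idx) if v in rare], dtype=int
        )
        if keep.size == 0:
            raise ValueError("no rare-variant interaction columns to test")
        return self.residuals.subset_columns(keep)

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int | None = None,
        convention: str = "add-one",
        K: int = 10,
        permute_raw: bool = False,
    ) -> "GEInteractionResults":
        """Run the permutation test and return the results object."""
        r = (
            self._rare_scope_residuals()
            if (self.scope == "rare" and self.method in ("tow-ge", "wss"))
            else self.residuals
        )
        if self.method == "tow-ge":
            raw = permutation_pvalue(
                r, B=n_permutations, seed=seed, convention=convention,
                permute_raw=permute_raw,
            )
        elif self.method == "vw-tow-ge":
            raw = vw_tow_ge_test(
                self.residuals, self.partition, B=n_permutations, K=K,
                seed=seed, convention=convention,
            )
        elif self.method == "wss":
            raw = wss_ge_test(
                r, self.genotypes, B=n_permutations, seed=seed,
                convention=convention,
            )
        else:  # cmc
            raw = cmc_ge_test(
                self.residuals, self.partition, self.pheno.E, self.genotypes,
                B=n_permutations, seed=seed, convention=convention,
            )
        return GEInteractionResults(self, raw, tested=r)


class GEInteractionResults:
    """Results of a fitted gene-environment interaction test."""

    def __init__(self, model: GEInteractionModel, raw: TestResult, tested: ResidualSet):
        self.model = model
        self._raw = raw
        self._tested = tested
        self.statistic = raw.statistic
        self.pvalue = raw.p_value
        self.n_permutations = raw.n_perm
        self.method = raw.method
        self.seed = raw.seed
        self.lambda_star = raw.lambda_star

    @property
    def weights(self) -> pd.Series | None:
        """Optimal per-interaction weights, indexed by variant id."""
        if self._raw.weights is None:
            return None
        ids = [self.model.genotypes.variant_ids[v] for v in self._tested.kept_idx]
        return pd.Series(self._raw.weights.w, index=ids, name="weight")

    def summary(self) -> str:
        m = self.model
        part = m.partition
        lines = [
            "Gene-Environment Interaction Permutation Test",
            "=" * 54,
            f"{'Method:':<28}{self.method}",
            f"{'No. individuals:':<28}{m.pheno.n}",
            f"{'No. variants:':<28}{m.genotypes.n_variants} "
            f"({part.rare_idx.size} rare, {part.common_idx.size} common "
            f"at MAF < {m.maf_threshold})",
            f"{'Trait type:':<28}{m.pheno.trait_type}",
            f"{'Interaction columns:':<28}{self._tested.n_columns} retained, "
            f"{m.residuals.dropped_idx.size} dropped",
            f"{'Permutations:':<28}{self.n_permutations}",
            f"{'Seed:':<28}{self.seed}",
            "-" * 54,
            f"{'Statistic:':<28}{self.statistic:.6g}",
            f"{'Permutation p-value:':<28}{self.pvalue:.6g}",
        ]
        if self.lambda_star is not None:
            lines.append(f"{'lambda* (rare weight):':<28}{self.lambda_star:.2f}")
        w = self.weights
        if w is not None and w.size <= 25:
            lines.append("-" * 54)
            lines.append("Optimal weights (U_j / V_j):")
            for vid, val in w.items():
                lines.append(f"  {vid:<16}{val:>12.4g}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "statistic": self.statistic,
                    "p_value": self.pvalue,
                    "n_perm": self.n_permutations,
                    "seed": self.seed,
                    "n_retained": self._tested.n_columns,
                    "n_dropped": self.model.residuals.dropped_idx.size,
                    "lambda_star": self.lambda_star,
                }
            ]
        )

    def __repr__(self) -> str:
        return (
            f"<GEInteractionResults method={self.method!r} "
            f"statistic={self.statistic:.4g} p={self.pvalue:.4g}>"
        )
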