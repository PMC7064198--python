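"""Genotype and phenotype containers and I/O.

Genotypes are held as an individuals x variants matrix of minor-allele
dosages (0/1/2, possibly fractional after mean imputation).  Two on-disk
formats are supported: VCF (biallelic records, parsed with cyvcf2) and a
plain TSV dosage table with a header row of variant ids and the individual
id in the first column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenoTable",
    "VariantPartition",
    "load_genotypes",
    "load_phenotypes",
    "classify_variants",
    "build_interactions",
]


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-variant metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n, m)
        Minor-allele counts; in [0, 2] (fractional only where a missing
        call was mean-imputed).
    variant_ids : list of str
    maf : ndarray, shape (m,)
        Sample minor-allele frequency, computed after imputation and
        folded to <= 0.5.
    flipped : ndarray of bool, shape (m,)
        True where the raw allele frequency exceeded 0.5 and the coding
        was flipped to the minor allele.
    sample_ids : list of str or None
    """

    dosages: np.ndarray
    variant_ids: list[str]
    maf: np.ndarray
    flipped: np.ndarray
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        variant_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Build from a raw dosage matrix (NaN marks missing calls).

        Missing entries are mean-imputed per variant; the sample MAF is
        computed from the imputed matrix and folded to the minor allele,
        flipping the dosage coding (d -> 2 - d) where needed.
        """
        d = np.asarray(dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        n, m = d.shape
        if variant_ids is None:
            variant_ids = [f"v{j + 1}" for j in range(m)]
        if len(variant_ids) != m:
            raise ValueError("variant_ids length does not match matrix")

        missing = np.isnan(d)
        if missing.all(axis=0).any():
            bad = [variant_ids[j] for j in np.where(missing.all(axis=0))[0]]
            raise ValueError(f"all genotypes missing for variant(s): {bad}")
        if missing.any():
            col_means = np.nanmean(d, axis=0)
            d = np.where(missing, col_means[None, :], d)
            logger.info("mean-imputed %d missing genotype calls", int(missing.sum()))
        with np.errstate(invalid="ignore"):
            if np.nanmin(d) < 0 or np.nanmax(d) > 2:
                raise ValueError("dosages must lie in [0, 2]")

        freq = d.sum(axis=0) / (2.0 * n)
        flipped = freq > 0.5
        if flipped.any():
            d = d.copy()
            d[:, flipped] = 2.0 - d[:, flipped]
            freq = np.where(flipped, 1.0 - freq, freq)
            logger.info(
                "flipped allele coding to minor allele for %d variant(s)",
                int(flipped.sum()),
            )
        return cls(
            dosages=d,
            variant_ids=list(variant_ids),
            maf=freq,
            flipped=flipped,
            sample_ids=list(sample_ids) if sample_ids is not None else None,
        )

    def to_table(self, path: str | Path) -> None:
        """Write the dosage matrix as a TSV table (round-trips exactly)."""
        ids = self.sample_ids or [f"s{i + 1}" for i in range(self.n)]
        df = pd.DataFrame(self.dosages, index=ids, columns=self.variant_ids)
        df.index.name = "individual"
        df.to_csv(path, sep="\t")


@dataclass
class PhenoTable:
    """Trait, covariates and environmental factor for n individuals."""

    y: np.ndarray
    X: np.ndarray  # (n, q); q may be 0
    E: np.ndarray
    trait_type: str = "quantitative"  # or "binary"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.E = np.asarray(self.E, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.size == 0:
            self.X = np.empty((self.y.size, 0))
        n = self.y.size
        if self.E.size != n or self.X.shape[0] != n:
            raise ValueError("y, X and E must have matching lengths")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError("trait_type must be 'quantitative' or 'binary'")
        if self.trait_type == "binary" and not np.isin(self.y, [0.0, 1.0]).all():
            raise ValueError("binary trait must be coded 0/1")
        if np.var(self.E) == 0:
            raise ValueError("environmental factor has zero variance")

    @property
    def n(self) -> int:
        return self.y.size

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        trait: str,
        environment: str,
        covariates: Sequence[str] = (),
        trait_type: str = "auto",
        id_column: str | None = None,
    ) -> "PhenoTable":
        """Extract named columns; rows with any missing value are dropped."""
        cols = [trait, environment, *covariates]
        missing_cols = [c for c in cols if c not in data.columns]
        if missing_cols:
            raise KeyError(f"phenotype columns not found: {missing_cols}")
        sub = data[cols].apply(pd.to_numeric, errors="coerce")
        keep = ~sub.isna().any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("listwise-deleted %d individuals with missing values", n_drop)
        sub = sub.loc[keep]
        if id_column is not None:
            ids = data.loc[keep, id_column].astype(str).tolist()
        elif data.index.name is not None or not isinstance(data.index, pd.RangeIndex):
            ids = data.index[keep].astype(str).tolist()
        else:
            ids = None
        y = sub[trait].to_numpy()
        if trait_type == "auto":
            trait_type = (
                "binary" if np.isin(y, [0.0, 1.0]).all() and np.unique(y).size <= 2
                else "quantitative"
            )
        return cls(
            y=y,
            X=sub[list(covariates)].to_numpy() if covariates else np.empty((y.size, 0)),
            E=sub[environment].to_numpy(),
            trait_type=trait_type,
            sample_ids=ids,
        )


@dataclass
class VariantPartition:
    """Disjoint split of variant indices into rare and common by MAF."""

    rare_idx: np.ndarray
    common_idx: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.rare_idx = np.asarray(self.rare_idx, dtype=int)
        self.common_idx = np.asarray(self.common_idx, dtype=int)


def classify_variants(g: GenotypeMatrix, threshold: float = 0.05) -> VariantPartition:
    """Partition variants into rare (MAF strictly below ``threshold``) and common."""
    rare = np.where(g.maf < threshold)[0]
    common = np.where(g.maf >= threshold)[0]
    return VariantPartition(rare_idx=rare, common_idx=common, threshold=threshold)


def build_interactions(g: GenotypeMatrix | np.ndarray, E: np.ndarray) -> np.ndarray:
    """Elementwise gene-environment interaction matrix S[i, j] = E[i] * g[i, j]."""
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    E = np.asarray(E, dtype=float).ravel()
    if d.shape[0] != E.size:
        raise ValueError(
            f"genotypes have {d.shape[0]} rows but environment has {E.size} values"
        )
    return d * E[:, None]


def _load_vcf(path: Path, split_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    for var in vcf:
        alts = var.ALT
        if len(alts) == 0:
            continue
        name = var.ID or f"{var.CHROM}:{var.POS}"
        gts = np.array([g[:-1] for g in var.genotypes], dtype=float)  # allele codes
        gts[gts < 0] = np.nan
        if len(alts) == 1:
            dos = np.nansum(gts == 1, axis=1).astype(float)
            dos[np.isnan(gts).any(axis=1)] = np.nan
            cols.append(dos)
            ids.append(name)
        elif split_multiallelic:
            for k in range(1, len(alts) + 1):
                dos = np.nansum(gts == k, axis=1).astype(float)
                dos[np.isnan(gts).any(axis=1)] = np.nan
                cols.append(dos)
                ids.append(f"{name}_alt{k}")
        else:
            raise ValueError(
                f"multi-allelic record {name}; re-run with splitting enabled"
            )
    if not cols:
        raise ValueError(f"no usable variant records in {path}")
    return GenotypeMatrix.from_dosages(
        np.column_stack(cols), variant_ids=ids, sample_ids=samples
    )


def _load_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"dosage table {path} has no variant columns")
    return GenotypeMatrix.from_dosages(
        df.to_numpy(dtype=float),
        variant_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def load_genotypes(
    path: str | Path,
    format: str = "auto",
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read genotypes from a VCF or a TSV dosage table.

    Parameters
    ----------
    path : file path
    format : {"auto", "vcf", "table"}
        "auto" keys on the file extension (.vcf / .vcf.gz -> VCF).
    split_multiallelic : bool
        Split multi-allelic VCF records into one dosage column per
        alternate allele instead of rejecting them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "vcf" if ".vcf" in path.name.lower() else "table"
    if format == "vcf":
        return _load_vcf(path, split_multiallelic)
    if format == "table":
        return _load_table(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def load_phenotypes(
    path: str | Path,
    trait: str,
    environment: str,
    covariates: Sequence[str] = (),
    trait_type: str = "auto",
    id_column: str | None = None,
) -> PhenoTable:
    """Read a phenotype TSV and extract trait/covariate/environment columns."""
    df = pd.read_csv(path, sep="\t")
    if id_column is None and df.columns.size and df.columns[0].lower() in (
        "individual", "id", "sample", "iid",
    ):
        id_column = df.columns[0]
    return PhenoTable.from_dataframe(
        df, trait=trait, environment=environment, covariates=covariates,
        trait_type=trait_type, id_column=id_column,
    )


def align_samples(g: GenotypeMatrix, pheno: PhenoTable) -> tuple[GenotypeMatrix, PhenoTable]:
    """Subset both containers to their shared individuals, in genotype order."""
    if g.sample_ids is None or pheno.sample_ids is None:
        if g.n != pheno.n:
            raise ValueError(
                "sample ids unavailable and genotype/phenotype row counts differ"
            )
        return g, pheno
    common = [s for s in g.sample_ids if s in set(pheno.sample_ids)]
    if not common:
        raise ValueError("no individuals shared between genotype and phenotype files")
    gi = [g.sample_ids.index(s) for s in common]
    pmap = {s: i for i, s in enumerate(pheno.sample_ids)}
    pi = [pmap[s] for s in common]
    g2 = GenotypeMatrix.from_dosages(
        g.dosages[gi], variant_ids=g.variant_ids, sample_ids=common
    )
    p2 = PhenoTable(
        y=pheno.y[pi], X=pheno.X[pi], E=pheno.E[pi],
        trait_type=pheno.trait_type, sample_ids=common,
    )
    if len(common) < g.n or len(common) < pheno.n:
        warnings.warn(
            f"analysis restricted to {len(common)} individuals present in both files",
            stacklevel=2,
        )
    return g2, p2
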