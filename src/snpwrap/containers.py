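"""In-memory containers for genotype and phenotype data.

Genotypes are held as an ``(n_samples, n_snps)`` float array of
minor-allele copy counts (0/1/2) with ``NaN`` marking missing calls —
the additive coding used by PLINK's ``--logistic``.  Variant metadata
travels alongside in a :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: PLINK phenotype coding for binary traits.
CONTROL, CASE, MISSING_PHENO = 1, 2, -9

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """Samples × SNPs genotype matrix with metadata.

    Parameters
    ----------
    genotypes:
        ``(n_samples, n_snps)`` float array; entries in {0, 1, 2, NaN}.
        Values count copies of ``allele1`` (the minor allele).
    sample_ids:
        Unique sample identifiers, length ``n_samples``.
    variants:
        DataFrame with columns ``snp_id, chrom, pos, allele1, allele2``
        (1-based positions; allele1 = minor allele as determined in the
        analysis sample, ties at MAF 0.5 broken alphabetically).
    sex:
        Optional per-sample sex coded 0/1 (used as a covariate).
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x SNPs array")
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} genotype rows"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"{len(self.variants)} variant records for {m} genotype columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {missing_cols}")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive (1-based)")
        valid = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or NaN")
        self.variants = self.variants.reset_index(drop=True)
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=float)
            if self.sex.shape != (n,):
                raise ValueError("sex must be one value per sample")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.variants["snp_id"].tolist()

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset samples by boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[index],
            sample_ids=[self.sample_ids[i] for i in index],
            variants=self.variants.copy(),
            sex=None if self.sex is None else self.sex[index],
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNPs by boolean mask or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index],
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            sex=self.sex,
        )

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.isnan(self.genotypes).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.genotypes).mean(axis=0)


@dataclass
class PhenotypeTable:
    """Sample id, sex and one binary status column per trait.

    Statuses use the PLINK convention 1=control, 2=case, -9=missing.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if "sample_id" not in self.table.columns:
            raise ValueError("phenotype table needs a sample_id column")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        for trait in self.traits:
            bad = ~self.table[trait].isin([CONTROL, CASE, MISSING_PHENO])
            if bad.any():
                raise ValueError(
                    f"trait {trait!r} has codes outside {{1, 2, -9}}"
                )

    @property
    def traits(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "sex")]

    def binary(self, trait: str, sample_ids: list[str] | None = None) -> np.ndarray:
        """Return the trait as a 0/1 float array (NaN = missing), aligned
        to ``sample_ids`` when given."""
        tab = self.table.set_index("sample_id")
        if sample_ids is not None:
            tab = tab.loc[sample_ids]
        codes = tab[trait].to_numpy(dtype=float)
        y = np.where(codes == CASE, 1.0, np.where(codes == CONTROL, 0.0, np.nan))
        return y
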