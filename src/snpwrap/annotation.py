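"""Harmonization of selected SNPs against a user-supplied cis-eQTL table.

Palindromic variants (A/T or C/G allele pairs) are strand-ambiguous when
their minor-allele frequency approaches 0.5; those at or above the MAF
cutoff are excluded outright, the remainder pass through flagged.  The
join is a left join on rsID; entries are significant at ``qval <
q_cutoff``.  Coordinates follow the GRCh38 1-based convention of the
supplied table; slopes are emitted as supplied, without allele-direction
re-harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EQTL_COLUMNS = [
    "snp_id", "gene_id", "gene_name", "tissue",
    "slope", "slope_se", "pval_nominal", "qval",
]


@dataclass
class AnnotationConfig:
    palindrome_maf_cutoff: float = 0.40
    q_cutoff: float = 0.05

    def validate(self) -> None:
        for name in ("palindrome_maf_cutoff", "q_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


def is_palindromic(allele1: str, allele2: str) -> bool:
    for a in (allele1, allele2):
        if a not in _COMPLEMENT:
            raise ValueError(f"invalid allele symbol {a!r}")
    return _COMPLEMENT[allele1] == allele2


def filter_palindromic(
    snps: pd.DataFrame, config: AnnotationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split SNPs into retained and excluded by the palindrome rule.

    ``snps`` needs columns ``snp_id, allele1, allele2, maf``.  A SNP is
    excluded iff its allele pair is complementary (A/T or C/G) AND its
    MAF is at or above the cutoff (inclusive at the boundary).  Retained
    palindromic SNPs below the cutoff carry the flag
    ``palindromic-low-maf``; exclusions are logged with a reason.
    """
    config = config or AnnotationConfig()
    config.validate()
    need = {"snp_id", "allele1", "allele2", "maf"}
    if not need.issubset(snps.columns):
        raise ValueError(f"SNP table needs columns {sorted(need)}")
    palin = snps.apply(lambda r: is_palindromic(r["allele1"], r["allele2"]), axis=1)
    exclude = palin & (snps["maf"] >= config.palindrome_maf_cutoff)
    retained = snps.loc[~exclude].copy()
    retained["flag"] = [
        "palindromic-low-maf" if p else "" for p in palin[~exclude]
    ]
    excluded = snps.loc[exclude].copy()
    excluded["reason"] = "palindromic-ambiguous-maf"
    return retained.reset_index(drop=True), excluded.reset_index(drop=True)


def eqtl_join(
    selected: pd.DataFrame,
    eqtl: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Left-join selected SNPs onto cis-eQTL records and flag significance.

    ``selected`` needs a ``snp_id`` column; ``eqtl`` the
    :data:`EQTL_COLUMNS`.  Duplicate conflicting records for one
    (snp_id, gene_id, tissue) key raise; SNPs with no record are kept
    with empty annotation; a record is significant iff
    ``qval < q_cutoff``.
    """
    config = config or AnnotationConfig()
    config.validate()
    if "snp_id" not in selected.columns:
        raise ValueError("selected SNP table needs a snp_id column")
    missing = [c for c in EQTL_COLUMNS if c not in eqtl.columns]
    if missing:
        raise ValueError(f"eQTL table lacks columns: {missing}")
    key = ["snp_id", "gene_id", "tissue"]
    dup = eqtl.duplicated(subset=key, keep=False)
    if dup.any():
        conflicting = eqtl.loc[dup].drop_duplicates(subset=key + ["slope", "qval"])
        if conflicting.duplicated(subset=key).any():
            bad = conflicting.loc[conflicting.duplicated(subset=key), key]
            raise ValueError(
                "conflicting duplicate eQTL records for keys:\n" + bad.to_string()
            )
        eqtl = eqtl.drop_duplicates(subset=key)
    out = selected.merge(eqtl[EQTL_COLUMNS], on="snp_id", how="left")
    out["significant"] = out["qval"] < config.q_cutoff
    out.loc[out["qval"].isna(), "significant"] = False
    return out
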