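"""Readers and writers for PLINK text formats and the package's TSVs.

Text PED/MAP is the canonical interchange format here: at desk scale it
is diffable and needs no binary tooling.  Alleles are recoded on read to
minor-allele copy counts; ``0 0`` genotype fields become missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, MISSING_PHENO, GenotypeMatrix, PhenotypeTable

VALID_ALLELES = {"A", "C", "G", "T"}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_map(path: str | Path) -> pd.DataFrame:
    """Read a PLINK MAP file (chrom, snp_id, cM, pos)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric position {pos!r}") from exc
            rows.append({"chrom": chrom, "snp_id": snp_id, "pos": pos_i})
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Alleles are recoded so each genotype counts copies of the minor
    allele (frequency tie at 0.5 broken by alphabetical allele order);
    ``0 0`` becomes missing.  The PED phenotype column is returned as a
    single-trait :class:`PhenotypeTable` named ``pheno``.
    """
    variants = read_map(map_path)
    m = len(variants)
    sample_ids, sexes, phenos = [], [], []
    allele_rows: list[list[str | None]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sex, pheno = parts[:6]
            sample_ids.append(iid)
            sexes.append(float(sex) - 1 if sex in ("1", "2") else np.nan)
            phenos.append(int(pheno) if pheno in ("1", "2", "-9") else MISSING_PHENO)
            row: list[str | None] = []
            for j in range(m):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                for al in (a, b):
                    if al != "0" and al not in VALID_ALLELES:
                        raise ParseError(
                            f"{ped_path}:{lineno}: invalid allele {al!r} for SNP {j + 1}"
                        )
                if a == "0" or b == "0":
                    row.extend([None, None])
                else:
                    row.extend([a, b])
            allele_rows.append(row)

    n = len(sample_ids)
    geno = np.full((n, m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for k in (2 * j, 2 * j + 1):
                al = allele_rows[i][k]
                if al is not None:
                    counts[al] = counts.get(al, 0) + 1
        alleles = sorted(counts)  # alphabetical for determinism
        if len(alleles) > 2:
            raise ParseError(f"SNP {variants['snp_id'][j]}: more than two alleles")
        if not alleles:
            a1, a2 = "A", "A"  # fully missing column
        elif len(alleles) == 1:
            a1, a2 = alleles[0], alleles[0]
        else:
            # minor = less frequent; tie broken alphabetically
            x, z = alleles
            a1, a2 = (x, z) if counts[x] <= counts[z] else (z, x)
        a1_list.append(a1)
        a2_list.append(a2)
        for i in range(n):
            a, b = allele_rows[i][2 * j], allele_rows[i][2 * j + 1]
            if a is not None:
                geno[i, j] = (a == a1) + (b == a1)

    variants = variants.assign(allele1=a1_list, allele2=a2_list)[
        ["snp_id", "chrom", "pos", "allele1", "allele2"]
    ]
    sex = np.asarray(sexes)
    G = GenotypeMatrix(geno, sample_ids, variants, sex=sex if not np.isnan(sex).all() else None)
    pheno_tab = PhenotypeTable(
        pd.DataFrame({"sample_id": sample_ids, "sex": sex, "pheno": phenos})
    )
    return G, pheno_tab


def write_ped_map(
    G: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    phenotypes: PhenotypeTable | None = None,
    trait: str | None = None,
) -> None:
    """Write a PED/MAP pair; missing genotypes become ``0 0``."""
    with open(map_path, "w") as fh:
        for _, v in G.variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['snp_id']}\t0\t{v['pos']}\n")
    pheno_codes = None
    if phenotypes is not None and trait is not None:
        tab = phenotypes.table.set_index("sample_id")
        pheno_codes = [int(tab.loc[s, trait]) for s in G.sample_ids]
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            sex_code = 0
            if G.sex is not None and not np.isnan(G.sex[i]):
                sex_code = int(G.sex[i]) + 1
            pheno = pheno_codes[i] if pheno_codes is not None else MISSING_PHENO
            fields = [sid, sid, "0", "0", str(sex_code), str(pheno)]
            for j in range(G.n_snps):
                g = G.genotypes[i, j]
                a1 = G.variants["allele1"][j]
                a2 = G.variants["allele2"][j]
                if np.isnan(g):
                    fields.extend(["0", "0"])
                else:
                    k = int(g)
                    fields.extend([a1] * k + [a2] * (2 - k))
            fh.write(" ".join(fields) + "\n")


def read_genotypes(prefix: str | Path, format: str = "ped_map") -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Read genotypes from ``<prefix>.ped`` / ``<prefix>.map``.

    Only the text PED/MAP route is implemented; ``bim_fam_bed`` is
    accepted for forward compatibility but raises until binary support
    lands.
    """
    prefix = Path(prefix)
    if format == "ped_map":
        return read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    raise NotImplementedError(f"unsupported genotype format: {format}")


# ---------------------------------------------------------------- TSVs


def write_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


def write_visits(visits: pd.DataFrame, path: str | Path) -> None:
    visits.to_csv(path, sep="\t", index=False)


def read_visits(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "icd9_code": str})
    need = {"patient_id", "icd9_code"}
    if not need.issubset(tab.columns):
        raise ParseError(f"visits table needs columns {sorted(need)}")
    return tab


def write_ground_truth(truth: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_default)
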