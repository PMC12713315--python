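"""Genotype quality control: call rate, MAF, Hardy-Weinberg, heterozygosity
and relatedness filters, applied in a fixed order with an auditable report.

Filter order matters (as it does in PLINK); the report records per-step
removal counts so a run can be audited step by step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


class EmptyResultError(ValueError):
    """QC removed every sample or every SNP."""


@dataclass
class QCThresholds:
    """PLINK-style QC cutoffs.

    Defaults follow community-standard tutorial values: sample and SNP
    call rate >= 0.95, MAF >= 0.05, HWE exact p >= 1e-6 in controls,
    per-sample heterozygosity within 3 SD of the mean, and pairwise
    relatedness (standardized allele sharing) below 0.1875.
    """

    min_sample_call_rate: float = 0.95
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 1e-6
    het_z_limit: float = 3.0
    max_relatedness: float = 0.1875

    def validate(self) -> None:
        for name in ("min_sample_call_rate", "min_snp_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.het_z_limit <= 0:
            raise ValueError("het_z_limit must be positive")


@dataclass
class QCReport:
    """Ordered per-filter removal counts plus survivor totals."""

    steps: list[dict] = field(default_factory=list)
    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    def add(self, step: str, axis: str, removed: int) -> None:
        self.steps.append({"step": step, "axis": axis, "removed": int(removed)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "steps": self.steps,
                    "n_samples_in": self.n_samples_in,
                    "n_snps_in": self.n_snps_in,
                    "n_samples_out": self.n_samples_out,
                    "n_snps_out": self.n_snps_out,
                },
                fh,
                indent=2,
            )

    @property
    def total_removed(self) -> int:
        return sum(s["removed"] for s in self.steps)


# ---------------------------------------------------------------- statistics


def compute_maf(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-SNP minor-allele frequency among non-missing calls.

    SNPs with zero non-missing calls get NaN (flagged undefined).
    """
    geno = G.genotypes if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    n_called = (~np.isnan(geno)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.nansum(geno, axis=0) / (2.0 * n_called)
    alt = np.where(n_called == 0, np.nan, alt)
    return np.minimum(alt, 1.0 - alt)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given the allele counts, sums the conditional probabilities of all
    heterozygote counts that are no more probable than the observed one
    (two-sided, the standard exact HWE test).  Uses the stable
    mid-point recurrence over the parity-constrained support.
    """
    if n_hom1 < 0 or n_het < 0 or n_hom2 < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all-zero genotype table: HWE p-value undefined")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: single outcome

    # support: heterozygote counts with the parity of the rare-allele count
    h_max = min(n_rare, 2 * n - n_rare)
    h_min = h_max % 2
    support = np.arange(h_min, h_max + 1, 2)

    # start at the mode-ish expected het count and recurse outwards:
    # P(h+2)/P(h) = (nr-h)(nc-h) / ((h+2)(h+1))  with nr+nc = 2n alleles
    nr, nc = n_rare, 2 * n - n_rare
    h_mid = int(round(nr * nc / (2.0 * n)))
    if (h_mid - h_min) % 2 != 0:
        h_mid += 1 if h_mid < h_max else -1
    h_mid = min(max(h_mid, h_min), h_max)

    probs = {h_mid: 1.0}
    h = h_mid
    while h + 2 <= h_max:
        probs[h + 2] = probs[h] * (nr - h) * (nc - h) / ((h + 2.0) * (h + 1.0))
        h += 2
    h = h_mid
    while h - 2 >= h_min:
        probs[h - 2] = probs[h] * h * (h - 1.0) / ((nr - h + 2.0) * (nc - h + 2.0))
        h -= 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(p, 1.0)


def hwe_pvalues(G: GenotypeMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """HWE exact p per SNP, optionally restricted to a sample mask."""
    geno = G.genotypes if mask is None else G.genotypes[mask]
    out = np.ones(geno.shape[1])
    for j in range(geno.shape[1]):
        col = geno[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return out


def heterozygosity_z(G: GenotypeMatrix) -> np.ndarray:
    """Per-sample heterozygosity rate as a z-score across samples."""
    het = (G.genotypes == 1).sum(axis=1) / (~np.isnan(G.genotypes)).sum(axis=1)
    sd = het.std()
    if sd == 0:
        return np.zeros_like(het)
    return (het - het.mean()) / sd


def relatedness_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Standardized allele-sharing kinship estimate between all sample pairs.

    Entry (i, j) is the mean over SNPs of
    ``(g_i - 2p)(g_j - 2p) / (2p(1-p))`` — the usual GRM off-diagonal,
    ~0 for unrelated pairs, ~0.5 for first-degree relatives, ~1 for
    duplicates.  Missing genotypes are mean-imputed per SNP.
    """
    X = G.genotypes.copy()
    p = np.nansum(X, axis=0) / (2.0 * (~np.isnan(X)).sum(axis=0))
    X = np.where(np.isnan(X), 2 * p, X)
    denom = 2 * p * (1 - p)
    keep = denom > 0
    Z = (X[:, keep] - 2 * p[keep]) / np.sqrt(denom[keep])
    m = keep.sum()
    if m == 0:
        return np.zeros((G.n_samples, G.n_samples))
    return (Z @ Z.T) / m


# ---------------------------------------------------------------- pipeline


def apply_qc(
    G: GenotypeMatrix,
    control_mask: np.ndarray | None,
    thresholds: QCThresholds | None = None,
    max_passes: int = 50,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the QC filters in fixed order and report per-step removals.

    Order within a pass: sample call rate -> SNP call rate -> MAF ->
    HWE (controls) -> heterozygosity outliers -> relatedness (greedy
    removal of one member per flagged pair, lower call rate first).
    Because sample removals shift per-SNP statistics (and vice versa),
    the pass is repeated until a full sweep removes nothing, so the
    result is a fixed point: re-applying the same thresholds removes
    nothing more.  Per-step counts accumulate across passes.

    ``control_mask`` selects the samples used for the HWE filter; when
    None, all samples are used (a conservative fallback for unlabeled
    data).
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    report = QCReport(n_samples_in=G.n_samples, n_snps_in=G.n_snps)
    for step, axis in [
        ("sample_call_rate", "samples"),
        ("snp_call_rate", "snps"),
        ("maf", "snps"),
        ("hwe", "snps"),
        ("heterozygosity", "samples"),
        ("relatedness", "samples"),
    ]:
        report.add(step, axis, 0)
    counts = {s["step"]: s for s in report.steps}

    for _ in range(max_passes):
        before = (G.n_samples, G.n_snps)
        G, control_mask = _qc_pass(G, control_mask, thresholds, counts)
        if (G.n_samples, G.n_snps) == before:
            break

    report.n_samples_out = G.n_samples
    report.n_snps_out = G.n_snps
    return G, report


def _qc_pass(
    G: GenotypeMatrix,
    control_mask: np.ndarray | None,
    thresholds: QCThresholds,
    counts: dict,
) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """One ordered sweep of the six filters, accumulating removal counts."""
    keep = G.call_rate_samples() >= thresholds.min_sample_call_rate
    counts["sample_call_rate"]["removed"] += int((~keep).sum())
    if control_mask is not None:
        control_mask = np.asarray(control_mask, dtype=bool)[keep]
    G = G.take_samples(keep)
    _check_nonempty(G)

    # 2. SNP call rate
    keep = G.call_rate_snps() >= thresholds.min_snp_call_rate
    counts["snp_call_rate"]["removed"] += int((~keep).sum())
    G = G.take_snps(keep)
    _check_nonempty(G)

    # 3. MAF
    maf = compute_maf(G)
    keep = ~np.isnan(maf) & (maf >= thresholds.min_maf)
    counts["maf"]["removed"] += int((~keep).sum())
    G = G.take_snps(keep)
    _check_nonempty(G)

    # 4. HWE in controls
    hwe_p = hwe_pvalues(G, control_mask)
    keep = np.isnan(hwe_p) | (hwe_p >= thresholds.min_hwe_p)
    counts["hwe"]["removed"] += int((~keep).sum())
    G = G.take_snps(keep)
    _check_nonempty(G)

    # 5. heterozygosity outliers
    z = heterozygosity_z(G)
    keep = np.abs(z) <= thresholds.het_z_limit
    counts["heterozygosity"]["removed"] += int((~keep).sum())
    if control_mask is not None:
        control_mask = control_mask[keep]
    G = G.take_samples(keep)
    _check_nonempty(G)

    # 6. relatedness: greedy removal of one member per flagged pair
    rel = relatedness_matrix(G)
    call = G.call_rate_samples()
    drop: set[int] = set()
    iu, ju = np.triu_indices(G.n_samples, k=1)
    flagged = np.flatnonzero(rel[iu, ju] > thresholds.max_relatedness)
    for k in flagged:
        i, j = int(iu[k]), int(ju[k])
        if i in drop or j in drop:
            continue
        # drop the member with the lower call rate; tie -> later sample
        drop.add(j if call[j] <= call[i] else i)
    keep = np.array([i not in drop for i in range(G.n_samples)])
    counts["relatedness"]["removed"] += len(drop)
    if control_mask is not None:
        control_mask = control_mask[keep]
    G = G.take_samples(keep)
    _check_nonempty(G)
    return G, control_mask


def _check_nonempty(G: GenotypeMatrix) -> None:
    if G.n_samples == 0 or G.n_snps == 0:
        raise EmptyResultError("QC thresholds removed all samples or all SNPs")
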