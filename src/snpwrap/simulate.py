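"""Synthetic genotype, phenotype and visit-record generators.

Every downstream stage of the pipeline is testable against data with
known ground truth: genotypes drawn at Hardy-Weinberg equilibrium with
an optional Gaussian-copula LD block structure, binary traits generated
from an explicit additive + pairwise-interaction logistic model with an
optional shared liability linking traits, and visit records with planted
antecedent/consequent lift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .containers import CASE, CONTROL, GenotypeMatrix, PhenotypeTable

_NUCLEOTIDES = np.array(list("ACGT"))


class InvalidConfigError(ValueError):
    pass


class InvalidModelError(ValueError):
    pass


@dataclass
class SimConfig:
    """Genotype-simulation settings.

    ``ld_block_size = 1`` gives independent SNPs; larger blocks couple
    adjacent SNPs through a latent AR(1) Gaussian copula with parameter
    ``ld_rho``.
    """

    n_samples: int
    n_snps: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_snps <= 0:
            raise InvalidConfigError("n_samples and n_snps must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise InvalidConfigError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.ld_block_size < 1:
            raise InvalidConfigError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise InvalidConfigError("ld_rho must be in [0, 1)")


@dataclass
class TraitModel:
    """Generative logistic model for one binary trait.

    The linear predictor for sample *i* is::

        intercept + sex_beta * sex_i
                  + sum_j  additive_effects[j]   * g_ij
                  + sum_jk interaction_effects[(j, k)] * g_ij * g_ik
                  + w / (1 - w) * u_i          (shared liability, w = trait_correlation)

    where ``u_i`` is a standard-normal liability shared by all traits of
    the same cohort, so ``trait_correlation = 0`` decouples traits.
    """

    intercept: float = 0.0
    sex_beta: float = 0.0
    additive_effects: dict[int, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[int, int], float] = field(default_factory=dict)
    trait_correlation: float = 0.0
    #: if set, the intercept is retuned so the expected prevalence hits this value
    target_prevalence: float | None = None

    def validate(self, n_snps: int) -> None:
        for j in self.additive_effects:
            if not (0 <= j < n_snps):
                raise InvalidModelError(f"additive effect references SNP {j} out of range")
        for i, j in self.interaction_effects:
            if i == j:
                raise InvalidModelError("interaction pair (i, i) is not allowed")
            if not (0 <= i < n_snps and 0 <= j < n_snps):
                raise InvalidModelError(
                    f"interaction ({i}, {j}) references a missing SNP"
                )
        if not (0.0 <= self.trait_correlation < 1.0):
            raise InvalidModelError("trait_correlation must be in [0, 1)")


@dataclass
class GroundTruth:
    causal_snp_ids: set[str]
    interaction_pairs: set[tuple[str, str]]
    prevalence: dict[str, float]


@dataclass
class VisitSimConfig:
    n_patients: int
    code_prevalences: dict[str, float]
    planted_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise InvalidConfigError("n_patients must be >= 0")
        for code, p in self.code_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise InvalidConfigError(f"prevalence of {code} outside [0, 1]")
        for (d, c), lift in self.planted_pairs.items():
            if lift < 0:
                raise InvalidConfigError("planted lift must be >= 0")
            for code in (d, c):
                if code not in self.code_prevalences:
                    raise InvalidConfigError(f"planted code {code} has no prevalence")
            if lift * self.code_prevalences[c] > 1.0 + 1e-12:
                raise InvalidConfigError(
                    f"lift {lift} * P({c}) = {lift * self.code_prevalences[c]:.3f} > 1"
                )
            pd_ = self.code_prevalences[d]
            if pd_ < 1.0:
                p_not = self.code_prevalences[c] * (1 - lift * pd_) / (1 - pd_)
                if not (-1e-12 <= p_not <= 1.0 + 1e-12):
                    raise InvalidConfigError(
                        f"pair ({d}, {c}): implied P(C|not D) = {p_not:.3f} outside [0, 1]"
                    )


# ---------------------------------------------------------------- genotypes


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw a genotype matrix at HWE with optional LD blocks.

    Each SNP's minor-allele frequency is uniform on
    ``[maf_low, maf_high]``.  Haplotypes are generated as thresholded
    latent Gaussians: within an LD block the latents follow an AR(1)
    process with coefficient ``ld_rho``, inducing positive genotype
    correlation between adjacent SNPs while leaving every marginal at
    exact HWE.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    maf = rng.uniform(config.maf_low, config.maf_high, size=m)
    thresh = special.ndtri(maf)  # allele carried iff latent < Phi^{-1}(maf)

    hap = np.empty((2, n, m))
    for h in range(2):
        z = rng.standard_normal((n, m))
        if config.ld_block_size > 1 and config.ld_rho > 0:
            rho = config.ld_rho
            for j in range(1, m):
                if j % config.ld_block_size != 0:  # same block as j-1
                    z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        hap[h] = z < thresh
    geno = hap.sum(axis=0)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        geno[mask] = np.nan

    alleles = np.empty((m, 2), dtype="<U1")
    for j in range(m):
        alleles[j] = rng.choice(_NUCLEOTIDES, size=2, replace=False)
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": np.repeat("1", m),
            "pos": np.arange(1, m + 1) * 1000,
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        }
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    sex = rng.integers(0, 2, size=n).astype(float)
    return GenotypeMatrix(geno, sample_ids, variants, sex=sex)


# ---------------------------------------------------------------- phenotypes


def _linear_predictor(G: np.ndarray, sex: np.ndarray, model: TraitModel) -> np.ndarray:
    """Linear predictor without the intercept or shared liability.

    Missing genotypes contribute their SNP mean (dosage expectation) so
    planted effects stay well defined under missingness.
    """
    eta = model.sex_beta * sex
    X = G
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    for j, beta in model.additive_effects.items():
        eta = eta + beta * X[:, j]
    for (i, j), gamma in model.interaction_effects.items():
        eta = eta + gamma * X[:, i] * X[:, j]
    return eta


def simulate_phenotypes(
    G: GenotypeMatrix,
    models: dict[str, TraitModel],
    seed: int = 0,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Draw one binary status per trait from the logistic models.

    A single standard-normal liability per sample is shared by all
    traits; each trait mixes it in with weight ``w/(1-w)`` on the
    log-odds scale, producing positive phenotype correlation
    (comorbidity) for ``w > 0``.  When ``target_prevalence`` is set on a
    model, the intercept is tuned by root finding so the expected
    prevalence matches it.
    """
    rng = np.random.default_rng(seed)
    sex = G.sex if G.sex is not None else rng.integers(0, 2, G.n_samples).astype(float)
    shared = rng.standard_normal(G.n_samples)

    data = {"sample_id": list(G.sample_ids), "sex": sex.astype(int)}
    causal: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    prevalence: dict[str, float] = {}
    snp_ids = G.snp_ids

    for trait, model in models.items():
        model.validate(G.n_snps)
        eta0 = _linear_predictor(G.genotypes, sex, model)
        w = model.trait_correlation
        if w > 0:
            eta0 = eta0 + (w / (1.0 - w)) * shared
        intercept = model.intercept
        if model.target_prevalence is not None:
            target = model.target_prevalence

            def gap(b0: float) -> float:
                return special.expit(b0 + eta0).mean() - target

            intercept = optimize.brentq(gap, -30.0, 30.0)
        p = special.expit(intercept + eta0)
        y = (rng.random(G.n_samples) < p).astype(int)
        data[trait] = np.where(y == 1, CASE, CONTROL)
        causal |= {snp_ids[j] for j in model.additive_effects}
        causal |= {snp_ids[j] for ij in model.interaction_effects for j in ij}
        pairs |= {(snp_ids[i], snp_ids[j]) for i, j in model.interaction_effects}
        prevalence[trait] = float(y.mean())

    table = PhenotypeTable(pd.DataFrame(data))
    return table, GroundTruth(causal, pairs, prevalence)


def resample_to_counts(
    G: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Subsample to exact case/control counts for a designed cohort."""
    rng = np.random.default_rng(seed)
    y = phenotypes.binary(trait, G.sample_ids)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise InvalidConfigError(
            f"cannot draw {n_cases}/{n_controls} from {len(cases)}/{len(controls)}"
        )
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(cases, n_cases, replace=False),
                rng.choice(controls, n_controls, replace=False),
            ]
        )
    )
    sub = G.take_samples(keep)
    tab = phenotypes.table.set_index("sample_id").loc[sub.sample_ids].reset_index()
    return sub, PhenotypeTable(tab)


# ---------------------------------------------------------------- visits


def simulate_visits(config: VisitSimConfig) -> pd.DataFrame:
    """Generate per-patient diagnosis records with planted lift.

    For each planted pair (D, C): ``P(C | D) = lift * P(C)`` and
    ``P(C | not D)`` is adjusted so the marginal prevalence of C equals
    ``code_prevalences[C]``.  All other codes are independent Bernoulli
    draws at their prevalence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    codes = list(config.code_prevalences)
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "icd9_code"])

    consequent_of: dict[str, list[tuple[str, float]]] = {}
    planted_consequents = set()
    for (d, c), lift in config.planted_pairs.items():
        consequent_of.setdefault(c, []).append((d, lift))
        planted_consequents.add(c)

    present = {}
    for code in codes:
        if code not in planted_consequents:
            present[code] = rng.random(n) < config.code_prevalences[code]
    for c in planted_consequents:
        if len(consequent_of[c]) > 1:
            raise InvalidConfigError(
                f"code {c} is the consequent of multiple planted pairs"
            )
        pc = config.code_prevalences[c]
        d, lift = consequent_of[c][0]
        pd_ = config.code_prevalences[d]
        p_given = min(lift * pc, 1.0)
        p_not = pc if pd_ >= 1.0 else pc * (1 - lift * pd_) / (1 - pd_)
        prob = np.where(present[d], p_given, np.clip(p_not, 0.0, 1.0))
        present[c] = rng.random(n) < prob

    rows = []
    for i in range(n):
        pid = f"P{i + 1:06d}"
        for code in codes:
            if present[code][i]:
                rows.append((pid, code))
    return pd.DataFrame(rows, columns=["patient_id", "icd9_code"])
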