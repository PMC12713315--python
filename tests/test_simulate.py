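"""Generator contracts: HWE marginals, planted effects, planted lift."""

import numpy as np
import pytest
import statsmodels.api as sm

from snpwrap.qc import hwe_pvalues
from snpwrap.simulate import (
    InvalidConfigError,
    InvalidModelError,
    SimConfig,
    TraitModel,
    VisitSimConfig,
    resample_to_counts,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_visits,
)


class TestSimulateGenotypes:
    def test_reproducible_from_seed(self):
        cfg = SimConfig(50, 30, missing_rate=0.05, seed=42)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert a.sample_ids == b.sample_ids

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 0, "n_snps": 10},
            {"n_samples": 10, "n_snps": -1},
            {"n_samples": 10, "n_snps": 10, "maf_low": 0.0, "maf_high": 0.0},
            {"n_samples": 10, "n_snps": 10, "missing_rate": 1.0},
            {"n_samples": 10, "n_snps": 10, "ld_rho": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            simulate_genotypes(SimConfig(**kwargs))

    def test_allele_frequency_within_binomial_bound(self):
        # one SNP at frequency 0.3, n=2000: 3-sigma binomial bound
        cfg = SimConfig(2000, 1, maf_low=0.3, maf_high=0.3, seed=5)
        G = simulate_genotypes(cfg)
        freq = G.genotypes.mean() / 2
        assert abs(freq - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / (2 * 2000))

    def test_hwe_holds_marginally(self):
        # null genotypes: >=93% of 1,000 SNPs non-significant at alpha=0.05
        G = simulate_genotypes(SimConfig(500, 1000, maf_low=0.05, seed=9))
        p = hwe_pvalues(G)
        assert (p >= 0.05).mean() >= 0.93

    def test_ld_blocks_induce_adjacent_correlation(self):
        cfg = SimConfig(3000, 20, maf_low=0.3, maf_high=0.4,
                        ld_block_size=5, ld_rho=0.8, seed=3)
        G = simulate_genotypes(cfg)
        X = G.genotypes
        within = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
                  for j in range(19) if (j + 1) % 5 != 0]
        across = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
                  for j in range(19) if (j + 1) % 5 == 0]
        assert min(within) > 0.3
        assert max(np.abs(across)) < 0.15

    def test_missingness_rate(self):
        G = simulate_genotypes(SimConfig(400, 50, missing_rate=0.1, seed=1))
        assert np.isnan(G.genotypes).mean() == pytest.approx(0.1, abs=0.02)


class TestSimulatePhenotypes:
    def test_null_model_prevalence_half(self):
        G = simulate_genotypes(SimConfig(5000, 5, seed=2))
        phen, truth = simulate_phenotypes(G, {"t": TraitModel()}, seed=3)
        prev = truth.prevalence["t"]
        assert abs(prev - 0.5) <= 3 * np.sqrt(0.25 / 5000)
        assert truth.causal_snp_ids == set()

    def test_additive_effect_recovered_by_logistic_refit(self):
        beta = np.log(2.0)
        G = simulate_genotypes(SimConfig(5000, 10, maf_low=0.3, maf_high=0.3, seed=4))
        models = {"t": TraitModel(additive_effects={3: beta})}
        phen, truth = simulate_phenotypes(G, models, seed=5)
        y = phen.binary("t", G.sample_ids)
        X = sm.add_constant(G.genotypes[:, 3])
        fit = sm.Logit(y, X).fit(disp=0)
        assert fit.params[1] == pytest.approx(beta, abs=0.15)
        assert truth.causal_snp_ids == {G.snp_ids[3]}

    def test_uncorrelated_traits_independent(self):
        G = simulate_genotypes(SimConfig(5000, 4, seed=6))
        models = {
            "a": TraitModel(trait_correlation=0.0),
            "b": TraitModel(trait_correlation=0.0),
        }
        phen, _ = simulate_phenotypes(G, models, seed=7)
        ya = phen.binary("a", G.sample_ids)
        yb = phen.binary("b", G.sample_ids)
        assert abs(np.corrcoef(ya, yb)[0, 1]) < 0.05

    def test_shared_liability_couples_traits(self):
        G = simulate_genotypes(SimConfig(5000, 4, seed=6))
        models = {
            "a": TraitModel(trait_correlation=0.6),
            "b": TraitModel(trait_correlation=0.6),
        }
        phen, _ = simulate_phenotypes(G, models, seed=7)
        r = np.corrcoef(
            phen.binary("a", G.sample_ids), phen.binary("b", G.sample_ids)
        )[0, 1]
        assert r > 0.2

    def test_interaction_referencing_missing_snp_rejected(self):
        G = simulate_genotypes(SimConfig(20, 5, seed=1))
        bad = {"t": TraitModel(interaction_effects={(0, 99): 1.0})}
        with pytest.raises(InvalidModelError):
            simulate_phenotypes(G, bad, seed=0)
        with pytest.raises(InvalidModelError):
            simulate_phenotypes(G, {"t": TraitModel(interaction_effects={(1, 1): 1.0})}, seed=0)

    def test_target_prevalence_tunes_intercept(self):
        G = simulate_genotypes(SimConfig(4000, 5, seed=8))
        models = {"t": TraitModel(additive_effects={0: 1.0}, target_prevalence=0.2)}
        phen, truth = simulate_phenotypes(G, models, seed=9)
        assert truth.prevalence["t"] == pytest.approx(0.2, abs=0.03)

    def test_resample_to_counts_exact(self):
        G = simulate_genotypes(SimConfig(500, 5, seed=10))
        phen, _ = simulate_phenotypes(G, {"t": TraitModel()}, seed=11)
        sub, sub_phen = resample_to_counts(G, phen, "t", 80, 16, seed=12)
        y = sub_phen.binary("t", sub.sample_ids)
        assert (y == 1).sum() == 80 and (y == 0).sum() == 16


class TestSimulateVisits:
    def test_empty_cohort(self):
        out = simulate_visits(VisitSimConfig(0, {"250": 0.2}))
        assert out.empty

    def test_unit_lift_is_independence(self):
        cfg = VisitSimConfig(
            10_000, {"250": 0.2, "401": 0.3}, {("250", "401"): 1.0}, seed=13
        )
        visits = simulate_visits(cfg)
        wide = visits.assign(x=1).pivot_table(
            index="patient_id", columns="icd9_code", values="x", fill_value=0
        )
        p_c = wide["401"].sum() / 10_000  # over the full cohort, not the pivot
        conf = wide.loc[wide["250"] == 1, "401"].mean()
        assert conf / p_c == pytest.approx(1.0, abs=0.2)

    def test_planted_lift_recovered(self):
        cfg = VisitSimConfig(
            10_000, {"250": 0.1, "366": 0.05}, {("250", "366"): 8.0}, seed=14
        )
        visits = simulate_visits(cfg)
        wide = visits.assign(x=1).pivot_table(
            index="patient_id", columns="icd9_code", values="x", fill_value=0
        )
        # patients with no code at all drop out of the pivot; recount over cohort
        n = 10_000
        n_d = wide["250"].sum()  # P(D) = 0.1 keeps lift * P(D) < 1 feasible
        n_c = wide["366"].sum()
        n_both = ((wide["250"] == 1) & (wide["366"] == 1)).sum()
        lift = (n_both / n_d) / (n_c / n)
        assert lift == pytest.approx(8.0, abs=1.0)
        # marginal prevalence preserved despite the planted association
        assert n_c / n == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n))

    def test_impossible_lift_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_visits(
                VisitSimConfig(100, {"a": 0.5, "b": 0.5}, {("a", "b"): 8.0})
            )
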