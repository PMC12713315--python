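"""Association scan, genomic control, thresholds and candidate sets."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from snpwrap.gwas import (
    CovariateModel,
    ThresholdConfig,
    candidate_union,
    lambda_gc,
    logistic_assoc,
    multiple_testing,
    pca_covariates,
)
from snpwrap.simulate import SimConfig, TraitModel, simulate_genotypes, simulate_phenotypes
from tests.conftest import make_genotype_matrix


def _no_covariates(n):
    return CovariateModel("none", np.empty((n, 0)))


class TestLogisticAssoc:
    def test_two_by_two_closed_form(self):
        # binary genotype; cases 10 exposed / 40 unexposed, controls 5 / 45
        g = np.array([1.0] * 10 + [0.0] * 40 + [1.0] * 5 + [0.0] * 45)
        y = np.array([1.0] * 50 + [0.0] * 50)
        G = make_genotype_matrix(g[:, None])
        res = logistic_assoc(G, y, _no_covariates(100))
        assert res["effect"][0] == pytest.approx(np.log(2.25), abs=1e-4)

    def test_monomorphic_flagged(self):
        geno = np.column_stack([np.zeros(40), np.random.default_rng(0).binomial(2, 0.4, 40)])
        y = np.repeat([0.0, 1.0], 20)
        res = logistic_assoc(make_genotype_matrix(geno), y, _no_covariates(40))
        assert res["status"][0] == "monomorphic"
        assert np.isnan(res["p_value"][0])
        assert res["status"][1] == "ok"

    def test_separation_flagged_not_numeric(self):
        g = np.repeat([0.0, 2.0], 20)
        y = np.repeat([0.0, 1.0], 20)  # genotype separates labels perfectly
        res = logistic_assoc(make_genotype_matrix(g[:, None]), y, _no_covariates(40))
        assert res["status"][0] == "separation"
        assert np.isnan(res["p_value"][0])

    def test_single_class_phenotype_rejected(self):
        G = make_genotype_matrix(np.random.default_rng(1).binomial(2, 0.3, (20, 3)).astype(float))
        with pytest.raises(ValueError):
            logistic_assoc(G, np.ones(20), _no_covariates(20))

    def test_matches_statsmodels_with_covariates_and_missing(self):
        rng = np.random.default_rng(5)
        G = simulate_genotypes(SimConfig(250, 30, missing_rate=0.05, seed=5))
        phen, _ = simulate_phenotypes(
            G, {"t": TraitModel(additive_effects={2: 0.7}, sex_beta=0.4)}, seed=6
        )
        y = phen.binary("t", G.sample_ids)
        model = CovariateModel.sex_only(G.sex)
        res = logistic_assoc(G, y, model)
        for j in [0, 2, 17]:
            g = G.genotypes[:, j]
            ok = ~np.isnan(g)
            X = sm.add_constant(np.column_stack([G.sex[ok], g[ok]]))
            fit = sm.Logit(y[ok], X).fit(disp=0)
            assert res["effect"][j] == pytest.approx(fit.params[2], abs=1e-6)
            assert res["se"][j] == pytest.approx(fit.bse[2], abs=1e-6)
            assert res["n_used"][j] == ok.sum()

    def test_planted_snp_power(self):
        # OR 3 at MAF 0.3, n=500: p < 1e-4 in >= 80% of replicates
        hits = 0
        for rep in range(25):
            G = simulate_genotypes(
                SimConfig(500, 2, maf_low=0.3, maf_high=0.3, seed=rep)
            )
            phen, _ = simulate_phenotypes(
                G, {"t": TraitModel(additive_effects={0: np.log(3)},
                                    target_prevalence=0.5)}, seed=rep + 100
            )
            y = phen.binary("t", G.sample_ids)
            res = logistic_assoc(G, y, CovariateModel.sex_only(G.sex))
            hits += res["p_value"][0] < 1e-4
        assert hits / 25 >= 0.8


class TestPcaCovariates:
    def test_k_zero_empty(self, small_cohort):
        G, _ = small_cohort
        assert pca_covariates(G, 0).shape == (60, 0)

    def test_k_too_large_rejected(self, small_cohort):
        G, _ = small_cohort
        with pytest.raises(ValueError):
            pca_covariates(G, 61)

    def test_orthogonal_scores(self, small_cohort):
        G, _ = small_cohort
        pcs = pca_covariates(G, 5)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_deterministic(self, small_cohort):
        G, _ = small_cohort
        np.testing.assert_allclose(pca_covariates(G, 3), pca_covariates(G, 3))

    def test_pc1_separates_planted_subpopulations(self):
        rng = np.random.default_rng(8)
        a = rng.binomial(2, 0.1, size=(50, 300)).astype(float)
        b = rng.binomial(2, 0.5, size=(50, 300)).astype(float)
        G = make_genotype_matrix(np.vstack([a, b]))
        pcs = pca_covariates(G, 1)
        group = np.repeat([0.0, 1.0], 50)
        r = np.corrcoef(pcs[:, 0], group)[0, 1]
        assert abs(r) > 0.9


class TestLambdaGC:
    def test_null_median(self):
        assert lambda_gc(np.full(100, 0.5)).lambda_gc == pytest.approx(1.0)

    def test_quantile_arithmetic(self):
        # all p = 0.1: chi2 90% quantile over the null median
        expected = stats.chi2.ppf(0.9, 1) / stats.chi2.ppf(0.5, 1)
        assert lambda_gc(np.full(50, 0.1)).lambda_gc == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(5.947, abs=0.001)

    def test_uniform_calibration(self):
        p = np.random.default_rng(0).uniform(size=10_000)
        lam = lambda_gc(p).lambda_gc
        assert 0.9 <= lam <= 1.1

    def test_qq_sorted_equal_length(self):
        rep = lambda_gc(np.random.default_rng(1).uniform(size=500))
        assert len(rep.qq_expected) == len(rep.qq_observed)
        assert (np.diff(rep.qq_expected) >= 0).all()
        assert (np.diff(rep.qq_observed) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lambda_gc(np.array([]))


class TestMultipleTesting:
    def test_bonferroni_cutoff(self):
        bonf, _ = multiple_testing(np.full(20, 0.5))
        assert bonf == pytest.approx(0.05 / 20)

    def test_bh_step_up_all_significant(self):
        _, mask = multiple_testing(np.array([0.01, 0.02, 0.03, 0.04]))
        assert mask.all()

    def test_single_nonsignificant(self):
        bonf, mask = multiple_testing(np.array([0.9]))
        assert bonf == pytest.approx(0.05)
        assert not mask.any()


class TestCandidateUnion:
    def _frame(self, ids, pvals):
        return pd.DataFrame(
            {"snp_id": ids, "p_value": pvals, "status": "ok"}
        )

    def test_simple_union(self):
        res = {
            "t1": self._frame(["a", "b", "x"], [0.001, 0.001, 0.5]),
            "t2": self._frame(["b", "c", "x"], [0.001, 0.001, 0.5]),
            "t3": self._frame(["d", "x", "y"], [0.001, 0.5, 0.5]),
        }
        union, per_trait = candidate_union(res, 0.01)
        assert union == {"a", "b", "c", "d"}
        assert per_trait["t1"] == {"a", "b"}

    def test_multiplicity_counts_give_union_size(self):
        # per-trait sizes 10, 27, 20 with 5 duplicate memberships -> 52 unique
        t1 = [f"s{i}" for i in range(10)]
        t2 = [f"s{i + 10}" for i in range(27)]
        t3 = [f"s{i + 37}" for i in range(15)] + t1[:3] + t2[:2]
        res = {
            k: self._frame(ids, [1e-5] * len(ids))
            for k, ids in [("t1", t1), ("t2", t2), ("t3", t3)]
        }
        union, per_trait = candidate_union(res, 1e-4)
        sizes = [len(per_trait[k]) for k in ("t1", "t2", "t3")]
        assert sizes == [10, 27, 20]
        assert sum(sizes) - len(union) == 5
        assert len(union) == 52

    def test_threshold_one_keeps_everything(self):
        res = {"t": self._frame(["a", "b"], [0.2, 0.9])}
        union, _ = candidate_union(res, 1.0)
        assert union == {"a", "b"}
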