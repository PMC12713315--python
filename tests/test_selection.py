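"""Wrapper selection: LOOCV scoring, best-first search, leakage protocols."""

import itertools

import numpy as np
import pytest

from snpwrap.classifiers import ClassifierSpec
from snpwrap.gwas import make_gwas_screen
from snpwrap.selection import (
    BestFirstSelector,
    SearchConfig,
    best_first_search,
    embedded_selection_cv,
    fixed_subset_workflow,
    loocv_accuracy,
)

KNN = ClassifierSpec("knn")
ZERO = ClassifierSpec("zero_rule")


class TestLoocvAccuracy:
    def test_majority_fraction_for_zero_rule(self):
        # LOOCV of the majority baseline equals the majority fraction:
        # removing a case makes the fold predict control, and vice versa
        y = np.array([1] * 46 + [0] * 50)
        assert loocv_accuracy(np.empty((96, 0)), y, ZERO) == pytest.approx(50 / 96)
        y = np.array([1] * 34 + [0] * 62)
        assert loocv_accuracy(np.empty((96, 0)), y, ZERO) == pytest.approx(62 / 96)

    def test_perfect_predictor_with_1nn(self):
        y = np.repeat([0, 1], 15)
        X = y[:, None].astype(float)
        assert loocv_accuracy(X, y, KNN) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            loocv_accuracy(np.zeros((5, 1)), np.ones(5), KNN)

    def test_fast_knn_path_matches_generic_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        from sklearn.neighbors import KNeighborsClassifier

        fast = loocv_accuracy(X, y, KNN)
        slow = loocv_accuracy(X, y, KNeighborsClassifier(n_neighbors=1))
        assert fast == pytest.approx(slow)

    def test_sklearn_estimator_accepted(self):
        from sklearn.tree import DecisionTreeClassifier

        y = np.repeat([0, 1], 10)
        X = np.column_stack([y, np.zeros(20)]).astype(float)
        acc = loocv_accuracy(X, y, DecisionTreeClassifier(random_state=0))
        assert acc == 1.0


class TestBestFirstSearch:
    def test_matches_exhaustive_on_small_lattice(self):
        # unbounded stale budget must fully explore <=8-feature lattices
        spec = KNN
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 3, size=(18, 6)).astype(float)
            y = np.array([0, 1] * 9)
            res = best_first_search(X, y, spec, SearchConfig(stale_limit=10**9))
            best = loocv_accuracy(np.empty((18, 0)), y, spec)
            for k in range(1, 7):
                for sub in itertools.combinations(range(6), k):
                    best = max(best, loocv_accuracy(X[:, list(sub)], y, spec))
            assert res.score == pytest.approx(best)
            assert res.n_evaluations == 2**6

    def test_planted_feature_recovered(self):
        from sklearn.tree import DecisionTreeClassifier

        found = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 40)
            X = rng.integers(0, 3, size=(40, 21)).astype(float)
            X[:, 13] = y  # fully predictive feature among 20 noise columns
            res = best_first_search(
                X, y, DecisionTreeClassifier(random_state=0), SearchConfig()
            )
            found += 13 in res.features
        assert found >= 9

    def test_pure_noise_zero_rule_returns_empty(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(30, 6)).astype(float)
        y = np.array([0] * 18 + [1] * 12)
        res = best_first_search(X, y, ZERO, SearchConfig())
        assert res.features == ()
        assert res.score == pytest.approx(loocv_accuracy(np.empty((30, 0)), y, ZERO))

    def test_trace_best_score_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(24, 8)).astype(float)
        y = rng.integers(0, 2, 24)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        res = best_first_search(X, y, KNN, SearchConfig())
        best = [t["best_score"] for t in res.trace]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_singleton_pool(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(20, 1)).astype(float)
        y = np.array([0, 1] * 10)
        res = best_first_search(X, y, KNN, SearchConfig())
        assert res.features in ((), (0,))
        single = loocv_accuracy(X, y, KNN)
        empty = loocv_accuracy(np.empty((20, 0)), y, KNN)
        assert res.score == pytest.approx(max(single, empty))

    def test_max_subset_size_respected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 8))
        y = np.array([0, 1] * 10)
        res = best_first_search(X, y, KNN, SearchConfig(max_subset_size=2))
        assert len(res.features) <= 2


class TestWorkflows:
    def test_fixed_workflow_deterministic(self, small_cohort):
        G, y = small_cohort
        a = fixed_subset_workflow(G.genotypes, y, KNN, SearchConfig(seed=1))
        b = fixed_subset_workflow(G.genotypes, y, KNN, SearchConfig(seed=1))
        assert a.features == b.features and a.score == b.score

    def test_embedded_null_behaviour(self):
        # pure noise, 50/50: honest accuracy stays near chance
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 3, size=(20, 10)).astype(float)
            y = np.array([0, 1] * 10)
            _, honest = embedded_selection_cv(X, y, KNN, SearchConfig())
            accs.append(honest)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_fix_once_optimism_exceeds_embedded(self):
        # selection leakage: in-search LOOCV beats honest accuracy on noise
        gaps = []
        for seed in range(8):
            rng = np.random.default_rng(seed + 50)
            X = rng.integers(0, 3, size=(24, 15)).astype(float)
            y = np.array([0, 1] * 12)
            fix = fixed_subset_workflow(X, y, KNN, SearchConfig())
            _, honest = embedded_selection_cv(X, y, KNN, SearchConfig())
            gaps.append(fix.score - honest)
        assert np.mean(gaps) > 0.1

    def test_embedded_recovers_planted_signal(self):
        spec = ClassifierSpec("knn", {"n_neighbors": 5})
        frac_folds = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.array([0, 1] * (n // 2))
            X = rng.integers(0, 3, size=(n, 12)).astype(float)
            # two strong causal columns: genotype tracks the label closely
            for j in (3, 9):
                flip = rng.random(n) < 0.15
                X[:, j] = np.where(flip, rng.integers(0, 3, n), y * 2)
            folds, _ = embedded_selection_cv(X, y, spec, SearchConfig())
            hit = [bool(set(f.features) & {3, 9}) for f in folds]
            frac_folds.append(np.mean(hit))
        assert np.mean(frac_folds) >= 0.8

    def test_embedded_screen_runs_inside_fold(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.3, size=(30, 50)).astype(float)
        y = np.array([0, 1] * 15)
        calls = []

        def screen(X_tr, y_tr):
            calls.append(X_tr.shape[0])
            return make_gwas_screen(0.05)(X_tr, y_tr)

        embedded_selection_cv(X, y, KNN, SearchConfig(), screen=screen)
        assert calls and all(c == 29 for c in calls)


class TestBestFirstSelector:
    def test_sklearn_contract(self):
        from sklearn.utils.estimator_checks import check_estimator

        check_estimator(
            BestFirstSelector(classifier="zero_rule", stale_limit=1),
            expected_failed_checks={
                "check_methods_subset_invariance": "selector output depends on the fitted subset only",
            },
        )

    def test_selects_predictive_column_in_pipeline(self):
        from sklearn.pipeline import Pipeline
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 40)
        X = rng.integers(0, 3, size=(40, 8)).astype(float)
        X[:, 5] = y
        pipe = Pipeline(
            [
                ("select", BestFirstSelector(classifier="knn")),
                ("clf", DecisionTreeClassifier(random_state=0)),
            ]
        )
        pipe.fit(X, y)
        mask = pipe.named_steps["select"].support_
        assert mask[5]
        assert pipe.score(X, y) == 1.0
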