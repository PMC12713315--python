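"""Classifier registry and the native rule-based baselines.

The benchmark covers fourteen named algorithms; Zero Rule and One Rule
are implemented natively (they are fully specified baselines), the rest
bind to scikit-learn estimators with documented defaults.  Four learners
without an exact scikit-learn analog (locally weighted learning, RIPPER,
PART, logistic model trees) map to nearest-equivalent substitutes and
are marked as such in the registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data


class ZeroRuleClassifier(ClassifierMixin, BaseEstimator):
    """Predict the training-majority class always (ZeroR baseline).

    Ties are broken toward the smaller class label for determinism.
    """

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=0)
        classes, counts = np.unique(y, return_counts=True)
        self.classes_ = classes
        self.majority_ = classes[np.argmax(counts)]  # argmax: first max wins
        self.majority_fraction_ = counts.max() / counts.sum()
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, ensure_min_features=0)
        return np.full(X.shape[0], self.majority_)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, ensure_min_features=0)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        proba[:, np.flatnonzero(self.classes_ == self.majority_)[0]] = 1.0
        return proba


class OneRuleClassifier(ClassifierMixin, BaseEstimator):
    """OneR: the single feature whose per-value majority rule minimizes
    training error; ties broken by feature order.

    Feature values are treated as categories (genotype codes are already
    discrete); values unseen in training fall back to the overall
    majority class.
    """

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        self.classes_ = classes
        counts = np.array([(y == c).sum() for c in classes])
        self.fallback_ = classes[np.argmax(counts)]
        best_err, best_j, best_rule = np.inf, 0, {}
        for j in range(X.shape[1]):
            rule, err = {}, 0
            for v in np.unique(X[:, j]):
                sub = y[X[:, j] == v]
                sub_counts = np.array([(sub == c).sum() for c in classes])
                rule[v] = classes[np.argmax(sub_counts)]
                err += sub_counts.sum() - sub_counts.max()
            if err < best_err:  # strict: first feature wins ties
                best_err, best_j, best_rule = err, j, rule
        self.feature_ = best_j
        self.rule_ = best_rule
        self.training_error_ = best_err / len(y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        col = X[:, self.feature_]
        return np.array([self.rule_.get(v, self.fallback_) for v in col])


@dataclass
class ClassifierSpec:
    """A named entry of the classifier registry plus hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self) -> BaseEstimator:
        return build_classifier(self.name, self.hyperparameters, self.seed)


def _registry(seed: int) -> dict[str, BaseEstimator]:
    return {
        "naive_bayes": GaussianNB(),
        "svm_lib": SVC(kernel="rbf", probability=False, random_state=seed),
        "svm_sgd": SGDClassifier(loss="hinge", random_state=seed),
        "smo_logistic": LogisticRegression(max_iter=1000, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=1),
        # nearest-equivalent substitute: distance-weighted KNN for LWL
        "lwl": KNeighborsClassifier(n_neighbors=5, weights="distance"),
        # nearest-equivalent substitute: pruned CART for the rule inducer
        "ripper": DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, ccp_alpha=0.01, random_state=seed
        ),
        "one_rule": OneRuleClassifier(),
        # nearest-equivalent substitute: pruned CART for partial decision trees
        "part": DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=seed
        ),
        "zero_rule": ZeroRuleClassifier(),
        "c45_tree": DecisionTreeClassifier(criterion="entropy", random_state=seed),
        # nearest-equivalent substitute: logistic regression for model trees
        "logistic_model_tree": LogisticRegression(max_iter=1000, random_state=seed),
        "random_tree": DecisionTreeClassifier(
            criterion="gini", max_features="sqrt", random_state=seed
        ),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
    }


REGISTRY_NAMES = tuple(_registry(0))

#: registry entries that are nearest-equivalent substitutes rather than
#: faithful reimplementations of the named algorithm
SUBSTITUTE_NAMES = ("lwl", "ripper", "part", "logistic_model_tree")


def build_classifier(name: str, hyperparameters: dict | None = None, seed: int = 0):
    """Instantiate a registry classifier; unknown hyperparameters raise."""
    reg = _registry(seed)
    if name not in reg:
        raise KeyError(f"unknown classifier {name!r}; registry: {sorted(reg)}")
    est = clone(reg[name])
    if hyperparameters:
        valid = est.get_params()
        unknown = set(hyperparameters) - set(valid)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {name}: {sorted(unknown)}")
        est.set_params(**hyperparameters)
    return est


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for AUC: probability of the positive (larger)
    class when available, else the decision function, else hard labels."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, -1]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict(X), dtype=float)
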