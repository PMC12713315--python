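"""Wrapper-based SNP subset selection: best-first forward search scored
by leave-one-out cross-validated accuracy.

Two protocols are provided because they answer different questions:

* :func:`fixed_subset_workflow` runs the search once on the full
  discovery data and freezes the subset — the protocol that produces a
  single interpretable marker set, but whose LOOCV score is optimistic
  because every held-out sample also steered the search.
* :func:`embedded_selection_cv` re-runs the search inside every
  leave-one-out training fold and aggregates predictions on the held-out
  samples — the leakage-safe estimate of generalization accuracy.

The gap between the two on null data is the classic selection-leakage
signature and is exercised directly in the test suite.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .classifiers import ClassifierSpec, OneRuleClassifier, ZeroRuleClassifier


@dataclass
class SearchConfig:
    """Best-first search settings (forward direction, accuracy metric)."""

    stale_limit: int = 5
    max_subset_size: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.stale_limit < 1:
            raise ValueError("stale_limit must be >= 1")
        if self.max_subset_size is not None and self.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1 when set")


@dataclass
class SubsetScore:
    """A selected subset with its LOOCV accuracy and search bookkeeping."""

    features: tuple[int, ...]
    score: float
    n_evaluations: int
    trace: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------- LOOCV


def _majority_label(y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    return classes[np.argmax(counts)]


def _loocv_zero_rule(y: np.ndarray) -> float:
    """Closed-form LOOCV of the majority-class baseline."""
    classes, counts = np.unique(y, return_counts=True)
    correct = 0
    for ci, c in enumerate(classes):
        rest = np.delete(counts, ci).copy()
        rest_classes = np.delete(classes, ci)
        n_c = counts[ci] - 1
        # after holding out one member of class c, predicted label:
        all_counts = np.append(rest, n_c)
        all_classes = np.append(rest_classes, c)
        order = np.argsort(all_classes)  # ties toward the smaller label
        all_counts, all_classes = all_counts[order], all_classes[order]
        pred = all_classes[np.argmax(all_counts)]
        if pred == c:
            correct += counts[ci]
    return correct / counts.sum()


def _loocv_knn(X: np.ndarray, y: np.ndarray, k: int = 1) -> float:
    """LOOCV of k-nearest-neighbours from a single distance matrix.

    Holding out sample i and predicting it with the remaining n-1
    samples is exactly nearest-neighbour search excluding self, so no
    refits are needed.  Distance ties resolve to the lower index;
    vote ties resolve to the smaller class label.
    """
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    n = len(y)
    if k == 1:
        nn = np.argmin(d2, axis=1)
        return float((y[nn] == y).mean())
    idx = np.argpartition(d2, min(k, n - 2), axis=1)[:, :k]
    votes = y[idx]  # (n, k)
    classes = np.unique(y)
    counts = np.stack([(votes == c).sum(axis=1) for c in classes], axis=1)
    pred = classes[np.argmax(counts, axis=1)]  # vote ties -> smaller label
    return float((pred == y).mean())


def loocv_accuracy(X: np.ndarray, y: np.ndarray, clf) -> float:
    """Leave-one-out cross-validated accuracy of a classifier.

    ``clf`` may be a :class:`ClassifierSpec` (enabling closed-form fast
    paths for the zero-rule and k-NN learners) or any scikit-learn
    classifier.  ``X`` with zero columns scores the majority baseline.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        raise ValueError(f"LOOCV needs at least 2 samples, got n_samples = {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("y has 1 class; both classes are required")

    name = clf.name if isinstance(clf, ClassifierSpec) else None
    if X.ndim != 2 or X.shape[1] == 0 or name == "zero_rule":
        return _loocv_zero_rule(y)
    if name == "knn" and not clf.hyperparameters.get("weights"):
        return _loocv_knn(X, y, k=int(clf.hyperparameters.get("n_neighbors", 1)))
    if name == "one_rule":
        est = OneRuleClassifier()
        correct = 0
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            est.fit(X[tr], y[tr])
            correct += int(est.predict(X[i: i + 1])[0] == y[i])
        return correct / n

    est = clf.build() if isinstance(clf, ClassifierSpec) else clf
    idx = np.arange(n)
    correct = 0
    for i in range(n):
        tr = idx != i
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            pred = _majority_label(y_tr)
        else:
            model = clone(est).fit(X[tr], y_tr)
            pred = model.predict(X[i: i + 1])[0]
        correct += int(pred == y[i])
    return correct / n


# ---------------------------------------------------------------- search


def best_first_search(
    X: np.ndarray,
    y: np.ndarray,
    clf,
    config: SearchConfig | None = None,
    candidates: np.ndarray | None = None,
) -> SubsetScore:
    """Best-first forward search over the feature-subset lattice.

    Starting from the empty set (scored as the majority baseline), the
    open list is a priority queue ordered by LOOCV accuracy; the best
    open node is expanded by every single-feature addition, and the
    search stops after ``stale_limit`` consecutive expansions that fail
    to improve the global best.  Ties in the global best go to the
    smaller subset, then lexicographic feature order, so results are
    platform-deterministic.  ``candidates`` restricts the pool to a
    subset of column indices.
    """
    config = config or SearchConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pool = (
        np.arange(X.shape[1]) if candidates is None else np.asarray(candidates, int)
    )
    if pool.size == 0:
        raise ValueError("need at least one candidate feature")

    cache: dict[tuple[int, ...], float] = {}
    trace: list[dict] = []

    def evaluate(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = loocv_accuracy(X[:, list(subset)], y, clf)
        return cache[subset]

    def better(sub_a: tuple[int, ...], score_a: float,
               sub_b: tuple[int, ...], score_b: float) -> bool:
        """True when (sub_a, score_a) beats the incumbent b."""
        if score_a != score_b:
            return score_a > score_b
        if len(sub_a) != len(sub_b):
            return len(sub_a) < len(sub_b)
        return sub_a < sub_b

    empty: tuple[int, ...] = ()
    best_subset, best_score = empty, evaluate(empty)
    trace.append({"subset": empty, "score": best_score, "best_score": best_score})
    # heap entries: (-score, len, subset) so ties expand smaller subsets first
    open_list: list[tuple[float, int, tuple[int, ...]]] = [
        (-best_score, 0, empty)
    ]
    in_open = {empty}
    stale = 0

    while open_list and stale < config.stale_limit:
        _, _, node = heapq.heappop(open_list)
        in_open.discard(node)
        improved = False
        for j in pool:
            if j in node:
                continue
            child = tuple(sorted(node + (int(j),)))
            if child in cache or child in in_open:
                continue
            if config.max_subset_size and len(child) > config.max_subset_size:
                continue
            score = evaluate(child)
            if better(child, score, best_subset, best_score):
                if score > best_score:
                    improved = True
                best_subset, best_score = child, score
            trace.append(
                {"subset": child, "score": score, "best_score": best_score}
            )
            heapq.heappush(open_list, (-score, len(child), child))
            in_open.add(child)
        stale = 0 if improved else stale + 1

    return SubsetScore(best_subset, best_score, len(cache), trace)


def fixed_subset_workflow(
    X: np.ndarray,
    y: np.ndarray,
    clf,
    config: SearchConfig | None = None,
    candidates: np.ndarray | None = None,
) -> SubsetScore:
    """Fix-once protocol: one search on the full discovery data.

    The returned subset is intended to be frozen for all downstream
    evaluation; its score is the in-search LOOCV accuracy and is an
    optimistic estimate (see module docstring).
    """
    return best_first_search(X, y, clf, config, candidates)


def embedded_selection_cv(
    X: np.ndarray,
    y: np.ndarray,
    clf,
    config: SearchConfig | None = None,
    screen=None,
) -> tuple[list[SubsetScore], float]:
    """Leakage-safe protocol: selection embedded in each LOOCV fold.

    For every held-out sample the search (and the optional candidate
    ``screen(X_train, y_train) -> column indices``, e.g. a per-fold GWAS
    filter) runs on the remaining n-1 samples only; the held-out
    prediction uses that fold's subset.  Returns the per-fold
    :class:`SubsetScore` list and the honest aggregate accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y has 1 class; both classes are required")
    idx = np.arange(n)
    fold_scores: list[SubsetScore] = []
    correct = 0
    for i in range(n):
        tr = idx != i
        X_tr, y_tr = X[tr], y[tr]
        if len(np.unique(y_tr)) < 2:
            fold_scores.append(SubsetScore((), 0.0, 0))
            correct += int(_majority_label(y_tr) == y[i])
            continue
        cand = None if screen is None else np.asarray(screen(X_tr, y_tr), int)
        if cand is not None and cand.size == 0:
            sub = SubsetScore((), _loocv_zero_rule(y_tr), 0)
        else:
            sub = best_first_search(X_tr, y_tr, clf, config, cand)
        fold_scores.append(sub)
        if not sub.features:
            pred = _majority_label(y_tr)
        else:
            cols = list(sub.features)
            est = clf.build() if isinstance(clf, ClassifierSpec) else clone(clf)
            if isinstance(clf, ClassifierSpec) and clf.name == "zero_rule":
                est = ZeroRuleClassifier()
            est.fit(X_tr[:, cols], y_tr)
            pred = est.predict(X[i: i + 1, cols])[0]
        correct += int(pred == y[i])
    return fold_scores, correct / n


# ---------------------------------------------------------------- estimator


class BestFirstSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping the best-first LOOCV search.

    Parameters
    ----------
    classifier:
        Registry name (str), :class:`ClassifierSpec`, or estimator used
        to score candidate subsets by LOOCV accuracy.
    stale_limit:
        Consecutive non-improving expansions before termination.
    max_subset_size:
        Optional cap on the subset size.
    seed:
        Passed to registry classifiers that accept one.

    Attributes
    ----------
    support_ : boolean mask of selected columns
    best_score_ : LOOCV accuracy of the selected subset
    trace_ : search audit trail of (subset, score, best_score) records
    n_evaluations_ : number of distinct subsets scored
    """

    def __init__(self, classifier="knn", stale_limit=5, max_subset_size=None, seed=0):
        self.classifier = classifier
        self.stale_limit = stale_limit
        self.max_subset_size = max_subset_size
        self.seed = seed

    def _spec(self):
        if isinstance(self.classifier, str):
            return ClassifierSpec(self.classifier, seed=self.seed)
        return self.classifier

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        config = SearchConfig(
            stale_limit=self.stale_limit,
            max_subset_size=self.max_subset_size,
            seed=self.seed,
        )
        result = best_first_search(X, y, self._spec(), config)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[list(result.features)] = True
        self.support_ = mask
        self.best_score_ = result.score
        self.trace_ = result.trace
        self.n_evaluations_ = result.n_evaluations
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
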