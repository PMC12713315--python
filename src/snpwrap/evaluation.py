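"""Internal cross-validation and external stratified-bootstrap evaluation.

Internal stability is measured by repeated stratified k-fold CV
(default 10 x 10); external robustness by B stratified bootstrap
replicates of the held-out cohort, resampling with replacement within
class so every replicate preserves the original case-control ratio.
Summaries are mean +/- SD with a percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import RepeatedStratifiedKFold

from .classifiers import ClassifierSpec, decision_scores


@dataclass
class CVConfig:
    k: int = 10
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class BootstrapConfig:
    B: int = 1000
    stratified: bool = True
    ci_level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class EvalResult:
    """Per-replicate metric values with summary statistics."""

    metric: str
    values: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_values(cls, metric: str, values, ci_level: float = 0.95) -> "EvalResult":
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        lo, hi = np.percentile(v, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
        return cls(metric, v, float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0,
                   float(lo), float(hi))


def train_baseline(name: str, X: np.ndarray, y: np.ndarray):
    """Fit one of the native rule baselines (``zero_rule`` or ``one_rule``)."""
    X, y = np.asarray(X, dtype=float), np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty training set")
    if name not in ("zero_rule", "one_rule"):
        raise KeyError(f"not a rule baseline: {name!r}")
    if name == "one_rule" and len(np.unique(y)) < 2:
        raise ValueError("one_rule needs both classes in training data")
    return ClassifierSpec(name).build().fit(X, y)


def auc_score(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for score ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("AUC needs exactly two classes in y")
    pos = y == classes[-1]
    n_pos, n_neg = pos.sum(), (~pos).sum()
    ranks = rankdata(scores)  # average ranks implement the tie convention
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def repeated_stratified_cv(
    X: np.ndarray,
    y: np.ndarray,
    clf,
    config: CVConfig | None = None,
) -> dict[str, EvalResult]:
    """repeats x k stratified cross-validation; accuracy and AUC per fold."""
    config = config or CVConfig()
    config.validate()
    X, y = np.asarray(X, dtype=float), np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < config.k:
        raise ValueError(
            f"smallest class ({counts.min()}) has fewer samples than k={config.k}"
        )
    est = clf.build() if isinstance(clf, ClassifierSpec) else clf
    splitter = RepeatedStratifiedKFold(
        n_splits=config.k, n_repeats=config.repeats, random_state=config.seed
    )
    accs, aucs = [], []
    for tr, te in splitter.split(X, y):
        model = clone(est).fit(X[tr], y[tr])
        pred = model.predict(X[te])
        accs.append((pred == y[te]).mean())
        if len(np.unique(y[te])) == 2:
            aucs.append(auc_score(decision_scores(model, X[te]), y[te]))
    return {
        "accuracy": EvalResult.from_values("accuracy", accs),
        "auc": EvalResult.from_values("auc", aucs),
    }


def stratified_bootstrap_external(
    model,
    X_ext: np.ndarray,
    y_ext: np.ndarray,
    config: BootstrapConfig | None = None,
) -> dict[str, EvalResult]:
    """External evaluation by B stratified bootstrap replicates.

    The model is already fitted on the discovery cohort and never
    refitted here; predictions on the external samples are computed once
    and replicate metrics are taken over within-class resamples whose
    class counts equal the originals exactly.
    """
    config = config or BootstrapConfig()
    config.validate()
    X_ext, y_ext = np.asarray(X_ext, dtype=float), np.asarray(y_ext)
    classes = np.unique(y_ext)
    if len(classes) < 2:
        raise ValueError("external set must contain both classes")
    pred = np.asarray(model.predict(X_ext))
    scores = decision_scores(model, X_ext)
    rng = np.random.default_rng(config.seed)
    class_idx = [np.flatnonzero(y_ext == c) for c in classes]
    accs, aucs = [], []
    for _ in range(config.B):
        if config.stratified:
            idx = np.concatenate(
                [rng.choice(ci, size=len(ci), replace=True) for ci in class_idx]
            )
        else:
            idx = rng.choice(len(y_ext), size=len(y_ext), replace=True)
        accs.append((pred[idx] == y_ext[idx]).mean())
        if len(np.unique(y_ext[idx])) == 2:
            aucs.append(auc_score(scores[idx], y_ext[idx]))
        else:
            aucs.append(np.nan)
    return {
        "accuracy": EvalResult.from_values("accuracy", accs, config.ci_level),
        "auc": EvalResult.from_values("auc", aucs, config.ci_level),
    }
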