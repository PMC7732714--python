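"""Boosting over heterogeneous weak learners' probability outputs.

The individual classifiers tend to err at opposite extremes on
out-of-context data (sequence models over-call the positive class,
traditional models under-call it), which makes their probability scores
complementary features. Adaptive boosting with decision stumps over the
score columns combines them against a reference labeling; accuracy is
averaged over repeated reshuffled train/test splits, and each learner's
contribution is the normalized impurity importance accumulated on its
column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from opirisk.corpus_io import PredictionRecord


@dataclass
class WeakLearnerMatrix:
    """Rows are posts, columns are weak-learner probability scores."""

    scores: np.ndarray          # (n_rows, n_learners), all in [0, 1]
    learners: list[str]
    labels: np.ndarray          # (n_rows,), binary reference labels

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.learners):
            raise ValueError("scores shape does not match the learner list")
        if self.scores.shape[0] != self.labels.size:
            raise ValueError("label count does not match the score rows")
        if np.isnan(self.scores).any():
            raise ValueError("score matrix contains missing cells")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")

    @classmethod
    def from_predictions(cls, predictions: Mapping[str, Sequence[PredictionRecord]],
                         labels: Sequence[int]) -> "WeakLearnerMatrix":
        learners = list(predictions)
        first = predictions[learners[0]]
        order = {r.id: i for i, r in enumerate(first)}
        scores = np.empty((len(first), len(learners)))
        for j, name in enumerate(learners):
            recs = predictions[name]
            if len(recs) != len(first):
                raise ValueError(f"learner {name!r} has a different row count")
            for r in recs:
                scores[order[r.id], j] = r.score
        return cls(scores=scores, learners=learners,
                   labels=np.asarray(labels, dtype=int))


@dataclass
class EnsembleResult:
    mean_accuracy: float
    per_run_accuracy: list[float]
    contributions: dict[str, float]   # non-negative, sums to 1


def fit_boosted(matrix: WeakLearnerMatrix, runs: int = 5,
                test_fraction: float = 0.2, n_estimators: int = 50,
                seed: int = 0) -> EnsembleResult:
    """Boosted stumps over the weak-learner score columns.

    Each run reshuffles an 8:2 train/test split and refits with a fresh
    random state; the reported accuracy is the mean over runs. Requires at
    least two learners, 50 rows and both label classes.
    """
    if len(matrix.learners) < 2:
        raise ValueError("need at least two weak learners")
    if matrix.scores.shape[0] < 50:
        raise ValueError("need at least 50 labeled rows")
    if np.unique(matrix.labels).size < 2:
        raise ValueError("reference labels are single-class")
    accs: list[float] = []
    importances = np.zeros(len(matrix.learners))
    for run in range(runs):
        rs = seed + run
        X_tr, X_te, y_tr, y_te = train_test_split(
            matrix.scores, matrix.labels, test_size=test_fraction,
            random_state=rs, shuffle=True, stratify=matrix.labels)
        booster = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=n_estimators, random_state=rs)
        booster.fit(X_tr, y_tr)
        accs.append(float(booster.score(X_te, y_te)))
        importances += booster.feature_importances_
    total = importances.sum()
    if total <= 0:
        shares = np.full(len(matrix.learners), 1.0 / len(matrix.learners))
    else:
        shares = importances / total
    return EnsembleResult(
        mean_accuracy=float(np.mean(accs)),
        per_run_accuracy=accs,
        contributions={name: float(s) for name, s in zip(matrix.learners, shares)},
    )


def ratio_ensemble_sweep(predictions: Mapping[str, Sequence[PredictionRecord]],
                         labels: Sequence[int],
                         ratios: Sequence[float] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1)),
                         n_rows: int = 500, runs: int = 5,
                         seed: int = 0) -> dict[float, EnsembleResult]:
    """Boosted-ensemble accuracy as the positive-label prevalence is swept.

    For each ratio the labeled rows are resampled with replacement to the
    requested prevalence (as in the label-ratio curves) and the boosted
    ensemble is refit from scratch.
    """
    base = WeakLearnerMatrix.from_predictions(predictions, labels)
    pos_idx = np.flatnonzero(base.labels == 1)
    neg_idx = np.flatnonzero(base.labels == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("ratio sweep needs both label classes")
    rng = np.random.default_rng(seed)
    out: dict[float, EnsembleResult] = {}
    for r in ratios:
        n_pos = int(round(r * n_rows))
        take = np.concatenate([
            rng.choice(pos_idx, size=n_pos, replace=True),
            rng.choice(neg_idx, size=n_rows - n_pos, replace=True),
        ])
        sub = WeakLearnerMatrix(scores=base.scores[take], learners=base.learners,
                                labels=base.labels[take])
        out[float(r)] = fit_boosted(sub, runs=runs, seed=seed + int(round(r * 10)))
    return out
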