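"""Cross-context transfer protocols and their evaluation machinery.

Two transfer cases are predefined:

* **C1** — train suicidal-vs-control (suicidewatch against the diverse
  control group), then predict suicidality on posts from the opioid
  communities;
* **C2** — train opioid-vs-depressed (opioid communities against the
  depression group), then predict opioid misuse on suicidewatch posts.

Evaluation of the out-of-context predictions uses a keyword-stratified
sample (500 posts of 30–500 words, at most half of them keyword-bearing, so
a rare positive class is not drowned out), majority-rule aggregation of an
odd number of annotator votes, keyword-presence heuristic labels, per-class
stratified accuracies, and label-ratio curves that sweep the positive-class
prevalence of the evaluation set from 10% to 90% by resampling with
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from opirisk.corpus_io import Post, PredictionRecord
from opirisk.preprocessing import clean_text, tokenize, tokenize_post, word_count
from opirisk.classifiers import ModelSpec, SplitSpec, EvalReport, evaluate, split as split_corpus, train as train_model, TrainedModel

#: Evaluation-sample keyword lists for the two cases. "want to do" is kept
#: verbatim from the protocol definition (plausibly intended as "want to od").
C1_KEYWORDS = [
    "commit suicide", "suicide", "suicidality", "suicidal",
    "want to die", "want to do", "want to overdose",
]
C2_KEYWORDS = [
    "benzodiazepines", "benzos", "cocaine", "codeine", "fentanyl", "heroin",
    "hydrocodine", "hydrocodone", "hydromorphone", "hydros", "kratom",
    "methadone", "morphine", "narcotic", "narcotics", "opiates", "opioid",
    "oxycodone", "oxycontin", "oxycottin", "oxycotton", "oxymorphone",
    "suboxone",
]


@dataclass
class CaseConfig:
    """One transfer experiment: which groups train the classifier, which
    group it predicts on, and the keyword list for stratified sampling."""

    name: str
    train_positive_group: str
    train_negative_group: str
    target_group: str
    keywords: list[str]

    @classmethod
    def c1(cls) -> "CaseConfig":
        return cls("C1", train_positive_group="suicidewatch",
                   train_negative_group="control", target_group="opiates",
                   keywords=list(C1_KEYWORDS))

    @classmethod
    def c2(cls) -> "CaseConfig":
        return cls("C2", train_positive_group="opiates",
                   train_negative_group="depression", target_group="suicidewatch",
                   keywords=list(C2_KEYWORDS))


@dataclass
class SampleSpec:
    """Keyword-stratified evaluation sample: ``n`` posts of
    [``min_words``, ``max_words``] length, at most ``keyword_cap`` of them
    containing a keyword."""

    n: int = 500
    keyword_cap: int = 250
    min_words: int = 30
    max_words: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.keyword_cap > self.n:
            raise ValueError("keyword_cap cannot exceed the sample size")
        if self.min_words >= self.max_words:
            raise ValueError("min_words must be below max_words")


def contains_keyword(post: Post, keywords: Sequence[str]) -> bool:
    """True iff any keyword occurs in the cleaned title+body as a contiguous
    token sequence (case-insensitive; token boundaries respected, so
    "suicidality" matches itself but "suicidal thoughts" does not match
    "suicide")."""
    if not keywords:
        return False
    tokens = tokenize_post(post).tokens
    token_set = set(tokens)
    for kw in keywords:
        kw_tokens = tokenize(clean_text(kw))
        if not kw_tokens:
            continue
        if len(kw_tokens) == 1:
            if kw_tokens[0] in token_set:
                return True
            continue
        k = len(kw_tokens)
        if any(tokens[i:i + k] == kw_tokens for i in range(len(tokens) - k + 1)):
            return True
    return False


def keyword_sample(posts: Sequence[Post], spec: SampleSpec,
                   keywords: Sequence[str]) -> list[Post]:
    """Draw the keyword-stratified evaluation sample.

    The pool is first filtered to the word-count window; up to
    ``keyword_cap`` posts are drawn uniformly from the keyword-bearing
    stratum and the remainder uniformly from the rest. Deterministic given
    the seed. Raises when the pool cannot supply ``n`` posts.
    """
    pool = [p for p in posts if spec.min_words <= word_count(p) <= spec.max_words]
    if len(pool) < spec.n:
        raise ValueError(
            f"pool holds {len(pool)} posts in the word window; need {spec.n}")
    rng = np.random.default_rng(spec.seed)
    with_kw = [p for p in pool if contains_keyword(p, keywords)]
    without_kw = [p for p in pool if not contains_keyword(p, keywords)]
    n_kw = min(spec.keyword_cap, len(with_kw))
    n_rest = spec.n - n_kw
    if n_rest > len(without_kw):
        # not enough keyword-free posts: top up from the keyword stratum
        n_kw = spec.n - len(without_kw)
        n_rest = len(without_kw)
    sample = [with_kw[i] for i in rng.choice(len(with_kw), size=n_kw, replace=False)] \
        if n_kw else []
    sample += [without_kw[i]
               for i in rng.choice(len(without_kw), size=n_rest, replace=False)]
    return sample


def majority_label(votes: Sequence[int]) -> int:
    """Strict-majority aggregation of an odd number of binary votes."""
    votes = list(votes)
    if len(votes) % 2 == 0:
        raise ValueError(f"majority rule needs an odd vote count, got {len(votes)}")
    return int(sum(votes) * 2 > len(votes))


def heuristic_labels(posts: Sequence[Post], keywords: Sequence[str]) -> np.ndarray:
    """Keyword-presence labels: 1 iff the post contains any listed keyword."""
    return np.asarray([int(contains_keyword(p, keywords)) for p in posts])


@dataclass
class StratifiedAccuracy:
    """Accuracy overall and within each label stratum, plus the number of
    posts the model called positive (score below 0.5)."""

    all_data: float
    positive_only: float | None
    negative_only: float | None
    predicted_positive_count: int


def stratified_accuracy(records: Sequence[PredictionRecord],
                        labels: Sequence[int]) -> StratifiedAccuracy:
    y = np.asarray(labels)
    pred = np.asarray([r.predicted_class for r in records])
    if y.size != pred.size:
        raise ValueError("records and labels differ in length")
    correct = pred == y
    pos, neg = y == 1, y == 0
    return StratifiedAccuracy(
        all_data=float(correct.mean()),
        positive_only=float(correct[pos].mean()) if pos.any() else None,
        negative_only=float(correct[neg].mean()) if neg.any() else None,
        predicted_positive_count=int((pred == 1).sum()),
    )


def ratio_curve(records: Sequence[PredictionRecord], labels: Sequence[int],
                ratios: Sequence[float] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1)),
                n_rows: int = 500, n_reps: int = 1, seed: int = 0) -> dict[float, float]:
    """Accuracy of fixed predictions on resampled sets of varying prevalence.

    For each ratio ``r``, ``round(r * n_rows)`` posts are drawn with
    replacement from the positive-labeled stratum and the rest from the
    negative stratum; accuracy is averaged over ``n_reps`` draws. In
    expectation the curve is r·a⁺ + (1−r)·a⁻ for class-conditional
    accuracies a⁺, a⁻.
    """
    y = np.asarray(labels)
    correct = np.asarray([r.predicted_class for r in records]) == y
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("ratio curve needs both positive and negative posts")
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for r in ratios:
        n_pos = int(round(r * n_rows))
        accs = []
        for _ in range(n_reps):
            take_pos = rng.choice(pos_idx, size=n_pos, replace=True)
            take_neg = rng.choice(neg_idx, size=n_rows - n_pos, replace=True)
            accs.append(np.concatenate([correct[take_pos], correct[take_neg]]).mean())
        out[float(r)] = float(np.mean(accs))
    return out


@dataclass
class CaseResult:
    """Outcome of one transfer case run."""

    case: CaseConfig
    predictions: dict[str, list[PredictionRecord]]
    in_sample_reports: dict[str, EvalReport]
    models: dict[str, TrainedModel] = field(repr=False, default_factory=dict)
    target_posts: list[Post] = field(repr=False, default_factory=list)


def run_case(case: CaseConfig, posts: Sequence[Post],
             model_specs: Sequence[ModelSpec],
             split_spec: SplitSpec | None = None,
             min_words: int = 30, max_words: int = 500) -> CaseResult:
    """Train each model on the case's source groups and score the target group.

    Target-group posts never enter training or validation. Scoring covers
    every target post inside the word-count window; records follow the
    0-means-positive orientation.
    """
    source = [p for p in posts
              if p.group in (case.train_positive_group, case.train_negative_group)]
    target = [p for p in posts if p.group == case.target_group
              and min_words <= word_count(p) <= max_words]
    if not target:
        raise ValueError(f"no posts in target group {case.target_group!r} "
                         f"within [{min_words}, {max_words}] words")
    docs = [tokenize_post(p) for p in source]
    y = [int(p.group == case.train_positive_group) for p in source]
    tr, y_tr, va, y_va, te, y_te = split_corpus(docs, y, split_spec)
    target_docs = [tokenize_post(p) for p in target]

    predictions: dict[str, list[PredictionRecord]] = {}
    reports: dict[str, EvalReport] = {}
    models: dict[str, TrainedModel] = {}
    for spec in model_specs:
        label = f"{spec.family.value}:{spec.combination.label}"
        model = train_model(spec, tr, y_tr, va, y_va)
        models[label] = model
        reports[label] = evaluate(model, te, y_te)
        predictions[label] = model.predict_records(target_docs)
    return CaseResult(case=case, predictions=predictions,
                      in_sample_reports=reports, models=models,
                      target_posts=list(target))
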