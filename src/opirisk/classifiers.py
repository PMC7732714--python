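"""Seven text-classifier families and the train/validate/test harness.

Families: logistic regression (LR), random forest (RF), support vector
machine (SVM) — fitted on document vectors via scikit-learn — and four
sequence models (FAST, RNN, ATTENTION, CNN) implemented in
:mod:`opirisk.nn`. Every trained model exposes calibrated-orientation
probability scores: 0 means the positive / at-risk class, 1 the negative
class, and the decision threshold is 0.5.

Splits are stratified 8:2 train/test, then 8:2 train/validation inside the
training part (64/16/20 overall). The evaluation report carries accuracy,
precision, recall, F1 (positive class by default) and AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from opirisk.corpus_io import PredictionRecord
from opirisk.features import (
    EMBEDDING_DIM,
    CharEmbeddingTable,
    EmbeddingTable,
    FeatureAssembler,
    FeatureCombination,
    TfidfModel,
    train_word_embeddings,
)
from opirisk.nn import AttentionBiLSTM, FastTextClassifier, LSTMClassifier, TextCNN, TrainConfig
from opirisk.preprocessing import DEFAULT_SEQUENCE_LENGTH, TokenizedDocument, Vocabulary, build_vocabulary, encode_corpus

logger = logging.getLogger(__name__)


class ModelFamily(Enum):
    LR = "LR"
    RF = "RF"
    SVM = "SVM"
    FAST = "FAST"
    RNN = "RNN"
    ATTENTION = "ATTENTION"
    CNN = "CNN"

    @property
    def is_sequence_model(self) -> bool:
        return self in (ModelFamily.FAST, ModelFamily.RNN, ModelFamily.ATTENTION, ModelFamily.CNN)


@dataclass
class CnnHyperparams:
    """Convolutional model defaults: two filter widths (3 and 8, the wider
    one suited to long documents), ReLU activations, max pooling, a learned
    100-dimensional embedding with dropout 0.5, batch size 512, 6 epochs,
    cross-entropy loss."""

    filter_sizes: tuple[int, ...] = (3, 8)
    n_filters: int = 100
    hidden: int = 100
    embedding_dim: int = EMBEDDING_DIM
    embedding_dropout: float = 0.5
    batch_size: int = 512
    epochs: int = 6
    lr: float = 1e-3


@dataclass
class ModelSpec:
    """What to train: a family, an input combination, and hyperparameters."""

    family: ModelFamily
    combination: FeatureCombination = FeatureCombination.W2V
    seed: int = 0
    sequence_length: int = DEFAULT_SEQUENCE_LENGTH
    embedding_dim: int = EMBEDDING_DIM
    cnn: CnnHyperparams = field(default_factory=CnnHyperparams)
    hidden: int = 100          # LSTM / attention hidden size
    epochs: int = 6
    batch_size: int = 512
    lr: float = 1e-3
    w2v_epochs: int = 3
    w2v_window: int = 5
    pretrained_path: str | None = None


@dataclass
class SplitSpec:
    """8:2 train/test then 8:2 train/validation, stratified by label."""

    test_fraction: float = 0.2
    validation_fraction: float = 0.2
    seed: int = 0


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc}


def split(docs: Sequence[TokenizedDocument], labels: Sequence[int],
          spec: SplitSpec | None = None):
    """Stratified 64/16/20 partition of documents and labels.

    Returns ``(train_docs, y_train, val_docs, y_val, test_docs, y_test)``.
    Raises when a label has fewer than 5 items (both ratios cannot hold).
    """
    spec = spec or SplitSpec()
    y = np.asarray(labels)
    values, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        scarce = values[counts.argmin()]
        raise ValueError(f"label {scarce!r} has {counts.min()} items; need at least 5")
    idx = np.arange(len(docs))
    tr_idx, te_idx = train_test_split(
        idx, test_size=spec.test_fraction, stratify=y, random_state=spec.seed)
    tr_idx, va_idx = train_test_split(
        tr_idx, test_size=spec.validation_fraction, stratify=y[tr_idx],
        random_state=spec.seed)
    pick = lambda ix: [docs[i] for i in ix]
    return (pick(tr_idx), y[tr_idx], pick(va_idx), y[va_idx], pick(te_idx), y[te_idx])


class TrainedModel:
    """A fitted classifier bundled with its feature models and vocabulary."""

    def __init__(self, spec: ModelSpec, assembler: FeatureAssembler,
                 vocab: Vocabulary | None, inner):
        self.spec = spec
        self.assembler = assembler
        self.vocab = vocab
        self.inner = inner

    # ---- inputs --------------------------------------------------------
    def _sequence_inputs(self, docs: Sequence[TokenizedDocument]):
        L = self.spec.sequence_length
        enc = encode_corpus(docs, self.vocab, L)
        ids = np.stack([e.indices for e in enc])
        side = self.assembler.side_vectors(docs)
        char = self.assembler.char_sequences(docs, L)
        return ids, char, side

    # ---- scoring -------------------------------------------------------
    def positive_probability(self, docs: Sequence[TokenizedDocument]) -> np.ndarray:
        """P(positive / at-risk class) per document."""
        if self.spec.family.is_sequence_model:
            ids, char, side = self._sequence_inputs(docs)
            return np.asarray(self.inner.predict_proba(ids, char=char, side=side))
        X = self.assembler.document_vectors(docs)
        return self.inner.predict_proba(X)[:, 1]

    def predict_records(self, docs: Sequence[TokenizedDocument],
                        labels: Sequence[int] | None = None) -> list[PredictionRecord]:
        """Oriented prediction records: score = 1 − P(positive), so a score
        near 0 flags the at-risk class."""
        p = self.positive_probability(docs)
        labels = list(labels) if labels is not None else [None] * len(docs)
        return [
            PredictionRecord(id=d.post_id, score=float(np.clip(1.0 - pi, 0.0, 1.0)),
                             true_label=li)
            for d, pi, li in zip(docs, p, labels)
        ]


def _fit_assembler(spec: ModelSpec, train_docs: Sequence[TokenizedDocument],
                   pretrained: EmbeddingTable | None,
                   word_table: EmbeddingTable | None = None) -> FeatureAssembler:
    parts = spec.combination.parts
    tfidf = TfidfModel().fit(train_docs) if "tfidf" in parts else None
    if "w2v" in parts and not spec.family.is_sequence_model:
        # sequence models learn their own embedding layer; traditional models
        # consume a mean-pooled skip-gram table trained on the training split
        # (a shared pre-fitted table may be passed in to avoid refitting)
        if word_table is None:
            word_table = train_word_embeddings(
                train_docs, dim=spec.embedding_dim, window=spec.w2v_window,
                epochs=spec.w2v_epochs, seed=spec.seed)
    elif "w2v" in parts:
        word_table = EmbeddingTable(vectors={}, dim=spec.embedding_dim)  # placeholder
    else:
        word_table = None
    if "glove" in parts and pretrained is None:
        raise ValueError("combination includes pretrained vectors but none were provided")
    char_table = (CharEmbeddingTable.random(dim=spec.embedding_dim, seed=spec.seed)
                  if "char2vec" in parts else None)
    return FeatureAssembler(spec.combination, tfidf=tfidf, word_table=word_table,
                            pretrained_table=pretrained, char_table=char_table)


def train(spec: ModelSpec,
          train_docs: Sequence[TokenizedDocument], y_train: Sequence[int],
          val_docs: Sequence[TokenizedDocument] | None = None,
          y_val: Sequence[int] | None = None,
          pretrained: EmbeddingTable | None = None,
          word_table: EmbeddingTable | None = None) -> TrainedModel:
    """Fit one classifier. Feature models are fitted on the training split
    only; the validation split is used for loss monitoring, never for
    early stopping. A pre-fitted ``word_table`` (trained on the same
    training split) may be shared across specs."""
    y_train = np.asarray(y_train, dtype=np.int64)
    from opirisk.features import load_pretrained

    if pretrained is None and spec.pretrained_path and "glove" in spec.combination.parts:
        pretrained = load_pretrained(spec.pretrained_path, seed=spec.seed)
    assembler = _fit_assembler(spec, train_docs, pretrained, word_table)

    if not spec.family.is_sequence_model:
        X = assembler.document_vectors(train_docs)
        if spec.family is ModelFamily.LR:
            inner = LogisticRegression(C=1.0, max_iter=2000, random_state=spec.seed)
        elif spec.family is ModelFamily.RF:
            inner = RandomForestClassifier(n_estimators=100, random_state=spec.seed)
        else:
            inner = SVC(kernel="rbf", probability=True, random_state=spec.seed)
        inner.fit(X, y_train)
        return TrainedModel(spec, assembler, None, inner)

    vocab = build_vocabulary(train_docs)
    cfg = TrainConfig(batch_size=spec.batch_size, epochs=spec.epochs, lr=spec.lr,
                      seed=spec.seed)
    L = spec.sequence_length
    enc = encode_corpus(train_docs, vocab, L)
    ids = np.stack([e.indices for e in enc])
    side = assembler.side_vectors(train_docs)
    char = assembler.char_sequences(train_docs, L)
    side_dim = side.shape[1] if side is not None else 0
    char_dim = char.shape[2] if char is not None else 0
    V = len(vocab)

    if spec.family is ModelFamily.CNN:
        hp = spec.cnn
        cnn_cfg = TrainConfig(batch_size=hp.batch_size, epochs=hp.epochs, lr=hp.lr,
                              embedding_dropout=hp.embedding_dropout, seed=spec.seed)
        inner = TextCNN(V, embedding_dim=hp.embedding_dim,
                        filter_sizes=hp.filter_sizes, n_filters=hp.n_filters,
                        hidden=hp.hidden, side_dim=side_dim, char_dim=char_dim,
                        config=cnn_cfg)
    elif spec.family is ModelFamily.RNN:
        inner = LSTMClassifier(V, embedding_dim=spec.embedding_dim, hidden=spec.hidden,
                               side_dim=side_dim, char_dim=char_dim, config=cfg)
    elif spec.family is ModelFamily.ATTENTION:
        inner = AttentionBiLSTM(V, embedding_dim=spec.embedding_dim, hidden=spec.hidden,
                                side_dim=side_dim, char_dim=char_dim, config=cfg)
    else:  # FAST
        inner = FastTextClassifier(V, embedding_dim=spec.embedding_dim,
                                   side_dim=side_dim, config=cfg)

    if pretrained is not None and "glove" in spec.combination.parts and "E" in inner.params:
        # initialize the learned embedding from the pretrained table
        for tok, i in vocab.index.items():
            if tok in pretrained:
                inner.params["E"][i] = pretrained.get(tok)[: spec.embedding_dim]

    val = None
    if val_docs:
        v_enc = encode_corpus(val_docs, vocab, L)
        v_ids = np.stack([e.indices for e in v_enc])
        v_char = assembler.char_sequences(val_docs, L)
        v_side = assembler.side_vectors(val_docs)
        val = (v_ids, np.asarray(y_val, dtype=np.int64), v_char, v_side)
    inner.fit(ids, y_train, char=char, side=side, val=val)
    return TrainedModel(spec, assembler, vocab, inner)


def evaluate(model: TrainedModel, docs: Sequence[TokenizedDocument],
             labels: Sequence[int], macro: bool = False) -> EvalReport:
    """Score a trained model on a labeled set.

    Precision/recall/F1 refer to the positive (at-risk) class unless
    ``macro`` is set. AUC is rank-based on the oriented scores and reported
    as missing for a single-class set.
    """
    y = np.asarray(labels)
    p_pos = model.positive_probability(docs)
    y_hat = (p_pos >= 0.5).astype(int)
    avg = "macro" if macro else "binary"
    auc = None
    if len(np.unique(y)) > 1:
        auc = float(roc_auc_score(y, p_pos))
    return EvalReport(
        accuracy=float(accuracy_score(y, y_hat)),
        precision=float(precision_score(y, y_hat, average=avg, zero_division=0)),
        recall=float(recall_score(y, y_hat, average=avg, zero_division=0)),
        f1=float(f1_score(y, y_hat, average=avg, zero_division=0)),
        auc=auc,
    )


def grid_run(docs: Sequence[TokenizedDocument], labels: Sequence[int],
             families: Sequence[ModelFamily],
             combinations: Sequence[FeatureCombination],
             split_spec: SplitSpec | None = None,
             base_spec: ModelSpec | None = None,
             pretrained: EmbeddingTable | None = None) -> pd.DataFrame:
    """One evaluation per (family, combination) pair on a shared split.

    Returns a tidy frame with one row per pair and the five metrics;
    infeasible pairs (for example a pretrained-vector combination without a
    vector table) are skipped with a logged reason. Row order is stable.
    """
    tr, y_tr, va, y_va, te, y_te = split(docs, labels, split_spec)
    word_table = None
    needs_w2v = any("w2v" in c.parts for c in combinations) and any(
        not f.is_sequence_model for f in families)
    if needs_w2v:
        ref = base_spec or ModelSpec(family=families[0])
        word_table = train_word_embeddings(
            tr, dim=ref.embedding_dim, window=ref.w2v_window,
            epochs=ref.w2v_epochs, seed=ref.seed)
    rows = []
    for family in families:
        for comb in combinations:
            if "glove" in comb.parts and pretrained is None and (
                    base_spec is None or base_spec.pretrained_path is None):
                logger.info("skipping %s/%s: no pretrained vectors available",
                            family.value, comb.label)
                continue
            spec = ModelSpec(
                family=family, combination=comb,
                **({k: getattr(base_spec, k) for k in
                    ("seed", "sequence_length", "embedding_dim", "hidden", "epochs",
                     "batch_size", "lr", "w2v_epochs", "w2v_window", "pretrained_path")}
                   if base_spec else {}),
            )
            model = train(spec, tr, y_tr, va, y_va, pretrained=pretrained,
                          word_table=word_table)
            report = evaluate(model, te, y_te)
            rows.append({"family": family.value, "combination": comb.label,
                         **report.as_dict()})
    return pd.DataFrame(rows)
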