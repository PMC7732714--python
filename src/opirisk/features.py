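"""Semantic input representations: TF-IDF, word embeddings, char embeddings.

Documents can be represented by any combination of

* a low-dimensional TF-IDF vector over in-sample unigrams and bigrams
  (default 100 features),
* word embeddings trained on the in-sample corpus (skip-gram with negative
  sampling, implemented here in numpy),
* pretrained word vectors loaded from a word-per-line text file,
* character embeddings: fixed random per-character vectors mean-pooled per
  token, producing token vectors of the same dimension as the word
  embeddings so the two can be concatenated position-wise.

Traditional classifiers consume a single document vector (TF-IDF and/or
mean-pooled embedding sequences concatenated); sequence models consume the
per-position vectors plus the TF-IDF vector as a document-level side input.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from opirisk.preprocessing import TokenizedDocument

TFIDF_DIM = 100
EMBEDDING_DIM = 100


class FeatureCombination(Enum):
    """Named input combinations for the classifier grid."""

    TFIDF = ("tfidf",)
    W2V = ("w2v",)
    TFIDF_W2V = ("tfidf", "w2v")
    TFIDF_GLOVE = ("tfidf", "glove")
    TFIDF_W2V_CHAR2VEC = ("tfidf", "w2v", "char2vec")

    @property
    def parts(self) -> tuple[str, ...]:
        return self.value

    @property
    def label(self) -> str:
        return "+".join(self.parts)


def _ngrams(tokens: Sequence[str]) -> list[str]:
    """Unigrams plus space-joined bigrams of a token list."""
    grams = list(tokens)
    grams.extend(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return grams


class TfidfModel:
    """Top-``dim`` unigram+bigram TF-IDF with smoothed idf and L2 norm.

    Feature selection is by total corpus frequency, ties broken
    lexicographically, so the selected n-gram set is deterministic. Weights
    follow the common smoothed convention idf(t) = ln((1+N)/(1+df(t))) + 1
    with raw term counts and L2-normalized rows.
    """

    def __init__(self, dim: int = TFIDF_DIM):
        self.dim = dim
        self._vectorizer: TfidfVectorizer | None = None
        self.ngrams_: list[str] = []

    def fit(self, docs: Sequence[TokenizedDocument]) -> "TfidfModel":
        if not docs:
            raise ValueError("cannot fit TF-IDF on an empty corpus")
        counts: Counter[str] = Counter()
        for doc in docs:
            counts.update(_ngrams(doc.tokens))
        ranked = sorted(counts, key=lambda g: (-counts[g], g))
        if len(ranked) < self.dim:
            import warnings

            warnings.warn(
                f"only {len(ranked)} n-grams available for {self.dim} TF-IDF features; using all",
                stacklevel=2,
            )
        self.ngrams_ = ranked[: self.dim]
        self._vectorizer = TfidfVectorizer(
            analyzer=_ngrams,
            vocabulary={g: i for i, g in enumerate(self.ngrams_)},
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        self._vectorizer.fit([d.tokens for d in docs])
        return self

    def transform(self, docs: Sequence[TokenizedDocument]) -> np.ndarray:
        if self._vectorizer is None:
            raise RuntimeError("TfidfModel is not fitted")
        return self._vectorizer.transform([d.tokens for d in docs]).toarray()

    @property
    def idf_(self) -> np.ndarray:
        if self._vectorizer is None:
            raise RuntimeError("TfidfModel is not fitted")
        return self._vectorizer.idf_

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"dim": self.dim, "ngrams": self.ngrams_,
                       "idf": self.idf_.tolist()}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TfidfModel":
        with open(path, encoding="utf-8") as fh:
            blob = json.load(fh)
        model = cls(dim=blob["dim"])
        model.ngrams_ = list(blob["ngrams"])
        model._vectorizer = TfidfVectorizer(
            analyzer=_ngrams,
            vocabulary={g: i for i, g in enumerate(model.ngrams_)},
            norm="l2", smooth_idf=True, sublinear_tf=False,
        )
        # restore fitted idf state without refitting
        model._vectorizer.idf_ = np.asarray(blob["idf"], dtype=np.float64)
        return model


@dataclass
class EmbeddingTable:
    """token -> d-dimensional vector, trained in-pipeline or loaded pretrained.

    Tokens absent from the table map to a single fixed random vector drawn
    once from the table's seed (``oov_vector``).
    """

    vectors: dict[str, np.ndarray]
    dim: int
    pretrained: bool = False
    oov_vector: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.oov_vector is None:
            self.oov_vector = np.zeros(self.dim, dtype=np.float32)
        for tok, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has shape {v.shape}, expected ({self.dim},)")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def get(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self.oov_vector)

    def mean_pool(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros(self.dim, dtype=np.float32)
        return np.mean([self.get(t) for t in tokens], axis=0)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok, vec in self.vectors.items():
                fh.write(tok + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def load_pretrained(path: str | Path, seed: int = 0) -> EmbeddingTable:
    """Load a word-per-line embedding file (token followed by floats).

    Raises on inconsistent dimensions (naming the line) and on duplicate
    tokens. The OOV vector is drawn from ``seed``.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} has no vector components")
            tok, comps = parts[0], parts[1:]
            vec = np.asarray([float(x) for x in comps], dtype=np.float32)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"{path}: line {lineno} has dimension {vec.size}, expected {dim}")
            if tok in vectors:
                raise ValueError(f"{path}: duplicate token {tok!r} on line {lineno}")
            vectors[tok] = vec
    if dim is None:
        raise ValueError(f"{path}: empty embedding file")
    rng = np.random.default_rng(seed)
    oov = rng.standard_normal(dim).astype(np.float32) * 0.1
    return EmbeddingTable(vectors=vectors, dim=dim, pretrained=True, oov_vector=oov)


def train_word_embeddings(
    docs: Sequence[TokenizedDocument],
    dim: int = EMBEDDING_DIM,
    window: int = 5,
    epochs: int = 3,
    seed: int = 0,
    min_count: int = 1,
    negatives: int = 5,
    lr: float = 0.05,
    max_pairs_per_epoch: int = 2_000_000,
) -> EmbeddingTable:
    """Skip-gram word embeddings with negative sampling, trained in numpy.

    For every (center, context) pair within ``window`` the input vector of the
    center token is pushed toward the output vector of the context token and
    away from ``negatives`` tokens sampled from the unigram^0.75 distribution.
    Gradients are accumulated densely per minibatch and applied with Adam,
    which keeps the summed same-token updates of a vectorized batch stable.
    On corpora with more than ``max_pairs_per_epoch`` co-occurrence pairs a
    uniform subsample is drawn each epoch. Deterministic given the seed
    (single-threaded). Raises when the corpus is smaller than the window.
    """
    counts: Counter[str] = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    vocab = [t for t, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
             if c >= min_count]
    if not vocab:
        raise ValueError("no tokens meet min_count; cannot train embeddings")
    total_tokens = sum(counts[t] for t in vocab)
    if total_tokens <= window:
        raise ValueError(f"corpus has {total_tokens} tokens, smaller than window {window}")
    tok2id = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim), dtype=np.float32) - 0.5) / dim
    W_out = np.zeros((V, dim), dtype=np.float32)

    # unigram^0.75 negative-sampling distribution
    freqs = np.asarray([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    neg_p = freqs / freqs.sum()

    encoded = [np.asarray([tok2id[t] for t in d.tokens if t in tok2id], dtype=np.int64)
               for d in docs]

    centers_all: list[np.ndarray] = []
    contexts_all: list[np.ndarray] = []
    for ids in encoded:
        n = ids.size
        if n < 2:
            continue
        for off in range(1, window + 1):
            if n <= off:
                break
            centers_all.append(ids[:-off])
            contexts_all.append(ids[off:])
    if not centers_all:
        raise ValueError("no co-occurrence pairs; corpus too small for the window")
    # symmetric pairs: each (i, j) also trains (j, i)
    centers = np.concatenate(centers_all + contexts_all)
    contexts = np.concatenate(contexts_all + centers_all)

    n_pairs = centers.size
    batch = 4096
    # Adam state for the two tables
    m_in = np.zeros_like(W_in); v_in = np.zeros_like(W_in)
    m_out = np.zeros_like(W_out); v_out = np.zeros_like(W_out)
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    neg_cdf = np.cumsum(neg_p)
    for _ in range(epochs):
        if n_pairs > max_pairs_per_epoch:
            order = rng.choice(n_pairs, size=max_pairs_per_epoch, replace=False)
        else:
            order = rng.permutation(n_pairs)
        for start in range(0, order.size, batch):
            idx = order[start:start + batch]
            c, o = centers[idx], contexts[idx]
            B = c.size
            neg = np.searchsorted(neg_cdf, rng.random((B, negatives)))
            v_c = W_in[c]                      # (B, d)
            u_pos = W_out[o]                   # (B, d)
            u_neg = W_out[neg]                 # (B, k, d)

            s_pos = 1.0 / (1.0 + np.exp(-np.clip(
                np.einsum("bd,bd->b", v_c, u_pos), -30, 30)))
            s_neg = 1.0 / (1.0 + np.exp(-np.clip(
                np.einsum("bd,bkd->bk", v_c, u_neg), -30, 30)))

            g_pos = ((s_pos - 1.0) / B).astype(np.float32)   # (B,)
            g_neg = (s_neg / B).astype(np.float32)           # (B, k)

            dW_in = np.zeros_like(W_in)
            dW_out = np.zeros_like(W_out)
            grad_c = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(dW_in, c, grad_c)
            np.add.at(dW_out, o, g_pos[:, None] * v_c)
            np.add.at(dW_out, neg.ravel(),
                      (g_neg[:, :, None] * v_c[:, None, :]).reshape(-1, dim))

            t += 1
            corr = np.float32(np.sqrt(1 - b2 ** t) / (1 - b1 ** t))
            for W, m, v, g in ((W_in, m_in, v_in, dW_in), (W_out, m_out, v_out, dW_out)):
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                W -= lr * corr * m / (np.sqrt(v) + eps)

    return EmbeddingTable(
        vectors={t: W_in[i].copy() for t, i in tok2id.items()},
        dim=dim, pretrained=False,
        oov_vector=np.zeros(dim, dtype=np.float32),
    )


@dataclass
class CharEmbeddingTable:
    """Fixed random per-character vectors, mean-pooled into token vectors.

    The token-level output dimension equals the word-embedding dimension so
    character and word representations can be concatenated per position.
    Characters outside the table contribute nothing (zero vector).
    """

    vectors: dict[str, np.ndarray]
    dim: int

    @classmethod
    def random(cls, dim: int = EMBEDDING_DIM, seed: int = 0,
               alphabet: str | None = None) -> "CharEmbeddingTable":
        if alphabet is None:
            alphabet = "abcdefghijklmnopqrstuvwxyz0123456789.,!?'"
        rng = np.random.default_rng(seed)
        return cls(
            vectors={c: rng.standard_normal(dim).astype(np.float32) * 0.1
                     for c in alphabet},
            dim=dim,
        )

    def token_vector(self, token: str) -> np.ndarray:
        vecs = [self.vectors[c] for c in token if c in self.vectors]
        if not vecs:
            return np.zeros(self.dim, dtype=np.float32)
        return np.mean(vecs, axis=0)


def char_embed(doc: TokenizedDocument, table: CharEmbeddingTable) -> np.ndarray:
    """Per-token character-derived vectors for one document, shape (n, d)."""
    if not doc.tokens:
        return np.zeros((0, table.dim), dtype=np.float32)
    return np.stack([table.token_vector(t) for t in doc.tokens]).astype(np.float32)


@dataclass
class FeatureBundle:
    """Assembled inputs for one document.

    ``document_vector`` feeds traditional classifiers; ``side_vector`` (the
    TF-IDF component, if requested) and per-position character vectors feed
    the sequence models, whose word-level sequence input is the integer
    encoding itself.
    """

    post_id: str
    document_vector: np.ndarray | None = None
    side_vector: np.ndarray | None = None
    char_sequence: np.ndarray | None = None


class FeatureAssembler:
    """Bind fitted feature models and produce combination-specific inputs."""

    def __init__(
        self,
        combination: FeatureCombination,
        tfidf: TfidfModel | None = None,
        word_table: EmbeddingTable | None = None,
        pretrained_table: EmbeddingTable | None = None,
        char_table: CharEmbeddingTable | None = None,
    ):
        self.combination = combination
        self.tfidf = tfidf
        self.word_table = word_table
        self.pretrained_table = pretrained_table
        self.char_table = char_table
        for part, model in (("tfidf", tfidf), ("w2v", word_table),
                            ("glove", pretrained_table), ("char2vec", char_table)):
            if part in combination.parts and model is None:
                raise ValueError(f"combination {combination.label} requires a {part} model")

    def document_vectors(self, docs: Sequence[TokenizedDocument]) -> np.ndarray:
        """Concatenated per-document vectors for traditional classifiers.

        Embedding sequences enter mean-pooled, so this representation is
        order-invariant by construction.
        """
        blocks: list[np.ndarray] = []
        if "tfidf" in self.combination.parts:
            blocks.append(self.tfidf.transform(docs))
        if "w2v" in self.combination.parts:
            blocks.append(np.stack([self.word_table.mean_pool(d.tokens) for d in docs]))
        if "glove" in self.combination.parts:
            blocks.append(np.stack([self.pretrained_table.mean_pool(d.tokens) for d in docs]))
        if "char2vec" in self.combination.parts:
            blocks.append(np.stack([
                char_embed(d, self.char_table).mean(axis=0)
                if d.tokens else np.zeros(self.char_table.dim, dtype=np.float32)
                for d in docs
            ]))
        return np.concatenate(blocks, axis=1).astype(np.float32)

    def side_vectors(self, docs: Sequence[TokenizedDocument]) -> np.ndarray | None:
        """Document-level side input for sequence models (TF-IDF, if present)."""
        if "tfidf" in self.combination.parts:
            return self.tfidf.transform(docs).astype(np.float32)
        return None

    def char_sequences(self, docs: Sequence[TokenizedDocument],
                       length: int) -> np.ndarray | None:
        """Padded (n_docs, length, d) char-derived sequences, if requested."""
        if "char2vec" not in self.combination.parts:
            return None
        out = np.zeros((len(docs), length, self.char_table.dim), dtype=np.float32)
        for i, d in enumerate(docs):
            seq = char_embed(d, self.char_table)[:length]
            out[i, : seq.shape[0]] = seq
        return out
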