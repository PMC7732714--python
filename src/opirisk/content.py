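"""Content overview of predicted-positive posts via phrase embeddings.

To assess what a classifier's positive predictions talk about, a bigram
phrase detector merges strongly collocated token pairs (scored by
(count(ab) − δ)·N / (count(a)·count(b)) against a threshold, δ = min_count),
a skip-gram embedding is trained on the merged token streams, and the
nearest neighbours of a seed word (default "suicidal") are reported by
cosine similarity.
"""

from __future__ import annotations

import difflib
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from opirisk.features import EmbeddingTable, train_word_embeddings
from opirisk.preprocessing import TokenizedDocument


@dataclass
class PhraseModel:
    """Scored bigram collocations; merged phrases join with an underscore."""

    min_count: int
    threshold: float
    phrases: dict[tuple[str, str], float] = field(default_factory=dict)

    def apply(self, doc: TokenizedDocument) -> TokenizedDocument:
        """Greedy left-to-right merge of detected bigrams."""
        tokens = doc.tokens
        out: list[str] = []
        i = 0
        while i < len(tokens):
            if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) in self.phrases:
                out.append(f"{tokens[i]}_{tokens[i + 1]}")
                i += 2
            else:
                out.append(tokens[i])
                i += 1
        return TokenizedDocument(post_id=doc.post_id, tokens=out, group=doc.group)


def detect_phrases(docs: Sequence[TokenizedDocument], min_count: int = 5,
                   threshold: float = 10.0) -> PhraseModel:
    """Score adjacent token pairs and keep those above the threshold.

    score(a, b) = (count(ab) − min_count) · N / (count(a) · count(b)), where
    N is the total token count; never-adjacent or rare pairs score ≤ 0 and
    are never merged. Raises on an empty corpus.
    """
    if not docs or all(not d.tokens for d in docs):
        raise ValueError("cannot detect phrases on an empty corpus")
    unigrams: Counter[str] = Counter()
    bigrams: Counter[tuple[str, str]] = Counter()
    for doc in docs:
        unigrams.update(doc.tokens)
        bigrams.update(zip(doc.tokens, doc.tokens[1:]))
    total = sum(unigrams.values())
    model = PhraseModel(min_count=min_count, threshold=threshold)
    if not np.isfinite(threshold):
        return model
    for (a, b), n_ab in bigrams.items():
        score = (n_ab - min_count) * total / (unigrams[a] * unigrams[b])
        if score >= threshold:
            model.phrases[(a, b)] = score
    return model


def phrase_embedding(docs: Sequence[TokenizedDocument], phrase_model: PhraseModel,
                     dim: int = 100, window: int = 5, epochs: int = 3,
                     seed: int = 0, min_count: int = 1) -> EmbeddingTable:
    """Skip-gram embedding over the phrase-merged token streams."""
    merged = [phrase_model.apply(d) for d in docs]
    return train_word_embeddings(merged, dim=dim, window=window, epochs=epochs,
                                 seed=seed, min_count=min_count)


def top_similar(table: EmbeddingTable, query: str = "suicidal",
                k: int = 15) -> list[tuple[str, float]]:
    """The ``k`` vocabulary tokens most cosine-similar to the query.

    The query itself is excluded; ties break lexicographically. An
    out-of-vocabulary query raises, suggesting close orthographic matches.
    """
    if query not in table:
        close = difflib.get_close_matches(query, list(table.vectors), n=3)
        hint = f"; close matches: {', '.join(close)}" if close else ""
        raise KeyError(f"query {query!r} not in the embedding vocabulary{hint}")
    tokens = sorted(t for t in table.vectors if t != query)
    if not tokens:
        return []
    M = np.stack([table.vectors[t] for t in tokens]).astype(np.float64)
    q = table.vectors[query].astype(np.float64)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(M, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where((norms > 0) & (qn > 0), M @ q / (norms * qn), 0.0)
    # sort by descending similarity; the token list is pre-sorted, and a
    # stable sort keeps lexicographic order within ties
    order = np.argsort(-sims, kind="stable")[:k]
    return [(tokens[i], float(sims[i])) for i in order]
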