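"""Text normalization, tokenization and fixed-length integer encoding.

The normalization is deliberately light: the high-level structure of the
language is preserved — no lemmatization, no stop-word or profanity removal.
Only lowercasing, URL removal and punctuation pruning are applied: every
punctuation mark is dropped except periods, commas, exclamation marks,
question marks and apostrophes; the retained marks become standalone tokens,
while apostrophes inside words (contractions) stay attached.  The title of a
post is prepended to the body, and encoded documents are zero padded or
truncated to a fixed length (default 1500 words).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from opirisk.corpus_io import Post

#: Punctuation kept during cleaning; everything else is stripped.
RETAINED_PUNCT = ".,!?'"

DEFAULT_SEQUENCE_LENGTH = 1500

_URL_RE = re.compile(r"(?:[a-z][a-z0-9+.-]*://|www\.)\S+")
# Curly quotes normalize to the ASCII apostrophe before any other handling.
_APOSTROPHE_VARIANTS = str.maketrans({"’": "'", "‘": "'", "ʼ": "'"})


def clean_text(raw: str) -> str:
    """Lowercase, strip URLs, prune punctuation and space out retained marks.

    The five retained marks (``. , ! ?`` and standalone apostrophes) end up
    surrounded by single spaces; apostrophes flanked by word characters stay
    inside the word (``what's`` survives intact). Idempotent.
    """
    text = raw.translate(_APOSTROPHE_VARIANTS).lower()
    text = _URL_RE.sub(" ", text)
    out: list[str] = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch.isalnum() or ch.isspace():
            out.append(ch)
        elif ch == "'":
            prev_w = i > 0 and text[i - 1].isalnum()
            next_w = i + 1 < n and text[i + 1].isalnum()
            if prev_w and next_w:
                out.append(ch)  # contraction: keep attached
            else:
                out.append(f" {ch} ")
        elif ch in RETAINED_PUNCT:
            out.append(f" {ch} ")
        else:
            out.append(" ")
    return " ".join("".join(out).split())


def tokenize(cleaned: str) -> list[str]:
    """Whitespace-split already-cleaned text into tokens."""
    return cleaned.split()


def join_title_body(post: Post) -> str:
    """Title, one separating space, then body; either part may be empty."""
    if post.title and post.body:
        return f"{post.title} {post.body}"
    return post.title or post.body


def word_count(post: Post) -> int:
    """Whitespace words in the raw title+body, excluding punctuation-only runs.

    Used by the 30–500-word evaluation-sample filter; counts raw words, not
    post-tokenization tokens (so ``out...`` is one word).
    """
    return sum(1 for w in join_title_body(post).split() if any(c.isalnum() for c in w))


@dataclass
class TokenizedDocument:
    post_id: str
    tokens: list[str]
    group: str = "unassigned"


def tokenize_post(post: Post) -> TokenizedDocument:
    return TokenizedDocument(
        post_id=post.id,
        tokens=tokenize(clean_text(join_title_body(post))),
        group=post.group,
    )


PAD_INDEX = 0
OOV_INDEX = 1


@dataclass
class Vocabulary:
    """Token -> contiguous integer index; 0 is padding, 1 is out-of-vocabulary.

    Real tokens are indexed from 2 in order of descending corpus frequency,
    ties broken lexicographically, which makes the mapping deterministic.
    """

    index: dict[str, int]
    frequency: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index) + 2

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, OOV_INDEX)

    def tokens(self) -> list[str]:
        """Real tokens ordered by index."""
        return sorted(self.index, key=self.index.__getitem__)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok in self.tokens():
                fh.write(f"{tok}\t{self.index[tok]}\t{self.frequency.get(tok, 0)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        index: dict[str, int] = {}
        freq: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                tok, idx, count = line.rstrip("\n").split("\t")
                index[tok] = int(idx)
                freq[tok] = int(count)
        return cls(index=index, frequency=freq)


def build_vocabulary(docs: Sequence[TokenizedDocument], min_count: int = 1) -> Vocabulary:
    """Frequency-ordered vocabulary over a tokenized corpus.

    Tokens with corpus frequency below ``min_count`` map to the OOV index.
    Raises on an empty corpus.
    """
    if not docs:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = [t for t, c in counts.items() if c >= min_count]
    kept.sort(key=lambda t: (-counts[t], t))
    return Vocabulary(
        index={t: i + 2 for i, t in enumerate(kept)},
        frequency={t: counts[t] for t in kept},
    )


@dataclass
class EncodedDocument:
    post_id: str
    indices: np.ndarray  # shape (L,), int32
    group: str = "unassigned"


def encode(doc: TokenizedDocument, vocab: Vocabulary,
           length: int = DEFAULT_SEQUENCE_LENGTH) -> EncodedDocument:
    """Map the first ``length`` tokens to indices, right-padding with zeros."""
    vec = np.zeros(length, dtype=np.int32)
    for i, tok in enumerate(doc.tokens[:length]):
        vec[i] = vocab[tok]
    return EncodedDocument(post_id=doc.post_id, indices=vec, group=doc.group)


def encode_corpus(docs: Iterable[TokenizedDocument], vocab: Vocabulary,
                  length: int = DEFAULT_SEQUENCE_LENGTH) -> list[EncodedDocument]:
    return [encode(d, vocab, length) for d in docs]
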