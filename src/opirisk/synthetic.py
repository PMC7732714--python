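"""Synthetic Reddit-like corpora with known latent risk flags.

The generator emulates four community groups — suicidewatch, depression,
control and an opioid-related cluster — using a group-conditioned topic
mixture with unigram-plus-keyphrase emission. Every post carries latent
ground truth (is the author's language suicidal? does it signal opioid
misuse?) assigned *before* the community, so intersection posts exist in both
directions: opioid-community posts with suicidal content and suicidewatch
posts with opioid content, at configurable rates. Qualitative features of the
real data the generator reproduces:

* lexical separability between groups, tunable via a single scalar;
* elevated first-person-singular pronoun use in suicidal/depressed posts;
* mixed emotional registers (anger / negative / joy) inside the opioid group,
  where active users, relapse and recovery posts share one label;
* multi-word risk keyphrases ("want to die", drug names) at a configurable
  inclusion rate, so keyword-stratified sampling is exercisable;
* post lengths spanning roughly 5–1500 words.

A simulated annotator pool (default 3 independent annotators with
configurable sensitivity/specificity) stands in for crowdsourced labeling,
and majority-rule aggregation downstream consumes its votes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from opirisk.corpus_io import DEFAULT_GROUP_MAP, Post

# ---------------------------------------------------------------------------
# default lexicons (topic -> word list); disjoint across content topics

SUICIDAL_LEXICON = [
    "suicide", "suicidal", "suicidality", "die", "dying", "death", "overdose",
    "od", "end", "ending", "goodbye", "hopeless", "worthless", "burden",
    "failure", "pain", "courage", "attempt", "pills", "jump", "cutting",
    "self-harm", "note", "final", "ready", "tired", "exhausted", "empty",
    "alone", "isolated", "trapped", "escape", "relief", "peace", "gone",
]

OPIOID_LEXICON = [
    "heroin", "fentanyl", "oxycodone", "oxycontin", "hydrocodone", "hydros",
    "morphine", "methadone", "suboxone", "kratom", "codeine", "benzos",
    "benzodiazepines", "narcotics", "opiates", "opioid", "dope", "dose",
    "tolerance", "high", "nod", "shot", "snort", "plug", "stamp", "bag",
    "gram", "script", "pharmacy", "dealer", "cop", "paws", "oxymorphone",
    "hydromorphone", "narcotic", "cocaine",
]

WITHDRAWAL_LEXICON = [
    "withdrawal", "withdrawals", "relapse", "relapsed", "clean", "sober",
    "sobriety", "detox", "tapering", "taper", "cravings", "craving", "sick",
    "sweats", "shakes", "restless", "insomnia", "nauseous", "vomiting",
    "aching", "kicking", "cold-turkey", "recovery", "rehab", "meetings",
]

CONTROL_LEXICON = [
    "book", "reading", "recipe", "workout", "running", "budget", "savings",
    "career", "interview", "resume", "garden", "travel", "movie", "guitar",
    "painting", "coffee", "hiking", "coding", "science", "history", "puppy",
    "wedding", "apartment", "cooking", "baking", "photography", "chess",
    "league", "season", "playlist", "keyboard", "camera", "marathon",
    "homework", "lecture", "project", "promotion", "vacation", "barbecue",
]

NEGATIVE_AFFECT_LEXICON = [
    "sad", "depressed", "depressing", "crying", "miserable", "anxious",
    "anxiety", "panic", "numb", "angry", "furious", "hate", "hatred",
    "fuck", "fucking", "shit", "damn", "screwed", "awful", "terrible",
    "lonely", "broken", "useless", "guilt", "shame", "regret", "stress",
]

POSITIVE_LEXICON = [
    "happy", "happiness", "grateful", "proud", "hope", "hopeful", "progress",
    "milestone", "celebrating", "better", "improving", "thankful", "glad",
    "excited", "strong", "winning", "smiling",
]

FUNCTION_WORDS = [
    "the", "a", "an", "and", "but", "or", "so", "to", "of", "in", "on",
    "at", "for", "with", "about", "from", "that", "this", "it", "is",
    "was", "are", "be", "been", "have", "has", "had", "do", "does", "did",
    "not", "no", "yes", "just", "really", "very", "then", "when", "because",
    "if", "what", "how", "we", "you", "they", "he", "she", "them", "their",
]

FIRST_PERSON_SINGULAR = ["i", "i'm", "i've", "me", "my", "myself"]

DEFAULT_LEXICONS: dict[str, list[str]] = {
    "suicidal": SUICIDAL_LEXICON,
    "opioid": OPIOID_LEXICON,
    "withdrawal": WITHDRAWAL_LEXICON,
    "control": CONTROL_LEXICON,
    "negative": NEGATIVE_AFFECT_LEXICON,
    "positive": POSITIVE_LEXICON,
}

#: Multi-word keyphrases injected into latently flagged posts at the
#: configured inclusion rate (single-word keywords already live in the
#: lexicons, so only the phrases need explicit injection).
SUICIDAL_KEYPHRASES = ["commit suicide", "want to die", "want to overdose"]
OPIOID_KEYPHRASES = list(OPIOID_LEXICON[:16])


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``separability`` is the probability that a content word is drawn from the
    post's own topic mixture rather than from the pooled cross-topic lexicon;
    at 1.0 with disjoint lexicons the groups are lexically separable and the
    Bayes error of group classification approaches zero.
    """

    seed: int = 0
    n_posts_per_group: dict[str, int] = field(default_factory=lambda: {
        "suicidewatch": 500, "depression": 500, "control": 500, "opiates": 500})
    length_distribution: tuple[int, int, float, float] = (5, 1500, 120.0, 1.0)
    lexicons: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LEXICONS.items()})
    intersection_rate_opiates: float = 0.15
    intersection_rate_sw: float = 0.2
    separability: float = 0.8
    pronoun_shift: float = 0.1
    keyword_inclusion_rate: float = 0.5
    contamination: float = 0.0           # suicidal posts misfiled in control
    function_word_rate: float = 0.45

    def __post_init__(self) -> None:
        for name in ("intersection_rate_opiates", "intersection_rate_sw",
                     "pronoun_shift", "keyword_inclusion_rate", "contamination"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.separability <= 1.0):
            raise ValueError(f"separability={self.separability} outside (0, 1]")
        mn, mx, mean, disp = self.length_distribution
        if mn < 1 or mn >= mx:
            raise ValueError(f"bad length bounds ({mn}, {mx})")
        for topic, words in self.lexicons.items():
            if not words:
                raise ValueError(f"lexicon {topic!r} is empty")


@dataclass
class LatentTruth:
    """Ground truth for one generated post; assigned before the community."""

    post_id: str
    is_suicidal: bool
    is_opioid: bool


@dataclass
class AnnotatorConfig:
    """Independent Bernoulli annotators with shared error rates."""

    n_annotators: int = 3
    sensitivity: float = 0.8
    specificity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")
        if self.n_annotators < 1:
            raise ValueError("need at least one annotator")


_TIME_WINDOW = (1496275200, 1530403200)  # one year of epoch seconds


def _post_topics(group: str, is_suicidal: bool, is_opioid: bool,
                 register: str) -> dict[str, float]:
    """Topic mixture over content lexicons for one post."""
    if group == "control":
        mix = {"control": 0.9, "positive": 0.1}
    elif group == "depression":
        mix = {"negative": 0.9, "positive": 0.1}
    elif group == "suicidewatch":
        mix = {"suicidal": 0.0, "negative": 0.4}  # suicidal share added below
    else:  # opiates: register varies post to post (anger/negative/joy)
        mix = {"opioid": 0.45, "withdrawal": 0.25, register: 0.3}
    if is_suicidal:
        mix["suicidal"] = mix.get("suicidal", 0.0) + 0.45
    if is_opioid:
        mix["opioid"] = mix.get("opioid", 0.0) + 0.3
        mix["withdrawal"] = mix.get("withdrawal", 0.0) + 0.15
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def _draw_words(rng: np.random.Generator, n: int, mix: dict[str, float],
                lexicons: dict[str, list[str]], pooled: list[str],
                separability: float, function_word_rate: float,
                fps_rate: float) -> list[str]:
    topics = list(mix)
    probs = np.asarray([mix[t] for t in topics])
    words: list[str] = []
    for _ in range(n):
        u = rng.random()
        if u < fps_rate:
            words.append(FIRST_PERSON_SINGULAR[rng.integers(len(FIRST_PERSON_SINGULAR))])
        elif u < fps_rate + function_word_rate:
            words.append(FUNCTION_WORDS[rng.integers(len(FUNCTION_WORDS))])
        elif rng.random() < separability:
            topic = topics[rng.choice(len(topics), p=probs)]
            lex = lexicons[topic]
            words.append(lex[rng.integers(len(lex))])
        else:
            words.append(pooled[rng.integers(len(pooled))])
    return words


def generate_corpus(config: GeneratorConfig) -> tuple[list[Post], list[LatentTruth]]:
    """Draw a corpus of posts plus their latent truth, deterministically.

    Latent flags are sampled first (their distribution depends on the group
    and the configured intersection rates), then the topic mixture, the body,
    a short title from the same mixture, and finally the community the post
    is filed under — uniform within its group.
    """
    rng = np.random.default_rng(config.seed)
    mn, mx, mean, disp = config.length_distribution
    pooled = sorted({w for words in config.lexicons.values() for w in words})
    posts: list[Post] = []
    truths: list[LatentTruth] = []
    counter = 0
    registers = ["negative", "negative", "positive"]
    for group in ("suicidewatch", "depression", "control", "opiates"):
        n_posts = config.n_posts_per_group.get(group, 0)
        communities = DEFAULT_GROUP_MAP[group]
        for _ in range(n_posts):
            pid = f"p{counter:06d}"
            counter += 1
            if group == "suicidewatch":
                is_suicidal = True
                is_opioid = bool(rng.random() < config.intersection_rate_sw)
            elif group == "opiates":
                is_opioid = True
                is_suicidal = bool(rng.random() < config.intersection_rate_opiates)
            elif group == "control":
                is_suicidal = bool(rng.random() < config.contamination)
                is_opioid = False
            else:
                is_suicidal = False
                is_opioid = False

            register = registers[rng.integers(len(registers))]
            mix = _post_topics(group, is_suicidal, is_opioid, register)
            # gamma-poisson length with overdispersion, clipped to bounds
            lam = rng.gamma(shape=1.0 / max(disp, 1e-6), scale=mean * max(disp, 1e-6))
            n_words = int(np.clip(rng.poisson(lam), mn, mx))

            fps = 0.08 + (config.pronoun_shift
                          if (is_suicidal or group in ("suicidewatch", "depression"))
                          else 0.0)
            body_words = _draw_words(rng, n_words, mix, config.lexicons, pooled,
                                     config.separability, config.function_word_rate, fps)
            # flagged posts always carry at least one on-topic word, and
            # multi-word keyphrases at the configured inclusion rate; a
            # phrase occupies a single unit so sentence breaks cannot split it
            if is_suicidal:
                lex = config.lexicons["suicidal"]
                body_words.insert(int(rng.integers(len(body_words) + 1)),
                                  lex[rng.integers(len(lex))])
                if rng.random() < config.keyword_inclusion_rate:
                    phrase = SUICIDAL_KEYPHRASES[rng.integers(len(SUICIDAL_KEYPHRASES))]
                    body_words.insert(int(rng.integers(len(body_words) + 1)), phrase)
            if is_opioid:
                lex = config.lexicons["opioid"]
                body_words.insert(int(rng.integers(len(body_words) + 1)),
                                  lex[rng.integers(len(lex))])
                if rng.random() < config.keyword_inclusion_rate:
                    phrase = OPIOID_KEYPHRASES[rng.integers(len(OPIOID_KEYPHRASES))]
                    body_words.insert(int(rng.integers(len(body_words) + 1)), phrase)

            title_words = _draw_words(rng, int(rng.integers(4, 11)), mix,
                                      config.lexicons, pooled, config.separability,
                                      config.function_word_rate, fps)
            sentences: list[str] = []
            i = 0
            while i < len(body_words):
                step = int(rng.integers(6, 15))
                sentences.append(" ".join(body_words[i:i + step]) + ".")
                i += step
            posts.append(Post(
                id=pid,
                community=communities[rng.integers(len(communities))],
                author=f"u{rng.integers(10_000):05d}",
                title=" ".join(title_words),
                body=" ".join(sentences),
                created=int(rng.integers(*_TIME_WINDOW)),
                group=group,
            ))
            truths.append(LatentTruth(post_id=pid, is_suicidal=is_suicidal,
                                      is_opioid=is_opioid))
    return posts, truths


def simulate_annotations(posts: Sequence[Post], truth: Sequence[LatentTruth],
                         config: AnnotatorConfig,
                         question: str = "suicide_risk") -> np.ndarray:
    """Per-post binary votes from independent noisy annotators.

    Each vote is a Bernoulli draw with success probability ``sensitivity``
    when the relevant latent flag is true and ``1 - specificity`` when false.
    Returns an (n_posts, n_annotators) 0/1 array aligned with ``posts``.
    """
    if question not in ("suicide_risk", "opioid_addiction"):
        raise ValueError(f"unknown question {question!r}")
    by_id = {t.post_id: t for t in truth}
    missing = [p.id for p in posts if p.id not in by_id]
    if missing:
        raise ValueError(f"truth missing for posts: {missing[:5]}")
    flag = np.asarray([
        (by_id[p.id].is_suicidal if question == "suicide_risk"
         else by_id[p.id].is_opioid)
        for p in posts
    ])
    rng = np.random.default_rng(config.seed)
    p_yes = np.where(flag, config.sensitivity, 1.0 - config.specificity)
    return (rng.random((len(posts), config.n_annotators)) < p_yes[:, None]).astype(int)


def corpus_report(posts: Sequence[Post], truth: Sequence[LatentTruth],
                  annotations: np.ndarray | None = None,
                  keywords: Sequence[str] | None = None) -> dict:
    """Summary of a generated corpus: group counts, word-count quantiles,
    latent-flag rates, keyword prevalence, and pairwise annotator agreement
    when votes are supplied."""
    from opirisk.preprocessing import word_count
    from opirisk.transfer import contains_keyword

    by_id = {t.post_id: t for t in truth}
    counts: dict[str, int] = {}
    for p in posts:
        counts[p.group] = counts.get(p.group, 0) + 1
    wc = np.asarray([word_count(p) for p in posts])
    report: dict = {
        "n_posts": len(posts),
        "group_counts": counts,
        "word_count_quantiles": {
            q: float(np.quantile(wc, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        } if len(posts) else {},
        "suicidal_rate": float(np.mean([by_id[p.id].is_suicidal for p in posts]))
        if posts else 0.0,
        "opioid_rate": float(np.mean([by_id[p.id].is_opioid for p in posts]))
        if posts else 0.0,
    }
    if keywords is not None:
        report["keyword_prevalence"] = float(
            np.mean([contains_keyword(p, keywords) for p in posts])) if posts else 0.0
    if annotations is not None and annotations.size:
        n_ann = annotations.shape[1]
        report["pairwise_agreement"] = {
            f"{a + 1}-{b + 1}": float(np.mean(annotations[:, a] == annotations[:, b]))
            for a in range(n_ann) for b in range(a + 1, n_ann)
        }
    return report


# ---------------------------------------------------------------------------
# sidecar files

def write_truth(truths: Sequence[LatentTruth], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in truths:
            fh.write(json.dumps({"post_id": t.post_id, "is_suicidal": t.is_suicidal,
                                 "is_opioid": t.is_opioid}) + "\n")


def read_truth(path: str | Path) -> list[LatentTruth]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(LatentTruth(post_id=rec["post_id"],
                                       is_suicidal=bool(rec["is_suicidal"]),
                                       is_opioid=bool(rec["is_opioid"])))
    return out


def write_annotations(posts: Sequence[Post], votes: np.ndarray,
                      path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id"] + [f"vote{i + 1}" for i in range(votes.shape[1])])
        for p, row in zip(posts, votes):
            writer.writerow([p.id] + [int(v) for v in row])


def read_annotations(path: str | Path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[list[int]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            ids.append(rec["post_id"])
            rows.append([int(v) for k, v in rec.items() if k.startswith("vote")])
    return ids, np.asarray(rows, dtype=int)
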