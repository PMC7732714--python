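"""Reading and writing post collections and derived artifacts.

Corpora live on disk as JSON Lines, one post per line; predictions are CSV.
Each post belongs to exactly one of four experiment groups — ``suicidewatch``,
``depression``, ``control`` and ``opiates`` — resolved from its community name
through a many-to-one group map. Communities absent from the map are kept and
flagged ``unassigned`` rather than dropped, so the map stays configuration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

GROUPS = ("control", "suicidewatch", "depression", "opiates")
UNASSIGNED = "unassigned"

#: Default community -> group mapping. The control list is deliberately broad:
#: it models healthy, non-disordered language across diverse topics.
DEFAULT_GROUP_MAP: dict[str, tuple[str, ...]] = {
    "suicidewatch": ("suicidewatch",),
    "depression": ("depression",),
    "control": (
        "askdocs", "askscience", "books", "careerguidance", "fitness",
        "frugal", "jokes", "lifeprotips", "offmychest", "parenting",
        "personalfinance", "productivity", "randomkindess", "relationships",
        "showerthoughts", "talesfromretail", "theoryofreddit",
        "wholesometextposts", "writing", "youshouldknow",
    ),
    "opiates": (
        "benzodiazepines", "benzorecovery", "heroin", "methadone",
        "opiates", "opiatesrecovery", "quittingkratom", "suboxone",
    ),
}


@dataclass
class Post:
    """One social-media submission.

    ``title`` and ``body`` may each be empty but not both. ``group`` is the
    resolved experiment group, or ``"unassigned"`` when the community is not
    in the group map.
    """

    id: str
    community: str
    title: str
    body: str
    author: str = ""
    created: int = 0
    group: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not self.title and not self.body:
            raise ValueError(f"post {self.id!r}: title and body both empty")


@dataclass
class GroupAssignment:
    """Many-to-one mapping from community names to the four experiment groups."""

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {g: tuple(cs) for g, cs in DEFAULT_GROUP_MAP.items()}
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, communities in self.groups.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
            for c in communities:
                c = c.lower()
                if c in seen and seen[c] != group:
                    raise ValueError(f"community {c!r} mapped to both {seen[c]!r} and {group!r}")
                seen[c] = group
        self._lookup = seen

    def group_of(self, community: str) -> str:
        return self._lookup.get(community.lower(), UNASSIGNED)


def read_corpus(path: str | Path, group_map: GroupAssignment | None = None) -> list[Post]:
    """Read a JSON Lines corpus, resolving each post's group from its community.

    Raises ``ValueError`` naming the line number for malformed lines, and on
    duplicate ids. Posts from unmapped communities are returned with
    ``group == "unassigned"``, never dropped.
    """
    group_map = group_map or GroupAssignment()
    posts: list[Post] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                post = Post(
                    id=str(rec["id"]),
                    community=str(rec["community"]),
                    title=str(rec.get("title", "")),
                    body=str(rec.get("body", "")),
                    author=str(rec.get("author", "")),
                    created=int(rec.get("created", 0)),
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: invalid post on line {lineno}: {exc}") from exc
            if post.id in seen_ids:
                raise ValueError(f"{path}: duplicate post id {post.id!r} on line {lineno}")
            seen_ids.add(post.id)
            post.group = group_map.group_of(post.community)
            posts.append(post)
    return posts


def write_corpus(posts: Iterable[Post], path: str | Path) -> None:
    """Write posts as JSON Lines (group labels are derived, not stored)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps({
                "id": p.id,
                "community": p.community,
                "author": p.author,
                "title": p.title,
                "body": p.body,
                "created": p.created,
            }, ensure_ascii=False) + "\n")


@dataclass
class PredictionRecord:
    """Per-post probability score.

    Orientation convention: a score near 0 means the *positive / at-risk*
    class, a score near 1 means the negative class. ``predicted_class`` is 1
    (positive) when ``score < 0.5``.
    """

    id: str
    score: float
    true_label: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"record {self.id!r}: score {self.score} outside [0, 1]")

    @property
    def predicted_class(self) -> int:
        return 1 if self.score < 0.5 else 0


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write prediction records as CSV; scores round-trip at 6 decimals."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "score", "predicted_class", "true_label"])
        for r in records:
            writer.writerow([
                r.id,
                f"{r.score:.6f}",
                r.predicted_class,
                "" if r.true_label is None else r.true_label,
            ])


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(PredictionRecord(
                id=row["id"],
                score=float(row["score"]),
                true_label=int(row["true_label"]) if row.get("true_label") else None,
            ))
    return records
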