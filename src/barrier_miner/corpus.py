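"""Reading, validating, filtering and writing forum-post corpora.

The on-disk format is JSON Lines (UTF-8, one object per line) with the fields
``post_id``, ``subreddit``, ``created``, ``kind``, ``parent_id`` and ``text``.
Raw text is preserved byte-for-byte at this layer; all normalization happens
downstream so that original quotes can always be reported alongside matches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

KINDS = ("submission", "comment")


class CorpusError(ValueError):
    """Raised on malformed corpus records in strict mode."""


@dataclass(frozen=True)
class Post:
    """One social-media record (submission or comment).

    ``created`` is a timezone-aware UTC timestamp. ``parent_id`` is present
    exactly when ``kind == "comment"``. For submissions the title and body are
    already concatenated into ``text`` (single newline separator) upstream.
    """

    post_id: str
    subreddit: str
    created: datetime
    kind: str
    text: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise CorpusError(f"unknown kind {self.kind!r} for post {self.post_id!r}")
        if (self.kind == "comment") != (self.parent_id is not None):
            raise CorpusError(
                f"post {self.post_id!r}: parent_id must be present iff kind=comment"
            )
        if self.created.tzinfo is None:
            raise CorpusError(f"post {self.post_id!r}: created must be timezone-aware")


@dataclass(frozen=True)
class CorpusFilter:
    """Subreddit / date-window predicate. Empty subreddit set means "all"."""

    subreddits: frozenset[str] = frozenset()
    date_start: datetime | None = None
    date_end: datetime | None = None

    def __post_init__(self) -> None:
        if (
            self.date_start is not None
            and self.date_end is not None
            and self.date_start > self.date_end
        ):
            raise ValueError("date_start must not exceed date_end")

    def accepts(self, post: Post) -> bool:
        if self.subreddits and post.subreddit not in self.subreddits:
            return False
        if self.date_start is not None and post.created < self.date_start:
            return False
        if self.date_end is not None and post.created > self.date_end:
            return False
        return True


def parse_timestamp(value: object) -> datetime:
    """Parse an ISO-8601 string or epoch-seconds number into aware UTC."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return datetime.fromtimestamp(value, tz=timezone.utc)
    if isinstance(value, str):
        try:
            return datetime.fromtimestamp(float(value), tz=timezone.utc)
        except ValueError:
            pass
        dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        return dt.astimezone(timezone.utc)
    raise CorpusError(f"unparseable timestamp: {value!r}")


def _post_from_record(rec: dict) -> Post:
    missing = {"post_id", "subreddit", "created", "kind", "text"} - rec.keys()
    if missing:
        raise CorpusError(f"missing fields: {sorted(missing)}")
    if not isinstance(rec["text"], str):
        raise CorpusError("text must be a string")
    return Post(
        post_id=str(rec["post_id"]),
        subreddit=str(rec["subreddit"]),
        created=parse_timestamp(rec["created"]),
        kind=str(rec["kind"]),
        parent_id=rec.get("parent_id"),
        text=rec["text"],
    )


def read_posts(path: str | Path, strict: bool = False) -> list[Post]:
    """Read a JSONL corpus.

    In strict mode the first malformed line or duplicate ``post_id`` aborts
    with :class:`CorpusError`; in lenient mode malformed lines are skipped
    (logged with a final skip count) and only the first record of a duplicate
    id is kept.
    """
    path = Path(path)
    posts: list[Post] = []
    seen: set[str] = set()
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                if not isinstance(rec, dict):
                    raise CorpusError("line is not a JSON object")
                post = _post_from_record(rec)
                if post.post_id in seen:
                    raise CorpusError(f"duplicate post_id {post.post_id!r}")
            except (json.JSONDecodeError, CorpusError) as exc:
                if strict:
                    raise CorpusError(f"{path}:{lineno}: {exc}") from exc
                logger.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
                skipped += 1
                continue
            seen.add(post.post_id)
            posts.append(post)
    if skipped:
        logger.warning("%s: skipped %d malformed record(s)", path, skipped)
    return posts


def filter_corpus(posts: Sequence[Post], f: CorpusFilter) -> list[Post]:
    """Return the subsequence of ``posts`` accepted by the filter."""
    return [p for p in posts if f.accepts(p)]


def write_posts(posts: Iterable[Post], path: str | Path) -> None:
    """Write posts as JSONL; ``read_posts`` round-trips every field."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in posts:
            rec = {
                "post_id": p.post_id,
                "subreddit": p.subreddit,
                "created": p.created.astimezone(timezone.utc).isoformat(),
                "kind": p.kind,
                "parent_id": p.parent_id,
                "text": p.text,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
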