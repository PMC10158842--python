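"""Character-level fuzzy retrieval of lexicon phrases from token streams.

For each search expression of *w* words, every contiguous *w*-token window of
a post is joined with single spaces and compared to the expression surface
with the Levenshtein ratio

    ratio(a, b) = (|a| + |b| - d(a, b)) / (|a| + |b|)

where ``d`` is the Levenshtein distance with unit-cost insertions/deletions
and substitutions costed at 2 (so the ratio equals 2·LCS/(|a|+|b|)). Windows
whose ratio is STRICTLY greater than the threshold (default 0.9) are matches.
With these conventions a single substitution in an expression of character
length L yields ratio 1 - 1/L (passes 0.9 only for L >= 11), a single
insertion 2L/(2L+1) (L >= 5) and a single deletion (2L-2)/(2L-1) (L >= 6).

Substitution cost 1 is exposed as a configuration alternative because the
choice flips threshold outcomes (one substitution in a 9-letter word scores
0.889 at cost 2 but 0.944 at cost 1).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .normalize import NormalizedPost, normalize_text, tokenize

THEMES = ("insurance", "stigma", "logistics", "facility_location", "other")

_ALTERNATION_RE = re.compile(r"\[([^\[\]]+)\]")


# ---------------------------------------------------------------------------
# distance / ratio primitives
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str, substitution_cost: int = 2) -> int:
    """Levenshtein distance with unit indels and the given substitution cost.

    Symmetric; zero iff ``a == b``. With ``substitution_cost=2`` a
    substitution is never cheaper than a delete+insert pair, so the distance
    reduces to ``|a| + |b| - 2·LCS(a, b)``.
    """
    if substitution_cost not in (1, 2):
        raise ValueError("substitution_cost must be 1 or 2")
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (0 if ca == cb else substitution_cost),
                )
            )
        prev = cur
    return prev[-1]


def _bounded_distance(a: str, b: str, limit: int, substitution_cost: int = 2) -> int | None:
    """Banded distance: exact value if <= limit, else None.

    Any alignment leaving the |i-j| <= limit band costs more than ``limit``
    (each off-diagonal step costs at least 1), so the band is sufficient.
    """
    la, lb = len(a), len(b)
    if abs(la - lb) > limit:
        return None
    INF = limit + 1
    prev = [j if j <= limit else INF for j in range(lb + 1)]
    for i in range(1, la + 1):
        lo = max(1, i - limit)
        hi = min(lb, i + limit)
        cur = [INF] * (lb + 1)
        if lo == 1:
            cur[0] = i if i <= limit else INF
        ca = a[i - 1]
        for j in range(lo, hi + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (0 if ca == b[j - 1] else substitution_cost),
            )
        prev = cur
    return prev[lb] if prev[lb] <= limit else None


def levenshtein_ratio(a: str, b: str, substitution_cost: int = 2) -> float:
    """Normalized similarity in [0, 1]; 1.0 iff identical (and for "" vs "")."""
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return (total - edit_distance(a, b, substitution_cost)) / total


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

class LexiconError(ValueError):
    """Raised on invalid lexicon contents or refinement operations."""


def expand_alternations(surface: str) -> list[str]:
    """Expand one optional-infix bracket: "drug [ab]user" -> both variants."""
    m = _ALTERNATION_RE.search(surface)
    if m is None:
        return [surface]
    with_infix = surface[: m.start()] + m.group(1) + surface[m.end():]
    without = surface[: m.start()] + surface[m.end():]
    return [without, with_infix]


@dataclass(frozen=True)
class SearchExpression:
    """A normalized lexicon phrase tagged with its barrier theme."""

    surface: str
    theme: str

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise LexiconError(f"unknown theme {self.theme!r}")
        if self.surface != normalize_text(self.surface) or not self.surface:
            raise LexiconError(f"surface {self.surface!r} is not normalized")

    @property
    def word_count(self) -> int:
        return len(self.surface.split())


@dataclass(frozen=True)
class ChangelogEntry:
    version: int
    added: tuple[str, ...]
    removed: tuple[str, ...]
    note: str


@dataclass(frozen=True)
class Lexicon:
    """Versioned set of search expressions with an append-only changelog."""

    expressions: tuple[SearchExpression, ...]
    version: int = 1
    changelog: tuple[ChangelogEntry, ...] = ()

    def __post_init__(self) -> None:
        surfaces = [e.surface for e in self.expressions]
        if len(surfaces) != len(set(surfaces)):
            raise LexiconError("duplicate surfaces in lexicon")

    def surfaces(self) -> set[str]:
        return {e.surface for e in self.expressions}

    def theme_of(self, surface: str) -> str:
        for e in self.expressions:
            if e.surface == surface:
                return e.theme
        raise KeyError(surface)

    def surfaces_at_version(self, version: int) -> set[str]:
        """Replay the changelog to reconstruct an earlier version's members."""
        if not 1 <= version <= self.version:
            raise LexiconError(f"no such version: {version}")
        members: set[str] = set()
        for entry in self.changelog:
            if entry.version > version:
                break
            members |= {v for s in entry.added for v in expand_alternations(s)}
            members -= {v for s in entry.removed for v in expand_alternations(s)}
        return members


def refine_lexicon(
    lex: Lexicon,
    add: Iterable[tuple[str, str]] = (),
    remove: Iterable[str] = (),
    note: str = "",
) -> Lexicon:
    """Return a new lexicon version with ``add`` (surface, theme) pairs added
    and ``remove`` surfaces dropped; prior versions stay reconstructable.

    Adding a present surface or removing an absent one is an error — the
    review loop should know what the current lexicon contains.
    """
    add = list(add)
    remove = list(remove)
    current = {e.surface: e for e in lex.expressions}
    removed_variants: list[str] = []
    for surface in remove:
        variants = [normalize_text(v) for v in expand_alternations(surface)]
        for v in variants:
            if v not in current:
                raise LexiconError(f"cannot remove absent phrase {v!r}")
            del current[v]
        removed_variants.append(surface)
    for surface, theme in add:
        for v in expand_alternations(surface):
            v = normalize_text(v)
            if v in current:
                raise LexiconError(f"phrase {v!r} already present")
            current[v] = SearchExpression(surface=v, theme=theme)
    entry = ChangelogEntry(
        version=lex.version + 1,
        added=tuple(s for s, _ in add),
        removed=tuple(removed_variants),
        note=note,
    )
    return Lexicon(
        expressions=tuple(current.values()),
        version=lex.version + 1,
        changelog=lex.changelog + (entry,),
    )


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a YAML lexicon, expanding bracket alternations and normalizing."""
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    expressions: list[SearchExpression] = []
    for item in doc.get("expressions", []):
        theme = item["theme"]
        for variant in expand_alternations(str(item["surface"])):
            expressions.append(
                SearchExpression(surface=normalize_text(variant), theme=theme)
            )
    changelog = tuple(
        ChangelogEntry(
            version=int(e["version"]),
            added=tuple(e.get("added", ())),
            removed=tuple(e.get("removed", ())),
            note=str(e.get("note", "")),
        )
        for e in doc.get("changelog", [])
    )
    return Lexicon(
        expressions=tuple(expressions),
        version=int(doc.get("version", 1)),
        changelog=changelog,
    )


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    doc = {
        "version": lex.version,
        "expressions": [
            {"surface": e.surface, "theme": e.theme} for e in lex.expressions
        ],
        "changelog": [
            {
                "version": e.version,
                "added": list(e.added),
                "removed": list(e.removed),
                "note": e.note,
            }
            for e in lex.changelog
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatcherConfig:
    """Threshold is compared strictly (ratio > threshold); ties excluded."""

    threshold: float = 0.9
    substitution_cost: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.substitution_cost not in (1, 2):
            raise ValueError("substitution_cost must be 1 or 2")


@dataclass(frozen=True)
class MatchRecord:
    """One above-threshold window hit for one expression in one post."""

    post_id: str
    expression_surface: str
    token_span: tuple[int, int]
    window_text: str
    ratio: float


def find_matches(
    np_: NormalizedPost,
    expression: SearchExpression,
    cfg: MatcherConfig = MatcherConfig(),
    window_counter: list[int] | None = None,
) -> list[MatchRecord]:
    """Slide a window of ``expression.word_count`` tokens across the post and
    return every window whose ratio strictly exceeds the threshold, in
    left-to-right order.

    ``window_counter``, when given, accumulates the number of windows
    evaluated (max(0, n_tokens - word_count + 1)).
    """
    tokens = np_.tokens
    w = expression.word_count
    n = len(tokens)
    n_windows = max(0, n - w + 1)
    if window_counter is not None:
        window_counter.append(n_windows)
    if n_windows == 0:
        return []
    la = len(expression.surface)
    thr = cfg.threshold
    # cumulative token lengths -> O(1) joined-window length
    cum = [0]
    for t in tokens:
        cum.append(cum[-1] + len(t))
    out: list[MatchRecord] = []
    for i in range(n_windows):
        lb = (cum[i + w] - cum[i]) + (w - 1)
        total = la + lb
        # d >= |la - lb| always, so prune on lengths alone
        if total == 0:
            if thr < 1.0:
                out.append(MatchRecord(np_.post_id, expression.surface, (i, i + w), "", 1.0))
            continue
        if (total - abs(la - lb)) / total <= thr:
            continue
        limit = int((1.0 - thr) * total) + 1
        window = " ".join(tokens[i : i + w])
        d = _bounded_distance(window, expression.surface, limit, cfg.substitution_cost)
        if d is None:
            continue
        ratio = (total - d) / total
        if ratio > thr:
            out.append(
                MatchRecord(np_.post_id, expression.surface, (i, i + w), window, ratio)
            )
    return out


def scan_corpus(
    posts: Sequence[NormalizedPost],
    lexicon: Lexicon,
    cfg: MatcherConfig = MatcherConfig(),
) -> tuple[list[MatchRecord], set[str]]:
    """Match every lexicon expression against every post.

    Returns all match records (post order, then lexicon order) and the set of
    retrieved post ids (posts with at least one match, counted once however
    many windows hit).
    """
    matches: list[MatchRecord] = []
    retrieved: set[str] = set()
    for np_ in posts:
        for expression in lexicon.expressions:
            hits = find_matches(np_, expression, cfg)
            if hits:
                matches.extend(hits)
                retrieved.add(np_.post_id)
    return matches, retrieved


def sample_for_review(
    matches: Sequence[MatchRecord], k: int, seed: int
) -> list[MatchRecord]:
    """Uniform sample without replacement of min(k, n) records; seeded."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = random.Random(seed)
    n = len(matches)
    if k >= n:
        return list(matches)
    return rng.sample(list(matches), k)
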