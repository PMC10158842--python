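"""Seeded generator of forum-like corpora with planted barrier phrases,
controlled misspellings, off-topic distractors, and gold labels.

Posts are short first-person template sentences; each barrier post embeds one
planted lexicon expression per gold subcategory (two or more, from distinct
subcategories, for the ``multiple`` bucket). Distractor posts are
rejection-sampled so they contain nothing within fuzzy-match range of any
lexicon expression. Typos touch only the planted expression, never template
text, so the closed-form Levenshtein-ratio bounds apply exactly to each
corrupted plant. Edits never delete or substitute whitespace (that would
merge words and change the sliding-window width the plant occupies);
insertions may fall anywhere.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus import Post
from .match import Lexicon, MatcherConfig, scan_corpus
from .normalize import normalize_post
from .taxonomy import (
    MULTIPLE,
    CategoryScheme,
    DEFAULT_RULEBOOK,
    DEFAULT_SCHEME,
)

DISTRACTOR = "distractor"
SUBREDDITS = ("suboxone", "Methadone", "naltrexone")
_ALPHABET = string.ascii_lowercase
_EPOCH_START = datetime(2014, 1, 1, tzinfo=timezone.utc).timestamp()
_EPOCH_END = datetime(2021, 8, 31, tzinfo=timezone.utc).timestamp()

#: Default bucket mixture: half the corpus is off-topic noise, the barrier
#: half split across the buckets reachable under the default rulebook in
#: proportion to their observed frequencies (68:40:4:14).
DEFAULT_MIXTURE: dict[str, float] = {
    "general_insurance_difficulty": 0.5 * 68 / 126,
    "stigma": 0.5 * 40 / 126,
    "provider_issues": 0.5 * 4 / 126,
    f"{MULTIPLE}_non_insurance": 0.5 * 14 / 126,
    DISTRACTOR: 0.5,
}


class GenerationError(ValueError):
    """Raised for unsatisfiable buckets or invalid generator specs."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_posts: int
    mixture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    typo_rate: float = 0.2
    max_edits_per_expression: int = 1
    seed: int = 0
    edit_ops: tuple[str, ...] = ("insert", "delete", "substitute")

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise GenerationError("n_posts must be positive")
        if not 0.0 <= self.typo_rate <= 1.0:
            raise GenerationError("typo_rate must be in [0, 1]")
        props = list(self.mixture.values())
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise GenerationError("mixture proportions must be >= 0 and sum to 1")
        if not set(self.edit_ops) <= {"insert", "delete", "substitute"}:
            raise GenerationError(f"unknown edit ops: {self.edit_ops}")


@dataclass(frozen=True)
class PlantedExpression:
    surface: str        # uncorrupted lexicon surface
    corrupted: str      # string actually embedded in the post
    n_edits: int
    start: int          # char span of `corrupted` in the raw post text
    end: int


@dataclass(frozen=True)
class GoldRecord:
    post_id: str
    bucket: str                      # counting bucket, or "distractor"
    codes: tuple[str, ...]           # gold subcategory codes (empty: distractor)
    planted: tuple[PlantedExpression, ...]


def load_templates(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load sentence templates (packaged default when no path given)."""
    if path is None:
        ref = resources.files("barrier_miner.data") / "templates.yaml"
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with Path(path).open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return {"barrier": list(doc["barrier"]), "distractor": list(doc["distractor"])}


def inject_typos(
    text: str,
    n_edits: int,
    rng: np.random.Generator,
    ops: Sequence[str] = ("insert", "delete", "substitute"),
) -> str:
    """Apply exactly ``n_edits`` character edits (uniform op and position,
    lowercase-letter alphabet). Whitespace characters are never deleted or
    substituted. The unit-cost edit distance to the original is <= n_edits.
    """
    if n_edits > len(text):
        raise GenerationError("n_edits exceeds text length")
    chars = list(text)
    for _ in range(n_edits):
        op = ops[int(rng.integers(len(ops)))]
        if op == "insert":
            pos = int(rng.integers(len(chars) + 1))
            chars.insert(pos, _ALPHABET[int(rng.integers(26))])
        else:
            positions = [i for i, c in enumerate(chars) if not c.isspace()]
            if not positions:
                continue
            pos = positions[int(rng.integers(len(positions)))]
            if op == "delete":
                del chars[pos]
            else:
                old = chars[pos]
                repl = _ALPHABET[int(rng.integers(26))]
                while repl == old:
                    repl = _ALPHABET[int(rng.integers(26))]
                chars[pos] = repl
    return "".join(chars)


def _bucket_expressions(
    lexicon: Lexicon, rulebook: Mapping[str, str | None]
) -> dict[str, list[str]]:
    """Map each reachable subcategory to the lexicon surfaces suggesting it."""
    out: dict[str, list[str]] = {}
    for e in lexicon.expressions:
        code = rulebook.get(e.theme)
        if code is not None:
            out.setdefault(code, []).append(e.surface)
    return out


def _parse_bucket(bucket: str, scheme: CategoryScheme) -> tuple[str | None, str | None]:
    """Split a mixture bucket key into (subcategory, major-for-multiple)."""
    if bucket == DISTRACTOR:
        return None, None
    if bucket.startswith(MULTIPLE):
        major = bucket[len(MULTIPLE) + 1 :] or "non_insurance"
        if major not in ("insurance", "non_insurance"):
            raise GenerationError(f"bad multiple bucket {bucket!r}")
        return None, major
    scheme.major_of(bucket)  # validates
    return bucket, None


def _random_created(rng: np.random.Generator) -> datetime:
    ts = float(rng.uniform(_EPOCH_START, _EPOCH_END))
    return datetime.fromtimestamp(int(ts), tz=timezone.utc)


def generate_post(
    bucket: str,
    lexicon: Lexicon,
    templates: Mapping[str, list[str]],
    rng: np.random.Generator,
    *,
    post_id: str = "syn000000",
    scheme: CategoryScheme = DEFAULT_SCHEME,
    rulebook: Mapping[str, str | None] = DEFAULT_RULEBOOK,
    cfg: MatcherConfig = MatcherConfig(),
    typo_rate: float = 0.0,
    max_edits: int = 1,
    edit_ops: Sequence[str] = ("insert", "delete", "substitute"),
    max_attempts: int = 100,
) -> tuple[Post, GoldRecord]:
    """Generate one post for the given counting bucket (or distractor).

    Barrier posts embed one planted expression per gold subcategory (for the
    ``multiple`` buckets, two distinct subcategories). The uncorrupted text is
    rejection-checked against the full lexicon so that no match falls outside
    the planted spans; distractor posts must produce zero matches.
    """
    reachable = _bucket_expressions(lexicon, rulebook)
    subcat, multi_major = _parse_bucket(bucket, scheme)

    if subcat is not None:
        if subcat not in reachable:
            raise GenerationError(f"no lexicon expression maps to bucket {subcat!r}")
        gold_codes = [subcat]
    elif multi_major is not None:
        candidates = [
            c for c in scheme.subcategories(multi_major) if c in reachable
        ]
        if len(candidates) < 2:
            raise GenerationError(
                f"need >= 2 reachable {multi_major} subcategories for {bucket!r}"
            )
        idx = rng.permutation(len(candidates))[:2]
        gold_codes = [candidates[int(i)] for i in sorted(idx)]
    else:
        gold_codes = []

    barrier_templates = templates["barrier"]
    distractor_templates = templates["distractor"]

    for _ in range(max_attempts):
        planted: list[PlantedExpression] = []
        sentences: list[str] = []
        offset = 0
        if gold_codes:
            for code in gold_codes:
                surfaces = reachable[code]
                surface = surfaces[int(rng.integers(len(surfaces)))]
                corrupted = surface
                n_edits = 0
                if typo_rate > 0 and max_edits >= 1 and rng.random() < typo_rate:
                    n_edits = int(rng.integers(1, max_edits + 1))
                    corrupted = inject_typos(surface, n_edits, rng, edit_ops)
                template = barrier_templates[int(rng.integers(len(barrier_templates)))]
                head, _, tail = template.partition("{expr}")
                start = offset + len(head)
                sentence = head + corrupted + tail
                planted.append(
                    PlantedExpression(surface, corrupted, n_edits, start, start + len(corrupted))
                )
                sentences.append(sentence)
                offset += len(sentence) + 1  # joining space
        else:
            k = 1 + int(rng.integers(2))
            idx = rng.permutation(len(distractor_templates))[:k]
            sentences = [distractor_templates[int(i)] for i in idx]

        text = " ".join(sentences)
        kind = "comment" if rng.random() < 0.4 else "submission"
        post = Post(
            post_id=post_id,
            subreddit=SUBREDDITS[int(rng.integers(len(SUBREDDITS)))],
            created=_random_created(rng),
            kind=kind,
            parent_id=f"t3_{post_id}" if kind == "comment" else None,
            text=text,
        )
        if _accept(post, planted, gold_codes, lexicon, cfg):
            gold = GoldRecord(
                post_id=post_id,
                bucket=bucket,
                codes=tuple(gold_codes),
                planted=tuple(planted),
            )
            return post, gold
    raise GenerationError(f"could not generate acceptable post for bucket {bucket!r}")


def _accept(
    post: Post,
    planted: Sequence[PlantedExpression],
    gold_codes: Sequence[str],
    lexicon: Lexicon,
    cfg: MatcherConfig,
) -> bool:
    """Reject posts whose template text creates stray lexicon matches."""
    # check the uncorrupted variant so corrupted plants cannot mask overlaps
    clean_text = post.text
    for p in sorted(planted, key=lambda p: p.start, reverse=True):
        clean_text = clean_text[: p.start] + p.surface + clean_text[p.end :]
    probe = Post(
        post_id=post.post_id,
        subreddit=post.subreddit,
        created=post.created,
        kind=post.kind,
        parent_id=post.parent_id,
        text=clean_text,
    )
    np_ = normalize_post(probe)
    matches, _ = scan_corpus([np_], lexicon, cfg)
    if not gold_codes:
        return not matches
    # every match window must overlap a planted span (shifted spans in clean text)
    spans: list[tuple[int, int]] = []
    shift = 0
    for p in sorted(planted, key=lambda p: p.start):
        spans.append((p.start + shift, p.start + shift + len(p.surface)))
        shift += len(p.surface) - len(p.corrupted)
    for m in matches:
        ws = np_.token_offsets[m.token_span[0]][0]
        we = np_.token_offsets[m.token_span[1] - 1][1]
        if not any(ws < e and s < we for s, e in spans):
            return False
    return True


def generate_corpus(
    spec: SyntheticSpec,
    lexicon: Lexicon,
    templates: Mapping[str, list[str]] | None = None,
    *,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    rulebook: Mapping[str, str | None] = DEFAULT_RULEBOOK,
    cfg: MatcherConfig = MatcherConfig(),
) -> tuple[list[Post], list[GoldRecord]]:
    """Generate a corpus under the given spec; fully reproducible from seed.

    Bucket assignment is multinomial over ``spec.mixture``; each planted
    expression is independently corrupted with probability ``typo_rate`` by
    1..max_edits edits.
    """
    if templates is None:
        templates = load_templates()
    rng = np.random.default_rng(spec.seed)
    buckets = list(spec.mixture.keys())
    probs = np.array([spec.mixture[b] for b in buckets], dtype=float)
    probs = probs / probs.sum()
    assignment = rng.choice(len(buckets), size=spec.n_posts, p=probs)
    posts: list[Post] = []
    golds: list[GoldRecord] = []
    for i, bi in enumerate(assignment):
        post, gold = generate_post(
            buckets[int(bi)],
            lexicon,
            templates,
            rng,
            post_id=f"syn{i:06d}",
            scheme=scheme,
            rulebook=rulebook,
            cfg=cfg,
            typo_rate=spec.typo_rate,
            max_edits=spec.max_edits_per_expression,
            edit_ops=spec.edit_ops,
        )
        posts.append(post)
        golds.append(gold)
    return posts, golds


# ---------------------------------------------------------------------------
# gold I/O and evaluation
# ---------------------------------------------------------------------------

def write_gold(golds: Sequence[GoldRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id", "bucket", "codes", "planted"])
        for g in golds:
            planted = ";".join(
                f"{p.surface}|{p.corrupted}|{p.n_edits}|{p.start}|{p.end}"
                for p in g.planted
            )
            writer.writerow([g.post_id, g.bucket, ";".join(g.codes), planted])


def read_gold(path: str | Path) -> list[GoldRecord]:
    golds: list[GoldRecord] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            planted = tuple(
                PlantedExpression(s, c, int(n), int(a), int(b))
                for item in row["planted"].split(";")
                if item
                for s, c, n, a, b in [item.split("|")]
            )
            codes = tuple(c for c in row["codes"].split(";") if c)
            golds.append(GoldRecord(row["post_id"], row["bucket"], codes, planted))
    return golds


@dataclass(frozen=True)
class RetrievalMetrics:
    """Precision is None when nothing was retrieved (undefined, not 0)."""

    precision: float | None
    recall: float
    per_bucket_recall: dict[str, float]
    n_retrieved: int
    n_barrier: int
    false_positives: int


def evaluate_retrieval(
    retrieved: set[str], golds: Sequence[GoldRecord]
) -> RetrievalMetrics:
    """Score a retrieved post-id set against gold barrier/distractor labels."""
    if not golds:
        raise GenerationError("empty gold record set")
    barrier_ids = {g.post_id for g in golds if g.bucket != DISTRACTOR}
    tp = len(retrieved & barrier_ids)
    fp = len(retrieved - barrier_ids)
    precision = tp / len(retrieved) if retrieved else None
    recall = tp / len(barrier_ids) if barrier_ids else 0.0
    per_bucket: dict[str, float] = {}
    for bucket in sorted({g.bucket for g in golds if g.bucket != DISTRACTOR}):
        ids = {g.post_id for g in golds if g.bucket == bucket}
        per_bucket[bucket] = len(retrieved & ids) / len(ids)
    return RetrievalMetrics(
        precision=precision,
        recall=recall,
        per_bucket_recall=per_bucket,
        n_retrieved=len(retrieved),
        n_barrier=len(barrier_ids),
        false_positives=fp,
    )
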