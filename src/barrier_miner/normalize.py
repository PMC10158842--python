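"""Deterministic text preprocessing feeding the fuzzy matcher.

Pipeline: URL spans removed first (stripping punctuation first would shred
URLs into spurious tokens), then per-character NFKC folding and lowercasing,
removal of all Unicode punctuation (general category P*, deleted rather than
replaced by space, so contractions collapse: "i'm" -> "im"), whitespace
collapse, and word-boundary tokenization. No stemming, stop-word removal or
spelling correction is applied — misspellings are the fuzzy matcher's job.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from .corpus import Post

# scheme:// or www. up to the next whitespace
_URL_RE = re.compile(r"(?:[A-Za-z][A-Za-z0-9+.\-]*://|www\.)\S*")


def _fold_char(ch: str) -> str:
    """NFKC-fold and lowercase one character; drop punctuation pieces."""
    out = []
    for c in unicodedata.normalize("NFKC", ch).lower():
        if unicodedata.category(c).startswith("P"):
            continue
        out.append(" " if c.isspace() else c)
    return "".join(out)


def normalize_text(raw: str) -> str:
    """Lowercase, URL-free, punctuation-free, whitespace-collapsed text."""
    without_urls = _URL_RE.sub(" ", raw)
    folded = "".join(_fold_char(ch) for ch in without_urls)
    return " ".join(folded.split())


def tokenize(normalized: str) -> list[str]:
    """Split normalized text at word boundaries (maximal non-space runs)."""
    return normalized.split()


@dataclass(frozen=True)
class NormalizedPost:
    """Token stream of one post plus raw-text character offsets.

    ``token_offsets[i]`` is the 0-based half-open raw-text span whose
    normalization yields ``tokens[i]`` (the span may include punctuation that
    normalization deletes).
    """

    post_id: str
    tokens: tuple[str, ...]
    token_offsets: tuple[tuple[int, int], ...]


def normalize_post(p: Post) -> NormalizedPost:
    """Normalize and tokenize one post, tracking raw-text offsets."""
    raw = p.text
    url_spans = [m.span() for m in _URL_RE.finditer(raw)]
    span_iter = iter(url_spans)
    cur_span = next(span_iter, None)

    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    buf: list[str] = []
    start = end = -1

    def flush() -> None:
        nonlocal buf, start, end
        if buf:
            tokens.append("".join(buf))
            offsets.append((start, end))
        buf = []
        start = end = -1

    for i, ch in enumerate(raw):
        while cur_span is not None and i >= cur_span[1]:
            cur_span = next(span_iter, None)
        if cur_span is not None and cur_span[0] <= i < cur_span[1]:
            continue  # inside a URL
        for c in _fold_char(ch):
            if c == " ":
                flush()
            else:
                if not buf:
                    start = i
                buf.append(c)
                end = i + 1
    flush()
    return NormalizedPost(
        post_id=p.post_id, tokens=tuple(tokens), token_offsets=tuple(offsets)
    )
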