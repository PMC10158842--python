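"""End-to-end pipeline: ingest -> normalize -> scan -> label -> report.

Every artifact written carries a provenance header (tool version, config
hash, seed) as ``#``-prefixed comment lines; no timestamps are written, so
identical configurations produce identical bytes.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .corpus import read_posts
from .match import (
    Lexicon,
    MatcherConfig,
    MatchRecord,
    load_lexicon,
    scan_corpus,
)
from .normalize import normalize_post
from .report import ReportError, frequency_report, render_report
from .taxonomy import (
    DEFAULT_RULEBOOK,
    DEFAULT_SCHEME,
    apply_exclusions,
    export_labels,
    import_labels,
    suggest_labels,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and settings for one pipeline run."""

    corpus: str
    lexicon: str
    out_dir: str
    labels: str | None = None  # manual labels CSV; None -> rule suggestions
    threshold: float = 0.9
    substitution_cost: int = 2
    strict: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def provenance_header(config: RunConfig) -> str:
    return (
        f"# barrier-miner {__version__}\n"
        f"# config={config.config_hash()} seed={config.seed}\n"
    )


def write_matches_tsv(
    matches: Sequence[MatchRecord], path: str | Path, header: str = ""
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write(header)
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["post_id", "expression", "start", "end", "window_text", "ratio"])
        for m in matches:
            writer.writerow(
                [
                    m.post_id,
                    m.expression_surface,
                    m.token_span[0],
                    m.token_span[1],
                    m.window_text,
                    f"{m.ratio:.6f}",
                ]
            )


def read_matches_tsv(path: str | Path) -> list[MatchRecord]:
    out: list[MatchRecord] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(filter(lambda ln: not ln.startswith("#"), fh), delimiter="\t")
        for row in reader:
            out.append(
                MatchRecord(
                    post_id=row["post_id"],
                    expression_surface=row["expression"],
                    token_span=(int(row["start"]), int(row["end"])),
                    window_text=row["window_text"],
                    ratio=float(row["ratio"]),
                )
            )
    return out


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns a map of artifact name -> path.

    Stage failures raise :class:`PipelineError` naming the stage; no partial
    outputs are written before the configuration is validated.
    """
    corpus_path = Path(config.corpus)
    lexicon_path = Path(config.lexicon)
    for stage, p in (("ingest", corpus_path), ("lexicon", lexicon_path)):
        if not p.exists():
            raise PipelineError(f"{stage}: missing input {p}")
    if config.labels is not None and not Path(config.labels).exists():
        raise PipelineError(f"labels: missing input {config.labels}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config)
    artifacts: dict[str, str] = {}

    try:
        posts = read_posts(corpus_path, strict=config.strict)
    except Exception as exc:
        raise PipelineError(f"ingest: {exc}") from exc
    try:
        lexicon: Lexicon = load_lexicon(lexicon_path)
    except Exception as exc:
        raise PipelineError(f"lexicon: {exc}") from exc

    normalized = [normalize_post(p) for p in posts]
    cfg = MatcherConfig(
        threshold=config.threshold, substitution_cost=config.substitution_cost
    )
    matches, retrieved = scan_corpus(normalized, lexicon, cfg)
    matches_path = out_dir / "matches.tsv"
    write_matches_tsv(matches, matches_path, header)
    artifacts["matches"] = str(matches_path)

    try:
        if config.labels is not None:
            labels = import_labels(config.labels, DEFAULT_SCHEME)
        else:
            labels = sorted(
                suggest_labels(matches, lexicon, DEFAULT_RULEBOOK),
                key=lambda r: r.post_id,
            )
            suggested_path = out_dir / "suggested.csv"
            with suggested_path.open("w", encoding="utf-8") as fh:
                fh.write(header)
            with suggested_path.open("a", encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["post_id", "codes", "source", "note"])
                for rec in labels:
                    writer.writerow(
                        [rec.post_id, ";".join(sorted(rec.codes)), rec.source, rec.note]
                    )
            artifacts["suggested"] = str(suggested_path)
    except Exception as exc:
        raise PipelineError(f"label: {exc}") from exc

    kept, excluded = apply_exclusions(labels, DEFAULT_SCHEME)
    if excluded:
        logger.info("excluded posts: %s", dict(excluded))

    for major in ("insurance", "non_insurance"):
        try:
            rep = frequency_report(kept, major, DEFAULT_SCHEME)
        except ReportError:
            logger.info("no posts labeled in %s; report skipped", major)
            continue
        path = out_dir / f"report_{major}.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write(header)
            fh.write(render_report(rep, "tsv"))
        artifacts[f"report_{major}"] = str(path)

    logger.info(
        "pipeline done: %d posts, %d matches, %d retrieved",
        len(posts),
        len(matches),
        len(retrieved),
    )
    return artifacts
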