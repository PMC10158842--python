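"""Frequency reports over labeled posts and the literature-prevalence table.

Percentages are rounded HALF-UP to one decimal (22.472 -> 22.5); Python's
built-in banker's rounding would silently disagree on real fixtures. Counts
are conserved exactly: bucket counts always sum to the report total, while
rounded percentages may sum to 100 ± 0.3 (e.g. a 100.1 column is a normal
rounding artifact).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .taxonomy import (
    MULTIPLE,
    CategoryScheme,
    DEFAULT_SCHEME,
    LabelRecord,
    TaxonomyError,
    resolve_counting_bucket,
)

BARRIER_FLAGS = (
    "stigma",
    "logistical_financial",
    "gender_specific",
    "fear",
    "lack_of_knowledge",
)

#: Tags a publication's targeted population may carry (multi-tag, ;-joined in
#: CSV). ``pregnant`` rows count toward the women tally in breakdowns.
POPULATION_TAGS = ("women", "pregnant", "racial_ethnic_minority", "rural", "carceral", "other")


class ReportError(ValueError):
    """Raised for empty inputs where a report denominator would be zero."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at the last digit rounds away from 0)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total)


@dataclass(frozen=True)
class FrequencyReport:
    """Per-bucket counts and percentages for one major category (or any
    named tally); counts sum to ``total`` exactly."""

    name: str
    rows: tuple[tuple[str, int, float], ...]  # (bucket, count, percentage)
    total: int

    def __post_init__(self) -> None:
        if sum(c for _, c, _ in self.rows) != self.total:
            raise ReportError("bucket counts do not sum to total")

    def counts(self) -> dict[str, int]:
        return {b: c for b, c, _ in self.rows}

    def percentages(self) -> dict[str, float]:
        return {b: p for b, _, p in self.rows}


def report_from_counts(counts: Mapping[str, int], name: str) -> FrequencyReport:
    """Build a report from pre-tallied bucket counts."""
    total = sum(counts.values())
    if total == 0:
        raise ReportError(f"empty report {name!r}: no labeled posts")
    rows = tuple((b, c, percentage(c, total)) for b, c in counts.items())
    return FrequencyReport(name=name, rows=rows, total=total)


def frequency_report(
    labels: Sequence[LabelRecord],
    major: str,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> FrequencyReport:
    """Counting-bucket frequency report for one major category.

    Only posts with at least one code in ``major`` contribute; a post labeled
    in both major categories contributes independently to each category's
    report. Order-independent in the input labels.
    """
    buckets = list(scheme.subcategories(major)) + [MULTIPLE]
    counts = {b: 0 for b in buckets}
    for rec in labels:
        codes = rec.codes_in(major, scheme)
        if not codes:
            continue
        counts[resolve_counting_bucket(codes, major, scheme)] += 1
    if sum(counts.values()) == 0:
        raise ReportError(f"no posts labeled in major category {major!r}")
    return report_from_counts(counts, name=major)


# ---------------------------------------------------------------------------
# literature table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiteratureTable:
    """Publication-level barrier flags and targeted-population tags."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame["publication_id"].duplicated().any():
            raise ReportError("duplicate publication_id in literature table")
        for flag in BARRIER_FLAGS:
            if not self.frame[flag].isin((0, 1)).all():
                raise ReportError(f"non-boolean flag column {flag!r}")

    def __len__(self) -> int:
        return len(self.frame)


def load_literature_table(path: str | Path) -> LiteratureTable:
    frame = pd.read_csv(path, keep_default_na=False, dtype={"targeted_population": str})
    return LiteratureTable(frame=frame)


def literature_prevalence(table: LiteratureTable, flag: str) -> tuple[int, float]:
    """(count, percentage) of publications reporting the given barrier flag,
    over all publications in the table."""
    if flag not in BARRIER_FLAGS:
        raise ReportError(f"unknown barrier flag {flag!r}")
    n = len(table)
    if n == 0:
        raise ReportError("empty literature table")
    count = int(table.frame[flag].sum())
    return count, percentage(count, n)


def _population_tags(cell: str) -> set[str]:
    return {t.strip() for t in str(cell).split(";") if t.strip()}


def population_breakdown(table: LiteratureTable) -> dict:
    """Targeted-population breakdown of the literature table.

    A publication is "targeted" if it carries any population tag. Per-tag
    counts use the targeted publications as denominator; tags may overlap, so
    per-tag percentages need not sum to 100. ``pregnant`` publications study
    women and are included in the ``women`` tally (also reported separately).
    """
    n = len(table)
    tag_sets = [_population_tags(c) for c in table.frame["targeted_population"]]
    targeted = [s for s in tag_sets if s]
    n_targeted = len(targeted)
    out: dict = {
        "n_publications": n,
        "n_targeted": n_targeted,
        "targeted_share_pct": percentage(n_targeted, n) if n else 0.0,
        "populations": {},
    }
    if n_targeted == 0:
        return out
    for tag in POPULATION_TAGS:
        if tag == "women":
            count = sum(1 for s in targeted if s & {"women", "pregnant"})
        else:
            count = sum(1 for s in targeted if tag in s)
        out["populations"][tag] = (count, percentage(count, n_targeted))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(report: FrequencyReport, fmt: str = "tsv") -> str:
    """Serialize a report deterministically.

    ``tsv``: bucket/count/percentage rows plus a TOTAL line; ``markdown``: a
    table with a header row; ``figure-data``: plain bucket/count/percentage
    triples ready for bar-chart plotting (no total line).
    """
    if fmt == "tsv" or fmt == "figure-data":
        lines = ["bucket\tcount\tpercentage"]
        for bucket, count, pct in report.rows:
            lines.append(f"{bucket}\t{count}\t{pct}")
        if fmt == "tsv":
            lines.append(f"TOTAL\t{report.total}\t100.0")
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = [
            f"### {report.name}",
            "",
            "| bucket | count | percentage |",
            "| --- | ---: | ---: |",
        ]
        for bucket, count, pct in report.rows:
            lines.append(f"| {bucket} | {count} | {pct} |")
        lines.append(f"| **total** | **{report.total}** | 100.0 |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def parse_report_tsv(text: str, name: str = "parsed") -> FrequencyReport:
    """Parse a TSV rendering back into a report (inverse of render tsv)."""
    rows: list[tuple[str, int, float]] = []
    total = None
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("bucket\t"):
            continue
        bucket, count, pct = line.split("\t")
        if bucket == "TOTAL":
            total = int(count)
        else:
            rows.append((bucket, int(count), float(pct)))
    if total is None:
        total = sum(c for _, c, _ in rows)
    return FrequencyReport(name=name, rows=tuple(rows), total=total)


def write_report(report: FrequencyReport, path: str | Path, fmt: str = "tsv",
                 header: str | None = None) -> None:
    text = render_report(report, fmt)
    with Path(path).open("w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write(text)
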