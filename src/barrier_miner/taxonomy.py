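"""Two-level barrier categorization scheme, label import/export, exclusions,
and the mutually-exclusive counting-bucket rule.

Posts may legitimately carry several subcategory codes ("multi-label"); for
reporting, each labeled post maps to exactly one counting bucket per major
category: its single subcategory if it has exactly one code there, otherwise
the synthetic bucket ``multiple``. Exclusion codes (off-topic posts, alcohol
use disorder) never co-occur with subcategory codes and are removed from the
analysis stream before any counting.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .match import MatchRecord, Lexicon

MULTIPLE = "multiple"
MAJORS = ("insurance", "non_insurance")
LABEL_SOURCES = ("manual", "rule")


class TaxonomyError(ValueError):
    """Raised on invalid schemes or label records."""


@dataclass(frozen=True)
class CategoryScheme:
    """Subcategory codes grouped by major category, plus exclusion codes."""

    insurance: tuple[str, ...]
    non_insurance: tuple[str, ...]
    exclusions: tuple[str, ...]

    def __post_init__(self) -> None:
        all_codes = list(self.insurance) + list(self.non_insurance) + list(self.exclusions)
        if len(all_codes) != len(set(all_codes)):
            raise TaxonomyError("duplicate codes in scheme")
        if not self.insurance or not self.non_insurance:
            raise TaxonomyError("each major category needs at least one subcategory")

    def subcategories(self, major: str) -> tuple[str, ...]:
        if major == "insurance":
            return self.insurance
        if major == "non_insurance":
            return self.non_insurance
        raise TaxonomyError(f"unknown major category {major!r}")

    def major_of(self, code: str) -> str:
        """The major category of a subcategory code, or "exclusion"."""
        if code in self.insurance:
            return "insurance"
        if code in self.non_insurance:
            return "non_insurance"
        if code in self.exclusions:
            return "exclusion"
        raise TaxonomyError(f"unknown code {code!r}")


DEFAULT_SCHEME = CategoryScheme(
    insurance=(
        "no_insurance",
        "treatment_not_covered",
        "fear_of_losing_coverage",
        "forced_treatment_switch",
        "general_insurance_difficulty",
    ),
    non_insurance=(
        "financial_difficulty",
        "stigma",
        "provider_issues",
        "poor_treatment_by_clinician_or_pharmacist",
        "fear_of_starting_treatment",
    ),
    exclusions=("unrelated", "alcohol_use_disorder"),
)

#: Default mapping from lexicon theme to the single subcategory a rule-based
#: pre-label may suggest. ``None`` means the theme suggests nothing on its own.
DEFAULT_RULEBOOK: dict[str, str | None] = {
    "insurance": "general_insurance_difficulty",
    "stigma": "stigma",
    "logistics": "provider_issues",
    "facility_location": "provider_issues",
    "other": None,
}


def load_scheme(path: str | Path | None = None) -> CategoryScheme:
    """Load a scheme from YAML, or return the built-in default."""
    if path is None:
        return DEFAULT_SCHEME
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return CategoryScheme(
        insurance=tuple(doc["insurance"]),
        non_insurance=tuple(doc["non_insurance"]),
        exclusions=tuple(doc.get("exclusions", ())),
    )


@dataclass(frozen=True)
class LabelRecord:
    """Post-level label: a non-empty code set, or a single exclusion code."""

    post_id: str
    codes: frozenset[str]
    source: str = "manual"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.codes:
            raise TaxonomyError(f"post {self.post_id!r}: empty code set")
        if self.source not in LABEL_SOURCES:
            raise TaxonomyError(f"unknown label source {self.source!r}")

    def validate(self, scheme: CategoryScheme) -> None:
        majors = {scheme.major_of(c) for c in self.codes}
        if "exclusion" in majors and len(self.codes) > 1:
            raise TaxonomyError(
                f"post {self.post_id!r}: exclusion code mixed with other codes"
            )

    def is_excluded(self, scheme: CategoryScheme) -> bool:
        return any(c in scheme.exclusions for c in self.codes)

    def codes_in(self, major: str, scheme: CategoryScheme) -> frozenset[str]:
        return frozenset(c for c in self.codes if c in scheme.subcategories(major))


def import_labels(path: str | Path, scheme: CategoryScheme) -> list[LabelRecord]:
    """Read a labels CSV (post_id, codes ;-separated, source, note).

    Unknown codes, empty code sets and exclusion/subcategory mixtures are
    rejected with the offending line number.
    """
    records: list[LabelRecord] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(
            filter(lambda line: not line.startswith("#"), fh)
        )
        for lineno, row in enumerate(reader, start=2):
            codes = frozenset(c.strip() for c in row["codes"].split(";") if c.strip())
            try:
                rec = LabelRecord(
                    post_id=row["post_id"],
                    codes=codes,
                    source=row.get("source") or "manual",
                    note=row.get("note") or "",
                )
                rec.validate(scheme)
            except TaxonomyError as exc:
                raise TaxonomyError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def export_labels(records: Iterable[LabelRecord], path: str | Path) -> None:
    """Write labels CSV; round-trips losslessly through import_labels."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id", "codes", "source", "note"])
        for rec in records:
            writer.writerow(
                [rec.post_id, ";".join(sorted(rec.codes)), rec.source, rec.note]
            )


def apply_exclusions(
    labels: Sequence[LabelRecord], scheme: CategoryScheme = DEFAULT_SCHEME
) -> tuple[list[LabelRecord], Counter]:
    """Drop excluded records; return (kept, per-exclusion-code tally)."""
    kept: list[LabelRecord] = []
    tally: Counter = Counter()
    for rec in labels:
        if rec.is_excluded(scheme):
            for code in rec.codes:
                tally[code] += 1
        else:
            kept.append(rec)
    return kept, tally


def resolve_counting_bucket(
    codes: Iterable[str], major: str, scheme: CategoryScheme = DEFAULT_SCHEME
) -> str:
    """Map a post's codes within one major category to its counting bucket.

    Exactly one code there -> that subcategory; two or more -> ``multiple``;
    none -> error (the caller must restrict to posts labeled in this major).
    """
    restricted = {c for c in codes if c in scheme.subcategories(major)}
    if not restricted:
        raise TaxonomyError(f"no codes in major category {major!r}")
    if len(restricted) == 1:
        return next(iter(restricted))
    return MULTIPLE


def suggest_labels(
    matches: Sequence[MatchRecord],
    lexicon: Lexicon,
    rulebook: Mapping[str, str | None] = DEFAULT_RULEBOOK,
    manual_post_ids: Iterable[str] = (),
) -> list[LabelRecord]:
    """Rule-based pre-labels: one record per retrieved post, unioning the
    subcategories its matched themes map to. Posts that already have a manual
    label are suppressed — suggestions never override manual coding.
    """
    manual = set(manual_post_ids)
    by_post: dict[str, set[str]] = {}
    for m in matches:
        if m.post_id in manual:
            continue
        code = rulebook.get(lexicon.theme_of(m.expression_surface))
        if code is None:
            continue
        by_post.setdefault(m.post_id, set()).add(code)
    return [
        LabelRecord(post_id=pid, codes=frozenset(codes), source="rule")
        for pid, codes in by_post.items()
    ]
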