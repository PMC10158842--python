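"""Packaged fixtures and the printed-value reproduction check.

The fixtures transcribe the published study's reported data so its printed
numbers are executable: per-bucket post counts for both major barrier
categories, the 19-publication literature flag table, a seed lexicon of the
example search expressions, and a small set of real-language example posts
for smoke-testing the matcher. Fixture files are embedded in the package and
checksum-verified at load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

from .corpus import Post, read_posts
from .match import Lexicon, load_lexicon
from .report import (
    FrequencyReport,
    LiteratureTable,
    literature_prevalence,
    load_literature_table,
    population_breakdown,
    report_from_counts,
)

_CHECKSUMS: dict[str, tuple[str, str]] = {
    # name -> (filename, sha256); filled for every packaged fixture
    "seed_lexicon": ("seed_lexicon.yaml", "dfed75b4b6f08c98399b93d9d2537410e6c5d114215ad5fe50bf34b5e27a35b0"),
    "insurance_counts": ("insurance_counts.csv", "0d369af702c66c85e92272a9745f3bcbe62ada31c39f1d6cb3400b7cdc3d298d"),
    "non_insurance_counts": ("non_insurance_counts.csv", "4779241d38f45563168962db35fbf053337fe4a66d41a8c366199df4802c48c3"),
    "table1": ("table1.csv", "dad38b3f4951674f9551ba0512e611c19b1ce9fdf54a1727d13707868bf4a674"),
    "example_posts": ("example_posts.jsonl", "53c659ae534d1e81b88067a01dce0b279f98d47f3bda66bae214274934353963"),
    "templates": ("templates.yaml", "4dfd9977e3ed0e12cff26f108ff39e213d8d359ffaed93f4de72435cf423311e"),
}


class FixtureError(ValueError):
    """Unknown fixture name or checksum mismatch."""


def _fixture_bytes(name: str) -> bytes:
    try:
        filename, expected_sha = _CHECKSUMS[name]
    except KeyError:
        raise FixtureError(f"unknown fixture {name!r}") from None
    data = (resources.files("barrier_miner.data") / filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha:
        raise FixtureError(
            f"fixture {name!r} checksum mismatch: {digest} != {expected_sha}"
        )
    return data


def fixture_path(name: str) -> str:
    """Verified filesystem path of a packaged fixture."""
    _fixture_bytes(name)  # verifies existence + checksum
    filename, _ = _CHECKSUMS[name]
    return str(resources.files("barrier_miner.data") / filename)


def load_fixture(name: str):
    """Load a packaged fixture as its natural in-memory object.

    Count fixtures load as :class:`FrequencyReport`, ``table1`` as a
    :class:`LiteratureTable`, ``seed_lexicon`` as a :class:`Lexicon`,
    ``example_posts`` as a list of :class:`Post`.
    """
    path = fixture_path(name)
    if name in ("insurance_counts", "non_insurance_counts"):
        counts: dict[str, int] = {}
        for line in _fixture_bytes(name).decode("utf-8").splitlines()[1:]:
            bucket, count = line.split(",")
            counts[bucket] = int(count)
        major = "insurance" if name == "insurance_counts" else "non_insurance"
        return report_from_counts(counts, name=major)
    if name == "table1":
        return load_literature_table(path)
    if name == "seed_lexicon":
        return load_lexicon(path)
    if name == "example_posts":
        return read_posts(path, strict=True)
    if name == "templates":
        from .simulate import load_templates

        return load_templates(path)
    raise FixtureError(f"unknown fixture {name!r}")


#: Printed reference values the reproduction check compares against:
#: per-bucket percentages for both major categories, and the literature
#: prevalence/population shares.
PRINTED_PERCENTAGES: dict[str, dict[str, float]] = {
    "insurance": {
        "no_insurance": 22.5,
        "treatment_not_covered": 24.7,
        "fear_of_losing_coverage": 4.5,
        "forced_treatment_switch": 2.8,
        "general_insurance_difficulty": 38.2,
        "multiple": 7.3,
    },
    "non_insurance": {
        "financial_difficulty": 26.2,
        "stigma": 47.6,
        "provider_issues": 4.8,
        "poor_treatment_by_clinician_or_pharmacist": 3.6,
        "fear_of_starting_treatment": 1.2,
        "multiple": 16.7,
    },
    "literature": {
        "stigma": 78.9,
        "logistical_financial": 73.7,
        "targeted_share": 84.2,
        "women": 43.8,
    },
}

PRINTED_TOTALS = {"insurance": 178, "non_insurance": 84, "literature": 19}


@dataclass(frozen=True)
class ReproductionResult:
    name: str
    computed: float
    expected: float

    @property
    def ok(self) -> bool:
        return abs(self.computed - self.expected) < 1e-9


def reproduce_printed_values() -> list[ReproductionResult]:
    """Recompute every checked printed percentage from the packaged fixtures.

    Returns one result per quantity; callers decide what to do on mismatch
    (the CLI exits nonzero on any).
    """
    results: list[ReproductionResult] = []
    for name in ("insurance_counts", "non_insurance_counts"):
        rep: FrequencyReport = load_fixture(name)
        expected = PRINTED_PERCENTAGES[rep.name]
        results.append(
            ReproductionResult(f"{rep.name}_total", rep.total, PRINTED_TOTALS[rep.name])
        )
        for bucket, pct in rep.percentages().items():
            results.append(
                ReproductionResult(f"{rep.name}_{bucket}_pct", pct, expected[bucket])
            )
    table: LiteratureTable = load_fixture("table1")
    lit = PRINTED_PERCENTAGES["literature"]
    results.append(
        ReproductionResult("literature_total", len(table), PRINTED_TOTALS["literature"])
    )
    for flag in ("stigma", "logistical_financial"):
        _, pct = literature_prevalence(table, flag)
        results.append(ReproductionResult(f"literature_{flag}_pct", pct, lit[flag]))
    breakdown = population_breakdown(table)
    results.append(
        ReproductionResult(
            "literature_targeted_share_pct",
            breakdown["targeted_share_pct"],
            lit["targeted_share"],
        )
    )
    results.append(
        ReproductionResult(
            "literature_women_pct", breakdown["populations"]["women"][1], lit["women"]
        )
    )
    return results
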