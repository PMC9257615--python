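"""Keyword implication: flag disease categories from treatment/procedure terms.

Crowdfunding campaigns often state a treatment rather than a diagnosis —
"she starts dialysis next week" implies genitourinary disease without naming
one.  The shipped rule set covers six categories: injuries and external
causes (accident, injury/injuries/injured, crash, collision, burn/burns/
burned), cardiovascular (heart transplant, heart surgery), neoplasms
(chemo/chemotherapy, radiation/radiotherapy, bone marrow transplant),
genitourinary (dialysis, kidney/renal transplant), gastrointestinal (liver
transplant) and respiratory (lung transplant).

Matching is literal, case-insensitive and word-boundary anchored: "burnout"
does not fire "burn", "crashing" does not fire "crash".  Multi-word phrases
tolerate any whitespace run between tokens.  Users may extend or replace the
set via a CSV of ``pattern,disease_category`` rows targeting any category.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .detector import Campaign
from .lexicon import CATEGORIES, OTHER, LexiconError


@dataclass(frozen=True)
class KeywordRule:
    """A word-boundary pattern implying one disease category."""

    pattern: str
    disease_category: str

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise ValueError("rule pattern must be non-empty")
        if self.disease_category not in (*CATEGORIES, OTHER):
            raise ValueError(f"unknown disease category {self.disease_category!r}")

    @property
    def regex(self) -> re.Pattern[str]:
        toks = [re.escape(t) for t in self.pattern.split()]
        return re.compile(r"\b" + r"\s+".join(toks) + r"\b", re.IGNORECASE)


def default_rules() -> list[KeywordRule]:
    """The shipped treatment/procedure rule set (21 patterns, 6 categories)."""
    path = resources.files("crowddx.data").joinpath("keyword_rules.csv")
    with path.open("r", encoding="utf-8") as fh:
        return _parse_rules(csv.DictReader(fh))


def load_rules(path: str | Path) -> list[KeywordRule]:
    """Load a user rule CSV (columns ``pattern,disease_category``)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"pattern", "disease_category"}.issubset(
            reader.fieldnames
        ):
            raise LexiconError("rules CSV must have columns pattern,disease_category")
        return _parse_rules(reader)


def _parse_rules(rows: Iterable[dict[str, str]]) -> list[KeywordRule]:
    return [
        KeywordRule(pattern=r["pattern"].strip().lower(), disease_category=r["disease_category"].strip())
        for r in rows
        if r.get("pattern", "").strip()
    ]


def apply_rules(
    campaign: Campaign, rules: Iterable[KeywordRule]
) -> set[tuple[str, str]]:
    """Categories implied by keyword hits in one campaign.

    Returns ``(disease_category, matched_pattern)`` pairs; a category may
    appear with several patterns (all retained for provenance) but counts
    once downstream.
    """
    hits: set[tuple[str, str]] = set()
    for rule in rules:
        if rule.regex.search(campaign.text):
            hits.add((rule.disease_category, rule.pattern))
    return hits
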