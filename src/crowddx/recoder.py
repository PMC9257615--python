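"""Prefix-trimming recoder: align out-of-table codes with the grouping lexicon.

Resolver output sometimes carries an ICD-10-CM code with no exact row in the
grouping table — typically a less specific stem like ``C5091`` when the table
only lists the full ``C50911``/``C50912``/``C50919``.  The recoder iteratively
shortens the code one character at a time and prefix-matches each candidate
against the table; the first (longest) prefix with any hits wins, and the
code inherits the modal disease category among the hits.

The untrimmed code itself is tried as a prefix first (k=0): a bare stem that
is a strict prefix of table codes should inherit their category without any
trimming.  Modal-category ties are broken by the fixed category priority
order and flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .lexicon import CATEGORIES, CODE_PATTERN, OTHER, Lexicon, LexiconError, normalize_code

_PRIORITY = {c: i for i, c in enumerate((*CATEGORIES, OTHER))}


class MatchKind(str, Enum):
    EXACT = "exact"
    PREFIX = "prefix"
    NONE = "none"


@dataclass(frozen=True)
class RecodeResult:
    """Outcome of recoding one code against a grouping lexicon."""

    input_code: str
    matched: MatchKind
    trims: int
    matching_codes: tuple[str, ...]
    disease_category: str | None
    tie: bool

    def __post_init__(self) -> None:
        if self.matched is MatchKind.EXACT and (self.trims != 0 or len(self.matching_codes) != 1):
            raise ValueError("exact match implies trims=0 and a single matching code")
        if self.matched is MatchKind.NONE and self.disease_category is not None:
            raise ValueError("unmatched code has no disease category")


def modal_category(categories: list[str]) -> tuple[str, bool]:
    """Most common category, ties broken by priority order; flags the tie."""
    counts = Counter(categories)
    top = max(counts.values())
    tied = sorted((c for c, n in counts.items() if n == top), key=_PRIORITY.__getitem__)
    return tied[0], len(tied) > 1


def recode(code: str, lexicon: Lexicon) -> RecodeResult:
    """Recode one ICD-10-CM code against the grouping lexicon.

    Exact table codes pass through with their own category.  Otherwise the
    longest prefix of the code (starting with the untrimmed code itself) that
    matches any table codes determines the category by majority vote.
    """
    code = normalize_code(code)
    if not CODE_PATTERN.match(code):
        raise LexiconError(f"malformed ICD-10-CM code: {code!r}")

    entry = lexicon.get(code)
    if entry is not None:
        return RecodeResult(
            input_code=code,
            matched=MatchKind.EXACT,
            trims=0,
            matching_codes=(entry.code,),
            disease_category=entry.disease_category,
            tie=False,
        )

    for k in range(len(code)):
        prefix = code[: len(code) - k]
        matches = lexicon.codes_with_prefix(prefix) if len(lexicon) else []
        if matches:
            category, tie = modal_category([e.disease_category for e in matches])
            return RecodeResult(
                input_code=code,
                matched=MatchKind.PREFIX,
                trims=k,
                matching_codes=tuple(e.code for e in matches),
                disease_category=category,
                tie=tie,
            )

    return RecodeResult(
        input_code=code,
        matched=MatchKind.NONE,
        trims=len(code) - 1,
        matching_codes=(),
        disease_category=None,
        tie=False,
    )
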