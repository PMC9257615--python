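"""ICD-10-CM lexicon store: codes, descriptions, and disease-category grouping.

The lexicon is the grouping table the whole pipeline runs against: each entry
carries an ICD-10-CM code (stored dot-free and uppercase, e.g. ``C50.911`` →
``C50911``), its diagnosis description, a narrow CCSR-style clinical category,
and one of 11 broad disease categories (or ``OTHER``).  Codes are kept in a
sorted index so prefix range queries — the backbone of the trimming recoder —
are O(log n).

Category assignment, when not given explicitly per row, is resolved by a
:class:`CategoryScheme`: first by a CCSR-category reassignment override, then
by the ICD-10-CM chapter implied by the code's three-character stem.  The
shipped chapter map is an editable CSV approximating the standard chapter
conventions (A00–B99 infections, C00–D49 neoplasms, I00–I99 cardiovascular,
…); chapters outside the 11 target systems (pregnancy, eye/ear, blood/immune,
skin, symptoms, factors influencing health status) map to ``OTHER``.
"""

from __future__ import annotations

import csv
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

#: The 11 broad disease categories, in fixed priority order (used for
#: deterministic tie-breaking throughout the package).
CATEGORIES: tuple[str, ...] = (
    "cardiovascular",
    "endocrine",
    "gastrointestinal",
    "genitourinary",
    "infections",
    "injuries_external",
    "mental_health",
    "musculoskeletal",
    "neoplasms",
    "nervous_system",
    "respiratory",
)

#: Catch-all for codes outside the 11 target categories; removed before the
#: final per-campaign summary.
OTHER = "OTHER"

_VALID_CATEGORIES = frozenset(CATEGORIES) | {OTHER}

CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,4}$")


class LexiconError(ValueError):
    """Raised on malformed or inconsistent lexicon input."""


def normalize_code(code: str) -> str:
    """Uppercase an ICD-10-CM code and drop the decimal point."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class LexiconEntry:
    """One ICD-10-CM code with its description and category assignments."""

    code: str
    description: str
    ccsr_category: str
    disease_category: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not CODE_PATTERN.match(self.code):
            raise LexiconError(f"malformed ICD-10-CM code: {self.code!r}")
        if self.disease_category not in _VALID_CATEGORIES:
            raise LexiconError(
                f"unknown disease category {self.disease_category!r} for code {self.code}"
            )


@dataclass(frozen=True)
class CategoryScheme:
    """Maps CCSR categories / ICD-10-CM chapters onto the 11 disease categories.

    ``reassignments`` override the chapter default for named CCSR categories
    (the mechanism used to consolidate, e.g., congenital abnormalities into
    the organ system they affect).  ``chapter_ranges`` are
    ``(start_stem, end_stem, category)`` triples compared against the first
    three characters of a code.
    """

    categories: tuple[str, ...] = CATEGORIES
    reassignments: dict[str, str] = field(default_factory=dict)
    chapter_ranges: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if tuple(self.categories) != CATEGORIES:
            if len(self.categories) != 11 or OTHER in self.categories:
                raise LexiconError("a scheme must define exactly 11 non-OTHER categories")
        allowed = frozenset(self.categories) | {OTHER}
        for src, dst in self.reassignments.items():
            if dst not in allowed:
                raise LexiconError(f"reassignment {src!r} -> {dst!r}: unknown target category")
        for start, end, cat in self.chapter_ranges:
            if cat not in allowed:
                raise LexiconError(f"chapter range {start}-{end}: unknown category {cat!r}")

    @staticmethod
    def default() -> "CategoryScheme":
        """The shipped chapter-convention scheme with no reassignments."""
        return CategoryScheme(chapter_ranges=_load_chapter_ranges())

    def with_reassignments(self, reassignments: dict[str, str]) -> "CategoryScheme":
        merged = dict(self.reassignments)
        merged.update(reassignments)
        return CategoryScheme(
            categories=self.categories,
            reassignments=merged,
            chapter_ranges=self.chapter_ranges,
        )

    def assign(self, code: str, ccsr_category: str) -> str:
        """Disease category for a code, honouring reassignment overrides."""
        if ccsr_category in self.reassignments:
            return self.reassignments[ccsr_category]
        stem = code[:3]
        for start, end, cat in self.chapter_ranges:
            if start <= stem <= end:
                return cat
        return OTHER


def _load_chapter_ranges() -> tuple[tuple[str, str, str], ...]:
    path = resources.files("crowddx.data").joinpath("chapter_map.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return tuple((r["start"], r["end"], r["disease_category"]) for r in rows)


def load_scheme(path: str | Path) -> CategoryScheme:
    """Load CCSR-category reassignments (CSV ``ccsr_category,disease_category``)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "ccsr_category",
            "disease_category",
        }.issubset(reader.fieldnames):
            raise LexiconError("scheme CSV must have columns ccsr_category,disease_category")
        reassignments = {r["ccsr_category"]: r["disease_category"] for r in reader}
    return CategoryScheme.default().with_reassignments(reassignments)


class Lexicon:
    """An indexed set of :class:`LexiconEntry`, sorted by code.

    Supports exact lookup and lexicographic prefix range queries.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries = sorted(entries, key=lambda e: e.code)
        self._codes = [e.code for e in self._entries]
        self._by_code = {e.code: e for e in self._entries}
        if len(self._by_code) != len(self._entries):
            seen: set[str] = set()
            dups = sorted({c for c in self._codes if c in seen or seen.add(c)})
            raise LexiconError(f"duplicate codes in lexicon: {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries)

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self._by_code

    def get(self, code: str) -> LexiconEntry | None:
        return self._by_code.get(normalize_code(code))

    def codes_with_prefix(self, prefix: str) -> list[LexiconEntry]:
        """All entries whose code starts with ``prefix``, in code order."""
        if not prefix:
            raise LexiconError("prefix must be non-empty")
        prefix = normalize_code(prefix)
        lo = bisect_left(self._codes, prefix)
        hi = bisect_left(self._codes, prefix + "￿")
        return self._entries[lo:hi]

    @property
    def entries(self) -> list[LexiconEntry]:
        return list(self._entries)


def load_lexicon(path: str | Path, scheme: CategoryScheme | None = None) -> Lexicon:
    """Load a lexicon CSV and resolve every row's disease category.

    Expected columns: ``code,description,ccsr_category``, optionally
    ``disease_category`` (explicit per-row override) and ``synonyms``
    (pipe-separated lay synonyms).  Rows lacking an explicit category are
    assigned through ``scheme`` (reassignments, then chapter default).
    """
    scheme = scheme or CategoryScheme.default()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "description", "ccsr_category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LexiconError(
                "lexicon CSV must have columns code,description,ccsr_category"
            )
        entries: list[LexiconEntry] = []
        for lineno, row in enumerate(reader, start=2):
            code = normalize_code(row["code"])
            if not CODE_PATTERN.match(code):
                raise LexiconError(f"row {lineno}: malformed ICD-10-CM code {row['code']!r}")
            explicit = (row.get("disease_category") or "").strip()
            category = explicit or scheme.assign(code, row["ccsr_category"].strip())
            synonyms = tuple(
                s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()
            )
            try:
                entries.append(
                    LexiconEntry(
                        code=code,
                        description=row["description"].strip(),
                        ccsr_category=row["ccsr_category"].strip(),
                        disease_category=category,
                        synonyms=synonyms,
                    )
                )
            except LexiconError as exc:
                raise LexiconError(f"row {lineno}: {exc}") from exc
    return Lexicon(entries)


def codes_with_prefix(lexicon: Lexicon, prefix: str) -> list[LexiconEntry]:
    """Functional alias for :meth:`Lexicon.codes_with_prefix`."""
    return lexicon.codes_with_prefix(prefix)


def bundled_lexicon(scheme: CategoryScheme | None = None) -> Lexicon:
    """The packaged miniature lexicon (60 codes spanning all 12 categories).

    A synthetic desk-scale stand-in for the full CCSR grouping tables, meant
    for demos, tests and synthetic corpora — not for production annotation.
    """
    path = resources.files("crowddx.data").joinpath("mini_lexicon.csv")
    with resources.as_file(path) as p:
        return load_lexicon(p, scheme=scheme)
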