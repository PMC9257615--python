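"""Spell-tolerant detection of diagnosis mentions in campaign text.

This is the desk-scale stand-in for a learned clinical NER model: a fuzzy
dictionary matcher over the lexicon's diagnosis vocabulary.  Candidate spans
are generated by token blocking (windows with the same token count and first
character as an indexed term) and verified by bounded Damerau–Levenshtein
distance, so lay misspellings like "aneruism" or "lukemia" still match.

Term index construction
-----------------------
Full descriptions and lay synonyms are always indexed.  Contiguous
sub-phrases of descriptions are indexed too — that is what lets "myeloid
lukemia" hit the "myeloid leukemia" portion of a longer code description —
but a sub-phrase is dropped when it carries no diagnostic content of its own:
when every token is a function word, a generic clinical qualifier
("unspecified", "initial encounter", "left") or a bare anatomical site
("kidney", "heart").  A bare organ or qualifier is not a diagnosis, and
indexing them as standalone terms would flag a disease category every time a
campaign mentions a body part.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Mapping, Protocol, Sequence

from ._text import normalize, osa_distance, token_spans, tokens
from .lexicon import Lexicon

#: Connectives trimmed from sub-phrase edges (a term never starts/ends with one).
FUNCTION_WORDS = frozenset(
    "of and the in on at to for with without due not or by one".split()
)

#: Generic clinical qualifiers: meaningless as a standalone term.
GENERIC_TERMS = frozenset(
    """
    disease diseases disorder disorders syndrome unspecified specified other
    site sites part parts type types status stage initial subsequent encounter
    episode episodes single multiple major minor acute chronic severe mild
    moderate morbid benign malignant primary secondary essential right left
    bilateral unilateral lateral upper lower female male adult age related current
    having achieved remission complication complications uncomplicated
    intractable organism excess calories loss side end low high pain infection
    failure deficiency symptoms
    """.split()
)

#: Bare anatomical sites: a body part alone is not a diagnosis.
ANATOMY_TERMS = frozenset(
    "heart brain lung lungs liver kidney kidneys renal bone marrow blood head neck back breast".split()
)

STOP_TERMS = FUNCTION_WORDS | GENERIC_TERMS | ANATOMY_TERMS

#: Minimum indexed term length (characters) and fuzzy-matching floor.
MIN_TERM_LEN = 4
MIN_FUZZY_LEN = 6
MAX_EDITS = 2


@dataclass(frozen=True)
class Campaign:
    """One crowdfunding campaign record: an opaque id plus free text."""

    campaign_id: str
    text: str


@dataclass(frozen=True)
class DiagnosisMention:
    """A detected diagnosis span (0-based half-open character offsets)."""

    campaign_id: str
    start: int
    end: int
    surface: str
    matched_term: str
    edit_distance: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("mention offsets must satisfy 0 <= start < end")
        if self.edit_distance < 0:
            raise ValueError("edit_distance must be >= 0")


class MentionDetector(Protocol):
    """Contract for pluggable diagnosis detectors (e.g. a learned NER model)."""

    def __call__(self, campaign: Campaign, max_edit_fraction: float) -> list[DiagnosisMention]:
        ...


class TermIndex:
    """Normalized diagnosis terms, each linked back to its source codes."""

    def __init__(self, term_codes: Mapping[str, frozenset[str]]):
        self.term_codes: dict[str, frozenset[str]] = dict(term_codes)
        self._buckets: dict[tuple[int, str], list[str]] = {}
        for term in self.term_codes:
            key = (len(tokens(term)), term[0])
            self._buckets.setdefault(key, []).append(term)
        for bucket in self._buckets.values():
            bucket.sort()
        self.token_counts = sorted({k[0] for k in self._buckets})

    def __len__(self) -> int:
        return len(self.term_codes)

    def __contains__(self, term: str) -> bool:
        return term in self.term_codes

    def terms(self) -> list[str]:
        return sorted(self.term_codes)

    def bucket(self, n_tokens: int, first_char: str) -> Sequence[str]:
        return self._buckets.get((n_tokens, first_char), ())


def _subphrases(toks: Sequence[str]) -> set[tuple[str, ...]]:
    out: set[tuple[str, ...]] = set()
    n = len(toks)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if (i, j) == (0, n):
                continue
            out.add(tuple(toks[i:j]))
    return out


def indexable_subphrase(toks: Sequence[str]) -> bool:
    """Whether a proper sub-phrase carries diagnostic content of its own."""
    if not toks:
        return False
    if toks[0] in FUNCTION_WORDS or toks[-1] in FUNCTION_WORDS:
        return False
    return any(t not in STOP_TERMS for t in toks)


def build_term_index(lexicon: Lexicon) -> TermIndex:
    """Build the matchable term set from lexicon descriptions and synonyms."""
    if len(lexicon) == 0:
        raise ValueError("cannot build a term index from an empty lexicon")
    term_codes: dict[str, set[str]] = {}

    def add(term: str, code: str) -> None:
        if len(term) >= MIN_TERM_LEN:
            term_codes.setdefault(term, set()).add(code)

    for entry in lexicon:
        desc = normalize(entry.description)
        if desc:
            add(desc, entry.code)
            toks = desc.split()
            for sub in _subphrases(toks):
                if indexable_subphrase(sub):
                    add(" ".join(sub), entry.code)
        for syn in entry.synonyms:
            syn_norm = normalize(syn)
            if syn_norm:
                add(syn_norm, entry.code)
    return TermIndex({t: frozenset(c) for t, c in term_codes.items()})


def _term_threshold(term: str, max_edit_fraction: float) -> int:
    if len(term) < MIN_FUZZY_LEN:
        return 0
    return min(MAX_EDITS, floor(max_edit_fraction * len(term)))


def detect_mentions(
    campaign: Campaign, index: TermIndex, max_edit_fraction: float = 0.3
) -> list[DiagnosisMention]:
    """Detect non-overlapping diagnosis mentions in one campaign.

    Matching is case-insensitive and token-boundary aligned.  A window of
    tokens matches an indexed term when their edit distance is at most
    ``floor(max_edit_fraction * len(term))``, capped at 2 edits and disabled
    entirely for terms shorter than 6 characters.  Overlaps are resolved
    left to right, preferring the longest span, then the smallest edit
    distance, then the lexicographically smallest term.
    """
    if not 0 <= max_edit_fraction <= 0.4:
        raise ValueError("max_edit_fraction must be in [0, 0.4]")
    spans = token_spans(campaign.text)
    if not spans:
        return []

    candidates: dict[tuple[int, int], tuple[int, str]] = {}
    for t in index.token_counts:
        for i in range(len(spans) - t + 1):
            window = [s[2] for s in spans[i : i + t]]
            window_norm = " ".join(window)
            start, end = spans[i][0], spans[i + t - 1][1]
            best = candidates.get((start, end))
            if window_norm in index:
                if best is None or (0, window_norm) < best:
                    candidates[(start, end)] = (0, window_norm)
                continue
            if max_edit_fraction == 0 or not window_norm:
                continue
            for term in index.bucket(t, window_norm[0]):
                k = _term_threshold(term, max_edit_fraction)
                if k == 0 or abs(len(term) - len(window_norm)) > k:
                    continue
                d = osa_distance(window_norm, term, max_dist=k)
                if d <= k and (best is None or (d, term) < best):
                    best = (d, term)
            if best is not None:
                candidates[(start, end)] = best

    ordered = sorted(
        candidates.items(), key=lambda kv: (kv[0][0], -(kv[0][1] - kv[0][0]), kv[1])
    )
    mentions: list[DiagnosisMention] = []
    taken: list[tuple[int, int]] = []
    for (start, end), (dist, term) in ordered:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        mentions.append(
            DiagnosisMention(
                campaign_id=campaign.campaign_id,
                start=start,
                end=end,
                surface=campaign.text[start:end],
                matched_term=term,
                edit_distance=dist,
            )
        )
    mentions.sort(key=lambda m: m.start)
    return mentions
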