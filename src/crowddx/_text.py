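"""Shared text primitives: normalization, tokenization, edit distance.

Every stage that compares strings (term indexing, mention detection, code
resolution) goes through :func:`normalize` so that case, punctuation and
whitespace never influence a match.

The edit distance is the optimal-string-alignment (OSA) variant of the
Damerau–Levenshtein distance: substitutions, insertions, deletions and
transpositions of adjacent characters each cost 1.  Transpositions matter for
lay medical spelling — "aneruism" is two edits from "aneurysm" (one
transposition plus one substitution), not three.
"""

from __future__ import annotations

import re
from typing import Iterator

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_TOKEN_RE_RAW = re.compile(r"[A-Za-z0-9]+")
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


def normalize(text: str) -> str:
    """Lowercase, replace punctuation with spaces, collapse whitespace."""
    return _NON_ALNUM_RE.sub(" ", text.lower()).strip()


def tokens(text: str) -> list[str]:
    """Tokens of a normalized string."""
    return _TOKEN_RE.findall(text.lower())


def token_spans(text: str) -> list[tuple[int, int, str]]:
    """``(start, end, lowercased token)`` for every token of raw ``text``.

    Offsets are 0-based, half-open, into the *original* string, so that a
    span of consecutive tokens can be mapped back to the exact surface form.
    """
    return [(m.start(), m.end(), m.group(0).lower()) for m in _TOKEN_RE_RAW.finditer(text)]


def osa_distance(a: str, b: str, max_dist: int | None = None) -> int:
    """Damerau–Levenshtein distance, optimal-string-alignment variant.

    Parameters
    ----------
    a, b:
        The strings to compare.
    max_dist:
        Early-abandon bound.  When the true distance exceeds ``max_dist`` a
        value ``> max_dist`` is returned (not necessarily the exact
        distance), which is all a thresholded caller needs.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if max_dist is not None and abs(la - lb) > max_dist:
        return max_dist + 1
    if la == 0:
        return lb
    if lb == 0:
        return la

    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        row_min = i
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and ca == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)  # type: ignore[index]
            cur[j] = d
            if d < row_min:
                row_min = d
        if max_dist is not None and row_min > max_dist:
            return max_dist + 1
        prev2, prev = prev, cur
    return prev[lb]


def ngrams(text: str, n: int = 3) -> Iterator[str]:
    """Sliding character n-grams of ``text`` (no padding)."""
    for i in range(len(text) - n + 1):
        yield text[i : i + n]
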