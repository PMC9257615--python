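"""Entity resolution: link a diagnosis mention to its best ICD-10-CM code.

A mention's surface form is scored against every lexicon entry's textual
forms (description plus lay synonyms) and the highest-scoring codes are
returned.  The shipped scorer is cosine similarity between character-trigram
count vectors of the normalized strings — symmetric, 1.0 exactly on identical
normalized strings, and tolerant of the character-level misspellings typical
of crowdfunding text.  The scorer is a swappable contract: any callable
``(str, str) -> float`` (e.g. an embedding similarity) can be substituted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import sqrt
from typing import Callable

from ._text import ngrams, normalize
from .detector import DiagnosisMention
from .lexicon import Lexicon

Scorer = Callable[[str, str], float]


@dataclass(frozen=True)
class ResolvedCode:
    """One candidate code for a mention, with its similarity score and rank."""

    mention: DiagnosisMention
    code: str
    score: float
    rank: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")
        if self.rank < 1:
            raise ValueError("rank is 1-based")


def _trigram_vector(text: str) -> Counter[str]:
    return Counter(ngrams(text, 3))


def similarity(a: str, b: str) -> float:
    """Cosine similarity of character-trigram count vectors.

    Inputs are normalized (lowercased, punctuation-stripped) before
    comparison; identical normalized strings score exactly 1.0.
    """
    na, nb = normalize(a), normalize(b)
    if not na or not nb:
        raise ValueError("similarity requires non-empty normalized strings")
    if na == nb:
        return 1.0
    va, vb = _trigram_vector(na), _trigram_vector(nb)
    if not va or not vb:
        return 0.0
    dot = sum(cnt * vb[g] for g, cnt in va.items())
    if dot == 0:
        return 0.0
    norm = sqrt(sum(c * c for c in va.values())) * sqrt(sum(c * c for c in vb.values()))
    return dot / norm


def _entry_score(surface: str, entry_texts: tuple[str, ...], scorer: Scorer) -> float:
    return max(scorer(surface, t) for t in entry_texts)


def resolve(
    mention: DiagnosisMention,
    lexicon: Lexicon,
    top_k: int = 1,
    scorer: Scorer = similarity,
) -> list[ResolvedCode]:
    """Top-``k`` codes for a mention by descending similarity.

    Ties are broken by shorter code, then lexicographic code, so the ranking
    is deterministic and invariant to lexicon row order.  Rank 1 is the code
    that flows into disease categorization.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(lexicon) == 0:
        raise ValueError("cannot resolve against an empty lexicon")
    scored: list[tuple[float, int, str]] = []
    for entry in lexicon:
        texts = (entry.description, *entry.synonyms)
        score = _entry_score(mention.surface, texts, scorer)
        scored.append((score, len(entry.code), entry.code))
    scored.sort(key=lambda s: (-s[0], s[1], s[2]))
    return [
        ResolvedCode(mention=mention, code=code, score=score, rank=i + 1)
        for i, (score, _, code) in enumerate(scored[:top_k])
    ]
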