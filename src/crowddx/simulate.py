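"""Synthetic crowdfunding-campaign corpora with known ground truth.

Real medical crowdfunding text cannot be redistributed, so every stage of
the pipeline is exercised against generated campaigns that emulate the
register and failure modes of that corpus: first-person family narration,
diagnosis phrases drawn from lexicon descriptions, character-level
misspellings (substitution, deletion, adjacent transposition — never the
first character), treatment-only mentions expressed through keyword phrases
with no stated diagnosis, and multi-category co-occurrence.

Each campaign carries its ground-truth category labels and the list of
planted surface forms, so end-to-end precision/recall of the identification
pipeline is measurable exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._text import normalize
from .lexicon import CATEGORIES, OTHER, Lexicon, bundled_lexicon
from .rules import KeywordRule, default_rules

MECH_DIAGNOSIS = "diagnosis"
MECH_KEYWORD = "keyword"

_NAMES = ("Sarah", "Alex", "Jordan", "Rachel", "David", "Emily", "Chris", "Anna", "James", "Laura")
_RELATIONS = (
    "husband", "wife", "mother", "father", "son", "daughter",
    "sister", "brother", "cousin", "friend",
)
_INTROS = (
    "Hello everyone, my name is {name} and I am starting this fundraiser for my {relation}.",
    "Thank you for taking a moment to visit this page and read our story.",
    "Our family has been through so much over these past few months.",
)
_FILLERS = (
    "The medical bills have been piling up faster than we can manage.",
    "Every donation, no matter the size, means the world to us.",
    "Please consider sharing this page with your friends and loved ones.",
    "We are so grateful for all of the kindness shown to us so far.",
    "Any support will go directly toward care costs and travel expenses.",
)
_DIAGNOSIS_SENTENCES = (
    "Earlier this year the doctors told us it was {term}.",
    "After many tests, the specialists confirmed {term}.",
    "My {relation} was recently diagnosed with {term}.",
    "It turned out to be {term}, and everything changed overnight.",
)
_KEYWORD_SENTENCES = (
    "The care team says that {term} is the only option left.",
    "She will need to begin {term} very soon.",
    "He has already been through several rounds of {term}.",
    "The next step on this journey is {term}.",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    ``prevalence`` is the per-category base probability; when any category is
    drawn, the remaining categories' *odds* are multiplied by
    ``cooccurrence_boost`` (1.0 = independent labels).
    ``misspelling_rate`` is the expected number of character edits per
    planted diagnosis phrase (0–2); ``keyword_only_prob`` is the chance a
    planted category is expressed only through a treatment/procedure keyword.
    """

    n_campaigns: int = 500
    prevalence: tuple[float, ...] = field(default_factory=lambda: (0.10,) * 11)
    cooccurrence_boost: float = 2.0
    misspelling_rate: float = 0.5
    keyword_only_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prevalence) != len(CATEGORIES):
            raise ValueError("prevalence must give one probability per category")
        if not all(0.0 <= p <= 1.0 for p in self.prevalence):
            raise ValueError("prevalence values must lie in [0, 1]")
        if not 0.0 <= self.misspelling_rate <= 2.0:
            raise ValueError("misspelling_rate must lie in [0, 2]")
        if not 0.0 <= self.keyword_only_prob <= 1.0:
            raise ValueError("keyword_only_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticCampaign:
    """A generated campaign with its ground truth."""

    campaign_id: str
    text: str
    truth_labels: tuple[bool, ...]  # aligned with CATEGORIES
    planted: tuple[tuple[str, str, str], ...]  # (category, surface, mechanism)

    def __post_init__(self) -> None:
        for category, surface, _ in self.planted:
            if surface not in self.text:
                raise ValueError(f"planted surface {surface!r} missing from text")
        planted_cats = {c for c, _, _ in self.planted}
        for cat, flag in zip(CATEGORIES, self.truth_labels):
            if flag and cat not in planted_cats:
                raise ValueError(f"true label {cat} has no planted evidence")


def corrupt(term: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply ``n_edits`` random character edits to a diagnosis phrase.

    Edits (substitute, delete, transpose adjacent letters) touch only
    alphabetic positions and never the first character, mimicking the way
    lay authors misspell the middle of a medical word.  Edit sites are kept
    at least two characters apart so the edits compose independently and the
    resulting optimal-string-alignment distance to the source never exceeds
    ``n_edits`` (overlapping edits can otherwise collapse into a pattern the
    OSA metric charges extra for).  Phrases shorter than 6 characters are
    returned unchanged with a warning.
    """
    if n_edits < 0 or n_edits > 2:
        raise ValueError("n_edits must be 0, 1 or 2")
    if len(term) < 6:
        if n_edits:
            warnings.warn(f"term {term!r} too short to corrupt; returned unchanged")
        return term

    ops: list[tuple[int, str]] = []
    for i in range(1, len(term)):
        if term[i].isalpha():
            ops.append((i, "substitute"))
            ops.append((i, "delete"))
            if i + 1 < len(term) and term[i + 1].isalpha() and term[i] != term[i + 1]:
                ops.append((i, "transpose"))

    chosen: list[tuple[int, str]] = []
    for _ in range(n_edits):
        candidates = [
            (i, op)
            for i, op in ops
            if all(abs(i - j) > 2 for j, _ in chosen)
        ]
        if not candidates:
            break
        chosen.append(candidates[rng.integers(len(candidates))])

    chars = list(term)
    for i, op in sorted(chosen, reverse=True):
        if op == "substitute":
            alphabet = [c for c in "abcdefghijklmnopqrstuvwxyz" if c != chars[i].lower()]
            chars[i] = alphabet[rng.integers(len(alphabet))]
        elif op == "delete":
            del chars[i]
        else:
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def _boosted(p: float, boost: float) -> float:
    if p in (0.0, 1.0) or boost == 1.0:
        return p
    odds = boost * p / (1.0 - p)
    return odds / (1.0 + odds)


def generate(
    config: GeneratorConfig,
    lexicon: Lexicon | None = None,
    rules: list[KeywordRule] | None = None,
) -> list[SyntheticCampaign]:
    """Generate a labeled corpus under the configured study conditions."""
    lexicon = lexicon or bundled_lexicon()
    if len(lexicon) == 0:
        raise ValueError("generation requires a non-empty lexicon")
    rules = default_rules() if rules is None else rules
    rng = np.random.default_rng(config.seed)

    if all(p == 0.0 for p in config.prevalence) and config.n_campaigns > 0:
        warnings.warn("all prevalences are zero: generating an all-negative corpus")

    by_category: dict[str, list] = {c: [] for c in CATEGORIES}
    for entry in lexicon:
        if entry.disease_category != OTHER:
            by_category[entry.disease_category].append(entry)
    patterns_by_category: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for rule in rules:
        if rule.disease_category in patterns_by_category:
            patterns_by_category[rule.disease_category].append(rule.pattern)

    campaigns: list[SyntheticCampaign] = []
    for i in range(config.n_campaigns):
        drawn: list[str] = []
        boosted = False
        for cat, p in zip(CATEGORIES, config.prevalence):
            p_eff = _boosted(p, config.cooccurrence_boost) if boosted else p
            if by_category[cat] and rng.random() < p_eff:
                drawn.append(cat)
                boosted = True

        name = _NAMES[rng.integers(len(_NAMES))]
        relation = _RELATIONS[rng.integers(len(_RELATIONS))]
        sentences = [
            _INTROS[rng.integers(len(_INTROS))].format(name=name, relation=relation),
            _FILLERS[rng.integers(len(_FILLERS))],
        ]
        planted: list[tuple[str, str, str]] = []
        for cat in drawn:
            use_keyword = (
                patterns_by_category[cat]
                and rng.random() < config.keyword_only_prob
            )
            if use_keyword:
                pats = patterns_by_category[cat]
                surface = pats[rng.integers(len(pats))]
                template = _KEYWORD_SENTENCES[rng.integers(len(_KEYWORD_SENTENCES))]
                mechanism = MECH_KEYWORD
            else:
                entries = by_category[cat]
                entry = entries[rng.integers(len(entries))]
                surface = normalize(entry.description)
                n_edits = int(rng.binomial(2, config.misspelling_rate / 2.0))
                if n_edits:
                    surface = corrupt(surface, n_edits, rng)
                template = _DIAGNOSIS_SENTENCES[rng.integers(len(_DIAGNOSIS_SENTENCES))]
                mechanism = MECH_DIAGNOSIS
            sentences.append(template.format(term=surface, relation=relation))
            planted.append((cat, surface, mechanism))
        sentences.append(_FILLERS[rng.integers(len(_FILLERS))])

        truth = tuple(cat in drawn for cat in CATEGORIES)
        campaigns.append(
            SyntheticCampaign(
                campaign_id=f"syn{i:05d}",
                text=" ".join(sentences),
                truth_labels=truth,
                planted=tuple(planted),
            )
        )
    return campaigns


def campaigns_frame(campaigns: list[SyntheticCampaign]) -> pd.DataFrame:
    """``campaign_id,text`` frame ready for the identification pipeline."""
    return pd.DataFrame(
        {"campaign_id": [c.campaign_id for c in campaigns], "text": [c.text for c in campaigns]}
    )


def truth_frame(campaigns: list[SyntheticCampaign]) -> pd.DataFrame:
    """Ground-truth 0/1 label frame (campaign_id + one column per category)."""
    data = {"campaign_id": [c.campaign_id for c in campaigns]}
    for j, cat in enumerate(CATEGORIES):
        data[cat] = [int(c.truth_labels[j]) for c in campaigns]
    return pd.DataFrame(data)
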