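"""Term indexing and spell-tolerant mention detection."""

import re

import pytest

from crowddx import (
    Campaign,
    Lexicon,
    LexiconEntry,
    build_term_index,
    detect_mentions,
)
from crowddx._text import normalize
from crowddx.detector import MIN_TERM_LEN, indexable_subphrase
from crowddx.simulate import GeneratorConfig, generate


def test_index_contains_descriptions_synonyms_and_subphrases(index):
    assert "cerebral aneurysm nonruptured" in index  # full description
    assert "brain aneurysm" in index  # lay synonym
    assert "myeloid leukemia" in index  # informative sub-phrase
    assert "cerebral aneurysm" in index


def test_index_drops_generic_and_anatomy_only_subphrases(index):
    for term in ("left", "right female", "initial encounter", "kidney", "heart", "unspecified"):
        assert term not in index
    # ...but keeps generic-word phrases when they are the full lexicon text
    assert "end stage renal disease" in index


def test_index_terms_have_minimum_length_and_code_links(index, lexicon):
    codes = {e.code for e in lexicon}
    for term in index.terms():
        assert len(term) >= MIN_TERM_LEN
        assert index.term_codes[term] <= codes
        assert index.term_codes[term]


def test_shared_description_links_to_both_codes():
    lex = Lexicon(
        [
            LexiconEntry("C8200", "Follicular lymphoma grade I", "Lymphoma", "neoplasms"),
            LexiconEntry("C8201", "Follicular lymphoma grade I", "Lymphoma", "neoplasms"),
        ]
    )
    idx = build_term_index(lex)
    assert idx.term_codes["follicular lymphoma grade i"] == {"C8200", "C8201"}


def test_every_informative_subphrase_is_indexed(index, lexicon):
    """Exhaustive enumeration over fixture descriptions."""
    for entry in lexicon:
        toks = normalize(entry.description).split()
        for i in range(len(toks)):
            for j in range(i + 1, len(toks) + 1):
                sub = toks[i:j]
                phrase = " ".join(sub)
                if len(phrase) < MIN_TERM_LEN:
                    continue
                if (i, j) != (0, len(toks)) and not indexable_subphrase(sub):
                    continue
                assert phrase in index, phrase


def test_empty_lexicon_rejected():
    with pytest.raises(ValueError):
        build_term_index(Lexicon([]))


def test_misspelled_aneurysm_detected(index):
    campaign = Campaign("a", "Two weeks ago she suffered a brain aneruism at home.")
    mentions = detect_mentions(campaign, index, 0.3)
    hit = [m for m in mentions if m.matched_term == "brain aneurysm"]
    assert len(hit) == 1
    assert hit[0].surface == "brain aneruism"
    assert hit[0].edit_distance == 2


def test_misspelled_leukemia_detected(index):
    campaign = Campaign("b", "He was diagnosed with myeloid lukemia last spring.")
    mentions = detect_mentions(campaign, index, 0.3)
    assert any("leukemia" in m.matched_term for m in mentions)


def test_empty_text_yields_no_mentions(index):
    assert detect_mentions(Campaign("c", ""), index) == []
    assert detect_mentions(Campaign("d", "!!! ... ???"), index) == []


def test_edit_fraction_out_of_range_rejected(index):
    with pytest.raises(ValueError):
        detect_mentions(Campaign("e", "text"), index, 0.5)


def exact_scan(campaign, index):
    """Independent oracle: exact phrase scan over token windows + greedy pick."""
    spans = [(m.start(), m.end(), m.group(0).lower()) for m in re.finditer(r"[A-Za-z0-9]+", campaign.text)]
    terms = set(index.terms())
    max_tokens = max((len(t.split()) for t in terms), default=0)
    candidates = []
    for t in range(1, max_tokens + 1):
        for i in range(len(spans) - t + 1):
            phrase = " ".join(s[2] for s in spans[i : i + t])
            if phrase in terms:
                start, end = spans[i][0], spans[i + t - 1][1]
                candidates.append((start, -(end - start), 0, phrase))
    picked = []
    for start, neg_len, dist, phrase in sorted(candidates):
        end = start - neg_len
        if all(not (start < e and s < end) for s, e in picked):
            picked.append((start, end))
    return sorted(picked)


def test_zero_tolerance_equals_exact_phrase_scan(index, clf):
    corpus = generate(
        GeneratorConfig(n_campaigns=100, misspelling_rate=0.6, keyword_only_prob=0.2, seed=9)
    )
    for c in corpus:
        campaign = Campaign(c.campaign_id, c.text)
        got = sorted((m.start, m.end) for m in detect_mentions(campaign, index, 0.0))
        assert got == exact_scan(campaign, index)


def test_mentions_never_overlap_and_offsets_round_trip(index):
    corpus = generate(
        GeneratorConfig(n_campaigns=60, misspelling_rate=1.0, keyword_only_prob=0.2, seed=10)
    )
    for c in corpus:
        campaign = Campaign(c.campaign_id, c.text)
        mentions = detect_mentions(campaign, index, 0.3)
        for m in mentions:
            assert campaign.text[m.start : m.end] == m.surface
            assert 0 <= m.start < m.end <= len(campaign.text)
        spans = sorted((m.start, m.end) for m in mentions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


def test_raising_tolerance_never_drops_mentions(index):
    corpus = generate(
        GeneratorConfig(n_campaigns=60, misspelling_rate=1.0, keyword_only_prob=0.2, seed=11)
    )
    for c in corpus:
        campaign = Campaign(c.campaign_id, c.text)
        low = {(m.start, m.end) for m in detect_mentions(campaign, index, 0.15)}
        high = {(m.start, m.end) for m in detect_mentions(campaign, index, 0.3)}
        assert low <= high


def test_short_terms_never_fuzzy_matched(index):
    # "crohn" is indexed (5 chars) but below the fuzzy floor: 1-edit variants miss
    campaign = Campaign("f", "They suspect crohm according to the clinic.")
    assert all(
        m.matched_term != "crohn" for m in detect_mentions(campaign, index, 0.3)
    )
    exact = detect_mentions(Campaign("g", "They suspect crohn."), index, 0.3)
    assert any(m.matched_term == "crohn" and m.edit_distance == 0 for m in exact)
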