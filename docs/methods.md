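# Methods

## Problem and model

`crowddx` treats disease identification in crowdfunding text as multi-label
classification over 11 system-level disease categories. Categories are
mutually inclusive: one campaign can (and often does) mention several
conditions, so each category is an independent binary label. The pipeline
is entirely rule- and similarity-based — there is no training step — which
is why the scikit-learn estimator's `fit` only validates inputs and builds
the term index.

Three assumptions shape the design:

* **A diagnosis mention is a contiguous token span** resembling a known
  diagnosis phrase up to small character-level errors. Negation, hedging and
  historical mentions are *not* modelled: "does not have cancer" still
  flags neoplasms. This mirrors how lay campaign text rarely negates the
  condition the campaign is about, but it is a real failure mode for other
  corpora.
* **A treatment implies a disease category.** The keyword path encodes a
  small, curated implication table (dialysis → genitourinary, …). It is
  literal by construction: inflections outside the enumerated alternates
  ("crashing") deliberately do not fire, because an open-ended stemmer
  would trade precision for coverage in uncontrolled ways. Users extend
  coverage through the rules CSV instead.
* **ICD-10-CM prefixes are semantically coherent.** The recoder's trimming
  step assumes that codes sharing a stem share a disease category often
  enough that the modal category of prefix matches is the right inheritance
  rule.

## Pipeline stages and parameters

**Term index.** Full code descriptions and lay synonyms are always indexed.
Contiguous sub-phrases of descriptions are indexed only when they carry
diagnostic content: a sub-phrase is dropped if every token is a function
word, a generic clinical qualifier ("unspecified", "initial encounter",
"left") or a bare anatomical site ("kidney", "heart"), or if it starts/ends
with a function word. Rationale: a bare organ or qualifier is not a
diagnosis, and indexing them floods the detector with false spans (any
sentence containing "heart" would otherwise flag cardiovascular disease).
Indexed terms are at least 4 characters.

**Detector.** `max_edit_fraction` (default 0.3, admissible range [0, 0.4])
sets the spelling tolerance: a window matches a term when their
optimal-string-alignment (OSA) Damerau–Levenshtein distance is at most
⌊`max_edit_fraction` · |term|⌋, capped at 2 edits and disabled for terms
under 6 characters. The cap and floor keep short terms from matching
unrelated words; 0.3 admits the classic 1–2-edit lay misspellings
("aneruism", "lukemia") on realistic term lengths. Transpositions count as
one edit because swapped adjacent letters are among the most common lay
spelling errors. Candidate generation blocks on token count and first
character (misspellings of medical words rarely corrupt the initial
letter); verification uses a bounded OSA computation with early abandon.
Overlaps are resolved left to right with a fixed tie-break — longest span,
then smallest edit distance, then lexicographically smallest term — so
output is deterministic.

**Resolver.** Similarity is cosine between character-trigram count vectors
of the normalized strings (lowercased, punctuation stripped, whitespace
collapsed); identical normalized strings score exactly 1.0, and strings
with no common trigram score 0. An entry's score is the maximum over its
description and synonyms, since lay phrasings ("heart attack") legitimately
name the code. Ties at equal score break by shorter code, then
lexicographic code, making rank-1 invariant to lexicon row order. Only the
rank-1 code flows into categorization. The scorer is a plain
`(str, str) -> float` contract so an embedding similarity can be dropped in.

**Recoder.** The untrimmed code is tried as a prefix first (k = 0): a bare
stem that strictly prefixes table codes should inherit their category with
zero trims, which also subsumes the trim-first reading whenever trimming
would be needed. Modal-category ties are broken by the fixed category
priority order (the canonical category listing) and flagged in the result.
Codes that exhaust every prefix without a match are dropped downstream with
a warning — there is no principled category to assign.

**Category merge.** `OTHER`-category codes are removed after recoding and
before merging with keyword flags. Multiple codes in one category collapse
into a single present flag with all evidence retained; provenance is
`ner`, `keyword`, or `both` per campaign × category.

**Evaluation.** Wald 95% intervals are used *unclipped*: a proportion near
1 on a small sample honestly reports an upper bound above 1, and clipping
would silently change the stated coverage. Each metric's interval uses its
own denominator (predicted positives for precision, reference positives
for recall, all evaluated campaigns for accuracy). Weighted averages use
the per-category reference-positive counts as weights. Precision is left
undefined — not set to 0 — when a category is never predicted. Cohen κ uses
marginal-product chance agreement and is undefined when chance agreement
is 1. Annotator reconciliation is supported as a report
(`annotator_discrepancies`), not an algorithm: disagreements are for humans
to adjudicate.

## Synthetic corpus

The generator emulates the features of crowdfunding text the pipeline must
survive: first-person family narration (template bank), diagnosis phrases
planted verbatim from lexicon descriptions, bounded misspellings,
treatment-only mentions (keyword phrases with no diagnosis), and
multi-category co-occurrence. Defaults — 500 campaigns, per-category
prevalence 0.10, co-occurrence odds boost 2.0, misspelling rate 0.5
expected edits per planted phrase, keyword-only probability 0.15 — were
chosen once as a desk-scale rendering of those conditions: prevalences low
enough for realistic class imbalance but high enough that every category
accumulates double-digit positives at n=500, and a boost above 1 because
campaigns mentioning one condition disproportionately mention others.

Corruption applies substitution, deletion or adjacent transposition at
alphabetic positions, never the first character, with edit sites kept at
least two characters apart so the edits compose independently and the OSA
distance to the source never exceeds the number of edits (overlapping
edits can otherwise collapse into patterns the OSA metric charges extra
for). Template vocabulary is screened against the bundled diagnosis
vocabulary and keyword patterns so filler text plants no accidental
matches.

What passing synthetic tests does **not** show: robustness to informal
synonyms absent from the lexicon, negated or incidental mentions, grammar
far from the template register, or the coverage of a full-scale grouping
table — the bundled lexicon is a 60-code miniature, and real corpora
require the user to supply a complete code/category table.

## Numerical and degenerate-input choices

* Edit distance: pure-Python OSA dynamic programming with an early-abandon
  bound; strings compared are short (≤ ~70 characters), so no approximate
  prefilter is needed.
* Normalization is shared by every string-comparing stage, so case and
  punctuation can never cause asymmetric behaviour between stages.
* Empty campaign text yields an all-absent row set, not an error; an empty
  rule list is valid; an empty lexicon is an error for index building and
  resolution (there is nothing to match against) but valid for loading.
* Co-occurrence cells with an empty denominator are omitted rather than
  reported as 0%, keeping "no evidence" distinct from "evidence of zero".
* All randomness flows through one `numpy` generator seeded from the
  corpus config; identical configs produce byte-identical corpora.

## Known limitations

* Dictionary detection cannot find conditions phrased with vocabulary
  absent from the lexicon (the flip side of its precision); the detector
  contract exists precisely so a learned model can replace it.
* First-character blocking misses misspellings that corrupt a term's first
  letter.
* One category per code: cross-listed clinical categories are collapsed to
  a single disease category by design.
* Accuracy on imbalanced labels is optimistic; it is reported because the
  evaluation convention calls for it, but precision/recall/F1 are the
  informative numbers.
* The chapter-based default category map approximates the full
  clinical-category reassignment tables; users with access to a complete
  CCSR-derived mapping should supply it as data (lexicon CSV or scheme
  reassignments) rather than rely on the shipped approximation.
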