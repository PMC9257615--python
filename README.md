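# crowddx

Multi-label disease-category identification for medical crowdfunding
campaign text.

Medical crowdfunding descriptions are unstructured, first-person prose full
of misspelled diagnoses ("brain aneruism", "myeloid lukemia") and
treatment-only phrasings ("she starts dialysis next week") — yet health
services researchers need to know *which conditions* a campaign is about.
`crowddx` implements a disease identification algorithm for this setting:
it detects diagnosis mentions with spelling tolerance, links them to
ICD-10-CM codes, groups codes into 11 mutually inclusive disease categories
(cardiovascular, endocrine, gastrointestinal, genitourinary, infections,
injuries and external causes, mental health, musculoskeletal, neoplasms,
nervous system, respiratory), augments the result with a treatment/procedure
keyword search, and evaluates the resulting multi-label classification
against a manually annotated reference.

## The algorithm

For each campaign, two evidence paths run in parallel and merge at the
category level:

1. **NER path.** A spell-tolerant dictionary detector finds diagnosis spans:
   token windows matching an indexed diagnosis term within Damerau–Levenshtein
   distance ⌊`max_edit_fraction` · |term|⌋ (capped at 2 edits; exact-only for
   terms under 6 characters). Each mention is resolved to its best ICD-10-CM
   code by cosine similarity of character-trigram count vectors between the
   mention surface and code descriptions/synonyms. Codes missing from the
   grouping table are aligned by *prefix trimming*: the code is shortened one
   character at a time until some table code starts with the remaining stem,
   and it inherits the modal disease category of the matches (e.g. the bare
   stem `C5091` inherits *neoplasms* from `C50911`/`C50912`/`C50919`). Codes
   mapping to the catch-all `OTHER` category are dropped.
2. **Keyword path.** A literal, word-boundary word search for treatments and
   procedures that imply a category without stating a diagnosis
   (*chemotherapy* → neoplasms, *dialysis* → genitourinary, *accident* →
   injuries, …; 21 patterns across 6 categories, user-extensible via CSV).

Every positive campaign × category flag keeps its provenance (`ner`,
`keyword`, or `both`) and evidence, supporting corpus-level contribution
breakdowns and NER-vs-keyword co-occurrence grids.

Evaluation follows standard per-category binary conventions: precision,
recall, F1 and accuracy with unclipped 95% Wald intervals
(p ± 1.96·√(p(1−p)/n), where n is the metric's own denominator),
count-weighted averages across categories, and Cohen κ
((p_o − p_e)/(1 − p_e)) for inter-annotator agreement.

Both the detector and the resolution scorer are swappable contracts, so a
learned NER model or an embedding similarity can replace the shipped
dictionary machinery without touching the rest of the pipeline.

## Worked example

```python
import crowddx as cx

clf = cx.DiseaseCategoryClassifier().fit()   # packaged miniature lexicon + rules
text = ("Two weeks ago my wife suffered a brain aneruism. "
        "This disease resulted in my kidneys failing and having to start dialysis.")
print(clf.identify([cx.Campaign("demo-001", text)]).query("present"))
```

```
campaign_id disease_category  present  source    evidence
   demo-001   cardiovascular     True     ner     (I671,)
   demo-001    genitourinary     True keyword (dialysis,)
```

The misspelled "brain aneruism" is matched to the lay synonym *brain
aneurysm* at edit distance 2, resolved to ICD-10-CM `I671` (cerebral
aneurysm, nonruptured), and grouped as cardiovascular; "dialysis" states no
diagnosis but the keyword path flags genitourinary disease. `clf.predict`
returns the same result as a binary matrix aligned with `clf.classes_`:

```python
clf.predict([text])        # [[1 0 0 1 0 0 0 0 0 0 0]]
cx.recode("C5091", clf.lexicon_).disease_category   # 'neoplasms' via prefix trimming
```

The estimator is scikit-learn compatible (`get_params`/`set_params`/`clone`)
and a CLI mirrors the library:

```bash
crowddx simulate --n-campaigns 500 --seed 1 --out campaigns.jsonl --truth-out truth.csv
crowddx identify campaigns.jsonl --out assignments.csv
crowddx evaluate assignments.csv reference.csv --out metrics.csv
crowddx summarize campaigns.jsonl --contributions-out contrib.csv --cooccurrence-out cooc.csv
```

Because no crowdfunding text can be redistributed, the package ships a
synthetic-corpus generator (`crowddx.simulate`) that emulates the register
of such campaigns — planted diagnosis phrases, bounded character-level
misspellings, treatment-only mentions, multi-category co-occurrence — with
exact ground-truth labels, and a 60-code miniature lexicon spanning all
categories.

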