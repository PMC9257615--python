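"""End-to-end disease identification: text → mentions → codes → categories.

Two evidence paths run per campaign and are merged at the category level:

* the **NER path** — fuzzy mention detection, resolution of each mention to
  its best-matching ICD-10-CM code, prefix-trim recoding into the grouping
  table, mapping to a disease category (codes landing in ``OTHER`` are
  dropped before summarization);
* the **keyword path** — treatment/procedure word search implying a category
  directly.

Categories are mutually inclusive: a campaign may be positive for any subset
of the 11.  Every positive flag keeps its provenance (``ner``, ``keyword``
or ``both``) and its evidence (codes and/or matched patterns), which is what
the corpus-level contribution and co-occurrence summaries are computed from.

The user-facing surface is :class:`DiseaseCategoryClassifier`, a
scikit-learn estimator (``fit`` builds the term index from the lexicon and
rules; ``predict`` returns the n × 11 binary label matrix), so the pipeline
composes with sklearn model selection and pipelines.  The module-level
:func:`identify` is a thin functional wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .detector import Campaign, TermIndex, build_term_index, detect_mentions
from .lexicon import CATEGORIES, OTHER, Lexicon, bundled_lexicon, load_lexicon
from .recoder import MatchKind, recode
from .resolver import Scorer, resolve, similarity
from .rules import KeywordRule, apply_rules, default_rules, load_rules

logger = logging.getLogger("crowddx")

SOURCE_NER = "ner"
SOURCE_KEYWORD = "keyword"
SOURCE_BOTH = "both"


@dataclass(frozen=True)
class CategoryAssignment:
    """One campaign × category cell with provenance and evidence."""

    campaign_id: str
    disease_category: str
    present: bool
    source: str | None
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.present and not self.evidence:
            raise ValueError("a present category must carry evidence")
        if self.disease_category == OTHER:
            raise ValueError("final assignments never target OTHER")


def _coerce_campaigns(X) -> list[Campaign]:
    if isinstance(X, pd.DataFrame):
        if not {"campaign_id", "text"}.issubset(X.columns):
            raise ValueError("campaign frame needs columns campaign_id,text")
        return [
            Campaign(str(r.campaign_id), "" if pd.isna(r.text) else str(r.text))
            for r in X.itertuples(index=False)
        ]
    out: list[Campaign] = []
    for i, item in enumerate(X):
        if isinstance(item, Campaign):
            out.append(item)
        elif isinstance(item, str):
            out.append(Campaign(f"c{i:06d}", item))
        elif hasattr(item, "campaign_id") and hasattr(item, "text"):
            out.append(Campaign(str(item.campaign_id), str(item.text)))
        else:
            cid, text = item
            out.append(Campaign(str(cid), str(text)))
    return out


class DiseaseCategoryClassifier(BaseEstimator, ClassifierMixin):
    """Multi-label disease-category classifier for crowdfunding text.

    Parameters
    ----------
    lexicon:
        A :class:`~crowddx.lexicon.Lexicon`, a path to a lexicon CSV, or
        ``None`` for the packaged miniature lexicon.
    rules:
        Keyword rules (list, path to a rules CSV, or ``None`` for the
        shipped treatment/procedure set).
    max_edit_fraction:
        Spelling tolerance of the mention detector: allowed edits are
        ``floor(max_edit_fraction · term length)``, capped at 2.
    scorer:
        Similarity used by code resolution (default: character-trigram
        cosine).

    Attributes
    ----------
    classes_ : ndarray of shape (11,)
        The disease-category labels, in fixed order.
    lexicon_, rules_, index_ :
        The resolved lexicon, rule list and term index built by ``fit``.
    """

    def __init__(
        self,
        lexicon: Lexicon | str | Path | None = None,
        rules: Sequence[KeywordRule] | str | Path | None = None,
        max_edit_fraction: float = 0.3,
        scorer: Scorer | None = None,
    ):
        self.lexicon = lexicon
        self.rules = rules
        self.max_edit_fraction = max_edit_fraction
        self.scorer = scorer

    def fit(self, X=None, y=None) -> "DiseaseCategoryClassifier":
        """Resolve inputs and build the term index (no training step)."""
        if not 0 <= self.max_edit_fraction <= 0.4:
            raise ValueError("max_edit_fraction must be in [0, 0.4]")
        if isinstance(self.lexicon, Lexicon):
            self.lexicon_ = self.lexicon
        elif self.lexicon is None:
            self.lexicon_ = bundled_lexicon()
        else:
            self.lexicon_ = load_lexicon(self.lexicon)
        if self.rules is None:
            self.rules_ = default_rules()
        elif isinstance(self.rules, (str, Path)):
            self.rules_ = load_rules(self.rules)
        else:
            self.rules_ = list(self.rules)
        self.scorer_ = self.scorer or similarity
        self.index_: TermIndex = build_term_index(self.lexicon_)
        self.classes_ = np.asarray(CATEGORIES)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "index_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    def identify(self, X) -> pd.DataFrame:
        """Per-campaign assignments with provenance.

        Returns a long DataFrame with one row per campaign × category:
        ``campaign_id, disease_category, present, source, evidence``
        (evidence is a tuple of ICD-10-CM codes and/or matched patterns).
        """
        self._check_fitted()
        campaigns = _coerce_campaigns(X)
        stats = {"campaigns": len(campaigns), "mentions": 0, "resolved": 0,
                 "recode_exact": 0, "recode_prefix": 0, "recode_none": 0}
        rows: list[dict] = []
        for campaign in campaigns:
            ner_hits: dict[str, set[str]] = {}
            for mention in detect_mentions(campaign, self.index_, self.max_edit_fraction):
                stats["mentions"] += 1
                top = resolve(mention, self.lexicon_, top_k=1, scorer=self.scorer_)[0]
                stats["resolved"] += 1
                result = recode(top.code, self.lexicon_)
                stats[f"recode_{result.matched.value}"] += 1
                if result.matched is MatchKind.NONE:
                    logger.warning(
                        "campaign %s: code %s has no match in the grouping table; dropped",
                        campaign.campaign_id, top.code,
                    )
                    continue
                if result.disease_category == OTHER:
                    continue
                ner_hits.setdefault(result.disease_category, set()).add(top.code)
            kw_hits: dict[str, set[str]] = {}
            for category, pattern in apply_rules(campaign, self.rules_):
                if category != OTHER:
                    kw_hits.setdefault(category, set()).add(pattern)
            for category in CATEGORIES:
                codes = sorted(ner_hits.get(category, ()))
                patterns = sorted(kw_hits.get(category, ()))
                present = bool(codes or patterns)
                source = None
                if codes and patterns:
                    source = SOURCE_BOTH
                elif codes:
                    source = SOURCE_NER
                elif patterns:
                    source = SOURCE_KEYWORD
                rows.append(
                    {
                        "campaign_id": campaign.campaign_id,
                        "disease_category": category,
                        "present": present,
                        "source": source,
                        "evidence": tuple(codes) + tuple(patterns),
                    }
                )
        logger.info("identify: %s", stats)
        return pd.DataFrame(
            rows, columns=["campaign_id", "disease_category", "present", "source", "evidence"]
        )

    def predict(self, X) -> np.ndarray:
        """n × 11 binary label matrix, columns in ``classes_`` order."""
        assignments = self.identify(X)
        wide = to_wide(assignments)
        return wide[list(CATEGORIES)].to_numpy(dtype=int)


def to_wide(assignments: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long assignment table to a 0/1 campaign × category matrix."""
    wide = assignments.pivot(
        index="campaign_id", columns="disease_category", values="present"
    ).astype(int)
    # preserve first-seen campaign order and canonical category order
    order = assignments["campaign_id"].drop_duplicates()
    return wide.reindex(index=order, columns=list(CATEGORIES))


def identify(
    campaigns,
    lexicon: Lexicon | str | Path | None = None,
    rules: Sequence[KeywordRule] | str | Path | None = None,
    max_edit_fraction: float = 0.3,
) -> pd.DataFrame:
    """Functional wrapper: fit a classifier and return its assignment table."""
    clf = DiseaseCategoryClassifier(
        lexicon=lexicon, rules=rules, max_edit_fraction=max_edit_fraction
    ).fit()
    return clf.identify(campaigns)


def contribution_breakdown(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per category: how many positive campaigns each evidence path found.

    Each present campaign × category pair falls in exactly one bin — NER
    only, both, or keyword only — mirroring a stacked contribution chart.
    """
    present = assignments[assignments["present"]]
    rows = []
    for category in CATEGORIES:
        sub = present[present["disease_category"] == category]
        n_ner = int((sub["source"] == SOURCE_NER).sum())
        n_both = int((sub["source"] == SOURCE_BOTH).sum())
        n_kw = int((sub["source"] == SOURCE_KEYWORD).sum())
        total = n_ner + n_both + n_kw
        rows.append(
            {
                "disease_category": category,
                "n_total": total,
                "n_ner_only": n_ner,
                "n_both": n_both,
                "n_keyword_only": n_kw,
                "frac_ner_only": n_ner / total if total else np.nan,
                "frac_both": n_both / total if total else np.nan,
                "frac_keyword_only": n_kw / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cooccurrence_matrix(assignments: pd.DataFrame) -> pd.DataFrame:
    """Cross-path co-occurrence grid.

    Cell (r, c): of the campaigns where category ``r`` was flagged by the
    NER path, the percentage that also had category ``c`` flagged by the
    keyword path.  Cells with an empty denominator are omitted rather than
    reported as 0.
    """
    present = assignments[assignments["present"]]
    ner_sets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    kw_sets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for row in present.itertuples(index=False):
        if row.source in (SOURCE_NER, SOURCE_BOTH):
            ner_sets[row.disease_category].add(row.campaign_id)
        if row.source in (SOURCE_KEYWORD, SOURCE_BOTH):
            kw_sets[row.disease_category].add(row.campaign_id)
    cells = []
    for r in CATEGORIES:
        denominator = len(ner_sets[r])
        if denominator == 0:
            continue
        for c in CATEGORIES:
            numerator = len(ner_sets[r] & kw_sets[c])
            cells.append(
                {
                    "row_category": r,
                    "col_category": c,
                    "numerator": numerator,
                    "denominator": denominator,
                    "percentage": 100.0 * numerator / denominator,
                }
            )
    return pd.DataFrame(
        cells, columns=["row_category", "col_category", "numerator", "denominator", "percentage"]
    )
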