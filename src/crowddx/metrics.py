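"""Multi-label classification evaluation against a manually labeled reference.

Each of the 11 disease categories is evaluated as an independent binary
label: per-category confusion counts, precision, recall, F1 and accuracy
with 95% Wald (normal-approximation) confidence intervals, plus
count-weighted averages across categories and Cohen κ for inter-annotator
agreement.

Two conventions matter and are deliberate:

* Wald intervals are **not clipped** to [0, 1] — a proportion near 1 on a
  small sample legitimately reports an upper bound above 1 (e.g. 0.97 with
  n=35 gives 0.90–1.03).
* The CI sample size follows the metric's own denominator: predicted
  positives for precision, reference positives for recall, all evaluated
  campaigns for accuracy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from math import sqrt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import CATEGORIES

#: Reserved annotator id for the adjudicated consensus reference.
CONSENSUS = "consensus"

Z95 = 1.96


@dataclass(frozen=True)
class MetricsRow:
    """Per-category evaluation row (mirrors a standard performance table)."""

    disease_category: str
    n_reference_positive: int
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float
    precision_ci: tuple[float, float] | None
    recall_ci: tuple[float, float] | None
    accuracy_ci: tuple[float, float]


@dataclass(frozen=True)
class AgreementResult:
    """Cohen κ between two annotators for one category."""

    disease_category: str
    observed_agreement: float
    chance_agreement: float
    kappa: float | None


def wald_ci(p: float, n: int) -> tuple[float, float]:
    """95% Wald interval ``p ± 1.96·sqrt(p(1−p)/n)``, unclipped."""
    if n <= 0:
        raise ValueError("Wald CI requires n > 0")
    half = Z95 * sqrt(p * (1.0 - p) / n)
    return (p - half, p + half)


def _as_label_frame(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "campaign_id" in df.columns:
        df = df.set_index("campaign_id")
    return df


def confusion_counts(
    predicted: pd.DataFrame, reference: pd.DataFrame, category: str
) -> tuple[int, int, int, int]:
    """Per-category (tp, fp, fn, tn) over all evaluated campaigns.

    Both tables are 0/1 label frames with one column per category, indexed
    by (or carrying a column of) campaign ids; the id sets must coincide.
    """
    pred = _as_label_frame(predicted)
    ref = _as_label_frame(reference)
    missing = sorted(set(ref.index) ^ set(pred.index))
    if missing:
        raise ValueError(f"campaign id mismatch between tables: {missing}")
    p = pred.loc[ref.index, category].astype(bool)
    r = ref[category].astype(bool)
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    fn = int((~p & r).sum())
    tn = int((~p & ~r).sum())
    return tp, fp, fn, tn


def metrics_row(
    counts: tuple[int, int, int, int], total: int, disease_category: str = ""
) -> MetricsRow:
    """Precision/recall/F1/accuracy with 95% Wald CIs from confusion counts.

    ``tp+fp == 0`` leaves precision (and hence F1) undefined (``None``)
    rather than 0 — an algorithm that never fires a category has no
    measurable precision.
    """
    tp, fp, fn, tn = counts
    if tp + fp + fn + tn != total:
        raise ValueError("confusion counts do not sum to total")
    precision = precision_ci = None
    if tp + fp > 0:
        precision = tp / (tp + fp)
        precision_ci = wald_ci(precision, tp + fp)
    recall = recall_ci = None
    if tp + fn > 0:
        recall = tp / (tp + fn)
        recall_ci = wald_ci(recall, tp + fn)
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / total
    return MetricsRow(
        disease_category=disease_category,
        n_reference_positive=tp + fn,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        precision_ci=precision_ci,
        recall_ci=recall_ci,
        accuracy_ci=wald_ci(accuracy, total),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        raise ValueError("F1 undefined when precision + recall = 0")
    return 2 * precision * recall / (precision + recall)


def weighted_average(rows: Iterable[MetricsRow] | pd.DataFrame) -> tuple[float, float, float, float]:
    """Count-weighted (precision, recall, F1, accuracy) across categories.

    Weights are each category's number of reference-positive campaigns.
    Also accepts a DataFrame with columns ``n_reference_positive, precision,
    recall, f1, accuracy`` (e.g. a published performance table).
    """
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
        get = lambda r, k: r[k]  # noqa: E731
    else:
        records = list(rows)
        get = getattr
    weights = [get(r, "n_reference_positive") for r in records]
    if not records or sum(weights) == 0:
        raise ValueError("weighted average requires at least one positive reference count")
    out = []
    for key in ("precision", "recall", "f1", "accuracy"):
        vals = [get(r, key) for r in records]
        if any(v is None for v in vals):
            raise ValueError(f"{key} undefined for some categories; cannot average")
        out.append(sum(w * v for w, v in zip(weights, vals)) / sum(weights))
    return tuple(out)  # type: ignore[return-value]


def cohen_kappa(
    rater_a: Sequence[bool] | Sequence[int],
    rater_b: Sequence[bool] | Sequence[int],
    disease_category: str = "",
) -> AgreementResult:
    """Cohen κ for one category's binary labels from two annotators.

    Chance agreement is the marginal product ``p_e = p_A+·p_B+ + p_A−·p_B−``;
    κ is undefined (``None``) when ``p_e = 1``.
    """
    a = [bool(x) for x in rater_a]
    b = [bool(x) for x in rater_b]
    if len(a) != len(b) or not a:
        raise ValueError("raters must label the same non-empty item set")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa, pb = sum(a) / n, sum(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    kappa = None if p_e == 1.0 else (p_o - p_e) / (1 - p_e)
    return AgreementResult(
        disease_category=disease_category,
        observed_agreement=p_o,
        chance_agreement=p_e,
        kappa=kappa,
    )


def load_reference_labels(path: str | Path) -> pd.DataFrame:
    """Load a reference-label CSV: ``campaign_id,annotator_id,<11 categories>``."""
    df = pd.read_csv(path, dtype={"campaign_id": str, "annotator_id": str})
    required = {"campaign_id", "annotator_id", *CATEGORIES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
    if df.duplicated(["campaign_id", "annotator_id"]).any():
        raise ValueError("duplicate (campaign_id, annotator_id) rows in reference")
    return df


def evaluation_table(predicted: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-category metrics table over all 11 categories, one row each."""
    ref = _as_label_frame(reference)
    total = len(ref)
    rows = []
    for cat in CATEGORIES:
        row = metrics_row(confusion_counts(predicted, reference, cat), total, cat)
        rows.append(
            {
                "disease_category": cat,
                "n_reference_positive": row.n_reference_positive,
                "tp": row.tp,
                "fp": row.fp,
                "fn": row.fn,
                "tn": row.tn,
                "precision": row.precision,
                "recall": row.recall,
                "f1": row.f1,
                "accuracy": row.accuracy,
                "precision_ci_low": row.precision_ci[0] if row.precision_ci else None,
                "precision_ci_high": row.precision_ci[1] if row.precision_ci else None,
                "recall_ci_low": row.recall_ci[0] if row.recall_ci else None,
                "recall_ci_high": row.recall_ci[1] if row.recall_ci else None,
                "accuracy_ci_low": row.accuracy_ci[0],
                "accuracy_ci_high": row.accuracy_ci[1],
            }
        )
    return pd.DataFrame(rows)


def agreement_table(reference: pd.DataFrame, annotator_a: str, annotator_b: str) -> pd.DataFrame:
    """Per-category Cohen κ between two annotators of a reference table."""
    a = reference[reference["annotator_id"] == annotator_a].set_index("campaign_id")
    b = reference[reference["annotator_id"] == annotator_b].set_index("campaign_id")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("annotators share no campaigns")
    rows = []
    for cat in CATEGORIES:
        res = cohen_kappa(a.loc[shared, cat], b.loc[shared, cat], cat)
        rows.append(
            {
                "disease_category": cat,
                "observed_agreement": res.observed_agreement,
                "chance_agreement": res.chance_agreement,
                "kappa": res.kappa,
            }
        )
    return pd.DataFrame(rows)


def annotator_discrepancies(
    reference: pd.DataFrame, annotator_a: str, annotator_b: str
) -> pd.DataFrame:
    """Adjudication worklist: campaign × category cells where annotators differ."""
    a = reference[reference["annotator_id"] == annotator_a].set_index("campaign_id")
    b = reference[reference["annotator_id"] == annotator_b].set_index("campaign_id")
    shared = a.index.intersection(b.index)
    out = []
    for cid in shared:
        for cat in CATEGORIES:
            va, vb = int(a.loc[cid, cat]), int(b.loc[cid, cat])
            if va != vb:
                out.append(
                    {"campaign_id": cid, "disease_category": cat, annotator_a: va, annotator_b: vb}
                )
    return pd.DataFrame(out, columns=["campaign_id", "disease_category", annotator_a, annotator_b])


def reference_metrics() -> pd.DataFrame:
    """Published per-category benchmark metrics for this class of algorithm.

    The packaged table reports precision, recall, F1 and accuracy per disease
    category from a validation against 400 manually annotated crowdfunding
    campaigns; it is the input for recomputing count-weighted summary
    metrics.
    """
    path = resources.files("crowddx.data").joinpath("reference_metrics.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    df = pd.DataFrame(rows)
    for col in ("precision", "recall", "f1", "accuracy"):
        df[col] = df[col].astype(float)
    df["n_reference_positive"] = df["n_reference_positive"].astype(int)
    return df
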