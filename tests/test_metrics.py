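"""Confusion counts, Wald intervals, weighted averages and Cohen kappa."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from crowddx import (
    CATEGORIES,
    cohen_kappa,
    confusion_counts,
    evaluation_table,
    f1_score,
    metrics_row,
    reference_metrics,
    wald_ci,
    weighted_average,
)
from crowddx.metrics import agreement_table, annotator_discrepancies, load_reference_labels


def label_frame(rng, ids, p=0.3):
    data = {"campaign_id": ids}
    for cat in CATEGORIES:
        data[cat] = (rng.random(len(ids)) < p).astype(int)
    return pd.DataFrame(data)


def test_perfect_agreement_has_no_errors():
    rng = np.random.default_rng(0)
    ids = [f"c{i}" for i in range(50)]
    ref = label_frame(rng, ids)
    for cat in CATEGORIES:
        tp, fp, fn, tn = confusion_counts(ref, ref, cat)
        assert fp == 0 and fn == 0
        assert tp + tn == 50


def test_all_negative_tables():
    ids = [f"c{i}" for i in range(20)]
    zeros = pd.DataFrame({"campaign_id": ids, **{c: 0 for c in CATEGORIES}})
    tp, fp, fn, tn = confusion_counts(zeros, zeros, "neoplasms")
    assert (tp, fp, fn, tn) == (0, 0, 0, 20)


def test_confusion_counts_match_per_item_tally():
    rng = np.random.default_rng(1)
    ids = [f"c{i}" for i in range(400)]
    ref = label_frame(rng, ids, p=0.25)
    pred = ref.copy()
    for cat in CATEGORIES:  # plant known error rates
        flips = rng.random(len(ids)) < 0.15
        pred[cat] = np.where(flips, 1 - pred[cat], pred[cat])
    for cat in CATEGORIES:
        tp = fp = fn = tn = 0
        for i in range(len(ids)):
            p, r = bool(pred.loc[i, cat]), bool(ref.loc[i, cat])
            tp += p and r
            fp += p and not r
            fn += (not p) and r
            tn += (not p) and (not r)
        assert confusion_counts(pred, ref, cat) == (tp, fp, fn, tn)


def test_id_mismatch_is_reported():
    ids = [f"c{i}" for i in range(5)]
    rng = np.random.default_rng(2)
    ref = label_frame(rng, ids)
    pred = label_frame(rng, ids[:-1] + ["zz"])
    with pytest.raises(ValueError, match="zz"):
        confusion_counts(pred, ref, "neoplasms")


def test_f1_from_printed_precision_recall():
    assert round(f1_score(0.95, 0.98), 2) == 0.96


def test_recall_ci_reproduces_published_interval():
    # recall 0.8 on 35 reference positives: tp=28, fn=7
    row = metrics_row((28, 1, 7, 364), 400, "genitourinary")
    assert row.recall == pytest.approx(0.8)
    low, high = row.recall_ci
    assert (round(low, 2), round(high, 2)) == (0.67, 0.93)


def test_perfect_recall_has_zero_width_ci():
    row = metrics_row((30, 5, 0, 365), 400)
    assert row.recall == 1.0
    assert row.recall_ci == (1.0, 1.0)


def test_wald_ci_is_unclipped():
    low, high = wald_ci(0.97, 33)
    assert high > 1.0  # small-sample proportions near 1 exceed the unit interval


def test_ci_endpoints_match_closed_form():
    rng = random.Random(9)
    for _ in range(100):
        total = rng.randint(10, 500)
        tp = rng.randint(0, total // 2)
        fp = rng.randint(0, total // 4)
        fn = rng.randint(0, total - tp - fp)
        tn = total - tp - fp - fn
        row = metrics_row((tp, fp, fn, tn), total)
        if row.precision is not None:
            n = tp + fp
            half = 1.96 * math.sqrt(row.precision * (1 - row.precision) / n)
            assert row.precision_ci[0] == pytest.approx(row.precision - half, abs=1e-12)
            assert row.precision_ci[1] == pytest.approx(row.precision + half, abs=1e-12)
        half = 1.96 * math.sqrt(row.accuracy * (1 - row.accuracy) / total)
        assert row.accuracy_ci[0] == pytest.approx(row.accuracy - half, abs=1e-12)


def test_ci_width_shrinks_like_inverse_sqrt_n():
    low1, high1 = wald_ci(0.8, 50)
    low4, high4 = wald_ci(0.8, 200)
    assert (high4 - low4) == pytest.approx((high1 - low1) / 2, rel=1e-12)


def test_undefined_precision_is_flagged_not_zero():
    row = metrics_row((0, 0, 10, 390), 400)
    assert row.precision is None
    assert row.precision_ci is None
    assert row.f1 is None
    assert row.recall == 0.0


def test_inconsistent_counts_rejected():
    with pytest.raises(ValueError):
        metrics_row((1, 1, 1, 1), 400)


def test_f1_lies_between_precision_and_recall():
    rng = random.Random(11)
    for _ in range(100):
        p, r = rng.uniform(0.05, 1), rng.uniform(0.05, 1)
        f1 = f1_score(p, r)
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


def test_weighted_averages_recompute_published_summary():
    table = reference_metrics()
    p, r, f1, acc = weighted_average(table)
    assert (round(p, 2), round(r, 2), round(f1, 2), round(acc, 2)) == (0.83, 0.77, 0.78, 0.95)
    # weighted averages stay inside the per-category ranges
    for value, col in ((p, "precision"), (r, "recall"), (f1, "f1"), (acc, "accuracy")):
        assert table[col].min() <= value <= table[col].max()


def test_weighted_average_of_constant_metric_is_that_constant():
    df = pd.DataFrame(
        {
            "n_reference_positive": [5, 50, 500],
            "precision": [0.7] * 3,
            "recall": [0.7] * 3,
            "f1": [0.7] * 3,
            "accuracy": [0.7] * 3,
        }
    )
    assert weighted_average(df) == pytest.approx((0.7, 0.7, 0.7, 0.7))


def test_weighted_average_matches_direct_arithmetic():
    rng = random.Random(13)
    df = pd.DataFrame(
        {
            "n_reference_positive": [rng.randint(1, 100) for _ in range(5)],
            **{
                col: [rng.random() for _ in range(5)]
                for col in ("precision", "recall", "f1", "accuracy")
            },
        }
    )
    got = weighted_average(df)
    w = df["n_reference_positive"]
    for value, col in zip(got, ("precision", "recall", "f1", "accuracy")):
        assert value == pytest.approx((w * df[col]).sum() / w.sum())


def test_all_zero_weights_rejected():
    df = pd.DataFrame(
        {"n_reference_positive": [0, 0], "precision": [1, 1], "recall": [1, 1],
         "f1": [1, 1], "accuracy": [1, 1]}
    )
    with pytest.raises(ValueError):
        weighted_average(df)


def test_kappa_perfect_agreement():
    labels = [1, 0, 1, 1, 0, 0, 1]
    res = cohen_kappa(labels, labels)
    assert res.kappa == pytest.approx(1.0)
    assert res.observed_agreement == 1.0


def test_kappa_hand_worked_two_by_two_table():
    # a=40 both-positive, b=10, c=5, d=45 agree-negative: p_o=0.85, p_e=0.5
    a = [1] * 40 + [1] * 10 + [0] * 5 + [0] * 45
    b = [1] * 40 + [0] * 10 + [1] * 5 + [0] * 45
    res = cohen_kappa(a, b)
    assert res.observed_agreement == pytest.approx(0.85)
    assert res.chance_agreement == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.7)


def test_kappa_near_zero_for_independent_raters():
    rng = np.random.default_rng(3)
    a = rng.random(20000) < 0.5
    b = rng.random(20000) < 0.5
    assert abs(cohen_kappa(a, b).kappa) < 0.05


def test_kappa_undefined_when_chance_agreement_is_one():
    res = cohen_kappa([1, 1, 1], [1, 1, 1])
    assert res.chance_agreement == 1.0
    assert res.kappa is None


def test_kappa_symmetric_and_label_swap_invariant():
    rng = np.random.default_rng(5)
    a = rng.random(500) < 0.3
    b = rng.random(500) < 0.4
    k = cohen_kappa(a, b).kappa
    assert cohen_kappa(b, a).kappa == pytest.approx(k)
    assert cohen_kappa(~a, ~b).kappa == pytest.approx(k)
    assert k == pytest.approx(cohen_kappa_score(a, b))  # independent implementation


def test_reference_label_io_and_agreement_reports(tmp_path):
    rng = np.random.default_rng(8)
    ids = [f"c{i}" for i in range(30)]
    rows = []
    for annotator in ("rater1", "rater2"):
        frame = label_frame(rng, ids, p=0.3)
        frame.insert(1, "annotator_id", annotator)
        rows.append(frame)
    path = tmp_path / "ref.csv"
    pd.concat(rows).to_csv(path, index=False)
    ref = load_reference_labels(path)
    assert len(ref) == 60
    agreement = agreement_table(ref, "rater1", "rater2")
    assert set(agreement["disease_category"]) == set(CATEGORIES)
    discrepancies = annotator_discrepancies(ref, "rater1", "rater2")
    a = ref[ref["annotator_id"] == "rater1"].set_index("campaign_id")
    b = ref[ref["annotator_id"] == "rater2"].set_index("campaign_id")
    expected = sum(
        int(a.loc[i, c]) != int(b.loc[i, c]) for i in ids for c in CATEGORIES
    )
    assert len(discrepancies) == expected


def test_evaluation_table_covers_all_categories():
    rng = np.random.default_rng(21)
    ids = [f"c{i}" for i in range(100)]
    ref = label_frame(rng, ids, p=0.3)
    pred = label_frame(rng, ids, p=0.3)
    table = evaluation_table(pred, ref)
    assert list(table["disease_category"]) == list(CATEGORIES)
    assert (table[["tp", "fp", "fn", "tn"]].sum(axis=1) == 100).all()
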