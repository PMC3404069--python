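"""AUROC/AUPR against brute-force pair-counting and hand-derived curves."""

from fractions import Fraction

import numpy as np
import pytest

from qtlcommittee import (
    RankedEdgeList,
    aupr,
    auroc,
    label_predictions,
    pr_curve,
    roc_curve,
)
from qtlcommittee.evalmetrics import aupr_tied, auroc_tied
from qtlcommittee.simdata import GoldNetwork


def brute_force_auroc(labels, p, n):
    """Exhaustive positive-negative pair counting in rational arithmetic.

    Ranked items occupy their list positions; all unranked items tie
    uniformly below the list (half credit against ranked items of the
    other class never arises -- a ranked item always beats an unranked
    one; unranked-vs-unranked pairs tie).
    """
    labels = list(labels)
    p_listed = sum(labels)
    n_listed = len(labels) - p_listed
    credit = Fraction(0)
    # both ranked
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if li == 1 and lj == 0 and i < j:
                credit += 1
    # ranked positive vs unranked negative: positive wins
    credit += p_listed * (n - n_listed)
    # unranked positive vs unranked negative: tie
    credit += Fraction(1, 2) * (p - p_listed) * (n - n_listed)
    return credit / (p * n)


def brute_force_aupr(labels, p):
    total = Fraction(0)
    tp = 0
    for k, lab in enumerate(labels, start=1):
        if lab == 1:
            tp += 1
            total += Fraction(tp, k)
    return total / p


def test_worked_interleaved_example():
    labels = [1, 0, 1, 0]
    assert auroc(labels, 2, 2) == 0.75
    assert aupr(labels, 2, 2) == pytest.approx((1 + Fraction(2, 3)) / 2)
    assert auroc([0, 1, 0, 1], 2, 2) == 0.25


def test_worked_curve_example():
    labels = [1, 1, 0]
    roc = roc_curve(labels, 2, 1)
    assert roc.points == [(0.0, 0.0), (0.0, 0.5), (0.0, 1.0), (1.0, 1.0)]
    pr = pr_curve(labels, 2, 1)
    assert pr.points == [(0.0, 1.0), (0.5, 1.0), (1.0, 1.0), (1.0, 2 / 3)]
    assert (0.5, 1.0) in pr.points and (1.0, 2 / 3) in pr.points


def test_perfect_and_closed_form_cases():
    assert auroc([1, 1, 1, 0, 0], 3, 2) == 1.0
    assert aupr([1, 1, 1, 0, 0], 3, 2) == 1.0
    # single positive ranked last among k predictions
    for k in (3, 7):
        labels = [0] * (k - 1) + [1]
        assert aupr(labels, 1, k - 1) == pytest.approx(1 / k)


def test_oracle_equivalence_exact():
    rng = np.random.default_rng(123)
    for _ in range(300):
        p = int(rng.integers(1, 6))
        n = int(rng.integers(1, 8))
        length = int(rng.integers(1, min(10, p + n) + 1))
        # a random ranked prefix consistent with the totals
        pool = [1] * p + [0] * n
        rng.shuffle(pool)
        labels = pool[:length]
        assert auroc(labels, p, n) == float(brute_force_auroc(labels, p, n))
        assert aupr(labels, p, n) == pytest.approx(float(brute_force_aupr(labels, p)), abs=1e-12)


def test_reversal_symmetry_complete_lists():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p, n = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        labels = [1] * p + [0] * n
        rng.shuffle(labels)
        assert auroc(labels, p, n) + auroc(labels[::-1], p, n) == pytest.approx(1.0)


def test_random_ranking_averages_one_half():
    rng = np.random.default_rng(99)
    vals = []
    for _ in range(500):
        labels = [1] * 5 + [0] * 20
        rng.shuffle(labels)
        vals.append(auroc(labels, 5, 20))
    # mean of a random ranking is 1/2; 0.03 is ~4.5 Monte-Carlo sd here
    assert abs(np.mean(vals) - 0.5) < 0.03


def test_trapezoid_and_step_sum_match_scalar_metrics():
    rng = np.random.default_rng(17)
    for _ in range(20):
        p, n = int(rng.integers(1, 6)), int(rng.integers(1, 8))
        labels = [1] * p + [0] * n
        rng.shuffle(labels)
        assert roc_curve(labels, p, n).trapezoid_area() == pytest.approx(auroc(labels, p, n))
        pr = pr_curve(labels, p, n)
        step = sum(
            (x2 - x1) * y2 * p  # recall increments are 1/p per positive
            for (x1, _), (x2, y2) in zip(pr.points, pr.points[1:])
            if x2 > x1
        ) / p
        assert step == pytest.approx(aupr(labels, p, n))


def test_label_predictions_hand_count():
    genes = ["a", "b", "c", "d"]
    gold = GoldNetwork(edges=[("a", "b"), ("b", "c"), ("c", "d")], weights={}, gene_ids=genes)
    preds = RankedEdgeList(
        ["a", "a", "b", "d", "c"], ["b", "c", "c", "a", "a"], np.arange(5, 0, -1, dtype=float)
    )
    labels, p, n = label_predictions(preds, gold, genes)
    assert labels.sum() == 2 and p == 3 and n == 9


def test_label_predictions_errors():
    genes = ["a", "b"]
    empty_gold = GoldNetwork(edges=[], weights={}, gene_ids=genes)
    preds = RankedEdgeList(["a"], ["b"], np.array([1.0]))
    with pytest.raises(ValueError):
        label_predictions(preds, empty_gold, genes)
    gold = GoldNetwork(edges=[("a", "b")], weights={}, gene_ids=genes)
    outside = RankedEdgeList(["a"], ["z"], np.array([1.0]))
    with pytest.raises(ValueError):
        label_predictions(outside, gold, genes)


def test_empty_prediction_list_degenerate_contract():
    assert auroc(np.array([]), 3, 5) == 0.0
    assert aupr(np.array([]), 3, 5) == 0.0
    assert roc_curve(np.array([]), 3, 5).points == [(0.0, 0.0)]
    assert pr_curve(np.array([]), 3, 5).points == [(0.0, 1.0)]


def test_relabeling_invariance():
    genes = ["a", "b", "c"]
    gold = GoldNetwork(edges=[("a", "b")], weights={}, gene_ids=genes)
    preds = RankedEdgeList(["a", "c"], ["b", "a"], np.array([2.0, 1.0]))
    labels, p, n = label_predictions(preds, gold, genes)
    mapping = {"a": "x", "b": "y", "c": "z"}
    gold2 = GoldNetwork(edges=[("x", "y")], weights={}, gene_ids=list(mapping.values()))
    preds2 = RankedEdgeList(["x", "z"], ["y", "x"], np.array([2.0, 1.0]))
    labels2, p2, n2 = label_predictions(preds2, gold2, list(mapping.values()))
    assert auroc(labels, p, n) == auroc(labels2, p2, n2)
    assert aupr(labels, p, n) == aupr(labels2, p2, n2)


def test_tie_aware_variants():
    # all scores equal: AUROC must be exactly 1/2 on a complete list
    labels = np.array([1, 0, 1, 0, 0])
    scores = np.ones(5)
    assert auroc_tied(labels, scores, 2, 3) == 0.5
    # no ties: agrees with the list-order metric
    distinct = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    assert auroc_tied(labels, distinct, 2, 3) == auroc(labels, 2, 3)
    assert aupr_tied(labels, distinct, 2, 3) == pytest.approx(aupr(labels, 2, 3))
    # one tie block at the top: both positives get the block-end precision
    labels2 = np.array([1, 1, 0])
    scores2 = np.array([2.0, 2.0, 1.0])
    assert aupr_tied(labels2, scores2, 2, 1) == pytest.approx(1.0)
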