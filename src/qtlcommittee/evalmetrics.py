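"""ROC / precision-recall evaluation of ranked edge predictions.

The prediction universe is the set of all ordered, non-self gene pairs;
positives are the gold-standard edges (P of them), negatives everything
else (N).  AUROC is the Mann--Whitney probability that a true edge
outranks a non-edge; AUPR is the non-interpolated average precision, the
mean precision at the ranks of the retrieved positives.  Average precision
is used deliberately: linear interpolation between points in PR space
overstates performance, which matters here because the edge classes are
extremely imbalanced (a few thousand true edges among ~a million pairs).

Truncated lists are handled by treating every never-predicted pair as tied
uniformly below the list (half credit against ranked items of the other
class for AUROC, zero precision contribution for AUPR).  To reproduce the
challenge's convention instead, pad the list to the evaluation budget with
:func:`qtlcommittee.ranking.pad_predictions` before evaluating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ranking import RankedEdgeList
from .simdata import GoldNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CurvePoints",
    "label_predictions",
    "auroc",
    "aupr",
    "roc_curve",
    "pr_curve",
    "auroc_tied",
    "aupr_tied",
    "evaluate_predictions",
]


@dataclass
class CurvePoints:
    """An evaluation curve: ROC (FPR, TPR) or PR (recall, precision)."""

    points: list[tuple[float, float]]
    curve_kind: str  # 'roc' or 'pr'

    def __post_init__(self) -> None:
        if self.curve_kind not in ("roc", "pr"):
            raise ValueError("curve_kind must be 'roc' or 'pr'")
        xs = [p[0] for p in self.points]
        if any(b < a - 1e-12 for a, b in zip(xs, xs[1:])):
            raise ValueError("curve x-coordinates must be non-decreasing")

    def trapezoid_area(self) -> float:
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return float(np.trapezoid(ys, xs))


def _check_counts(p: int, n: int) -> None:
    if p < 1:
        raise ValueError("metrics undefined without positives (empty gold set)")
    if n < 1:
        raise ValueError("metrics undefined without negatives")


def label_predictions(
    edges: RankedEdgeList, gold: GoldNetwork, universe_genes: list[str]
) -> tuple[np.ndarray, int, int]:
    """Binary labels for a ranked list, plus class totals (P, N).

    The universe is every ordered non-self pair over ``universe_genes``;
    predictions outside it are an error, and the gold set must be a
    non-empty subset of the universe.
    """
    genes = set(universe_genes)
    gold_set = gold.edge_set
    if not gold_set:
        raise ValueError("empty gold network: no positives, metrics undefined")
    for reg, tgt in gold_set:
        if reg not in genes or tgt not in genes:
            raise ValueError(f"gold edge {reg}->{tgt} outside the gene universe")
    for reg, tgt in zip(edges.regulators, edges.targets):
        if reg not in genes or tgt not in genes:
            raise ValueError(f"predicted edge {reg}->{tgt} outside the gene universe")

    universe_size = len(genes) * (len(genes) - 1)
    p = len(gold_set)
    n = universe_size - p
    labels = np.fromiter(
        (1 if pair in gold_set else 0 for pair in zip(edges.regulators, edges.targets)),
        dtype=np.int8,
        count=len(edges),
    )
    return labels, p, n


def auroc(labels: np.ndarray, p: int, n: int) -> float:
    """Mann--Whitney AUROC of a ranked (possibly truncated) label list.

    Concordant positive--negative pairs get full credit, ties (the
    unranked-vs-unranked block below a truncated list) half credit.  The
    numerator is computed in exact integer arithmetic.
    """
    _check_counts(p, n)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        logger.warning("empty prediction list: AUROC reported as 0")
        return 0.0
    p_listed = int(labels.sum())
    n_listed = int(labels.size - p_listed)
    if p_listed > p or n_listed > n:
        raise ValueError("list contains more positives/negatives than the totals allow")
    p_rest = p - p_listed
    n_rest = n - n_listed
    # positives ranked above each listed negative
    pos_before = int((np.cumsum(labels)[labels == 0]).sum())
    numerator2 = 2 * (pos_before + p_listed * n_rest) + p_rest * n_rest
    return numerator2 / (2 * p * n)


def aupr(labels: np.ndarray, p: int, n: int) -> float:
    """Average precision: mean precision at the ranks of the positives.

    Positives never ranked contribute zero, so a truncated list is
    penalized exactly by its missing recall.
    """
    _check_counts(p, n)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        logger.warning("empty prediction list: AUPR reported as 0")
        return 0.0
    tp = np.cumsum(labels)
    ranks = np.arange(1, labels.size + 1)
    hit = labels == 1
    return float((tp[hit] / ranks[hit]).sum() / p)


def roc_curve(labels: np.ndarray, p: int, n: int) -> CurvePoints:
    """ROC step curve: one (FPR, TPR) point per rank prefix, plus the origin."""
    _check_counts(p, n)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        logger.warning("empty prediction list: ROC curve is the origin only")
        return CurvePoints(points=[(0.0, 0.0)], curve_kind="roc")
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    pts = [(0.0, 0.0)] + [(float(fp[k] / n), float(tp[k] / p)) for k in range(labels.size)]
    return CurvePoints(points=pts, curve_kind="roc")


def pr_curve(labels: np.ndarray, p: int, n: int) -> CurvePoints:
    """PR curve: one (recall, precision) point per rank prefix, from (0, 1)."""
    _check_counts(p, n)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        logger.warning("empty prediction list: PR curve is the origin only")
        return CurvePoints(points=[(0.0, 1.0)], curve_kind="pr")
    tp = np.cumsum(labels)
    ranks = np.arange(1, labels.size + 1)
    pts = [(0.0, 1.0)] + [(float(tp[k] / p), float(tp[k] / ranks[k])) for k in range(labels.size)]
    return CurvePoints(points=pts, curve_kind="pr")


def auroc_tied(labels: np.ndarray, scores: np.ndarray, p: int, n: int) -> float:
    """Tie-aware AUROC: positive--negative pairs with equal score get half credit."""
    _check_counts(p, n)
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size:
        raise ValueError("labels and scores must have equal length")
    if labels.size == 0:
        logger.warning("empty prediction list: AUROC reported as 0")
        return 0.0
    p_listed = int(labels.sum())
    n_listed = int(labels.size - p_listed)
    p_rest, n_rest = p - p_listed, n - n_listed
    concord2 = 0  # doubled credit to stay in integers
    pos_above = 0
    i = 0
    order = np.argsort(-scores, kind="mergesort")
    lab = labels[order]
    sc = scores[order]
    while i < lab.size:
        j = i
        while j < lab.size and sc[j] == sc[i]:
            j += 1
        block_pos = int(lab[i:j].sum())
        block_neg = (j - i) - block_pos
        concord2 += 2 * pos_above * block_neg + block_pos * block_neg
        pos_above += block_pos
        i = j
    numerator2 = concord2 + 2 * p_listed * n_rest + p_rest * n_rest
    return numerator2 / (2 * p * n)


def aupr_tied(labels: np.ndarray, scores: np.ndarray, p: int, n: int) -> float:
    """Tie-aware average precision, evaluated at tie-block boundaries.

    Every positive in a block of equal scores receives the precision at
    the end of its block (the only defensible cut points under ties).
    """
    _check_counts(p, n)
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        logger.warning("empty prediction list: AUPR reported as 0")
        return 0.0
    order = np.argsort(-scores, kind="mergesort")
    lab = labels[order]
    sc = scores[order]
    total = 0.0
    tp = 0
    i = 0
    while i < lab.size:
        j = i
        while j < lab.size and sc[j] == sc[i]:
            j += 1
        block_pos = int(lab[i:j].sum())
        tp += block_pos
        total += block_pos * (tp / j)
        i = j
    return total / p


def evaluate_predictions(
    edges: RankedEdgeList, gold: GoldNetwork, universe_genes: list[str]
) -> dict:
    """AUROC, AUPR and curves for a ranked list against a gold network."""
    labels, p, n = label_predictions(edges, gold, universe_genes)
    return {
        "auroc": auroc(labels, p, n),
        "aupr": aupr(labels, p, n),
        "n_predictions": int(labels.size),
        "n_true_positives": int(labels.sum()),
        "P": p,
        "N": n,
        "roc": roc_curve(labels, p, n),
        "pr": pr_curve(labels, p, n),
    }
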