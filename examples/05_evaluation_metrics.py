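"""AUROC and AUPR on ranked edge lists, including truncation and padding.

Walks through the evaluation conventions on a toy universe: labels from
a gold network, the Mann-Whitney AUROC, non-interpolated average
precision, and the challenge convention of padding sparse submissions to
a fixed budget with random edges.
"""

import numpy as np

from qtlcommittee import (
    RankedEdgeList,
    aupr,
    auroc,
    label_predictions,
    pad_predictions,
    pr_curve,
    roc_curve,
)
from qtlcommittee.simdata import GoldNetwork

genes = ["g1", "g2", "g3", "g4"]
gold = GoldNetwork(edges=[("g1", "g2"), ("g2", "g3"), ("g3", "g4")],
                   weights={}, gene_ids=genes)

predictions = RankedEdgeList(
    regulators=["g1", "g1", "g2", "g4"],
    targets=["g2", "g3", "g3", "g1"],
    scores=np.array([0.9, 0.7, 0.5, 0.1]),
)
labels, p, n = label_predictions(predictions, gold, genes)
print(f"labels {labels.tolist()}  (P={p} true edges, N={n} non-edges)")
print(f"AUROC {auroc(labels, p, n):.4f}   AUPR {aupr(labels, p, n):.4f}")
print("ROC points:", [(round(float(x), 2), round(float(y), 2))
                      for x, y in roc_curve(labels, p, n).points])
print("PR  points:", [(round(float(x), 2), round(float(y), 2))
                      for x, y in pr_curve(labels, p, n).points])

padded = pad_predictions(predictions, budget=10, gene_universe=genes, seed=0)
labels2, _, _ = label_predictions(padded, gold, genes)
print(f"\nafter padding to 10 edges: AUROC {auroc(labels2, p, n):.4f} "
      f"AUPR {aupr(labels2, p, n):.4f}")
print("Padding appends random unseen edges with score 0 -- the challenge")
print("convention for sparse submissions; never-ranked true edges cost")
print("recall, which AUPR penalizes directly.")
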