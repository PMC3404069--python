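"""From score matrices to ordered directed edge predictions.

The marker--gene score of (marker m, gene g) becomes a candidate directed
edge gene(m) -> g through the one-to-one marker/gene correspondence of the
benchmark design.  Self-pairs are excluded, scores sort descending with a
deterministic lexicographic tie-break, and the DREAM submission convention
(truncate or randomly pad the list to a fixed budget, 100,000 by default)
is available via :func:`pad_predictions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import ScoreMatrix
from .simdata import MarkerMap

__all__ = ["RankedEdgeList", "scores_to_edges", "pad_predictions", "DEFAULT_BUDGET"]

DEFAULT_BUDGET = 100_000


@dataclass
class RankedEdgeList:
    """Ordered directed edge predictions (rank 1 first)."""

    regulators: list[str]
    targets: list[str]
    scores: np.ndarray
    padded: np.ndarray = field(default=None)  # bool per record

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.padded is None:
            self.padded = np.zeros(len(self.scores), dtype=bool)
        self.padded = np.asarray(self.padded, dtype=bool)
        n = len(self.scores)
        if not (len(self.regulators) == len(self.targets) == len(self.padded) == n):
            raise ValueError("ranked edge list columns must have equal length")
        pairs = set()
        for r, t in zip(self.regulators, self.targets):
            if r == t:
                raise ValueError(f"self-edge {r}->{t} not allowed")
            if (r, t) in pairs:
                raise ValueError(f"duplicate predicted edge {r}->{t}")
            pairs.add((r, t))
        real = ~self.padded
        if real.any() and np.any(np.diff(self.scores[real]) > 1e-12):
            raise ValueError("scores must be non-increasing over non-padded records")

    def __len__(self) -> int:
        return len(self.scores)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.regulators, self.targets))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "regulator": self.regulators,
                "target": self.targets,
                "score": self.scores,
                "padded": self.padded,
            }
        )


def scores_to_edges(
    scores: ScoreMatrix, marker_map: MarkerMap, drop_zero: bool = False
) -> RankedEdgeList:
    """Rank all marker--gene pairs as directed gene->gene edge predictions.

    ``drop_zero`` removes pairs whose score is exactly 0 — the filtered
    committee's "no prediction" semantics.  Ties are broken by ascending
    (regulator, target) identifier, which keeps the order reproducible.
    """
    gene_of = dict(zip(marker_map.marker_ids, marker_map.gene_ids))
    missing = [m for m in scores.marker_ids if m not in gene_of]
    if missing:
        raise ValueError(f"markers without a gene mapping: {missing[:5]}")

    regulators = np.array([gene_of[m] for m in scores.marker_ids])
    tgt = np.array(scores.gene_ids)
    reg_grid = np.repeat(regulators, len(tgt))
    tgt_grid = np.tile(tgt, len(regulators))
    vals = scores.values.ravel()

    keep = reg_grid != tgt_grid
    if drop_zero:
        keep &= vals != 0.0
    frame = pd.DataFrame({"regulator": reg_grid[keep], "target": tgt_grid[keep], "score": vals[keep]})
    frame = frame.sort_values(
        ["score", "regulator", "target"], ascending=[False, True, True], kind="mergesort"
    )
    return RankedEdgeList(
        regulators=frame["regulator"].tolist(),
        targets=frame["target"].tolist(),
        scores=frame["score"].to_numpy(),
    )


def pad_predictions(
    edges: RankedEdgeList,
    budget: int,
    gene_universe: list[str],
    seed: int = 0,
) -> RankedEdgeList:
    """Truncate to ``budget`` records, or pad with random unseen edges.

    Mirrors the challenge evaluation: sparse submissions are topped up
    with uniformly drawn, non-duplicate, non-self edges (score 0, flagged
    ``padded``) until the list reaches the evaluation budget.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    genes = list(gene_universe)
    universe_size = len(genes) * (len(genes) - 1)
    if budget > universe_size:
        raise ValueError(f"budget {budget} exceeds universe size {universe_size}")
    if len(edges) >= budget:
        return RankedEdgeList(
            regulators=edges.regulators[:budget],
            targets=edges.targets[:budget],
            scores=edges.scores[:budget],
            padded=edges.padded[:budget],
        )

    rng = np.random.default_rng(seed)
    taken = set(zip(edges.regulators, edges.targets))
    need = budget - len(edges)
    new_pairs: list[tuple[str, str]] = []
    g = len(genes)
    for _ in range(50):
        if len(new_pairs) == need:
            break
        k = 2 * (need - len(new_pairs)) + 8
        ridx = rng.integers(0, g, size=k)
        tidx = rng.integers(0, g, size=k)
        for ri, ti in zip(ridx, tidx):
            if ri == ti:
                continue
            pair = (genes[ri], genes[ti])
            if pair in taken:
                continue
            taken.add(pair)
            new_pairs.append(pair)
            if len(new_pairs) == need:
                break
    if len(new_pairs) < need:
        # dense regime: enumerate the remaining pairs and sample directly
        existing = set(zip(edges.regulators, edges.targets)) | set(new_pairs)
        remaining = [(r, t) for r in genes for t in genes if r != t and (r, t) not in existing]
        idx = rng.choice(len(remaining), size=need - len(new_pairs), replace=False)
        new_pairs.extend(remaining[i] for i in idx)

    return RankedEdgeList(
        regulators=edges.regulators + [p[0] for p in new_pairs],
        targets=edges.targets + [p[1] for p in new_pairs],
        scores=np.concatenate([edges.scores, np.zeros(need)]),
        padded=np.concatenate([edges.padded, np.ones(need, dtype=bool)]),
    )
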