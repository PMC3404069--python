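"""Committees of marker-importance scores.

An unfiltered committee is the entrywise mean of the member score matrices
after each has been centered and scaled (z-scored); scaling puts the four
methods' very different score scales (split counts, MSE increases,
absolute coefficients) on a common footing before averaging.  The filtered
committee additionally gates the average through the LASSO support: every
marker--gene pair whose LASSO coefficient is zero is set to zero, yielding
a very sparse prediction in which, within a linked region, only the single
marker picked by the LASSO survives.

Committee specifications are written ``"RF.sf+LASSO"`` (unfiltered) or
``"{RF.sf+RF.pi+ElNet}|LASSO"`` (filtered: the braces hold the averaged
members, the method after ``|`` supplies the gate and is not averaged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .learners import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CommitteeSpec",
    "parse_committee",
    "zscore_matrix",
    "apply_lasso_gate",
    "combine_unfiltered",
    "combine_filtered",
    "build_committee",
]

SCALING_SCOPES = ("global", "per_gene")


@dataclass(frozen=True)
class CommitteeSpec:
    members: tuple[str, ...]
    filter_by_lasso: bool = False
    scaling_scope: str = "global"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("committee must have at least one member")
        if self.scaling_scope not in SCALING_SCOPES:
            raise ValueError(f"scaling_scope must be one of {SCALING_SCOPES}")

    @property
    def label(self) -> str:
        inner = "+".join(self.members)
        return f"{{{inner}}}|LASSO" if self.filter_by_lasso else inner


def parse_committee(spec: str, scaling_scope: str = "global") -> CommitteeSpec:
    """Parse a committee string such as ``"{RF.sf+RF.pi+ElNet}|LASSO"``."""
    text = spec.strip()
    filtered = False
    if "|" in text:
        head, _, gate = text.partition("|")
        if gate.strip() != "LASSO":
            raise ValueError(f"only a LASSO filter is supported, got {gate.strip()!r}")
        filtered = True
        text = head.strip()
    if text.startswith("{") and text.endswith("}"):
        text = text[1:-1]
    members = tuple(m.strip() for m in text.split("+") if m.strip())
    if not members:
        raise ValueError(f"no committee members in {spec!r}")
    return CommitteeSpec(members=members, filter_by_lasso=filtered, scaling_scope=scaling_scope)


def _check_aligned(matrices: list[ScoreMatrix]) -> None:
    ref = matrices[0]
    for m in matrices[1:]:
        if m.marker_ids != ref.marker_ids:
            bad = next(
                (a for a, b in zip(m.marker_ids, ref.marker_ids) if a != b),
                "<length mismatch>",
            )
            raise ValueError(f"marker index mismatch between members, first offender: {bad!r}")
        if m.gene_ids != ref.gene_ids:
            bad = next((a for a, b in zip(m.gene_ids, ref.gene_ids) if a != b), "<length mismatch>")
            raise ValueError(f"gene index mismatch between members, first offender: {bad!r}")


def _zscore(values: np.ndarray, scope: str) -> np.ndarray:
    if values.size == 0:
        raise ValueError("cannot z-score an empty matrix")
    if scope == "global":
        centered = values - values.mean()
        sd = values.std(ddof=1) if values.size > 1 else 0.0
        if sd == 0:
            logger.warning("zero standard deviation: returning centered scores unscaled")
            return centered
        return centered / sd
    # per_gene: center and scale within each gene column
    centered = values - values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    sd = np.atleast_1d(sd)
    flat = sd == 0
    if flat.any():
        logger.warning("%d gene columns have zero sd: centered, unscaled", int(flat.sum()))
    out = centered.copy()
    out[:, ~flat] = centered[:, ~flat] / sd[None, ~flat]
    return out


def zscore_matrix(scores: ScoreMatrix, scope: str = "global") -> ScoreMatrix:
    """Center and scale a score matrix, globally or within each gene."""
    if scope not in SCALING_SCOPES:
        raise ValueError(f"scope must be one of {SCALING_SCOPES}")
    return ScoreMatrix(
        values=_zscore(scores.values, scope),
        marker_ids=list(scores.marker_ids),
        gene_ids=list(scores.gene_ids),
        method_label=f"z({scores.method_label})",
    )


def combine_unfiltered(matrices: list[ScoreMatrix], scope: str = "global") -> ScoreMatrix:
    """Entrywise mean of the z-scored member matrices."""
    if not matrices:
        raise ValueError("need at least one member matrix")
    _check_aligned(matrices)
    stacked = np.stack([_zscore(m.values, scope) for m in matrices])
    label = "+".join(m.method_label for m in matrices)
    return ScoreMatrix(
        values=stacked.mean(axis=0),
        marker_ids=list(matrices[0].marker_ids),
        gene_ids=list(matrices[0].gene_ids),
        method_label=label,
    )


def apply_lasso_gate(values: np.ndarray, lasso_values: np.ndarray, zero_tol: float = 1e-10) -> np.ndarray:
    """Zero every entry whose LASSO score is (numerically) zero."""
    if values.shape != lasso_values.shape:
        raise ValueError("gate shape mismatch")
    return np.where(lasso_values < zero_tol, 0.0, values)


def combine_filtered(
    members: list[ScoreMatrix],
    lasso: ScoreMatrix,
    scope: str = "global",
    zero_tol: float = 1e-10,
) -> ScoreMatrix:
    """Average the members, then zero every pair outside the LASSO support."""
    if (lasso.values < 0).any():
        raise ValueError("LASSO gate scores must be non-negative (absolute coefficients)")
    combined = combine_unfiltered(members, scope)
    _check_aligned([combined, lasso])
    gated = apply_lasso_gate(combined.values, lasso.values, zero_tol)
    label = "{" + "+".join(m.method_label for m in members) + "}|" + lasso.method_label
    return ScoreMatrix(
        values=gated,
        marker_ids=list(combined.marker_ids),
        gene_ids=list(combined.gene_ids),
        method_label=label,
    )


def build_committee(
    spec: CommitteeSpec,
    matrices: dict[str, ScoreMatrix],
    zero_tol: float = 1e-10,
) -> ScoreMatrix:
    """Assemble a committee from per-method score matrices by label."""
    try:
        members = [matrices[m] for m in spec.members]
    except KeyError as exc:
        raise KeyError(f"missing score matrix for committee member {exc.args[0]!r}") from exc
    if spec.filter_by_lasso:
        if "LASSO" not in matrices:
            raise KeyError("filtered committee needs a LASSO score matrix as the gate")
        return combine_filtered(members, matrices["LASSO"], spec.scaling_scope, zero_tol)
    return combine_unfiltered(members, spec.scaling_scope)
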