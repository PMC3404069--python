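"""Tab-separated file formats.

Matrices (genotypes, expression, score matrices) are written samples- or
markers-in-rows with a header row of column identifiers and an id column
first.  Edge lists are two columns (gold networks) or three columns with a
score (ranked predictions, submission style).  Every writer prepends
comment lines beginning ``#`` carrying tool version, seed and parameters;
all readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .learners import ScoreMatrix
from .ranking import RankedEdgeList
from .simdata import ExpressionMatrix, GenotypeMatrix, GoldNetwork, MarkerMap

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list",
    "read_edge_list",
    "write_marker_map",
    "read_marker_map",
    "write_score_matrix",
    "read_score_matrix",
    "write_genotypes",
    "write_expression",
    "read_genotypes",
    "read_expression",
]


class TsvParseError(ValueError):
    """Malformed tab-separated input; the message carries the line number."""


def _metadata_lines(metadata: dict | None) -> list[str]:
    from . import __version__

    lines = [f"# qtlcommittee {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_matrix_tsv(
    values: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
    path,
    metadata: dict | None = None,
    id_label: str = "id",
) -> None:
    values = np.asarray(values)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValueError("matrix shape does not match row/column ids")
    with open(path, "w") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        fh.write("\t".join([id_label, *col_ids]) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix TSV; returns (values, row_ids, col_ids).

    Ragged rows, duplicate identifiers and non-numeric cells raise
    :class:`TsvParseError` naming the offending line.
    """
    col_ids: list[str] | None = None
    row_ids: list[str] = []
    rows: list[list[float]] = []
    seen_rows: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if col_ids is None:
                col_ids = cells[1:]
                if len(set(col_ids)) != len(col_ids):
                    dup = next(c for c in col_ids if col_ids.count(c) > 1)
                    raise TsvParseError(f"line {lineno}: duplicate column id {dup!r}")
                continue
            if len(cells) != len(col_ids) + 1:
                raise TsvParseError(
                    f"line {lineno}: expected {len(col_ids) + 1} columns, got {len(cells)}"
                )
            rid = cells[0]
            if rid in seen_rows:
                raise TsvParseError(f"line {lineno}: duplicate row id {rid!r}")
            seen_rows.add(rid)
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise TsvParseError(f"line {lineno}: non-numeric cell ({exc})") from None
            row_ids.append(rid)
    if col_ids is None:
        raise TsvParseError("empty file: no header row")
    return np.array(rows, dtype=float), row_ids, col_ids


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def write_edge_list(edges, path, metadata: dict | None = None) -> None:
    """Write a gold network (2 columns) or ranked predictions (3 columns)."""
    with open(path, "w") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        if isinstance(edges, GoldNetwork):
            for reg, tgt in edges.edges:
                fh.write(f"{reg}\t{tgt}\n")
        elif isinstance(edges, RankedEdgeList):
            for reg, tgt, score in zip(edges.regulators, edges.targets, edges.scores):
                fh.write(f"{reg}\t{tgt}\t{float(score)!r}\n")
        else:
            raise TypeError(f"cannot write edge container of type {type(edges).__name__}")


def read_edge_list(path, scored: bool = False, gene_ids: list[str] | None = None):
    """Read an edge-list file.

    ``scored=False`` returns a :class:`GoldNetwork` (order-free set,
    self-edges and duplicates rejected); ``scored=True`` returns a
    :class:`RankedEdgeList` in file order, tolerating a missing score
    column (rank order taken as given).
    """
    regs: list[str] = []
    tgts: list[str] = []
    scores: list[float] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) not in (2, 3):
                raise TsvParseError(f"line {lineno}: expected 2 or 3 columns, got {len(cells)}")
            reg, tgt = cells[0], cells[1]
            if reg == tgt:
                raise TsvParseError(f"line {lineno}: self-edge {reg}->{tgt}")
            if (reg, tgt) in seen:
                raise TsvParseError(f"line {lineno}: duplicate edge {reg}->{tgt}")
            seen.add((reg, tgt))
            regs.append(reg)
            tgts.append(tgt)
            if len(cells) == 3:
                try:
                    scores.append(float(cells[2]))
                except ValueError:
                    raise TsvParseError(f"line {lineno}: non-numeric score {cells[2]!r}") from None
    if scored:
        if scores and len(scores) != len(regs):
            raise TsvParseError("mixed scored and unscored lines")
        score_arr = np.array(scores) if scores else -np.arange(len(regs), dtype=float)
        return RankedEdgeList(regulators=regs, targets=tgts, scores=score_arr)
    genes = gene_ids if gene_ids is not None else sorted(set(regs) | set(tgts))
    return GoldNetwork(edges=list(zip(regs, tgts)), weights={}, gene_ids=genes)


# ---------------------------------------------------------------------------
# marker map and typed wrappers
# ---------------------------------------------------------------------------


def write_marker_map(marker_map: MarkerMap, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        fh.write("marker_id\tgene_id\tchromosome\tposition_index\tmutation_type\n")
        for i in range(len(marker_map)):
            fh.write(
                f"{marker_map.marker_ids[i]}\t{marker_map.gene_ids[i]}\t"
                f"{int(marker_map.chromosome[i])}\t{int(marker_map.position_index[i])}\t"
                f"{marker_map.mutation_type[i]}\n"
            )


def read_marker_map(path) -> MarkerMap:
    marker_ids: list[str] = []
    gene_ids: list[str] = []
    chrom: list[int] = []
    pos: list[int] = []
    mtype: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            cells = line.split("\t")
            if len(cells) != 5:
                raise TsvParseError(f"line {lineno}: expected 5 columns, got {len(cells)}")
            if cells[4] not in ("cis", "trans"):
                raise TsvParseError(f"line {lineno}: mutation_type must be cis or trans")
            marker_ids.append(cells[0])
            gene_ids.append(cells[1])
            try:
                chrom.append(int(cells[2]))
                pos.append(int(cells[3]))
            except ValueError:
                raise TsvParseError(f"line {lineno}: non-integer chromosome/position") from None
            mtype.append(cells[4])
    return MarkerMap(
        marker_ids=marker_ids,
        gene_ids=gene_ids,
        chromosome=np.array(chrom),
        position_index=np.array(pos),
        mutation_type=np.array(mtype, dtype="<U5"),
    )


def write_genotypes(genotypes: GenotypeMatrix, path, metadata: dict | None = None) -> None:
    write_matrix_tsv(
        genotypes.values, genotypes.sample_ids, genotypes.marker_map.marker_ids,
        path, metadata, id_label="sample",
    )


def read_genotypes(path, marker_map: MarkerMap) -> GenotypeMatrix:
    values, row_ids, col_ids = read_matrix_tsv(path)
    if col_ids != marker_map.marker_ids:
        raise ValueError("genotype columns do not match the marker map")
    return GenotypeMatrix(values=values.astype(np.int8), sample_ids=row_ids, marker_map=marker_map)


def write_expression(expression: ExpressionMatrix, path, metadata: dict | None = None) -> None:
    write_matrix_tsv(
        expression.values, expression.sample_ids, expression.gene_ids,
        path, metadata, id_label="sample",
    )


def read_expression(path) -> ExpressionMatrix:
    values, row_ids, col_ids = read_matrix_tsv(path)
    return ExpressionMatrix(values=values, sample_ids=row_ids, gene_ids=col_ids)


def write_score_matrix(scores: ScoreMatrix, path, metadata: dict | None = None) -> None:
    meta = {"method": scores.method_label, **(metadata or {})}
    write_matrix_tsv(scores.values, scores.marker_ids, scores.gene_ids, path, meta, id_label="marker")


def read_score_matrix(path) -> ScoreMatrix:
    method = "unknown"
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            if raw.startswith("# method="):
                method = raw.removeprefix("# method=").strip()
    values, row_ids, col_ids = read_matrix_tsv(path)
    return ScoreMatrix(values=values, marker_ids=row_ids, gene_ids=col_ids, method_label=method)
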