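"""End-to-end pipeline: simulate -> score -> combine -> rank -> evaluate.

A :class:`RunConfig` either points at existing genotype/expression/marker
map/gold files or carries :class:`~qtlcommittee.simdata.SimParams` to
generate them.  All intermediates are persisted under the output
directory with seed-carrying metadata headers, and a rerun with an
identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as qio
from .committee import CommitteeSpec, build_committee, parse_committee
from .evalmetrics import evaluate_predictions
from .learners import LearnerParams, map_all_genes
from .ranking import DEFAULT_BUDGET, pad_predictions, scores_to_edges
from .simdata import SimParams, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    out_dir: str
    committee: str = "RF.sf+LASSO"
    seed: int = 0
    sim: SimParams | None = None
    learner: LearnerParams = field(default_factory=LearnerParams)
    scaling_scope: str = "global"
    budget: int | None = None  # None: no truncation/padding
    drop_zero: bool | None = None  # default: True for filtered committees
    # input paths, used when sim is None
    genotypes_path: str | None = None
    expression_path: str | None = None
    marker_map_path: str | None = None
    gold_path: str | None = None


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    sim = None
    if "sim" in raw:
        sim_kwargs = dict(raw["sim"])
        sim_kwargs.setdefault("seed", seed)
        sim = SimParams(**sim_kwargs)
    learner_kwargs = dict(raw.get("learner", {}))
    learner_kwargs.setdefault("seed", seed)
    if "s_grid" in learner_kwargs:
        learner_kwargs["s_grid"] = tuple(learner_kwargs["s_grid"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    extra = {k: v for k, v in raw.items() if k in known - {"sim", "learner", "seed"}}
    return RunConfig(seed=seed, sim=sim, learner=LearnerParams(**learner_kwargs), **extra)


def _load_inputs(config: RunConfig, out: Path):
    if config.sim is not None:
        genotypes, gold, expression = simulate_dataset(config.sim)
        meta = {"seed": config.sim.seed, "params": dataclasses.asdict(config.sim)}
        qio.write_genotypes(genotypes, out / "genotypes.tsv", meta)
        qio.write_expression(expression, out / "expression.tsv", meta)
        qio.write_marker_map(genotypes.marker_map, out / "marker_map.tsv", meta)
        qio.write_edge_list(gold, out / "gold_edges.tsv", meta)
        return genotypes, expression, gold
    for name in ("genotypes_path", "expression_path", "marker_map_path", "gold_path"):
        if getattr(config, name) is None:
            raise ValueError(f"config needs either sim parameters or {name}")
        if not Path(getattr(config, name)).exists():
            raise FileNotFoundError(getattr(config, name))
    marker_map = qio.read_marker_map(config.marker_map_path)
    genotypes = qio.read_genotypes(config.genotypes_path, marker_map)
    expression = qio.read_expression(config.expression_path)
    gold = qio.read_edge_list(config.gold_path, scored=False, gene_ids=list(marker_map.gene_ids))
    return genotypes, expression, gold


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and return (and persist) the evaluation report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = parse_committee(config.committee, config.scaling_scope)

    genotypes, expression, gold = _load_inputs(config, out)

    needed = set(spec.members) | ({"LASSO"} if spec.filter_by_lasso else set())
    matrices = {}
    for method in sorted(needed):
        logger.info("pipeline stage: scoring with %s", method)
        scores = map_all_genes(genotypes, expression, method, config.learner)
        qio.write_score_matrix(scores, out / f"scores_{method.replace('.', '_')}.tsv",
                               {"seed": config.learner.seed})
        matrices[method] = scores

    combined = build_committee(spec, matrices, config.learner.zero_tol)
    qio.write_score_matrix(combined, out / "scores_committee.tsv", {"seed": config.learner.seed})

    drop_zero = config.drop_zero if config.drop_zero is not None else spec.filter_by_lasso
    edges = scores_to_edges(combined, genotypes.marker_map, drop_zero=drop_zero)
    if config.budget is not None:
        edges = pad_predictions(edges, config.budget, list(genotypes.marker_map.gene_ids), seed=config.seed)
    qio.write_edge_list(edges, out / "predictions.tsv", {"seed": config.seed})

    report = evaluate_predictions(edges, gold, list(genotypes.marker_map.gene_ids))
    roc, pr = report.pop("roc"), report.pop("pr")
    report["committee"] = spec.label
    report["seed"] = config.seed
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "roc_curve.tsv", "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in roc.points:
            fh.write(f"{x!r}\t{y!r}\n")
    with open(out / "pr_curve.tsv", "w") as fh:
        fh.write("recall\tprecision\n")
        for x, y in pr.points:
            fh.write(f"{x!r}\t{y!r}\n")
    return report
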