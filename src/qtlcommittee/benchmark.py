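"""Reference benchmark designs for the committee eQTL mapper.

Three seeded study designs used by the test suite, the reproduction
script and the examples:

* :func:`committee_gain_benchmark` — does averaging RF.sf and LASSO scores
  beat either method alone (average precision on a full edge ranking)?
* :func:`sparsity_benchmark` — how many edges does the LASSO-gated
  committee predict as the sample size grows, and does its support stay
  inside the LASSO support?
* :func:`planted_edge_benchmark` — with a single regulatory edge fed by a
  strong cis effect, how highly does each scorer rank the true edge?
"""

from __future__ import annotations

import logging

import numpy as np

from .committee import build_committee, parse_committee
from .evalmetrics import evaluate_predictions
from .learners import LearnerParams, map_all_genes
from .ranking import scores_to_edges
from .simdata import (
    GenotypeMatrix,
    GoldNetwork,
    SimParams,
    simulate_dataset,
    simulate_genotypes,
    simulate_expression,
)

logger = logging.getLogger(__name__)

__all__ = [
    "committee_gain_benchmark",
    "sparsity_benchmark",
    "planted_edge_benchmark",
]


def _score_and_evaluate(genotypes, expression, gold, methods, learner, committee_spec):
    """Per-method and committee AUROC/AUPR on the complete edge ranking."""
    matrices = {m: map_all_genes(genotypes, expression, m, learner) for m in methods}
    genes = list(genotypes.marker_map.gene_ids)
    out = {}
    for label, sm in matrices.items():
        edges = scores_to_edges(sm, genotypes.marker_map)
        rep = evaluate_predictions(edges, gold, genes)
        out[label] = {"auroc": rep["auroc"], "aupr": rep["aupr"]}
    spec = parse_committee(committee_spec)
    combined = build_committee(spec, matrices, learner.zero_tol)
    edges = scores_to_edges(combined, genotypes.marker_map, drop_zero=spec.filter_by_lasso)
    rep = evaluate_predictions(edges, gold, genes)
    out[spec.label] = {"auroc": rep["auroc"], "aupr": rep["aupr"]}
    return out, matrices, combined


def committee_gain_benchmark(
    n_replicates: int = 10,
    n_genes: int = 100,
    n_samples: int = 150,
    n_edges: int = 250,
    n_trees: int = 300,
    committee: str = "RF.sf+LASSO",
    base_seed: int = 0,
) -> list[dict]:
    """Committee vs constituents over seeded replicate networks.

    Returns one dict per replicate mapping each method label (and the
    committee label) to its AUROC/AUPR on the complete ranked edge list.
    """
    spec = parse_committee(committee)
    results = []
    for rep in range(n_replicates):
        seed = int(base_seed + rep)
        sim = SimParams(n_samples=n_samples, n_genes=n_genes, n_edges=n_edges, seed=seed)
        genotypes, gold, expression = simulate_dataset(sim)
        learner = LearnerParams(n_trees=n_trees, seed=seed)
        scores, _, _ = _score_and_evaluate(
            genotypes, expression, gold, list(spec.members), learner, committee
        )
        logger.info("replicate %d: %s", rep, {k: round(v["aupr"], 3) for k, v in scores.items()})
        results.append(scores)
    return results


def sparsity_benchmark(
    sample_sizes: tuple[int, ...] = (50, 100, 200),
    n_replicates: int = 1,
    n_genes: int = 250,
    n_edges: int = 625,
    n_target_genes: int = 30,
    n_trees: int = 40,
    base_seed: int = 0,
) -> dict[int, list[dict]]:
    """Filtered-committee sparsity as a function of sample size.

    For every sample size and replicate, runs the LASSO-gated committee
    {RF.sf+RF.pi+ElNet}|LASSO and records the number of nonzero LASSO
    scores, the number of nonzero committee scores and the length of the
    emitted (zero-dropped) prediction list.

    The marker panel is kept much larger than every sample size
    (``n_genes`` markers, the many-markers/few-lines regime of real eQTL
    panels); this is the regime in which the cross-validated L1 budget,
    and with it the committee's prediction count, grows with the number
    of lines.  Scoring is restricted to ``n_target_genes`` target genes
    to keep the design affordable; counts refer to those targets.
    """
    committee = "{RF.sf+RF.pi+ElNet}|LASSO"
    out: dict[int, list[dict]] = {}
    for n in sample_sizes:
        rows = []
        for rep in range(n_replicates):
            seed = int(base_seed + rep)
            sim = SimParams(n_samples=n, n_genes=n_genes, n_edges=n_edges, seed=seed)
            genotypes, gold, expression = simulate_dataset(sim)
            targets = expression.gene_ids[:n_target_genes]
            target_expr = type(expression)(
                values=expression.values[:, :n_target_genes],
                sample_ids=list(expression.sample_ids),
                gene_ids=list(targets),
            )
            learner = LearnerParams(n_trees=n_trees, seed=seed)
            spec = parse_committee(committee)
            matrices = {
                m: map_all_genes(genotypes, target_expr, m, learner)
                for m in (*spec.members, "LASSO")
            }
            combined = build_committee(spec, matrices, learner.zero_tol)
            edges = scores_to_edges(combined, genotypes.marker_map, drop_zero=True)
            rows.append(
                {
                    "n_samples": n,
                    "seed": seed,
                    "lasso_nonzero": int((matrices["LASSO"].values >= learner.zero_tol).sum()),
                    "committee_nonzero": int((combined.values != 0).sum()),
                    "n_predictions": len(edges),
                }
            )
            logger.info("sparsity n=%d rep=%d: %s", n, rep, rows[-1])
        out[n] = rows
    return out


def _planted_instance(n_genes: int, n_samples: int, seed: int, noise_sd: float,
                      cis_effect: float) -> tuple[GenotypeMatrix, GoldNetwork, SimParams]:
    """A single regulatory edge fed by the one cis mutation in the system.

    Only the regulator gene carries a cis mutation; every other marker is
    a trans mutation with no outgoing edges, hence inert.  The planted
    regulator's genotype is then the sole genetic driver of the target's
    expression.
    """
    params = SimParams(
        n_samples=n_samples, n_genes=n_genes, n_edges=0, n_chromosomes=5,
        noise_sd=noise_sd, effect_size_cis=cis_effect, seed=seed,
    )
    genotypes = simulate_genotypes(params)
    genes = list(genotypes.marker_map.gene_ids)
    rng = np.random.default_rng(seed)
    reg, tgt = rng.choice(len(genes), size=2, replace=False)
    genotypes.marker_map.mutation_type[:] = "trans"
    genotypes.marker_map.mutation_type[reg] = "cis"
    gold = GoldNetwork(
        edges=[(genes[reg], genes[tgt])],
        weights={(genes[reg], genes[tgt]): 1.0},
        gene_ids=genes,
    )
    return genotypes, gold, params


def planted_edge_benchmark(
    methods: tuple[str, ...] = ("RF.sf", "RF.pi", "LASSO", "ElNet"),
    n_replicates: int = 10,
    n_genes: int = 50,
    n_samples: int = 200,
    n_trees: int = 100,
    noise_sd: float = 0.05,
    cis_effect: float = 2.0,
    base_seed: int = 0,
) -> dict[str, list[int]]:
    """Rank of the single true edge under each scorer, per replicate.

    Rank 1 means the planted regulator->target pair tops the full edge
    ranking; linked markers on the regulator's chromosome are the usual
    competitors immediately below it.
    """
    ranks: dict[str, list[int]] = {m: [] for m in methods}
    for rep in range(n_replicates):
        seed = int(base_seed + rep)
        genotypes, gold, params = _planted_instance(
            n_genes, n_samples, seed, noise_sd, cis_effect
        )
        expression = simulate_expression(gold, genotypes, params)
        learner = LearnerParams(n_trees=n_trees, seed=seed)
        true_edge = gold.edges[0]
        for m in methods:
            sm = map_all_genes(genotypes, expression, m, learner)
            edges = scores_to_edges(sm, genotypes.marker_map)
            rank = edges.pairs().index(true_edge) + 1
            ranks[m].append(rank)
            logger.info("planted rep=%d method=%s rank=%d", rep, m, rank)
    return ranks
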