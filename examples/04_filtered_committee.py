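"""The LASSO-gated (filtered) committee: few predictions, high precision.

Builds the committee {RF.sf+RF.pi+ElNet}|LASSO: RF.sf, RF.pi and ElNet
scores are z-scored and averaged, then every marker-gene pair whose LASSO
coefficient is zero is erased.  The result predicts far fewer edges than
the unfiltered committee -- within a linked region only the one marker
the LASSO picked survives -- trading recall for precision.
"""

from qtlcommittee import (
    LearnerParams,
    SimParams,
    build_committee,
    evaluate_predictions,
    map_all_genes,
    parse_committee,
    scores_to_edges,
    simulate_dataset,
)

sim = SimParams(n_samples=150, n_genes=40, n_edges=100, n_chromosomes=8, seed=3)
genotypes, gold, expression = simulate_dataset(sim)
learner = LearnerParams(n_trees=150, seed=3)
genes = list(genotypes.marker_map.gene_ids)

spec = parse_committee("{RF.sf+RF.pi+ElNet}|LASSO")
matrices = {
    m: map_all_genes(genotypes, expression, m, learner)
    for m in (*spec.members, "LASSO")
}
filtered = build_committee(spec, matrices)

universe = len(genes) * (len(genes) - 1)
lasso_support = int((matrices["LASSO"].values > 0).sum())
edges = scores_to_edges(filtered, genotypes.marker_map, drop_zero=True)
rep = evaluate_predictions(edges, gold, genes)

print(f"pair universe: {universe}, LASSO support: {lasso_support}, "
      f"filtered-committee predictions: {len(edges)}")
print(f"{spec.label}: AUROC {rep['auroc']:.3f}  AUPR {rep['aupr']:.3f}  "
      f"({rep['n_true_positives']} of {rep['P']} true edges retrieved)")
print("\nThe prediction list is sparse by construction (its support is a")
print("subset of the LASSO support); precision among the emitted edges is")
print(f"{rep['n_true_positives'] / rep['n_predictions']:.2f}.")
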