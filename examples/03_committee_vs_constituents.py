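"""The committee effect: averaging RF.sf and LASSO scores beats either alone.

Runs one replicate of the committee-gain benchmark: a 100-gene network
with 250 edges observed in 150 RILs, mapped gene by gene with the
random-forest selection frequency and the LASSO, combined as the mean of
the globally z-scored score matrices, and evaluated against the gold
network over the complete edge ranking.
"""

from qtlcommittee.benchmark import committee_gain_benchmark

(scores,) = committee_gain_benchmark(
    n_replicates=1, n_genes=100, n_samples=150, n_edges=250,
    n_trees=300, committee="RF.sf+LASSO", base_seed=0,
)
for label, rep in scores.items():
    print(f"{label:12s} AUROC {rep['auroc']:.3f}  AUPR {rep['aupr']:.3f}")

print("\nAUPR is the discriminating metric under class imbalance (250 true")
print("edges among 9,900 pairs); the committee's gain concentrates there,")
print("because averaging z-scored matrices suppresses the false positives")
print("each method produces for its own private reasons.")
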