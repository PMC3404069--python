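"""Simulate a small RIL systems-genetics benchmark and inspect its structure.

Generates genotypes for a recombinant-inbred-line population (one binary
marker per gene, local linkage along chromosomes), a directed regulatory
network with scale-free out-degree, and steady-state expression with cis
and trans genetic effects.
"""

import numpy as np

from qtlcommittee import SimParams, simulate_dataset

params = SimParams(
    n_samples=200, n_genes=50, n_edges=120, n_chromosomes=10,
    recomb_prob=0.1, seed=7,
)
genotypes, network, expression = simulate_dataset(params)

print(f"genotypes: {genotypes.n_samples} samples x {genotypes.n_markers} markers")
print(f"allele frequency mean {genotypes.values.mean():.3f} (RIL cross: expect ~0.5)")

mm = genotypes.marker_map
cors = []
for ci in range(params.n_chromosomes):
    idx = np.flatnonzero(mm.chromosome == ci)
    for a, b in zip(idx, idx[1:]):
        cors.append(np.corrcoef(genotypes.values[:, a], genotypes.values[:, b])[0, 1])
print(f"adjacent-marker correlation {np.mean(cors):.3f} "
      f"(chain with flip prob {params.recomb_prob}: expect {1 - 2 * params.recomb_prob})")

out_deg = list(network.out_degrees().values())
in_deg = list(network.in_degrees().values())
print(f"network: {len(network)} edges, mean degree {np.mean(out_deg):.2f}, "
      f"max out-degree {max(out_deg)} (hub), max in-degree {max(in_deg)}")
print(f"cis markers: {mm.cis_mask.sum()} of {len(mm)} (expect ~25%)")
print(f"expression: {expression.n_samples} x {expression.n_genes}, "
      f"per-gene sd ranges {expression.values.std(axis=0).min():.3f}"
      f"..{expression.values.std(axis=0).max():.3f}")
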