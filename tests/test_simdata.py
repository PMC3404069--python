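"""Simulator behavior: linkage structure, network shape, expression model."""

import numpy as np
import pytest

from qtlcommittee import (
    SimParams,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
    simulate_network,
)
from qtlcommittee.simdata import GoldNetwork, steady_state_system


def test_genotypes_are_binary_and_evenly_partitioned():
    params = SimParams(n_samples=50, n_genes=47, n_edges=0, n_chromosomes=9, seed=1)
    geno = simulate_genotypes(params)
    assert set(np.unique(geno.values)) <= {0, 1}
    sizes = np.bincount(geno.marker_map.chromosome)
    assert len(sizes) == 9
    assert sizes.max() - sizes.min() <= 1
    # one marker per gene, bijection
    assert len(set(geno.marker_map.gene_ids)) == 47


def test_no_recombination_limit_gives_uniform_chromosomes():
    params = SimParams(n_samples=40, n_genes=30, n_edges=0, n_chromosomes=5,
                       recomb_prob=1e-12, seed=3)
    geno = simulate_genotypes(params)
    for ci in range(5):
        block = geno.values[:, geno.marker_map.chromosome == ci]
        assert (block == block[:, [0]]).all()


@pytest.mark.parametrize("recomb,expected", [(0.5, 0.0), (0.1, 0.8)])
def test_adjacent_marker_correlation_matches_markov_chain(recomb, expected):
    # flip probability r gives adjacent-marker correlation 1 - 2r
    params = SimParams(n_samples=2000, n_genes=40, n_edges=0, n_chromosomes=4,
                       recomb_prob=recomb, seed=11)
    geno = simulate_genotypes(params)
    mm = geno.marker_map
    cors = []
    for ci in range(4):
        idx = np.flatnonzero(mm.chromosome == ci)
        for a, b in zip(idx, idx[1:]):
            cors.append(np.corrcoef(geno.values[:, a], geno.values[:, b])[0, 1])
    assert abs(np.mean(cors) - expected) < 0.05


def test_cross_chromosome_markers_uncorrelated_and_balanced():
    params = SimParams(n_samples=3000, n_genes=20, n_edges=0, n_chromosomes=2,
                       recomb_prob=0.1, seed=5)
    geno = simulate_genotypes(params)
    mm = geno.marker_map
    a = np.flatnonzero(mm.chromosome == 0)[0]
    b = np.flatnonzero(mm.chromosome == 1)[0]
    assert abs(np.corrcoef(geno.values[:, a], geno.values[:, b])[0, 1]) < 0.06
    # symmetric RIL cross: allele frequency 1/2 at every marker
    freqs = geno.values.mean(axis=0)
    se = 0.5 / np.sqrt(params.n_samples)
    assert (np.abs(freqs - 0.5) < 3.5 * se).all()


def test_network_edge_count_and_structure_invariants():
    for seed in range(10):
        params = SimParams(n_samples=2, n_genes=25, n_edges=70, n_chromosomes=5, seed=seed)
        net = simulate_network(params)
        assert len(net) == 70
        assert len(net.edge_set) == 70  # no duplicates
        assert all(r != t for r, t in net.edges)  # no self-loops


def test_network_empty_and_infeasible():
    assert len(simulate_network(SimParams(n_samples=2, n_genes=10, n_edges=0, n_chromosomes=2))) == 0
    with pytest.raises(ValueError):
        SimParams(n_samples=2, n_genes=5, n_edges=21, n_chromosomes=2)


def test_network_mean_out_degree_matches_requested_density():
    # 1000 genes / 2000 edges is the density of the benchmark's sparsest net
    params = SimParams(n_samples=2, n_genes=1000, n_edges=2000, seed=0)
    net = simulate_network(params)
    assert np.mean(list(net.out_degrees().values())) == pytest.approx(2.0)


def test_out_degree_heavier_tailed_than_in_degree():
    wins = 0
    for seed in range(20):
        params = SimParams(n_samples=2, n_genes=100, n_edges=300, n_chromosomes=10, seed=seed)
        net = simulate_network(params)
        if np.var(list(net.out_degrees().values())) > np.var(list(net.in_degrees().values())):
            wins += 1
    assert wins >= 18


def test_cis_effect_without_network_shifts_only_its_gene():
    params = SimParams(n_samples=60, n_genes=10, n_edges=0, n_chromosomes=2,
                       noise_sd=0.0, effect_size_cis=1.0, seed=9)
    geno = simulate_genotypes(params)
    geno.marker_map.mutation_type[:] = "cis"
    net = GoldNetwork(edges=[], weights={}, gene_ids=list(geno.marker_map.gene_ids))
    expr = simulate_expression(net, geno, params)
    for k in range(10):
        g0 = expr.values[geno.values[:, k] == 0, k]
        g1 = expr.values[geno.values[:, k] == 1, k]
        if len(g0) and len(g1):
            assert g1.mean() - g0.mean() == pytest.approx(1.0, abs=1e-12)
    # no propagation: each gene constant within its genotype class
    for k in range(10):
        for allele in (0, 1):
            vals = expr.values[geno.values[:, k] == allele, k]
            assert np.ptp(vals) < 1e-12 if len(vals) else True


def test_zero_effects_zero_noise_is_constant():
    params = SimParams(n_samples=30, n_genes=12, n_edges=20, n_chromosomes=3,
                       noise_sd=0.0, effect_size_cis=0.0, effect_size_trans=0.0, seed=4)
    geno, net, expr = simulate_dataset(params)
    assert np.ptp(expr.values, axis=0).max() < 1e-10


def test_single_edge_propagates_cis_signal():
    params = SimParams(n_samples=200, n_genes=6, n_edges=0, n_chromosomes=2,
                       noise_sd=0.01, effect_size_cis=2.0, seed=13)
    geno = simulate_genotypes(params)
    geno.marker_map.mutation_type[:] = "cis"
    genes = list(geno.marker_map.gene_ids)
    net = GoldNetwork(edges=[(genes[0], genes[3])], weights={(genes[0], genes[3]): 1.0},
                      gene_ids=genes)
    expr = simulate_expression(net, geno, params)
    r = np.corrcoef(geno.values[:, 0], expr.values[:, 3])[0, 1]
    assert r > 0.5


def test_noiseless_expression_is_exact_fixed_point():
    params = SimParams(n_samples=25, n_genes=15, n_edges=40, n_chromosomes=3,
                       noise_sd=0.0, seed=21)
    geno, net, expr = simulate_dataset(params)
    b, c = steady_state_system(net, geno, params)
    for s in range(params.n_samples):
        recon = c[s] + b[s] @ expr.values[s]
        np.testing.assert_allclose(recon, expr.values[s], atol=1e-9)
    # damping bound honored for every sample
    for s in range(params.n_samples):
        rho = np.max(np.abs(np.linalg.eigvals(b[s])))
        assert rho <= params.network_damping + 1e-9


def test_pipeline_determinism_bit_identical():
    params = SimParams(n_samples=20, n_genes=12, n_edges=25, n_chromosomes=4, seed=77)
    g1, n1, e1 = simulate_dataset(params)
    g2, n2, e2 = simulate_dataset(params)
    assert (g1.values == g2.values).all()
    assert n1.edges == n2.edges and n1.weights == n2.weights
    assert (e1.values == e2.values).all()
    assert list(g1.marker_map.mutation_type) == list(g2.marker_map.mutation_type)


def test_parameter_validation():
    with pytest.raises(ValueError):
        SimParams(n_samples=0, n_genes=10, n_edges=0)
    with pytest.raises(ValueError):
        SimParams(n_samples=5, n_genes=10, n_edges=0, n_chromosomes=20)
    with pytest.raises(ValueError):
        SimParams(n_samples=5, n_genes=30, n_edges=0, recomb_prob=0.0)
    with pytest.raises(ValueError):
        SimParams(n_samples=5, n_genes=30, n_edges=0, network_damping=1.5)
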