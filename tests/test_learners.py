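"""Scorer behavior: planted-signal recovery, conservation, grouping, seeds."""

import numpy as np
import pytest

from qtlcommittee import (
    ExpressionMatrix,
    LearnerParams,
    elnet_scores,
    lasso_scores,
    map_all_genes,
    rf_permutation_importance,
    rf_selection_frequency,
)
from qtlcommittee.learners import _grow_forest, gene_seed

from conftest import planted_design

ALL_SCORERS = [rf_selection_frequency, rf_permutation_importance, lasso_scores, elnet_scores]


@pytest.fixture(scope="module")
def params():
    return LearnerParams(n_trees=120, seed=5)


@pytest.mark.parametrize("scorer", ALL_SCORERS)
def test_constant_response_scores_zero(scorer, params):
    rng = np.random.default_rng(0)
    x = (rng.random((40, 12)) < 0.5).astype(float)
    y = np.full(40, 3.7)
    assert np.all(scorer(x, y, params) == 0.0)


@pytest.mark.parametrize("scorer", ALL_SCORERS)
def test_too_few_samples_error(scorer, params):
    with pytest.raises(ValueError):
        scorer(np.zeros((1, 4)), np.zeros(1), params)


def test_selection_frequency_conserves_split_count(params):
    x, y = planted_design(n_samples=80, n_markers=20, seed=1, noise_sd=0.3)
    scores = rf_selection_frequency(x, y, params, seed=99)
    # regrow the identical forest from the same stream and count its splits
    forest = _grow_forest(x, y, params, np.random.default_rng(99))
    total_internal = sum(
        tree.tree_.node_count - tree.tree_.n_leaves for tree, _ in forest
    )
    assert scores.sum() == total_internal
    assert (scores >= 0).all()


def test_rf_scorers_recover_planted_marker(params):
    x, y = planted_design(n_samples=100, n_markers=50, planted=7, seed=2)
    sf = rf_selection_frequency(x, y, params, seed=3)
    pi = rf_permutation_importance(x, y, params, seed=3)
    assert sf.argmax() == 7 and sf[7] > np.delete(sf, 7).max()
    assert pi.argmax() == 7 and pi[7] > 0


def test_unused_marker_has_zero_permutation_importance(params):
    x, y = planted_design(n_samples=80, n_markers=10, planted=0, seed=4)
    x[:, 5] = 1.0  # constant column can never be a split variable
    pi = rf_permutation_importance(x, y, params, seed=6)
    assert pi[5] == 0.0


def test_lasso_planted_signal_sparse_support(params):
    rng = np.random.default_rng(11)
    x = rng.standard_normal((100, 30))
    y = 2.0 * x[:, 4]
    scores = lasso_scores(x, y, params, seed=12)
    assert scores.argmax() == 4
    assert (scores > 0).sum() <= 5


def test_lasso_concentrates_on_one_of_two_linked_markers(params):
    # tight LD pair (one discordant sample): the LASSO hands essentially
    # all coefficient mass to the marker more correlated with the response
    rng = np.random.default_rng(21)
    x = (rng.random((120, 10)) < 0.5).astype(float)
    x[:, 7] = x[:, 3]
    x[0, 7] = 1 - x[0, 7]
    y = x[:, 3].astype(float)
    las = lasso_scores(x, y, params, seed=22)
    eln = elnet_scores(x, y, params, seed=22)
    pair = np.sort(las[[3, 7]])
    assert las.argmax() == 3
    assert pair[0] <= 0.10 * pair[1]  # winner takes (almost) all
    assert (las > 0).sum() <= (eln > 0).sum()  # grouping: wider ElNet support


def test_elnet_spreads_mass_over_identical_markers(params):
    # exactly duplicated markers: the ridge term makes the Elastic Net
    # optimum symmetric, so both copies score alike
    rng = np.random.default_rng(21)
    x = (rng.random((120, 10)) < 0.5).astype(float)
    x[:, 3] = x[:, 7]
    y = x[:, 3].astype(float)
    eln = elnet_scores(x, y, params, seed=22)
    pair = np.sort(eln[[3, 7]])
    assert pair[1] > 0
    assert pair[0] >= 0.5 * pair[1]
    assert eln.argmax() in (3, 7)


@pytest.mark.parametrize("scorer", [lasso_scores, elnet_scores])
def test_penalized_scores_invariant_to_marker_order(scorer, params):
    x, y = planted_design(n_samples=60, n_markers=15, planted=2, seed=31, noise_sd=0.2)
    perm = np.random.default_rng(32).permutation(15)
    direct = scorer(x, y, params, seed=33)
    permuted = scorer(x[:, perm], y, params, seed=33)
    # identical support; values agree to the coordinate-descent tolerance
    np.testing.assert_array_equal(permuted > 0, direct[perm] > 0)
    np.testing.assert_allclose(permuted, direct[perm], atol=1e-4)


def test_planted_marker_ranked_first_across_seeds():
    # each scorer should find one strong predictor among 50 markers in
    # nearly every replicate
    params = LearnerParams(n_trees=150, seed=0)
    for scorer in ALL_SCORERS:
        hits = 0
        for rep in range(10):
            x, y = planted_design(n_samples=150, n_markers=50, planted=rep % 50,
                                  seed=100 + rep, noise_sd=0.05)
            scores = scorer(x, y, params, seed=200 + rep)
            hits += scores.argmax() == rep % 50
        assert hits >= 9, scorer.__name__


def test_map_all_genes_matrix_structure(small_dataset, fast_learner):
    genotypes, _, expression = small_dataset
    sub = ExpressionMatrix(
        values=expression.values[:, :3],
        sample_ids=list(expression.sample_ids),
        gene_ids=list(expression.gene_ids[:3]),
    )
    sm = map_all_genes(genotypes, sub, "LASSO", fast_learner)
    assert sm.values.shape == (genotypes.n_markers, 3)
    assert sm.method_label == "LASSO"
    # single-gene mapping equals the corresponding column
    one = ExpressionMatrix(
        values=expression.values[:, [1]],
        sample_ids=list(expression.sample_ids),
        gene_ids=[expression.gene_ids[1]],
    )
    sm_one = map_all_genes(genotypes, one, "LASSO", fast_learner)
    np.testing.assert_array_equal(sm_one.values[:, 0], sm.values[:, 1])


def test_map_all_genes_gene_order_independent(small_dataset, fast_learner):
    genotypes, _, expression = small_dataset
    sub_ids = list(expression.gene_ids[:4])
    fwd = ExpressionMatrix(expression.values[:, :4], list(expression.sample_ids), sub_ids)
    rev = ExpressionMatrix(expression.values[:, :4][:, ::-1], list(expression.sample_ids), sub_ids[::-1])
    m_fwd = map_all_genes(genotypes, fwd, "RF.sf", fast_learner)
    m_rev = map_all_genes(genotypes, rev, "RF.sf", fast_learner)
    np.testing.assert_array_equal(m_fwd.values, m_rev.values[:, ::-1])


def test_map_all_genes_deterministic(small_dataset, fast_learner):
    genotypes, _, expression = small_dataset
    sub = ExpressionMatrix(expression.values[:, :2], list(expression.sample_ids),
                           list(expression.gene_ids[:2]))
    a = map_all_genes(genotypes, sub, "ElNet", fast_learner)
    b = map_all_genes(genotypes, sub, "ElNet", fast_learner)
    np.testing.assert_array_equal(a.values, b.values)


def test_gene_seed_is_identity_keyed():
    assert gene_seed(1, "G01") == gene_seed(1, "G01")
    assert gene_seed(1, "G01") != gene_seed(1, "G02")
    assert gene_seed(1, "G01") != gene_seed(2, "G01")


def test_unknown_method_and_param_validation(small_dataset, fast_learner):
    genotypes, _, expression = small_dataset
    with pytest.raises(ValueError):
        map_all_genes(genotypes, expression, "Gini", fast_learner)
    with pytest.raises(ValueError):
        LearnerParams(n_trees=0)
    with pytest.raises(ValueError):
        LearnerParams(cv_folds=1)
    with pytest.raises(ValueError):
        LearnerParams(s_grid=(0.0, 0.5))
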