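"""Multivariate marker-importance scorers for eQTL mapping.

Each scorer treats one gene's expression vector as the response and the
full genotype matrix as predictors, and returns one importance score per
marker:

``RF.sf``
    random-forest selection frequency — the number of internal nodes, over
    all trees, whose splitting variable is the marker.
``RF.pi``
    random-forest permutation importance — the mean (over trees) increase
    in out-of-bag mean-squared error when the marker's out-of-bag values
    are permuted; *unscaled*, i.e. not divided by its standard deviation.
``LASSO``
    absolute coefficients of an L1-constrained linear fit with a tiny
    quadratic penalty (lambda2 = 0.001), the constraint expressed as a
    fraction ``s`` of the full-model L1 norm, ``s`` chosen by 10-fold
    cross-validation with an imposed floor of 0.25.
``ElNet``
    the same procedure with a substantial quadratic penalty (lambda2 = 1),
    which spreads coefficient mass over groups of correlated markers
    (e.g. markers in linkage disequilibrium) instead of picking one.

The penalized fits solve the elastic net as a LASSO on the ridge-augmented
design (append sqrt(lambda2) * I rows, rescale by 1/sqrt(1+lambda2)) and
read coefficients off the least-angle-regression path, which makes the
L1-norm-fraction parameterisation exact at the path knots and piecewise
linear in between.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .simdata import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerParams",
    "ScoreMatrix",
    "rf_selection_frequency",
    "rf_permutation_importance",
    "lasso_scores",
    "elnet_scores",
    "map_all_genes",
    "METHOD_LABELS",
]

_DEFAULT_S_GRID = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class LearnerParams:
    """Hyperparameters of the four scorers.

    ``n_trees`` defaults to 5000 (the production value); tests and the
    bundled benchmarks use a few hundred.  ``mtry_fraction`` is the
    regression default of one third of the predictors, ``min_node_size``
    the default of 5.  ``s_min`` is the cross-validation floor on the L1
    fraction for the LASSO; the Elastic Net applies no floor unless
    ``elnet_s_min`` is set.
    """

    n_trees: int = 5000
    mtry_fraction: float = 1.0 / 3.0
    min_node_size: int = 5
    lasso_lambda2: float = 0.001
    elnet_lambda2: float = 1.0
    s_grid: tuple[float, ...] = _DEFAULT_S_GRID
    s_min: float = 0.25
    elnet_s_min: float | None = None
    cv_folds: int = 10
    zero_tol: float = 1e-10
    scale_response: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not all(0.0 < s <= 1.0 for s in self.s_grid):
            raise ValueError("all s_grid values must lie in (0, 1]")
        if not (min(self.s_grid) <= self.s_min <= max(self.s_grid)):
            raise ValueError("s_min must lie within the s_grid range")
        if not 0.0 < self.mtry_fraction <= 1.0:
            raise ValueError("mtry_fraction must lie in (0, 1]")

    def replace(self, **kwargs) -> "LearnerParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ScoreMatrix:
    """Markers x genes importance scores for one method or committee."""

    values: np.ndarray
    marker_ids: list[str]
    gene_ids: list[str]
    method_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.marker_ids), len(self.gene_ids)):
            raise ValueError("score shape does not match marker_ids / gene_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.marker_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, method_label: str) -> "ScoreMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            marker_ids=[str(i) for i in frame.index],
            gene_ids=[str(c) for c in frame.columns],
            method_label=method_label,
        )


def _as_design(genotypes) -> np.ndarray:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.values.astype(float)
    return np.asarray(genotypes, dtype=float)


def _check_xy(x: np.ndarray, y: np.ndarray) -> None:
    if x.ndim != 2:
        raise ValueError("genotype design must be 2-D")
    if y.ndim != 1 or len(y) != x.shape[0]:
        raise ValueError("expression vector length must match sample count")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")


# ---------------------------------------------------------------------------
# random forest scorers
# ---------------------------------------------------------------------------


def _grow_forest(
    x: np.ndarray, y: np.ndarray, params: LearnerParams, rng: np.random.Generator
) -> list[tuple[DecisionTreeRegressor, np.ndarray]]:
    """Bagged regression trees with per-split feature subsampling.

    Bootstrap indices are drawn from ``rng`` so that out-of-bag sets are
    known exactly; each tree's split randomness is seeded from the same
    stream.  Returns (tree, oob_indices) pairs.
    """
    n, p = x.shape
    mtry = max(1, int(p * params.mtry_fraction))
    all_idx = np.arange(n)
    forest = []
    for _ in range(params.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_idx, boot)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=params.min_node_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x[boot], y[boot])
        forest.append((tree, oob))
    return forest


def _split_counts(tree: DecisionTreeRegressor, n_features: int) -> np.ndarray:
    feats = tree.tree_.feature
    return np.bincount(feats[feats >= 0], minlength=n_features)


def rf_selection_frequency(genotypes, expression_of_gene, params: LearnerParams, seed: int | None = None) -> np.ndarray:
    """RF.sf: how often each marker is the chosen splitting variable.

    The scores over all markers sum to the total number of internal split
    nodes in the forest.  A constant response grows trees with no splits,
    so every marker scores 0.
    """
    x = _as_design(genotypes)
    y = np.asarray(expression_of_gene, dtype=float)
    _check_xy(x, y)
    if np.ptp(y) == 0:
        return np.zeros(x.shape[1])
    rng = np.random.default_rng(params.seed if seed is None else seed)
    forest = _grow_forest(x, y, params, rng)
    counts = np.zeros(x.shape[1])
    for tree, _ in forest:
        counts += _split_counts(tree, x.shape[1])
    return counts


def rf_permutation_importance(genotypes, expression_of_gene, params: LearnerParams, seed: int | None = None) -> np.ndarray:
    """RF.pi: mean out-of-bag MSE increase under marker permutation.

    One permutation per (tree, marker); only markers actually used by a
    tree can change its predictions, so unused markers contribute exactly
    zero.  The mean is over all trees and is left unscaled.
    """
    x = _as_design(genotypes)
    y = np.asarray(expression_of_gene, dtype=float)
    _check_xy(x, y)
    if np.ptp(y) == 0:
        return np.zeros(x.shape[1])
    rng = np.random.default_rng(params.seed if seed is None else seed)
    forest = _grow_forest(x, y, params, rng)
    p = x.shape[1]
    imp = np.zeros(p)
    for tree, oob in forest:
        if len(oob) == 0:
            continue
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if len(used) == 0:
            continue
        xo = x[oob]
        yo = y[oob]
        base = float(np.mean((tree.predict(xo) - yo) ** 2))
        m = len(oob)
        stacked = np.repeat(xo[None, :, :], len(used), axis=0)
        for k, j in enumerate(used):
            stacked[k, :, j] = xo[rng.permutation(m), j]
        preds = tree.predict(stacked.reshape(-1, p)).reshape(len(used), m)
        imp[used] += ((preds - yo[None, :]) ** 2).mean(axis=1) - base
    return imp / params.n_trees


# ---------------------------------------------------------------------------
# penalized regression scorers
# ---------------------------------------------------------------------------


@dataclass
class _PathFit:
    mu: np.ndarray
    sd: np.ndarray
    ybar: float
    coefs: np.ndarray  # features x knots, augmented-problem scale
    l1: np.ndarray  # L1 norm at each knot
    lambda2: float

    def coefs_at(self, s: float) -> np.ndarray:
        """Naive elastic-net coefficients at L1-norm fraction ``s``."""
        total = self.l1[-1]
        if total <= 0:
            return np.zeros(self.coefs.shape[0])
        target = s * total
        k = int(np.searchsorted(self.l1, target))
        if k == 0:
            beta = self.coefs[:, 0] * (target / self.l1[0] if self.l1[0] > 0 else 0.0)
        elif k >= self.coefs.shape[1]:
            beta = self.coefs[:, -1]
        else:
            span = self.l1[k] - self.l1[k - 1]
            w = (target - self.l1[k - 1]) / span if span > 0 else 1.0
            beta = (1 - w) * self.coefs[:, k - 1] + w * self.coefs[:, k]
        # augmented-problem coefficients relate to the naive elastic net by
        # a factor sqrt(1 + lambda2)
        return beta / np.sqrt(1.0 + self.lambda2)

    def predict(self, x: np.ndarray, s: float) -> np.ndarray:
        beta = self.coefs_at(s)
        return self.ybar + ((x - self.mu) / self.sd) @ beta


def _fit_path(x: np.ndarray, y: np.ndarray, lambda2: float) -> _PathFit:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd
    ybar = float(y.mean())
    yc = y - ybar
    p = x.shape[1]
    if lambda2 > 0:
        scale = 1.0 / np.sqrt(1.0 + lambda2)
        xa = np.vstack([xs, np.sqrt(lambda2) * np.eye(p)]) * scale
        ya = np.concatenate([yc, np.zeros(p)])
    else:
        xa, ya = xs, yc
    # coordinate-descent L1 path (robust where LARS degenerates on
    # near-collinear designs); the grid end approximates the full model
    alpha_max = np.max(np.abs(xa.T @ ya)) / xa.shape[0]
    if alpha_max <= 0:
        alpha_max = 1.0
    grid = np.geomspace(alpha_max, alpha_max * 1e-4, 60)
    with warnings.catch_warnings():
        # at the dense end of the path (many markers, many active
        # coefficients) the duality gap can stall marginally above the
        # stopping tolerance; those near-saturated solutions only set the
        # full-model L1-norm reference for the s fraction, where ~1e-3
        # relative error is immaterial, so the stock warning is noise here
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        _, coefs, _ = lasso_path(xa, ya, alphas=grid, precompute=True)
    if coefs.shape[1] == 1:  # degenerate: constant response
        coefs = np.hstack([coefs, coefs])
    l1 = np.abs(coefs).sum(axis=0)
    return _PathFit(mu=mu, sd=sd, ybar=ybar, coefs=coefs, l1=l1, lambda2=lambda2)


def _penalized_scores(
    x: np.ndarray,
    y: np.ndarray,
    lambda2: float,
    params: LearnerParams,
    seed: int,
    s_min: float | None,
) -> np.ndarray:
    _check_xy(x, y)
    n = x.shape[0]
    if float(np.std(y)) < 1e-14:
        return np.zeros(x.shape[1])
    # predictors are standardized inside the path fit; the response is
    # centered there but, by default, NOT scaled — coefficient magnitudes
    # then carry a gene's signal strength into the global cross-gene
    # ranking (scale_response restores per-gene unit variance instead)
    y = y - y.mean()
    if params.scale_response:
        y = y / np.std(y)

    rng = np.random.default_rng(seed)
    folds = params.cv_folds
    if n < folds:
        logger.warning("reducing cv_folds from %d to %d (only %d samples)", folds, n, n)
        folds = n
    s_grid = np.asarray(params.s_grid, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1)))
    cv_err = np.zeros((folds, len(s_grid)))
    for i, (tr, va) in enumerate(kf.split(x)):
        fit = _fit_path(x[tr], y[tr], lambda2)
        for j, s in enumerate(s_grid):
            resid = y[va] - fit.predict(x[va], s)
            cv_err[i, j] = float(np.mean(resid**2))
    mean_err = cv_err.mean(axis=0)
    # minimum CV error; ties broken toward the larger (less restrictive) s
    best = len(mean_err) - 1 - int(np.argmin(mean_err[::-1]))
    s_hat = float(s_grid[best])
    if s_min is not None:
        s_hat = max(s_hat, s_min)
    logger.debug("penalized fit: lambda2=%g chose s=%.2f", lambda2, s_hat)

    fit = _fit_path(x, y, lambda2)
    scores = np.abs(fit.coefs_at(s_hat))
    scores[scores < params.zero_tol] = 0.0
    return scores


def lasso_scores(genotypes, expression_of_gene, params: LearnerParams, seed: int | None = None) -> np.ndarray:
    """|LASSO coefficients| at the cross-validated L1 fraction (floor 0.25)."""
    x = _as_design(genotypes)
    y = np.asarray(expression_of_gene, dtype=float)
    return _penalized_scores(
        x, y, params.lasso_lambda2, params,
        params.seed if seed is None else seed, params.s_min,
    )


def elnet_scores(genotypes, expression_of_gene, params: LearnerParams, seed: int | None = None) -> np.ndarray:
    """|Elastic-Net coefficients| (lambda2 = 1) at the cross-validated L1 fraction."""
    x = _as_design(genotypes)
    y = np.asarray(expression_of_gene, dtype=float)
    return _penalized_scores(
        x, y, params.elnet_lambda2, params,
        params.seed if seed is None else seed, params.elnet_s_min,
    )


# ---------------------------------------------------------------------------
# per-gene mapping loop
# ---------------------------------------------------------------------------

_SCORERS = {
    "RF.sf": rf_selection_frequency,
    "RF.pi": rf_permutation_importance,
    "LASSO": lasso_scores,
    "ElNet": elnet_scores,
}

METHOD_LABELS = tuple(_SCORERS)


def gene_seed(global_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed keyed on gene identity.

    Keying on the identifier (not the column position) makes the score
    matrix invariant to the order genes are presented in.
    """
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(gene_id.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def map_all_genes(genotypes, expression: ExpressionMatrix, method: str, params: LearnerParams) -> ScoreMatrix:
    """Apply one scorer to every gene; column g holds gene g's marker scores.

    Genes are scored independently with per-gene seeds derived from the
    global seed and the gene identifier, so the result does not depend on
    processing order.
    """
    if method not in _SCORERS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_LABELS}")
    scorer = _SCORERS[method]
    x = _as_design(genotypes)
    if isinstance(genotypes, GenotypeMatrix):
        if genotypes.sample_ids != expression.sample_ids:
            raise ValueError("genotype and expression sample sets differ")
        marker_ids = list(genotypes.marker_map.marker_ids)
    else:
        marker_ids = [f"M{i + 1}" for i in range(x.shape[1])]

    values = np.empty((x.shape[1], expression.n_genes))
    for gi, gene in enumerate(expression.gene_ids):
        try:
            values[:, gi] = scorer(x, expression.values[:, gi], params, seed=gene_seed(params.seed, gene))
        except Exception as exc:  # attach gene identity to any failure
            raise RuntimeError(f"scoring gene {gene!r} with {method} failed: {exc}") from exc
        logger.info("scored gene %s (%d/%d) with %s", gene, gi + 1, expression.n_genes, method)
    return ScoreMatrix(values=values, marker_ids=marker_ids, gene_ids=list(expression.gene_ids), method_label=method)
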