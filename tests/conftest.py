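import numpy as np
import pytest

from qtlcommittee import LearnerParams, SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_params():
    """A 30-gene RIL benchmark, small enough for per-test scoring."""
    return SimParams(n_samples=100, n_genes=30, n_edges=60, n_chromosomes=10, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def fast_learner():
    """Desk-scale learner settings (the production default is 5000 trees)."""
    return LearnerParams(n_trees=80, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def planted_design(n_samples=100, n_markers=50, planted=0, noise_sd=0.01, seed=0, slope=1.0):
    """Genotypes plus a response driven by a single planted marker."""
    r = np.random.default_rng(seed)
    x = (r.random((n_samples, n_markers)) < 0.5).astype(float)
    y = slope * x[:, planted] + noise_sd * r.standard_normal(n_samples)
    return x, y
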