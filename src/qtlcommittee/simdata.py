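"""Synthetic systems-genetics benchmark data.

Emulates the design of the DREAM5 SYSGEN A in-silico challenge at a
configurable scale: a recombinant-inbred-line (RIL) population genotyped at
one biallelic marker per gene (0/1 coding for the two homozygous parental
alleles), markers spread evenly over chromosomes with local linkage between
adjacent positions, a directed gene-regulatory network with scale-free
out-degree and exponential in-degree, and steady-state expression in which
each mutation acts either in *cis* (shifting the expression of its own gene)
or in *trans* (rescaling the gene's regulatory effect on its downstream
targets).

Expression is the fixed point of a linear propagation model

    x = c + B(g) x + e

where ``c`` is basal expression (plus cis shifts), ``B(g)`` the
genotype-dependent weighted adjacency, and ``e`` Gaussian noise.  ``B`` is
rescaled once so that its spectral radius stays below ``network_damping``
for every genotype, which guarantees a unique, stable steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimParams",
    "MarkerMap",
    "GenotypeMatrix",
    "GoldNetwork",
    "ExpressionMatrix",
    "simulate_genotypes",
    "simulate_network",
    "simulate_expression",
    "simulate_dataset",
]

# independent child streams of the master seed, one per stochastic stage
_STREAM_GENOTYPES = 11
_STREAM_MARKER_MAP = 12
_STREAM_NETWORK = 13
_STREAM_EXPRESSION = 14


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic RIL benchmark.

    Defaults mirror the published challenge description where it states a
    value (20 chromosomes, cis probability 0.25, one marker per gene) and
    otherwise use a strong-signal regime: a cis allele shifts its gene by
    one expression unit (signal sd 0.5 for a balanced 0/1 marker) against
    measurement noise of sd 0.2.
    """

    n_samples: int
    n_genes: int
    n_edges: int
    n_chromosomes: int = 20
    recomb_prob: float = 0.1
    cis_prob: float = 0.25
    effect_size_cis: float = 1.0
    effect_size_trans: float = 1.0
    edge_weight_scale: float = 1.0
    basal_expression: float = 1.0
    noise_sd: float = 0.2
    network_damping: float = 0.5
    out_degree_exponent: float = 2.0
    seed: int = 0

    @property
    def trans_prob(self) -> float:
        return 1.0 - self.cis_prob

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_samples, n_genes and n_chromosomes must be positive")
        if self.n_genes < self.n_chromosomes:
            raise ValueError(
                f"n_genes ({self.n_genes}) must be >= n_chromosomes ({self.n_chromosomes})"
            )
        if not 0.0 < self.recomb_prob <= 0.5:
            raise ValueError("recomb_prob must lie in (0, 0.5]")
        if not 0.0 <= self.cis_prob <= 1.0:
            raise ValueError("cis_prob must lie in [0, 1]")
        if self.n_edges < 0 or self.n_edges > self.n_genes * (self.n_genes - 1):
            raise ValueError(
                f"n_edges must lie in [0, n_genes*(n_genes-1)] = "
                f"[0, {self.n_genes * (self.n_genes - 1)}], got {self.n_edges}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.network_damping < 1.0:
            raise ValueError("network_damping must lie in (0, 1)")
        if self.out_degree_exponent <= 1.0:
            raise ValueError("out_degree_exponent must be > 1")
        if self.effect_size_trans < 0:
            raise ValueError(
                "effect_size_trans must be >= 0 (trans alleles rescale outgoing "
                "edge weights by 1 + effect_size_trans)"
            )

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class MarkerMap:
    """One marker per gene: identity, chromosome layout and mutation type."""

    marker_ids: list[str]
    gene_ids: list[str]
    chromosome: np.ndarray  # int, per marker
    position_index: np.ndarray  # int, ordinal within chromosome
    mutation_type: np.ndarray  # '<U5', 'cis' or 'trans'

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        if not (len(self.gene_ids) == len(self.chromosome) == len(self.position_index) == len(self.mutation_type) == n):
            raise ValueError("marker map columns must have equal length")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids must be a bijection onto the gene set")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def gene_of(self, marker_id: str) -> str:
        return self.gene_ids[self.marker_ids.index(marker_id)]

    @property
    def cis_mask(self) -> np.ndarray:
        return self.mutation_type == "cis"

    @property
    def trans_mask(self) -> np.ndarray:
        return self.mutation_type == "trans"


@dataclass
class GenotypeMatrix:
    """RIL genotypes: samples x markers, entries 0/1 (parental allele)."""

    values: np.ndarray
    sample_ids: list[str]
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x markers)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1 (RIL homozygous coding)")
        if self.values.shape != (len(self.sample_ids), len(self.marker_map)):
            raise ValueError("genotype shape does not match sample_ids / marker_map")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class GoldNetwork:
    """Directed regulator -> target edges; weights are simulation-internal."""

    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        seen = set()
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop {reg}->{tgt} not allowed")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge {reg}->{tgt}")
            seen.add((reg, tgt))

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def out_degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_ids}
        for reg, _ in self.edges:
            deg[reg] += 1
        return deg

    def in_degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_ids}
        for _, tgt in self.edges:
            deg[tgt] += 1
        return deg


@dataclass
class ExpressionMatrix:
    """Steady-state expression: samples x genes, real-valued."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("expression shape does not match sample_ids / gene_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression entries must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _ids(prefix: str, n: int) -> list[str]:
    width = max(len(str(n)), 1)
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def default_gene_ids(n_genes: int) -> list[str]:
    return _ids("G", n_genes)


def _chromosome_blocks(n_genes: int, n_chromosomes: int) -> list[np.ndarray]:
    # even partition: block sizes differ by at most one
    return list(np.array_split(np.arange(n_genes), n_chromosomes))


def simulate_genotypes(params: SimParams) -> GenotypeMatrix:
    """Simulate RIL genotypes with local linkage.

    Within each chromosome, every sample's genotype vector is a two-state
    Markov chain: the first marker carries either parental allele with
    probability 1/2 and each subsequent marker flips the previous allele
    with probability ``recomb_prob``.  Adjacent markers therefore have
    expected Pearson correlation ``1 - 2 * recomb_prob``; chromosomes and
    samples are independent.
    """
    rng = np.random.default_rng([_STREAM_GENOTYPES, params.seed])
    map_rng = np.random.default_rng([_STREAM_MARKER_MAP, params.seed])

    n, g = params.n_samples, params.n_genes
    blocks = _chromosome_blocks(g, params.n_chromosomes)
    geno = np.empty((n, g), dtype=np.int8)
    chrom = np.empty(g, dtype=int)
    pos = np.empty(g, dtype=int)
    for ci, block in enumerate(blocks):
        length = len(block)
        bits = np.empty((n, length), dtype=np.int64)
        bits[:, 0] = rng.random(n) < 0.5
        if length > 1:
            bits[:, 1:] = rng.random((n, length - 1)) < params.recomb_prob
        # cumulative XOR along the chromosome = parity of initial state + flips
        geno[:, block] = np.cumsum(bits, axis=1) % 2
        chrom[block] = ci
        pos[block] = np.arange(length)

    gene_ids = default_gene_ids(g)
    mutation = np.where(map_rng.random(g) < params.cis_prob, "cis", "trans")
    marker_map = MarkerMap(
        marker_ids=_ids("M", g),
        gene_ids=gene_ids,
        chromosome=chrom,
        position_index=pos,
        mutation_type=mutation.astype("<U5"),
    )
    return GenotypeMatrix(values=geno, sample_ids=_ids("S", n), marker_map=marker_map)


def simulate_network(params: SimParams) -> GoldNetwork:
    """Draw a directed network with scale-free out- and exponential in-degree.

    Each gene receives an out-propensity drawn from a discrete power law
    with exponent ``out_degree_exponent`` and an in-propensity drawn from an
    exponential with mean equal to the requested mean degree.  Edges are
    sampled regulator ~ out-propensity, target ~ in-propensity, rejecting
    self-loops and duplicates, until exactly ``n_edges`` distinct edges
    exist.  Edge weights are signed, with magnitude ``edge_weight_scale``
    times Uniform(0.5, 1.5).
    """
    rng = np.random.default_rng([_STREAM_NETWORK, params.seed])
    g = params.n_genes
    gene_ids = default_gene_ids(g)
    if params.n_edges == 0:
        return GoldNetwork(edges=[], weights={}, gene_ids=gene_ids)

    # Chung-Lu target sequence: propensities rank^(-1/(gamma-1)) yield a
    # degree distribution with power-law exponent gamma; ranks are assigned
    # to genes at random so hub identity varies with the seed
    ranks = rng.permutation(g) + 1.0
    out_prop = ranks ** (-1.0 / (params.out_degree_exponent - 1.0))
    mean_degree = max(params.n_edges / g, 0.1)
    in_prop = rng.exponential(scale=mean_degree, size=g) + 1e-3
    p_out = out_prop / out_prop.sum()
    p_in = in_prop / in_prop.sum()

    chosen: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    max_rounds = 200
    for _ in range(max_rounds):
        need = params.n_edges - len(chosen)
        if need == 0:
            break
        regs = rng.choice(g, size=2 * need + 16, p=p_out)
        tgts = rng.choice(g, size=2 * need + 16, p=p_in)
        for r, t in zip(regs, tgts):
            if r == t or (r, t) in seen:
                continue
            seen.add((r, t))
            chosen.append((r, t))
            if len(chosen) == params.n_edges:
                break
    if len(chosen) < params.n_edges:
        # propensities too concentrated for rejection sampling: fill the
        # remainder uniformly from the unused pairs
        remaining = [
            (r, t) for r in range(g) for t in range(g) if r != t and (r, t) not in seen
        ]
        idx = rng.choice(len(remaining), size=params.n_edges - len(chosen), replace=False)
        chosen.extend(remaining[i] for i in sorted(idx))

    signs = rng.choice((-1.0, 1.0), size=len(chosen))
    mags = params.edge_weight_scale * rng.uniform(0.5, 1.5, size=len(chosen))
    edges = [(gene_ids[r], gene_ids[t]) for r, t in chosen]
    weights = {e: float(s * m) for e, s, m in zip(edges, signs, mags)}
    return GoldNetwork(edges=edges, weights=weights, gene_ids=gene_ids)


def _spectral_radius(m: np.ndarray) -> float:
    if not m.any():
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(m))))


def steady_state_system(
    network: GoldNetwork, genotypes: GenotypeMatrix, params: SimParams
) -> tuple[np.ndarray, np.ndarray]:
    """The per-sample linear system ``x = c + B x``: returns (B, c).

    ``B`` has shape (samples, genes, genes) with entry [s, target,
    regulator]; ``c`` has shape (samples, genes).  A cis allele adds
    ``effect_size_cis`` to its gene's basal term; a trans allele multiplies
    the regulator's column of ``B`` by ``1 + effect_size_trans``.  The base
    weight matrix is rescaled once, by the spectral radius of its
    elementwise upper bound over genotypes (|W| * (1 + effect_size_trans)),
    so that the spectral radius of ``B`` stays at most ``network_damping``
    for every sample.
    """
    mm = genotypes.marker_map
    if set(mm.gene_ids) != set(network.gene_ids):
        raise ValueError("marker map gene set must equal network gene set")

    gene_ids = mm.gene_ids
    g = len(gene_ids)
    n = genotypes.n_samples
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}

    # W[target, regulator]
    w = np.zeros((g, g))
    for (reg, tgt), wt in network.weights.items():
        w[gene_index[tgt], gene_index[reg]] = wt

    bound = np.abs(w) * (1.0 + params.effect_size_trans)
    rho = _spectral_radius(bound)
    if rho > params.network_damping:
        w *= params.network_damping / rho

    geno = genotypes.values.astype(float)
    c = np.full((n, g), params.basal_expression)
    c += params.effect_size_cis * geno * mm.cis_mask[None, :]
    # trans allele rescales the regulator's column
    mult = np.where(mm.trans_mask[None, :] * geno == 1, 1.0 + params.effect_size_trans, 1.0)
    b = w[None, :, :] * mult[:, None, :]
    return b, c


def simulate_expression(
    network: GoldNetwork, genotypes: GenotypeMatrix, params: SimParams
) -> ExpressionMatrix:
    """Steady-state expression under cis/trans genetic perturbation.

    Per sample, expression solves ``x = c + B(g) x + e`` with the system
    from :func:`steady_state_system` and i.i.d. Gaussian noise ``e`` of sd
    ``noise_sd``.  The damping of ``B`` guarantees a unique stable fixed
    point for every genotype.
    """
    b, c = steady_state_system(network, genotypes, params)
    n, g = c.shape
    rng = np.random.default_rng([_STREAM_EXPRESSION, params.seed])
    noise = rng.normal(0.0, params.noise_sd, size=(n, g)) if params.noise_sd > 0 else np.zeros((n, g))

    eye = np.eye(g)
    x = np.empty((n, g))
    for s in range(n):
        x[s] = np.linalg.solve(eye - b[s], c[s] + noise[s])
    return ExpressionMatrix(
        values=x, sample_ids=list(genotypes.sample_ids), gene_ids=list(genotypes.marker_map.gene_ids)
    )


def simulate_dataset(params: SimParams) -> tuple[GenotypeMatrix, GoldNetwork, ExpressionMatrix]:
    """Convenience: genotypes, gold network and expression from one seed."""
    genotypes = simulate_genotypes(params)
    network = simulate_network(params)
    expression = simulate_expression(network, genotypes, params)
    return genotypes, network, expression
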