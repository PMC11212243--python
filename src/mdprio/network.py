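"""Confidence-weighted network propagation with an empirical patient-preserving null.

Genes carrying unusually frequent variants (UFVs) seed a diffusion over a
weighted protein-interaction network; every gene receives a smoothed
relevance score. Scores are calibrated against a null ensemble in which
each patient keeps their observed number of mutations but every mutation
is reassigned to a uniformly random network gene, so the null preserves
the cohort's mutation burden while destroying any disease association.
Per-gene z-scores — (observed - null mean) / null SD — rank genes;
large positive z marks genes whose network neighbourhood is unexpectedly
loaded with cohort mutations.

The propagation operator is random walk with restart on the symmetric
degree-normalised adjacency:

    F <- alpha * W_norm @ F + (1 - alpha) * S,   W_norm = D^-1/2 W D^-1/2

with the seed vector S normalised to sum 1. For alpha < 1 the fixed point
is unique (spectral radius of alpha * W_norm < 1) and equals
(1 - alpha) (I - alpha W_norm)^-1 S.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ConvergenceError, CoverageError
from .filtering import VariantRecord
from .recurrence import GeneRecurrence

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "PropagationConfig",
    "PrioritizationConfig",
    "PatientMutationProfile",
    "GeneNetworkScore",
    "normalize_network",
    "propagate",
    "profiles_from_ufvs",
    "seed_counts",
    "null_ensemble",
    "zscore_genes",
    "prioritize",
    "write_score_table",
]


class InteractionNetwork:
    """Undirected gene-gene network with confidence weights in (0, 1].

    Edges are stored once; self-loops are rejected. The adjacency is kept
    as a symmetric sparse matrix over a fixed node ordering.
    """

    def __init__(self, nodes: Sequence[str], adjacency: sparse.csr_matrix):
        self.nodes: list[str] = list(nodes)
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        if len(self.index) != len(self.nodes):
            raise ValueError("duplicate node symbols in network")
        self.adjacency = sparse.csr_matrix(adjacency)
        if self.adjacency.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        """Build from (gene_a, gene_b, confidence) triples.

        Duplicate edges keep the larger confidence; self-loops are dropped
        with a warning. ``extra_nodes`` adds isolated genes to the universe.
        """
        weight: dict[tuple[str, str], float] = {}
        nodes: dict[str, None] = dict.fromkeys(extra_nodes)
        for a, b, w in edges:
            if a == b:
                logger.warning("self-loop on %s dropped", a)
                continue
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge {a}-{b}: confidence {w} outside (0, 1]")
            key = (a, b) if a < b else (b, a)
            weight[key] = max(weight.get(key, 0.0), w)
            nodes.setdefault(a)
            nodes.setdefault(b)
        node_list = list(nodes)
        index = {g: i for i, g in enumerate(node_list)}
        n = len(node_list)
        if weight:
            ii = np.fromiter((index[a] for a, _ in weight), dtype=np.int64)
            jj = np.fromiter((index[b] for _, b in weight), dtype=np.int64)
            ww = np.fromiter(weight.values(), dtype=float)
            adj = sparse.coo_matrix(
                (np.r_[ww, ww], (np.r_[ii, jj], np.r_[jj, ii])), shape=(n, n)
            ).tocsr()
        else:
            adj = sparse.csr_matrix((n, n))
        return cls(node_list, adj)

    @classmethod
    def from_networkx(cls, graph: nx.Graph, weight_attr: str = "weight"):
        edges = (
            (a, b, float(d.get(weight_attr, 1.0))) for a, b, d in graph.edges(data=True)
        )
        return cls.from_edges(edges, extra_nodes=graph.nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        g.add_weighted_edges_from(
            (self.nodes[i], self.nodes[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        )
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def edges(self) -> list[tuple[str, str, float]]:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return [
            (self.nodes[i], self.nodes[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]


@dataclass
class PropagationConfig:
    """Parameters of the propagation and its null ensemble.

    alpha
        Smoothing weight in (0, 1): the share of score received from
        network neighbours rather than directly from the seed vector.
    tol, max_iter
        Convergence is declared when the L1 change of the score vector
        falls below ``tol``.
    n_null
        Number of null-ensemble replicates used for per-gene moments.
    seed_mode
        ``"multiplicity"`` weights each seed gene by its total UFV
        mutation count across patients; ``"binary"`` weights every seeded
        gene equally.
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    n_null: int = 10000
    rng_seed: int = 0
    seed_mode: str = "multiplicity"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.seed_mode not in ("multiplicity", "binary"):
            raise ValueError("seed_mode must be 'multiplicity' or 'binary'")


@dataclass
class PrioritizationConfig:
    """Thresholds for combining recurrence and network evidence."""

    z_min: float = 3.0
    recur_min: int = 4

    def __post_init__(self):
        if self.z_min <= 0 or self.recur_min <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PatientMutationProfile:
    """One patient's UFV-mutated genes, with multiplicity (one entry per UFV)."""

    sample_id: str
    mutated_genes: list[str]

    @property
    def n_mutations(self) -> int:
        return len(self.mutated_genes)


@dataclass
class GeneNetworkScore:
    gene: str
    score: float
    null_mean: float
    null_sd: float
    z: float  # NaN when null_sd == 0


def normalize_network(network: InteractionNetwork) -> sparse.csr_matrix:
    """Symmetric degree-normalised adjacency W_ij / sqrt(d_i d_j).

    Degrees are weighted. Isolated nodes keep zero rows/columns so the
    node ordering of the network is preserved.
    """
    adj = network.adjacency.tocsr().astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    d = sparse.diags(inv_sqrt)
    return (d @ adj @ d).tocsr()


def _propagate_matrix(
    w_norm: sparse.csr_matrix,
    seed_matrix: np.ndarray,
    config: PropagationConfig,
) -> np.ndarray:
    """Iterate F <- alpha W F + (1-alpha) S to the fixed point, column-wise.

    ``seed_matrix`` is (n_nodes, n_profiles); each column must already be
    normalised to sum 1. Raises :class:`ConvergenceError` if any column
    fails to reach ``tol`` L1 change within ``max_iter`` iterations.
    """
    alpha = config.alpha
    f = seed_matrix.copy()
    for _ in range(config.max_iter):
        f_new = alpha * (w_norm @ f) + (1.0 - alpha) * seed_matrix
        residual = np.abs(f_new - f).sum(axis=0).max()
        f = f_new
        if residual < config.tol:
            return f
    raise ConvergenceError(
        f"propagation did not converge within {config.max_iter} iterations "
        f"(L1 residual {residual:.3g})",
        residual=float(residual),
    )


def _seed_vector_from_counts(
    counts: np.ndarray, seed_mode: str
) -> np.ndarray:
    if seed_mode == "binary":
        counts = (counts > 0).astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no seed gene carries positive weight")
    return counts / total


def propagate(
    seeds: Mapping[str, float],
    network: InteractionNetwork,
    config: PropagationConfig | None = None,
) -> dict[str, float]:
    """Propagate seed weights over the network; returns gene -> score.

    Seed genes absent from the network are dropped with a warning. The
    seed vector is normalised to sum 1 before diffusion, so scores are
    comparable across cohorts of different mutation burden.
    """
    config = config or PropagationConfig()
    vec = np.zeros(network.n_nodes)
    dropped = []
    for gene, weight in seeds.items():
        if weight < 0:
            raise ValueError(f"seed weight for {gene} is negative")
        idx = network.index.get(gene)
        if idx is None:
            dropped.append(gene)
        else:
            vec[idx] += weight
    if dropped:
        logger.warning(
            "%d seed gene(s) absent from the network were dropped (e.g. %s)",
            len(dropped),
            dropped[:5],
        )
    total = vec.sum()
    if total <= 0:
        raise ValueError("no seed gene with positive weight intersects the network")
    w_norm = normalize_network(network)
    scores = _propagate_matrix(w_norm, (vec / total)[:, None], config)[:, 0]
    return dict(zip(network.nodes, scores.tolist()))


def profiles_from_ufvs(
    ufvs: Sequence[VariantRecord],
) -> list[PatientMutationProfile]:
    """Build per-patient mutation profiles: one gene entry per carried UFV."""
    per_sample: dict[str, list[str]] = {}
    for v in ufvs:
        for s in v.carriers:
            per_sample.setdefault(s, []).append(v.gene)
    return [
        PatientMutationProfile(sample_id=s, mutated_genes=sorted(genes))
        for s, genes in sorted(per_sample.items())
    ]


def seed_counts(
    profiles: Sequence[PatientMutationProfile], network: InteractionNetwork
) -> np.ndarray:
    """Per-network-gene mutation counts pooled over patients."""
    counts = np.zeros(network.n_nodes)
    dropped: Counter[str] = Counter()
    for p in profiles:
        for gene in p.mutated_genes:
            idx = network.index.get(gene)
            if idx is None:
                dropped[gene] += 1
            else:
                counts[idx] += 1.0
    if dropped:
        logger.warning(
            "%d mutation(s) in %d gene(s) absent from the network excluded from seeds",
            sum(dropped.values()),
            len(dropped),
        )
    return counts


def null_ensemble(
    profiles: Sequence[PatientMutationProfile],
    network: InteractionNetwork,
    config: PropagationConfig | None = None,
    batch_size: int = 256,
) -> dict[str, tuple[float, float]]:
    """Per-gene propagation-score moments under uniformly random mutations.

    Each replicate keeps every patient's observed mutation count but
    reassigns each mutation to a gene drawn uniformly (with replacement)
    from the network's node set. Seeds are rebuilt exactly as for the
    observed cohort and propagated; a Welford accumulator over replicates
    yields the per-gene mean and SD. Replicate r uses the independent
    stream ``default_rng([rng_seed, r])`` so the ensemble is reproducible
    and order-independent.
    """
    config = config or PropagationConfig()
    if config.n_null < 2:
        raise ValueError("n_null must be >= 2 for a defined null SD")
    n = network.n_nodes
    total_mutations = sum(p.n_mutations for p in profiles)
    if total_mutations == 0:
        raise ValueError("profiles carry no mutations")
    w_norm = normalize_network(network)

    mean = np.zeros(n)
    m2 = np.zeros(n)
    count = 0
    for start in range(0, config.n_null, batch_size):
        reps = range(start, min(start + batch_size, config.n_null))
        seed_mat = np.empty((n, len(reps)))
        for j, r in enumerate(reps):
            rng = np.random.default_rng([config.rng_seed, r])
            # patients are independent and uniform, so the pooled counts of
            # one replicate are total_mutations iid uniform draws
            draws = rng.integers(0, n, size=total_mutations)
            counts = np.bincount(draws, minlength=n).astype(float)
            seed_mat[:, j] = _seed_vector_from_counts(counts, config.seed_mode)
        scores = _propagate_matrix(w_norm, seed_mat, config)
        for j in range(scores.shape[1]):
            count += 1
            delta = scores[:, j] - mean
            mean += delta / count
            m2 += delta * (scores[:, j] - mean)
    sd = np.sqrt(m2 / (count - 1))
    return {g: (float(mean[i]), float(sd[i])) for i, g in enumerate(network.nodes)}


def zscore_genes(
    observed: Mapping[str, float],
    null: Mapping[str, tuple[float, float]],
) -> list[GeneNetworkScore]:
    """z = (score - null mean) / null SD, sorted by z descending.

    Genes with zero null SD receive z = NaN (flagged undefined) and sort
    last. Raises :class:`CoverageError` when the two maps do not cover the
    same genes.
    """
    if set(observed) != set(null):
        missing = set(observed) ^ set(null)
        raise CoverageError(
            f"observed and null gene universes differ ({len(missing)} genes, "
            f"e.g. {sorted(missing)[:5]})"
        )
    out = []
    for gene, score in observed.items():
        mu, sd = null[gene]
        z = (score - mu) / sd if sd > 0 else math.nan
        out.append(GeneNetworkScore(gene=gene, score=score, null_mean=mu, null_sd=sd, z=z))
    out.sort(key=lambda s: (-s.z if not math.isnan(s.z) else math.inf, s.gene))
    return out


def network_scores_from_ufvs(
    ufvs: Sequence[VariantRecord],
    network: InteractionNetwork,
    config: PropagationConfig | None = None,
) -> tuple[list[GeneNetworkScore], list[PatientMutationProfile]]:
    """Observed propagation + null calibration in one call.

    Convenience wrapper chaining :func:`profiles_from_ufvs`,
    :func:`seed_counts`, :func:`propagate`-equivalent scoring and
    :func:`null_ensemble`.
    """
    config = config or PropagationConfig()
    profiles = profiles_from_ufvs(ufvs)
    counts = seed_counts(profiles, network)
    w_norm = normalize_network(network)
    seed_vec = _seed_vector_from_counts(counts, config.seed_mode)
    observed_vec = _propagate_matrix(w_norm, seed_vec[:, None], config)[:, 0]
    observed = dict(zip(network.nodes, observed_vec.tolist()))
    null = null_ensemble(profiles, network, config)
    return zscore_genes(observed, null), profiles


def prioritize(
    recurrence: Sequence[GeneRecurrence],
    netscores: Sequence[GeneNetworkScore],
    config: PrioritizationConfig | None = None,
) -> dict[str, set[str]]:
    """The three candidate gene sets: recurrence, network, intersection.

    ``recurrence``: genes with >= recur_min distinct UFVs. ``network``:
    genes with z > z_min. ``intersection``: both. The sets overlap (a gene
    passing both filters appears in all three).
    """
    config = config or PrioritizationConfig()
    rec = {r.gene for r in recurrence if r.n_ufv >= config.recur_min}
    net = {
        s.gene for s in netscores if not math.isnan(s.z) and s.z > config.z_min
    }
    return {"recurrence": rec, "network": net, "intersection": rec & net}


def write_score_table(
    netscores: Sequence[GeneNetworkScore], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "gene": s.gene,
                "score": s.score,
                "null_mean": s.null_mean,
                "null_sd": s.null_sd,
                "z": s.z,
            }
            for s in netscores
        ]
    ).to_csv(path, sep="\t", index=False)
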