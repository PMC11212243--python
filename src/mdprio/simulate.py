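"""Synthetic cohorts, networks, gene sets and expression atlases.

The generator produces fully self-contained inputs with the statistical
structure the analysis assumes: a diploid cohort carrying rare damaging
variants; a designated subset of *disease genes* whose variants occur in
the cohort at a configurable fold-inflation over their reference-panel
frequencies; a confidence-weighted interaction network in which the
disease genes form a connected module denser than the background graph;
gene-set collections in which disease genes are over-represented in
designated "relevant" sets; and a labeled expression atlas in which
disease genes are up-shifted in designated cell types.

Genotypes are independent across variants and individuals: each allele
of each individual carries a variant with probability q (the variant's
underlying population frequency, multiplied by ``fold`` in disease
genes). There is no linkage, relatedness or population structure —
matching the independence assumptions of the observed/expected frequency
filter and the Hardy-Weinberg control model downstream.

Every generator is deterministic given ``rng_seed``; each component uses
its own derived stream so cohorts, networks, gene sets and atlases can
be regenerated independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrichment import GeneSetCollection
from .expression import LabeledExpression
from .filtering import Consequence, VariantRecord, VariantType
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_cohort",
    "simulate_network",
    "simulate_gene_sets",
    "simulate_expression",
    "simulate_study",
]

# Consequence spectrum of the rare damaging protein-altering classes,
# defaulting to proportions typical of a filtered WGS cohort (missense
# dominates; indel classes determine the variant type).
_CONSEQUENCE_PROBS = {
    Consequence.missense: 10132,
    Consequence.nonsense: 775,
    Consequence.frameshift_del: 199,
    Consequence.nonstop: 41,
    Consequence.inframe_del: 31,
    Consequence.frameshift_ins: 22,
    Consequence.inframe_ins: 6,
    Consequence.splice_site: 3,
}

_TYPE_OF_CONSEQUENCE = {
    Consequence.frameshift_del: VariantType.DEL,
    Consequence.inframe_del: VariantType.DEL,
    Consequence.frameshift_ins: VariantType.INS,
    Consequence.inframe_ins: VariantType.INS,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    The cohort size defaults to 511 diploid individuals. ``fold`` is the
    allele-frequency inflation applied to variants in disease genes
    (cohort frequency = min(fold * reference frequency, 1)); it must
    exceed the downstream ratio threshold (1.3) for planted signal to be
    detectable, and defaults to 2.0. The rare-variant frequency law is a
    truncated Pareto on (af_min, af_max], heavy-tailed toward rare, with
    a fraction of variants novel (absent from the reference panel).
    """

    n_samples: int = 511
    n_genes: int = 2000
    n_disease_genes: int = 50
    variants_per_gene: float = 5.0  # Poisson mean of candidate variants per gene
    af_min: float = 5e-4
    af_max: float = 0.05
    af_pareto_alpha: float = 1.0
    novel_fraction: float = 0.10
    fold: float = 2.0
    #: emit variants with zero cohort allele count as well (a real cohort
    #: table only contains observed variants; zero-count rows make the
    #: table ascertainment-free, which calibration experiments need)
    include_unobserved: bool = False
    # nuisance variants exercising the rare/damaging filter
    common_fraction: float = 0.05
    benign_fraction: float = 0.10
    non_protein_altering_fraction: float = 0.05
    # network model
    edge_prob: float = 0.005
    module_factor: float = 10.0
    min_confidence: float = 0.2
    # gene-set collection
    n_gene_sets: int = 8
    gene_set_size: int = 100
    n_relevant_sets: int = 2
    geneset_planting_rate: float = 5.0
    # expression atlas
    n_cell_types: int = 8
    n_cells_per_type: int = 30
    n_upregulated_cell_types: int = 2
    expression_effect_size: float = 1.0  # log-scale shift of disease genes
    rng_seed: int = 0

    def __post_init__(self):
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        if not (0 < self.n_disease_genes < self.n_genes):
            raise ValueError("n_disease_genes must lie in (0, n_genes)")
        for name in ("novel_fraction", "common_fraction", "benign_fraction",
                     "non_protein_altering_fraction", "edge_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if not (0.0 < self.af_min < self.af_max <= 1.0):
            raise ValueError("require 0 < af_min < af_max <= 1")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples - 1))
        return [f"S{i:0{width}d}" for i in range(self.n_samples)]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, for recovery tests."""

    disease_genes: set[str]
    planted_gene_sets: set[str] = field(default_factory=set)
    upregulated_cell_types: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "disease_genes": sorted(self.disease_genes),
                    "planted_gene_sets": sorted(self.planted_gene_sets),
                    "upregulated_cell_types": sorted(self.upregulated_cell_types),
                },
                fh,
                indent=2,
            )


def _rng(config: SimulationConfig, component: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, component])


def _truncated_pareto(
    rng: np.random.Generator, size: int, alpha: float, lo: float, hi: float
) -> np.ndarray:
    """Inverse-CDF sampling of a Pareto law truncated to [lo, hi]."""
    u = rng.random(size)
    ratio = (lo / hi) ** alpha
    return lo / (1.0 - u * (1.0 - ratio)) ** (1.0 / alpha)


def make_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the planted disease-gene set (stream shared by all generators)."""
    rng = _rng(config, 0)
    genes = config.gene_names()
    disease = rng.choice(len(genes), size=config.n_disease_genes, replace=False)
    return SyntheticTruth(disease_genes={genes[i] for i in disease})


def simulate_cohort(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> tuple[list[VariantRecord], SyntheticTruth]:
    """Simulate the annotated cohort variant table.

    Per gene, a Poisson number of candidate variants is drawn; each gets
    an underlying population frequency from the truncated Pareto law.
    Cohort genotypes are two Bernoulli draws per individual at that
    frequency (times ``fold`` in disease genes). Only variants observed
    in at least one cohort member are emitted — a cohort table contains
    observed variants. Nuisance variants (common, benign-labelled, or
    non-protein-altering) are planted at the configured fractions to
    exercise the rare/damaging filter.
    """
    truth = truth or make_truth(config)
    rng = _rng(config, 1)
    genes = config.gene_names()
    samples = np.array(config.sample_ids())
    disease = truth.disease_genes

    csq_values = list(_CONSEQUENCE_PROBS)
    csq_probs = np.array(list(_CONSEQUENCE_PROBS.values()), dtype=float)
    csq_probs /= csq_probs.sum()

    records: list[VariantRecord] = []
    vid = 0
    counts = rng.poisson(config.variants_per_gene, size=config.n_genes)
    for gene, n_var in zip(genes, counts):
        if n_var == 0:
            continue
        is_disease = gene in disease
        afs = _truncated_pareto(
            rng, n_var, config.af_pareto_alpha, config.af_min, config.af_max
        )
        flags = rng.random((n_var, 4))
        for i in range(n_var):
            common = flags[i, 0] < config.common_fraction
            benign = flags[i, 1] < config.benign_fraction
            other_csq = flags[i, 2] < config.non_protein_altering_fraction
            novel = (not common) and flags[i, 3] < config.novel_fraction
            af = float(rng.uniform(0.06, 0.3)) if common else float(afs[i])
            q = min(config.fold * af, 1.0) if (is_disease and not common) else af
            if config.fold * af > 1.0 and is_disease and not common:
                logger.warning("fold * af exceeds 1 for a variant in %s; capped", gene)
            alleles = rng.binomial(2, q, size=config.n_samples)
            ac = int(alleles.sum())
            if ac == 0 and not config.include_unobserved:
                continue
            carriers = frozenset(samples[alleles > 0])
            if other_csq:
                csq = Consequence.other
                vtype = VariantType.SNP
            else:
                csq = csq_values[int(rng.choice(len(csq_values), p=csq_probs))]
                vtype = _TYPE_OF_CONSEQUENCE.get(csq, VariantType.SNP)
            if benign:
                which = "sift" if rng.random() < 0.5 else "polyphen"
                labels = {
                    "sift": "benign" if which == "sift" else "damaging",
                    "polyphen": "benign" if which == "polyphen" else "damaging",
                }
            else:
                labels = {"sift": "damaging", "polyphen": "damaging"}
            records.append(
                VariantRecord(
                    variant_id=f"var{vid:06d}",
                    gene=gene,
                    variant_type=vtype,
                    consequence=csq,
                    allele_count=ac,
                    carriers=carriers,
                    ref_af=None if novel else af,
                    deleterious_labels=labels,
                )
            )
            vid += 1
    return records, truth


def simulate_network(
    config: SimulationConfig, truth: SyntheticTruth
) -> InteractionNetwork:
    """Background Erdős–Rényi graph plus a connected planted disease module.

    Disease genes receive a random spanning tree (guaranteeing
    connectivity of the module) plus extra internal edges at
    ``module_factor`` times the background edge probability. Confidence
    weights are uniform on (min_confidence, 1].
    """
    rng = _rng(config, 2)
    genes = config.gene_names()
    n = len(genes)
    edges: set[tuple[int, int]] = set()
    # background edges, row-chunked to bound memory
    for i in range(n - 1):
        mask = rng.random(n - i - 1) < config.edge_prob
        for j in np.nonzero(mask)[0]:
            edges.add((i, i + 1 + int(j)))
    d_idx = sorted(genes.index(g) for g in truth.disease_genes)
    if config.module_factor > 1.0 and len(d_idx) > 1:
        order = rng.permutation(len(d_idx))
        for pos in range(1, len(order)):
            a = d_idx[order[pos]]
            b = d_idx[order[int(rng.integers(0, pos))]]
            edges.add((min(a, b), max(a, b)))
        extra_p = min((config.module_factor - 1.0) * config.edge_prob, 1.0)
        for ai in range(len(d_idx) - 1):
            mask = rng.random(len(d_idx) - ai - 1) < extra_p
            for bj in np.nonzero(mask)[0]:
                a, b = d_idx[ai], d_idx[ai + 1 + int(bj)]
                edges.add((min(a, b), max(a, b)))
    edge_list = [
        (genes[a], genes[b], float(w))
        for (a, b), w in zip(
            sorted(edges),
            rng.uniform(config.min_confidence, 1.0, size=len(edges)),
        )
    ]
    return InteractionNetwork.from_edges(edge_list, extra_nodes=genes)


def simulate_gene_sets(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Gene-set collection with disease genes planted into "relevant" sets.

    The first ``n_relevant_sets`` sets include each disease gene with
    probability ``geneset_planting_rate`` times the background inclusion
    rate (set size / universe size, capped at 1); all other membership is
    at the background rate. Planted set names are recorded in the truth.
    """
    rng = _rng(config, 3)
    genes = config.gene_names()
    base_rate = min(config.gene_set_size / config.n_genes, 1.0)
    planted_rate = min(config.geneset_planting_rate * base_rate, 1.0)
    disease = truth.disease_genes
    sets: dict[str, set[str]] = {}
    for s in range(config.n_gene_sets):
        relevant = s < config.n_relevant_sets
        name = f"{'RELEVANT' if relevant else 'RANDOM'}_SET_{s}"
        members = set()
        for g in genes:
            rate = planted_rate if (relevant and g in disease) else base_rate
            if rng.random() < rate:
                members.add(g)
        if not members:  # degenerate draw: resample one member
            members.add(genes[int(rng.integers(0, len(genes)))])
            logger.warning("gene set %s drawn empty; resampled one member", name)
        sets[name] = members
        if relevant:
            truth.planted_gene_sets.add(name)
    collection = GeneSetCollection(name="synthetic", sets=sets, universe=set(genes))
    return collection, truth


def simulate_expression(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[LabeledExpression, SyntheticTruth]:
    """Labeled expression atlas with disease genes shifted up in designated
    cell types.

    Per-gene baseline means are log-normal; counts are Poisson. In the
    first ``n_upregulated_cell_types`` cell types, disease-gene means are
    multiplied by exp(expression_effect_size).
    """
    rng = _rng(config, 4)
    genes = config.gene_names()
    n_cells = config.n_cell_types * config.n_cells_per_type
    cell_types = [
        f"CT{t}" for t in range(config.n_cell_types) for _ in range(config.n_cells_per_type)
    ]
    cells = [f"C{i:04d}" for i in range(n_cells)]
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    is_disease = np.array([g in truth.disease_genes for g in genes])
    up_types = {f"CT{t}" for t in range(config.n_upregulated_cell_types)}
    mean_matrix = np.tile(base_mean[:, None], (1, n_cells))
    up_cells = np.array([ct in up_types for ct in cell_types])
    boost = np.exp(config.expression_effect_size)
    mean_matrix[np.ix_(is_disease, up_cells)] *= boost
    matrix = rng.poisson(mean_matrix).astype(float)
    truth.upregulated_cell_types |= up_types
    expr = LabeledExpression(
        genes=genes, cells=cells, matrix=matrix, cell_types=cell_types
    )
    return expr, truth


@dataclass
class SimulatedStudy:
    """All synthetic inputs for one end-to-end pipeline run."""

    config: SimulationConfig
    truth: SyntheticTruth
    variants: list[VariantRecord]
    network: InteractionNetwork
    gene_sets: GeneSetCollection
    expression: LabeledExpression


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study (cohort, network, sets, atlas)."""
    config = config or SimulationConfig()
    truth = make_truth(config)
    variants, truth = simulate_cohort(config, truth)
    network = simulate_network(config, truth)
    gene_sets, truth = simulate_gene_sets(config, truth)
    expression, truth = simulate_expression(config, truth)
    return SimulatedStudy(
        config=config,
        truth=truth,
        variants=variants,
        network=network,
        gene_sets=gene_sets,
        expression=expression,
    )
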