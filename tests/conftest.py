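import numpy as np
import pytest

from mdprio import (
    InteractionNetwork,
    SimulationConfig,
    VariantRecord,
    simulate_study,
)


def make_variant(
    variant_id="v1",
    gene="GENE1",
    variant_type="SNP",
    consequence="missense",
    allele_count=None,
    carriers=("S1",),
    ref_af=0.001,
    labels=None,
    panel_afs=None,
):
    carriers = frozenset(carriers)
    if allele_count is None:
        allele_count = len(carriers)
    return VariantRecord(
        variant_id=variant_id,
        gene=gene,
        variant_type=variant_type,
        consequence=consequence,
        allele_count=allele_count,
        carriers=carriers,
        ref_af=ref_af,
        deleterious_labels=labels or {"sift": "damaging", "polyphen": "damaging"},
        panel_afs=panel_afs or {},
    )


@pytest.fixture
def mk_variant():
    return make_variant


@pytest.fixture
def path_network():
    """3-node path A-B-C with unit confidences."""
    return InteractionNetwork.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def tiny_network():
    """5-gene ring with mixed confidences, used for null-ensemble checks."""
    return InteractionNetwork.from_edges(
        [("A", "B", 1.0), ("B", "C", 0.8), ("C", "D", 0.5), ("D", "E", 0.9), ("A", "E", 0.3)]
    )


@pytest.fixture(scope="session")
def planted_study():
    """One small planted study shared across tests (deterministic)."""
    cfg = SimulationConfig(
        n_genes=300, n_disease_genes=20, n_samples=200, rng_seed=42
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
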