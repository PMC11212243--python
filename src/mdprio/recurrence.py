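"""Per-gene recurrence of unusually frequent variants (UFVs).

Recurrence counts *distinct* UFVs per gene, not allele occurrences: a
single very common variant contributes 1 regardless of how many cohort
members carry it, while the number of impacted samples is tracked
separately as the union of carrier sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .filtering import VariantRecord, obs_exp_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecurrence",
    "RecurrenceConfig",
    "gene_recurrence",
    "recurrent_gene_set",
    "write_recurrence_table",
]


@dataclass
class GeneRecurrence:
    """Recurrence summary for one gene.

    ``n_ufv`` counts distinct UFVs in the gene; ``n_samples`` counts
    distinct cohort members carrying at least one of them.
    """

    gene: str
    n_ufv: int
    n_samples: int
    obs_exp_ratios: list[float] = field(default_factory=list)


@dataclass
class RecurrenceConfig:
    """Threshold defining the highly recurrent gene set (>= recur_min UFVs)."""

    recur_min: int = 4

    def __post_init__(self):
        if self.recur_min < 1:
            raise ValueError("recur_min must be >= 1")


def gene_recurrence(
    ufvs: Sequence[VariantRecord], n_samples: int | None = None
) -> list[GeneRecurrence]:
    """Aggregate UFVs into per-gene recurrence records.

    Variants without a gene symbol are skipped with a warning. When the
    cohort size ``n_samples`` is supplied, the per-variant observed/expected
    frequency ratios are recorded (``None`` entries for novel variants are
    omitted). Output is sorted by ``n_ufv`` then ``n_samples`` descending,
    ties broken lexicographically by symbol.
    """
    by_gene: dict[str, dict] = {}
    for v in ufvs:
        if not v.gene:
            logger.warning("variant %s has no gene symbol; skipped", v.variant_id)
            continue
        entry = by_gene.setdefault(
            v.gene, {"variant_ids": set(), "carriers": set(), "ratios": []}
        )
        entry["variant_ids"].add(v.variant_id)
        entry["carriers"].update(v.carriers)
        if n_samples is not None:
            ratio = obs_exp_ratio(v, n_samples)
            if ratio is not None:
                entry["ratios"].append(ratio)
    records = [
        GeneRecurrence(
            gene=g,
            n_ufv=len(e["variant_ids"]),
            n_samples=len(e["carriers"]),
            obs_exp_ratios=e["ratios"],
        )
        for g, e in by_gene.items()
    ]
    records.sort(key=lambda r: (-r.n_ufv, -r.n_samples, r.gene))
    return records


def recurrent_gene_set(
    recurrence: Sequence[GeneRecurrence], config: RecurrenceConfig | None = None
) -> set[str]:
    """Genes with at least ``recur_min`` distinct UFVs."""
    config = config or RecurrenceConfig()
    return {r.gene for r in recurrence if r.n_ufv >= config.recur_min}


def write_recurrence_table(
    recurrence: Sequence[GeneRecurrence], path: str | Path
) -> None:
    df = pd.DataFrame(
        [{"gene": r.gene, "n_ufv": r.n_ufv, "n_samples": r.n_samples} for r in recurrence]
    )
    df.to_csv(path, sep="\t", index=False)
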