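"""Diagnostic-panel evaluation: cohort recovery vs expected control recovery.

Given genes ranked by recurrence, the observed curve reports the fraction
of the cohort carrying at least one qualifying variant in the top-k
genes. The control curve reports the fraction of a general-population
cohort expected to carry at least one of the same variants, assuming
independent variants in Hardy-Weinberg equilibrium:

    P(carrier) = 1 - prod_v (1 - q_v)^2

over the variants v in the top-k genes, with q_v the reference-population
allele frequency. Novel variants (no reference frequency) contribute
q = 0, so the control estimate is conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import VariantRecord
from .recurrence import GeneRecurrence

logger = logging.getLogger(__name__)

__all__ = [
    "PanelCurve",
    "rank_genes_by_recurrence",
    "cohort_recovery_curve",
    "expected_control_recovery",
    "expected_control_curve",
    "build_panel_curve",
    "panel_report",
    "write_panel_curve",
]


@dataclass
class PanelCurve:
    """Cumulative recovery curves for one ranked gene panel."""

    ranked_genes: list[str]
    cum_cohort_frac: list[float]
    expected_control_frac: list[float]

    def __post_init__(self):
        k = len(self.ranked_genes)
        if len(self.cum_cohort_frac) != k or len(self.expected_control_frac) != k:
            raise ValueError("curve lengths must match the ranking length")

    def smallest_k_reaching(self, target: float) -> int | None:
        """Smallest panel size whose cohort recovery reaches ``target``."""
        for i, frac in enumerate(self.cum_cohort_frac, start=1):
            if frac >= target:
                return i
        return None


def rank_genes_by_recurrence(recurrence: Sequence[GeneRecurrence]) -> list[str]:
    """Genes ranked by n_ufv, ties by n_samples, then symbol."""
    ordered = sorted(recurrence, key=lambda r: (-r.n_ufv, -r.n_samples, r.gene))
    return [r.gene for r in ordered]


def cohort_recovery_curve(
    ranked_genes: Sequence[str],
    ufvs: Sequence[VariantRecord],
    cohort_samples: Sequence[str],
) -> list[float]:
    """Fraction of the cohort carrying >= 1 qualifying variant in the top-k
    genes, for k = 1..len(ranked_genes)."""
    if not cohort_samples:
        raise ValueError("cohort_samples must be non-empty")
    carriers_by_gene: dict[str, set[str]] = {}
    for v in ufvs:
        carriers_by_gene.setdefault(v.gene, set()).update(v.carriers)
    n = len(set(cohort_samples))
    covered: set[str] = set()
    curve = []
    for gene in ranked_genes:
        gene_carriers = carriers_by_gene.get(gene)
        if gene_carriers is None:
            logger.info("ranked gene %s has no qualifying variants", gene)
        else:
            covered |= gene_carriers
        curve.append(len(covered) / n)
    return curve


def expected_control_recovery(
    ranked_genes: Sequence[str],
    ufvs: Sequence[VariantRecord],
    k: int,
) -> float:
    """Expected fraction of a control cohort carrying >= 1 of the panel's
    variants under Hardy-Weinberg, for the top-``k`` genes."""
    if k < 0 or k > len(ranked_genes):
        raise ValueError("k outside the ranking length")
    top = set(ranked_genes[:k])
    log_non_carrier = 0.0
    for v in ufvs:
        if v.gene not in top:
            continue
        q = 0.0 if v.ref_af is None else v.ref_af
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"variant {v.variant_id}: allele frequency {q} outside [0, 1]")
        if q >= 1.0:
            return 1.0
        log_non_carrier += 2.0 * np.log1p(-q)
    return float(-np.expm1(log_non_carrier))


def expected_control_curve(
    ranked_genes: Sequence[str], ufvs: Sequence[VariantRecord]
) -> list[float]:
    """Hardy-Weinberg control recovery for every panel size k."""
    by_gene: dict[str, float] = {}
    for v in ufvs:
        q = 0.0 if v.ref_af is None else v.ref_af
        if q >= 1.0:
            by_gene[v.gene] = -np.inf
            continue
        by_gene[v.gene] = by_gene.get(v.gene, 0.0) + 2.0 * np.log1p(-q)
    total = 0.0
    curve = []
    for gene in ranked_genes:
        total += by_gene.get(gene, 0.0)
        curve.append(float(-np.expm1(total)))
    return curve


def build_panel_curve(
    ranked_genes: Sequence[str],
    ufvs: Sequence[VariantRecord],
    cohort_samples: Sequence[str],
) -> PanelCurve:
    return PanelCurve(
        ranked_genes=list(ranked_genes),
        cum_cohort_frac=cohort_recovery_curve(ranked_genes, ufvs, cohort_samples),
        expected_control_frac=expected_control_curve(ranked_genes, ufvs),
    )


def panel_report(
    curves: Mapping[str, PanelCurve], recovery_target: float = 0.5
) -> pd.DataFrame:
    """Long-format comparison table across candidate panels.

    One row per (panel, k) with cohort recovery, expected control
    recovery, their difference, and a flag on the smallest k whose cohort
    recovery reaches ``recovery_target``.
    """
    if not curves:
        raise ValueError("at least one panel curve is required")
    rows = []
    for name, curve in curves.items():
        k_target = curve.smallest_k_reaching(recovery_target)
        for i, gene in enumerate(curve.ranked_genes):
            obs = curve.cum_cohort_frac[i]
            exp = curve.expected_control_frac[i]
            rows.append(
                {
                    "panel": name,
                    "k": i + 1,
                    "gene": gene,
                    "cum_cohort_frac": obs,
                    "expected_control_frac": exp,
                    "difference": obs - exp,
                    "reaches_target": (i + 1) == k_target,
                }
            )
    return pd.DataFrame(rows)


def write_panel_curve(curve: PanelCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "k": np.arange(1, len(curve.ranked_genes) + 1),
            "gene": curve.ranked_genes,
            "cum_cohort_frac": curve.cum_cohort_frac,
            "expected_control_frac": curve.expected_control_frac,
        }
    ).to_csv(path, sep="\t", index=False)
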