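"""Cohort variant filtering: rare, damaging, unusually frequent variants.

The analysis starts from an annotated cohort variant table (one row per
distinct variant) and reduces it in two stages:

1. *Rare & damaging*: drop variants that are common in any reference
   panel (allele frequency > ``common_af_max``), deemed benign by any
   configured deleteriousness predictor, or not protein-altering.
2. *Unusually frequent* (UFV): among the survivors, keep variants whose
   cohort allele frequency exceeds ``ratio_min`` times their expected
   (reference-panel) frequency, together with novel variants absent from
   the reference panel.

Cohort allele frequency uses the diploid convention AF = AC / (2N).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .exceptions import AnnotationError, ConsistencyError, InvalidGenotypeError

logger = logging.getLogger(__name__)

__all__ = [
    "VariantType",
    "Consequence",
    "PROTEIN_ALTERING",
    "VariantRecord",
    "FilterConfig",
    "FilterSummary",
    "cohort_allele_frequency",
    "obs_exp_ratio",
    "filter_rare_damaging",
    "ufv_filter",
    "variant_count_pvalue",
    "summarize_filtering",
]


class VariantType(str, Enum):
    SNP = "SNP"
    DEL = "DEL"
    INS = "INS"


class Consequence(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift_del = "frameshift_del"
    frameshift_ins = "frameshift_ins"
    inframe_del = "inframe_del"
    inframe_ins = "inframe_ins"
    nonstop = "nonstop"
    splice_site = "splice_site"
    other = "other"


#: Consequence classes retained by the protein-altering filter.
PROTEIN_ALTERING = frozenset(c for c in Consequence if c is not Consequence.other)


def _coerce_consequence(value: str | Consequence, variant_id: str) -> Consequence:
    if isinstance(value, Consequence):
        return value
    if value is None or (isinstance(value, str) and not value.strip()):
        raise AnnotationError(f"variant {variant_id!r} has no consequence annotation")
    try:
        return Consequence(str(value))
    except ValueError:
        logger.warning(
            "variant %s: unknown consequence %r mapped to 'other'", variant_id, value
        )
        return Consequence.other


@dataclass(frozen=True)
class VariantRecord:
    """One annotated cohort variant.

    Parameters
    ----------
    variant_id
        Unique identifier (rsID or ``chrom:pos:ref:alt``).
    gene
        Gene symbol the variant is assigned to (one gene per variant;
        multi-gene annotations must be resolved upstream).
    variant_type, consequence
        Structural class and functional consequence.
    allele_count
        Number of alternate alleles observed in the cohort.
    carriers
        Sample identifiers of cohort members carrying >= 1 alternate allele.
    ref_af
        Reference-population allele frequency; ``None`` marks a novel
        variant absent from the reference panel.
    deleterious_labels
        Mapping predictor name -> label (e.g. ``{"sift": "damaging"}``).
    panel_afs
        Allele frequencies in additional reference panels, used (together
        with ``ref_af``) by the common-variant filter.
    """

    variant_id: str
    gene: str
    variant_type: VariantType
    consequence: Consequence
    allele_count: int
    carriers: frozenset[str]
    ref_af: float | None = None
    deleterious_labels: Mapping[str, str] = field(default_factory=dict)
    panel_afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "variant_type", VariantType(self.variant_type))
        object.__setattr__(
            self, "consequence", _coerce_consequence(self.consequence, self.variant_id)
        )
        object.__setattr__(self, "carriers", frozenset(self.carriers))
        if self.allele_count < 0:
            raise InvalidGenotypeError(
                f"variant {self.variant_id!r}: negative allele count"
            )
        if not (len(self.carriers) <= self.allele_count <= 2 * len(self.carriers)):
            raise InvalidGenotypeError(
                f"variant {self.variant_id!r}: allele count {self.allele_count} "
                f"inconsistent with {len(self.carriers)} diploid carriers"
            )
        if self.ref_af is not None and not (0.0 <= self.ref_af <= 1.0):
            raise ValueError(
                f"variant {self.variant_id!r}: ref_af {self.ref_af} outside [0, 1]"
            )

    @property
    def novel(self) -> bool:
        """True when the variant is absent from the reference panel."""
        return self.ref_af is None

    def max_panel_af(self) -> float | None:
        """Largest allele frequency across all supplied reference panels."""
        afs = [af for af in self.panel_afs.values() if af is not None]
        if self.ref_af is not None:
            afs.append(self.ref_af)
        return max(afs) if afs else None


@dataclass
class FilterConfig:
    """Thresholds for the rare/damaging and unusually-frequent filters.

    ``common_af_max`` (default 0.05) and ``ratio_min`` (default 1.3) are
    both strict inequalities: a variant at exactly 5% reference frequency
    is retained, and a variant at exactly 1.3-fold is removed.
    """

    common_af_max: float = 0.05
    ratio_min: float = 1.3
    keep_protein_altering_only: bool = True
    benign_predictors: Sequence[str] = ("sift", "polyphen")

    def __post_init__(self):
        if not (0.0 < self.common_af_max <= 1.0):
            raise ValueError("common_af_max must be in (0, 1]")
        if self.ratio_min < 0:
            raise ValueError("ratio_min must be non-negative")


def cohort_allele_frequency(allele_count: int, n_samples: int) -> float:
    """Allele frequency of a variant in a diploid cohort: AC / (2N)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if allele_count < 0 or allele_count > 2 * n_samples:
        raise InvalidGenotypeError(
            f"allele count {allele_count} outside [0, {2 * n_samples}] "
            f"for {n_samples} diploid samples"
        )
    return allele_count / (2 * n_samples)


def obs_exp_ratio(variant: VariantRecord, n_samples: int) -> float | None:
    """Observed-over-expected frequency ratio; ``None`` for novel variants."""
    if variant.ref_af is None or variant.ref_af == 0.0:
        return None
    return cohort_allele_frequency(variant.allele_count, n_samples) / variant.ref_af


def _is_benign(variant: VariantRecord, predictors: Sequence[str]) -> bool:
    # removal if ANY configured predictor calls the variant benign
    for name in predictors:
        label = variant.deleterious_labels.get(name)
        if label is not None and str(label).strip().lower() == "benign":
            return True
    return False


def filter_rare_damaging(
    variants: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Keep rare, non-benign, protein-altering variants (order preserved).

    A variant is removed when its allele frequency in *any* supplied
    reference panel exceeds ``config.common_af_max``, when any configured
    predictor labels it benign, or (if ``keep_protein_altering_only``)
    when its consequence is not protein-altering.
    """
    config = config or FilterConfig()
    kept: list[VariantRecord] = []
    for v in variants:
        max_af = v.max_panel_af()
        if max_af is not None and max_af > config.common_af_max:
            continue
        if _is_benign(v, config.benign_predictors):
            continue
        if config.keep_protein_altering_only and v.consequence not in PROTEIN_ALTERING:
            continue
        kept.append(v)
    return kept


def ufv_filter(
    variants: Iterable[VariantRecord],
    n_samples: int,
    config: FilterConfig | None = None,
) -> list[VariantRecord]:
    """Keep unusually frequent variants (UFVs).

    A variant is retained when it is novel (no reference frequency) or its
    cohort allele frequency exceeds ``ratio_min`` times its reference
    frequency. A recorded reference frequency of exactly 0 is treated as
    novel, with a warning.
    """
    config = config or FilterConfig()
    kept: list[VariantRecord] = []
    for v in variants:
        if v.ref_af is None:
            kept.append(v)
            continue
        if v.ref_af == 0.0:
            logger.warning(
                "variant %s: ref_af is 0 but not flagged novel; treating as novel",
                v.variant_id,
            )
            kept.append(v)
            continue
        ratio = cohort_allele_frequency(v.allele_count, n_samples) / v.ref_af
        if ratio > config.ratio_min:
            kept.append(v)
    return kept


def variant_count_pvalue(allele_count: int, n_samples: int, ref_af: float) -> float:
    """Upper-tail binomial p-value for a variant's cohort allele count.

    Probability of observing >= ``allele_count`` alternate alleles among
    2N chromosomes when each carries the allele with probability
    ``ref_af``. This is the variant-level test evaluated as an alternative
    to the observed/expected ratio filter; the ratio filter is the one
    used by the pipeline.
    """
    if not (0.0 < ref_af < 1.0):
        raise ValueError("ref_af must lie strictly inside (0, 1)")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if allele_count < 0 or allele_count > 2 * n_samples:
        raise InvalidGenotypeError("allele count outside the diploid range")
    if allele_count == 0:
        return 1.0
    # P(X >= k) = sf(k - 1) for X ~ Binomial(2N, ref_af)
    return float(stats.binom.sf(allele_count - 1, 2 * n_samples, ref_af))


@dataclass
class FilterSummary:
    """Counts produced by the two-stage filter, for reporting."""

    n_input: int
    n_after_rare_damaging: int
    n_ufv: int
    pct_ufv: float
    counts_by_type: dict[str, int]
    counts_by_consequence: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_rare_damaging": self.n_after_rare_damaging,
            "n_ufv": self.n_ufv,
            "pct_ufv": self.pct_ufv,
            "counts_by_type": dict(self.counts_by_type),
            "counts_by_consequence": dict(self.counts_by_consequence),
        }


def summarize_filtering(
    variants_in: Sequence[VariantRecord],
    variants_rare_damaging: Sequence[VariantRecord],
    variants_ufv: Sequence[VariantRecord],
) -> FilterSummary:
    """Summarize the filter cascade; the three lists must be successive subsets.

    ``pct_ufv`` is the UFV share of the rare/damaging set, as a percentage
    rounded to one decimal. Category counts describe the UFV set only.
    """
    ids_in = {v.variant_id for v in variants_in}
    ids_rd = {v.variant_id for v in variants_rare_damaging}
    ids_ufv = {v.variant_id for v in variants_ufv}
    if not ids_rd <= ids_in or not ids_ufv <= ids_rd:
        raise ConsistencyError(
            "filter stages are not successive subsets of the input table"
        )
    n_rd = len(variants_rare_damaging)
    n_ufv = len(variants_ufv)
    pct = round(100.0 * n_ufv / n_rd, 1) if n_rd else 0.0
    by_type = Counter(v.variant_type.value for v in variants_ufv)
    by_csq = Counter(v.consequence.value for v in variants_ufv)
    return FilterSummary(
        n_input=len(variants_in),
        n_after_rare_damaging=n_rd,
        n_ufv=n_ufv,
        pct_ufv=pct,
        counts_by_type=dict(by_type),
        counts_by_consequence=dict(by_csq),
    )
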