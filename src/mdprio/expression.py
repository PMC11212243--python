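"""Cell-type expression specificity of prioritized genes.

Within each cell type of a labeled expression matrix, every gene's mean
expression is converted to a fractional rank (percentile in [0, 1],
average ranks for ties). Prioritized genes are then compared against a
baseline gene set — by default all genes carrying at least one cohort
variant — with a two-sided Wilcoxon rank-sum test per cell type and
Benjamini-Hochberg correction across cell types.

Percentile ranking is invariant to any monotone per-cell-type transform
of mean expression, so the choice of normalization (raw vs log counts)
does not affect the comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledExpression",
    "celltype_percentiles",
    "relative_average_expression",
    "compare_gene_sets",
    "significance_tier",
]


@dataclass
class LabeledExpression:
    """A genes x cells expression matrix with one cell-type label per cell."""

    genes: list[str]
    cells: list[str]
    matrix: np.ndarray  # (n_genes, n_cells), non-negative
    cell_types: list[str]  # one label per cell

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise ValueError("matrix shape must be (n_genes, n_cells)")
        if len(self.cell_types) != len(self.cells):
            raise ValueError("every cell needs exactly one cell-type label")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if (self.matrix < 0).any():
            raise ValueError("expression values must be non-negative")

    def type_means(self) -> pd.DataFrame:
        """Per-gene mean expression within each cell type (genes x types)."""
        ct = np.asarray(self.cell_types)
        cols = {}
        for t in dict.fromkeys(self.cell_types):
            mask = ct == t
            if not mask.any():
                logger.warning("cell type %s has no cells; excluded", t)
                continue
            cols[t] = self.matrix[:, mask].mean(axis=1)
        return pd.DataFrame(cols, index=self.genes)


def celltype_percentiles(expr: LabeledExpression) -> pd.DataFrame:
    """Fractional expression rank of every gene within every cell type.

    Returns a long-format frame with columns ``gene, cell_type,
    mean_expression, percentile``; percentile = average rank / n_genes,
    so the top gene of a type scores 1.0 and a fully tied type scores
    (n+1)/(2n) ≈ 0.5 everywhere.
    """
    if len(expr.genes) < 2:
        raise ValueError("at least two genes are required for ranking")
    means = expr.type_means()
    rows = []
    n = len(expr.genes)
    for t in means.columns:
        vals = means[t].to_numpy()
        pct = stats.rankdata(vals, method="average") / n
        rows.extend(
            {
                "gene": g,
                "cell_type": t,
                "mean_expression": float(v),
                "percentile": float(p),
            }
            for g, v, p in zip(expr.genes, vals, pct)
        )
    return pd.DataFrame(rows)


def relative_average_expression(expr: LabeledExpression) -> pd.DataFrame:
    """Per-gene min-max scaling of cell-type means to [0, 1] (heatmap scale).

    Genes expressed identically across all types map to 0.
    """
    means = expr.type_means()
    lo = means.min(axis=1)
    span = means.max(axis=1) - lo
    span = span.replace(0.0, 1.0)
    return means.sub(lo, axis=0).div(span, axis=0)


def significance_tier(p_adj: float) -> str:
    if math.isnan(p_adj):
        return "NA"
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def compare_gene_sets(
    percentiles: pd.DataFrame,
    prioritized: set[str],
    baseline: set[str],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Per-cell-type rank-sum comparison of prioritized vs baseline percentiles.

    For each cell type, the percentile distributions of the two gene sets
    are compared with a two-sided Wilcoxon rank-sum (Mann-Whitney U) test;
    p-values are BH-adjusted across cell types. ``median_difference`` is
    median(prioritized) - median(baseline); the significance tier follows
    the FDR < 0.001 / 0.01 / 0.05 / ns convention. Cell types where either
    set has fewer than ``min_set_size`` genes with percentiles are skipped
    with NaN statistics.
    """
    universe = set(percentiles["gene"])
    for name, s in (("prioritized", prioritized), ("baseline", baseline)):
        outside = s - universe
        if outside:
            logger.warning(
                "%d %s gene(s) missing from the expression matrix", len(outside), name
            )
    rows = []
    for t, sub in percentiles.groupby("cell_type", sort=False):
        pct = dict(zip(sub["gene"], sub["percentile"]))
        a = np.array([pct[g] for g in prioritized if g in pct])
        b = np.array([pct[g] for g in baseline if g in pct])
        if len(a) < min_set_size or len(b) < min_set_size:
            logger.warning(
                "cell type %s: gene set below %d members; test skipped", t, min_set_size
            )
            rows.append(
                {
                    "cell_type": t,
                    "n_prioritized": len(a),
                    "n_baseline": len(b),
                    "median_prioritized": float(np.median(a)) if len(a) else math.nan,
                    "median_baseline": float(np.median(b)) if len(b) else math.nan,
                    "median_difference": math.nan,
                    "p": math.nan,
                }
            )
            continue
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical sets: no evidence of a difference
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "cell_type": t,
                "n_prioritized": len(a),
                "n_baseline": len(b),
                "median_prioritized": float(np.median(a)),
                "median_baseline": float(np.median(b)),
                "median_difference": float(np.median(a) - np.median(b)),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].tolist())
    df["tier"] = [significance_tier(p) for p in df["p_adj"]]
    return df
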