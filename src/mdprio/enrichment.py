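"""Hypergeometric gene-set over-representation with BH correction.

For a query gene set Q, an annotation set A and a universe U, the
enrichment p-value is the upper tail of the hypergeometric distribution:
the probability of drawing at least |Q ∩ A| annotated genes when |Q|
genes are sampled from U without replacement. Effect sizes are reported
as log observed/expected overlap and as the log odds ratio of the 2x2
table (with a Haldane 0.5 correction when any cell is empty).
Benjamini-Hochberg adjustment is applied within each query across the
sets of a collection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import FilterConfig, VariantRecord, ufv_filter
from .network import GeneNetworkScore, PrioritizationConfig, prioritize
from .recurrence import GeneRecurrence, RecurrenceConfig, gene_recurrence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_enrich",
    "enrich_collection",
    "bh_adjust",
    "threshold_sensitivity",
    "results_to_frame",
]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets over a shared universe."""

    name: str
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        if not self.universe:
            raise ValueError("collection universe must be non-empty")
        self.sets = {k: set(v) & self.universe for k, v in self.sets.items()}

    def restricted(self, universe: set[str]) -> "GeneSetCollection":
        """The collection with every set and the universe intersected with
        ``universe``."""
        return GeneSetCollection(
            name=self.name,
            sets={k: v & universe for k, v in self.sets.items()},
            universe=self.universe & universe,
        )


@dataclass
class EnrichmentResult:
    query_name: str
    set_name: str
    n_universe: int
    n_query: int
    n_set: int
    n_overlap: int
    expected_overlap: float
    log_obs_exp: float
    log_odds_ratio: float
    p: float
    p_adj: float = math.nan
    log_obs_exp_sd: float = math.nan  # bootstrap SD, when requested


def _log_odds(k: int, q: int, K: int, n: int) -> float:
    # 2x2 table: overlap / query-only / set-only / neither
    a, b, c, d = k, q - k, K - k, n - q - K + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log(a * d / (b * c))


def hypergeom_enrich(
    query: set[str],
    annotation: set[str],
    universe: set[str],
    query_name: str = "query",
    set_name: str = "set",
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of query/annotation overlap.

    Genes outside the universe are dropped from both sets before testing.
    With ``n_boot`` > 0, a bootstrap SD of log(obs/exp) is estimated by
    resampling the query with replacement.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query_r = query & universe
    annotation_r = annotation & universe
    if not query_r:
        raise ValueError("query is empty after restriction to the universe")
    n = len(universe)
    q = len(query_r)
    K = len(annotation_r)
    k = len(query_r & annotation_r)
    expected = q * K / n
    # P(overlap >= k) for overlap ~ Hypergeom(n, K, q)
    p = float(stats.hypergeom.sf(k - 1, n, K, q))
    p = min(max(p, 0.0), 1.0)
    log_oe = math.log(k / expected) if k > 0 and expected > 0 else -math.inf
    result = EnrichmentResult(
        query_name=query_name,
        set_name=set_name,
        n_universe=n,
        n_query=q,
        n_set=K,
        n_overlap=k,
        expected_overlap=expected,
        log_obs_exp=log_oe,
        log_odds_ratio=_log_odds(k, q, K, n),
        p=p,
    )
    if n_boot > 0:
        rng = rng or np.random.default_rng()
        members = sorted(query_r)
        in_set = np.fromiter((g in annotation_r for g in members), dtype=bool)
        draws = rng.integers(0, q, size=(n_boot, q))
        ks = in_set[draws].sum(axis=1)
        with np.errstate(divide="ignore"):
            log_oes = np.where(ks > 0, np.log(np.maximum(ks, 1) / expected), -np.inf)
        finite = log_oes[np.isfinite(log_oes)]
        result.log_obs_exp_sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else math.nan
    return result


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (NaN entries pass through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, math.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m:
        order = np.argsort(pm, kind="mergesort")
        ranked = pm[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out[mask] = adj
    return out.tolist()


def enrich_collection(
    queries: Mapping[str, set[str]],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Test every (query, set) pair; BH adjustment per query across sets.

    The testing universe defaults to the collection's own universe; pass
    ``universe`` to restrict further (e.g. to genes carrying variants).
    Query genes outside the universe are dropped with a logged count.
    """
    uni = collection.universe if universe is None else collection.universe & universe
    results: list[EnrichmentResult] = []
    for qname, qgenes in queries.items():
        dropped = len(qgenes) - len(qgenes & uni)
        if dropped:
            logger.info(
                "query %s: %d gene(s) outside the universe dropped", qname, dropped
            )
        per_query = [
            hypergeom_enrich(
                qgenes, sgenes, uni, query_name=qname, set_name=sname,
                n_boot=n_boot, rng=rng,
            )
            for sname, sgenes in collection.sets.items()
        ]
        for res, adj in zip(per_query, bh_adjust([r.p for r in per_query])):
            res.p_adj = adj
        results.extend(per_query)
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def threshold_sensitivity(
    variants_rare_damaging: Sequence[VariantRecord],
    netscores: Sequence[GeneNetworkScore],
    collection: GeneSetCollection,
    n_samples: int,
    ratio_grid: Sequence[float] = (1.2, 1.3, 1.4),
    z_grid: Sequence[float] = (2.5, 3.0, 3.5),
    recur_grid: Sequence[int] = (3, 4, 5),
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Re-derive the three candidate gene sets on a threshold grid and
    re-test enrichment at each grid point.

    The UFV set is recomputed for every ``ratio_min``; recurrence and the
    z cut are then re-applied. Network scores are held fixed across the
    grid (the propagation itself does not depend on the thresholds).
    Returns a long-format table with one row per (grid point, query, set);
    grid points that empty a query keep their rows with ``n_query`` 0 and
    ``p`` NaN.
    """
    if not (len(ratio_grid) and len(z_grid) and len(recur_grid)):
        raise ValueError("all threshold grids must be non-empty")
    rows = []
    for ratio_min in ratio_grid:
        ufvs = ufv_filter(
            variants_rare_damaging, n_samples, FilterConfig(ratio_min=ratio_min)
        )
        recurrence = gene_recurrence(ufvs, n_samples)
        for recur_min in recur_grid:
            for z_min in z_grid:
                sets = prioritize(
                    recurrence,
                    netscores,
                    PrioritizationConfig(z_min=z_min, recur_min=recur_min),
                )
                for qname, qgenes in sets.items():
                    base = {
                        "ratio_min": ratio_min,
                        "recur_min": recur_min,
                        "z_min": z_min,
                        "query_name": qname,
                    }
                    if not qgenes or not (qgenes & (
                        collection.universe if universe is None
                        else collection.universe & universe
                    )):
                        for sname in collection.sets:
                            rows.append(
                                base
                                | {
                                    "set_name": sname,
                                    "n_query": 0,
                                    "n_overlap": 0,
                                    "log_obs_exp": math.nan,
                                    "p": math.nan,
                                }
                            )
                        continue
                    for res in enrich_collection(
                        {qname: qgenes}, collection, universe=universe
                    ):
                        rows.append(
                            base
                            | {
                                "set_name": res.set_name,
                                "n_query": res.n_query,
                                "n_overlap": res.n_overlap,
                                "log_obs_exp": res.log_obs_exp,
                                "p": res.p,
                            }
                        )
    return pd.DataFrame(rows)
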