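import itertools
import math

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from mdprio import (
    GeneSetCollection,
    bh_adjust,
    enrich_collection,
    hypergeom_enrich,
    threshold_sensitivity,
)
from mdprio.network import GeneNetworkScore

from conftest import make_variant


def enumeration_pvalue(universe, annotation, query_size, observed_overlap):
    """Brute-force oracle: enumerate every possible query draw."""
    universe = sorted(universe)
    total = 0
    at_least = 0
    for combo in itertools.combinations(universe, query_size):
        total += 1
        if sum(g in annotation for g in combo) >= observed_overlap:
            at_least += 1
    return at_least / total


class TestHypergeomEnrich:
    def test_query_equals_universe(self):
        uni = {f"g{i}" for i in range(10)}
        ann = {f"g{i}" for i in range(4)}
        res = hypergeom_enrich(uni, ann, uni)
        assert res.n_overlap == len(ann)
        assert res.p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        uni = {f"g{i}" for i in range(20)}
        ann = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g10"}  # overlap 3
        res = hypergeom_enrich(query, ann, uni)
        assert res.n_overlap == 3
        oracle = enumeration_pvalue(uni, ann, 4, 3)
        assert res.p == pytest.approx(oracle, rel=1e-12)

    def test_overlap_at_expectation_gives_zero_log_ratio(self):
        uni = {f"g{i}" for i in range(20)}
        ann = {f"g{i}" for i in range(10)}  # expected overlap = 4*10/20 = 2
        query = {"g0", "g1", "g10", "g11"}  # overlap 2
        res = hypergeom_enrich(query, ann, uni)
        assert res.log_obs_exp == pytest.approx(0.0)

    def test_zero_overlap_effect_sizes(self):
        uni = {f"g{i}" for i in range(10)}
        res = hypergeom_enrich({"g0"}, {"g9"}, uni)
        assert res.log_obs_exp == -math.inf
        assert math.isfinite(res.log_odds_ratio)  # Haldane correction

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich({"a"}, {"a"}, set())
        with pytest.raises(ValueError):
            hypergeom_enrich({"zzz"}, {"a"}, {"a", "b"})

    def test_bootstrap_sd_is_reported(self, rng):
        uni = {f"g{i}" for i in range(30)}
        ann = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(0, 12, 2)}
        res = hypergeom_enrich(query, ann, uni, n_boot=500, rng=rng)
        assert res.log_obs_exp_sd > 0

    def test_adding_annotated_gene_never_decreases_overlap(self):
        uni = {f"g{i}" for i in range(15)}
        ann = {f"g{i}" for i in range(6)}
        query = {"g0", "g7"}
        before = hypergeom_enrich(query, ann, uni).n_overlap
        after = hypergeom_enrich(query | {"g1"}, ann, uni).n_overlap
        assert after >= before


class TestBHAdjustment:
    def test_matches_statsmodels(self, rng):
        p = rng.random(25).tolist()
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_monotone_and_bounded(self, rng):
        p = sorted(rng.random(40))
        adj = bh_adjust(p)
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= pv for a, pv in zip(adj, p))

    def test_nan_passthrough(self):
        adj = bh_adjust([0.01, math.nan, 0.04])
        assert math.isnan(adj[1]) and not math.isnan(adj[0])


class TestEnrichCollection:
    def _collection(self):
        uni = {f"g{i}" for i in range(50)}
        sets = {
            "s1": {f"g{i}" for i in range(10)},
            "s2": {f"g{i}" for i in range(10, 20)},
            "s3": {f"g{i}" for i in range(20, 30)},
            "s4": {f"g{i}" for i in range(30, 40)},
            "s5": {f"g{i}" for i in range(40, 50)},
        }
        return GeneSetCollection(name="toy", sets=sets, universe=uni)

    def test_bookkeeping_three_queries_five_sets(self):
        coll = self._collection()
        queries = {
            "q1": {"g0", "g1"},
            "q2": {"g10", "g11"},
            "q3": {"g20", "g40"},
        }
        results = enrich_collection(queries, coll)
        assert len(results) == 15
        for qname in queries:
            sub = [r for r in results if r.query_name == qname]
            assert np.allclose(
                [r.p_adj for r in sub], bh_adjust([r.p for r in sub]), equal_nan=True
            )

    def test_disjoint_set_has_p_one(self):
        coll = self._collection()
        results = enrich_collection({"q": {"g0"}}, coll)
        disjoint = [r for r in results if r.set_name != "s1"]
        assert all(r.p == pytest.approx(1.0) for r in disjoint)

    def test_planted_set_attains_smallest_adjusted_p(self, rng):
        # disease genes seeded into one set at 5x the background rate
        wins = 0
        n_sim = 100
        genes = [f"g{i}" for i in range(400)]
        disease = set(genes[:40])
        for _ in range(n_sim):
            sets = {}
            for name, planted in (("planted", True), ("bg1", False), ("bg2", False)):
                members = set()
                for g in genes:
                    rate = 0.5 if (planted and g in disease) else 0.1
                    if rng.random() < rate:
                        members.add(g)
                sets[name] = members
            coll = GeneSetCollection(name="sim", sets=sets, universe=set(genes))
            results = enrich_collection({"q": disease}, coll)
            best = min(results, key=lambda r: r.p_adj)
            wins += best.set_name == "planted"
        assert wins >= 95


class TestThresholdSensitivity:
    def _inputs(self):
        variants = []
        for i in range(30):
            gene = f"g{i % 6}"
            variants.append(
                make_variant(
                    variant_id=f"v{i}",
                    gene=gene,
                    carriers=[f"S{j}" for j in range(5)],
                    allele_count=5,
                    ref_af=5 / 200 / 2.0,  # cohort AF 2x reference at N=100
                )
            )
        netscores = [
            GeneNetworkScore(gene=f"g{i}", score=1, null_mean=0, null_sd=1, z=4 - i)
            for i in range(6)
        ]
        uni = {f"g{i}" for i in range(6)}
        coll = GeneSetCollection(
            name="c", sets={"sA": {"g0", "g1"}, "sB": {"g4", "g5"}}, universe=uni
        )
        return variants, netscores, coll

    def test_default_grid_point_reproduces_direct_enrichment(self):
        variants, netscores, coll = self._inputs()
        table = threshold_sensitivity(
            variants, netscores, coll, n_samples=100,
            ratio_grid=[1.3], z_grid=[3.0], recur_grid=[4],
        )
        from mdprio import FilterConfig, ufv_filter, gene_recurrence, prioritize

        ufvs = ufv_filter(variants, 100, FilterConfig())
        sets = prioritize(gene_recurrence(ufvs), netscores)
        direct = enrich_collection(sets, coll)
        for r in direct:
            row = table[
                (table.query_name == r.query_name) & (table.set_name == r.set_name)
            ].iloc[0]
            assert row.p == pytest.approx(r.p)
            assert row.n_query == r.n_query

    def test_unreachable_threshold_keeps_rows_with_nan(self):
        variants, netscores, coll = self._inputs()
        table = threshold_sensitivity(
            variants, netscores, coll, n_samples=100,
            ratio_grid=[1.3], z_grid=[3.0], recur_grid=[999],
        )
        rec_rows = table[table.query_name == "recurrence"]
        assert (rec_rows.n_query == 0).all()
        assert rec_rows.p.isna().all()

    def test_empty_grid_rejected(self):
        variants, netscores, coll = self._inputs()
        with pytest.raises(ValueError):
            threshold_sensitivity(variants, netscores, coll, 100, ratio_grid=[])
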