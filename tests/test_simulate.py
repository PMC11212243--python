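import numpy as np
import pytest
from scipy import stats

from mdprio import (
    SimulationConfig,
    celltype_percentiles,
    compare_gene_sets,
    simulate_cohort,
    simulate_gene_sets,
    simulate_network,
    simulate_study,
)
from mdprio import io as mio
from mdprio.simulate import make_truth, simulate_expression


class TestCohortGenerator:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimulationConfig(n_genes=100, n_disease_genes=10, n_samples=50, rng_seed=5)
        v1, _ = simulate_cohort(cfg)
        v2, _ = simulate_cohort(cfg)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        mio.write_variant_table(v1, p1)
        mio.write_variant_table(v2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fold_one_cohort_af_matches_reference(self):
        # with no planted inflation, pooled cohort AF should equal the
        # reference AF on average (ratio approximately 1 within MC error)
        ratios = []
        for seed in range(6):
            cfg = SimulationConfig(
                n_genes=150, n_disease_genes=10, fold=1.0, novel_fraction=0.0,
                common_fraction=0.0, include_unobserved=True, rng_seed=seed,
            )
            variants, _ = simulate_cohort(cfg)
            ac = np.array([v.allele_count for v in variants], dtype=float)
            exp = np.array([2 * cfg.n_samples * v.ref_af for v in variants])
            ratios.append(ac.sum() / exp.sum())
        grand = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(grand - 1.0) < max(3 * se, 0.01)

    def test_disease_gene_allele_counts_scale_with_fold(self):
        cfg = SimulationConfig(
            n_genes=200, n_disease_genes=40, fold=2.0, novel_fraction=0.0,
            common_fraction=0.0, include_unobserved=True, rng_seed=2,
        )
        variants, truth = simulate_cohort(cfg)
        disease = [v for v in variants if v.gene in truth.disease_genes]
        ac = sum(v.allele_count for v in disease)
        # closed form: E[AC] = 2 N min(fold * q, 1); af_max * fold < 1 here
        expected = sum(2 * cfg.n_samples * cfg.fold * v.ref_af for v in disease)
        assert ac / expected == pytest.approx(1.0, abs=0.1)

    def test_carriers_consistent_with_allele_counts(self):
        cfg = SimulationConfig(n_genes=80, n_disease_genes=8, n_samples=40, rng_seed=3)
        variants, _ = simulate_cohort(cfg)
        assert variants  # non-degenerate draw
        for v in variants:
            assert len(v.carriers) <= v.allele_count <= 2 * len(v.carriers)

    def test_nuisance_variants_planted(self):
        cfg = SimulationConfig(n_genes=300, n_disease_genes=10, rng_seed=4)
        variants, _ = simulate_cohort(cfg)
        assert any(v.ref_af is not None and v.ref_af > 0.05 for v in variants)
        assert any(
            "benign" in v.deleterious_labels.values() for v in variants
        )
        assert any(v.consequence.value == "other" for v in variants)
        assert any(v.novel for v in variants)


class TestNetworkGenerator:
    def test_planted_module_denser_and_connected(self):
        cfg = SimulationConfig(n_genes=300, n_disease_genes=30, module_factor=10, rng_seed=7)
        truth = make_truth(cfg)
        net = simulate_network(cfg, truth)
        g = net.to_networkx()
        module = g.subgraph(truth.disease_genes)
        import networkx as nx

        assert nx.is_connected(module)
        background = set(net.nodes) - truth.disease_genes
        mean_module_internal = 2 * module.number_of_edges() / len(truth.disease_genes)
        mean_bg = np.mean([g.degree(n) for n in background])
        assert mean_module_internal > mean_bg

    def test_module_factor_one_indistinguishable_degrees(self):
        cfg = SimulationConfig(n_genes=400, n_disease_genes=40, module_factor=1.0, rng_seed=8)
        truth = make_truth(cfg)
        net = simulate_network(cfg, truth)
        g = net.to_networkx()
        d_deg = [g.degree(n) for n in truth.disease_genes]
        b_deg = [g.degree(n) for n in set(net.nodes) - truth.disease_genes]
        p = stats.mannwhitneyu(d_deg, b_deg).pvalue
        assert p > 0.01

    def test_zero_background_leaves_only_module(self):
        cfg = SimulationConfig(
            n_genes=100, n_disease_genes=10, edge_prob=0.0, module_factor=10, rng_seed=9
        )
        truth = make_truth(cfg)
        net = simulate_network(cfg, truth)
        for a, b, _ in net.edges():
            assert a in truth.disease_genes and b in truth.disease_genes

    def test_confidences_in_range(self):
        cfg = SimulationConfig(n_genes=100, n_disease_genes=10, rng_seed=10)
        net = simulate_network(cfg, make_truth(cfg))
        weights = [w for _, _, w in net.edges()]
        assert all(cfg.min_confidence < w <= 1.0 for w in weights)


class TestGeneSetGenerator:
    def test_disease_genes_planted_into_relevant_sets(self):
        cfg = SimulationConfig(n_genes=500, n_disease_genes=50, rng_seed=11)
        truth = make_truth(cfg)
        coll, truth = simulate_gene_sets(cfg, truth)
        assert truth.planted_gene_sets
        for name in truth.planted_gene_sets:
            planted = coll.sets[name]
            disease_rate = len(planted & truth.disease_genes) / len(truth.disease_genes)
            bg_rate = len(planted - truth.disease_genes) / (
                cfg.n_genes - cfg.n_disease_genes
            )
            assert disease_rate > bg_rate

    def test_planting_rate_one_matches_background(self):
        hits, total = 0, 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_genes=400, n_disease_genes=40, geneset_planting_rate=1.0,
                rng_seed=100 + seed,
            )
            truth = make_truth(cfg)
            coll, truth = simulate_gene_sets(cfg, truth)
            for name in truth.planted_gene_sets:
                hits += len(coll.sets[name] & truth.disease_genes)
                total += len(truth.disease_genes)
        rate = hits / total
        base = SimulationConfig().gene_set_size / 400
        se = np.sqrt(base * (1 - base) / total)
        assert abs(rate - base) < 4 * se

    def test_gmt_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=100, n_disease_genes=10, rng_seed=12)
        truth = make_truth(cfg)
        coll, _ = simulate_gene_sets(cfg, truth)
        path = tmp_path / "sets.gmt"
        mio.write_gmt(coll.sets, path)
        assert mio.read_gmt(path) == coll.sets


class TestExpressionGenerator:
    def test_zero_effect_size_is_type_one_calibrated(self):
        clean = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SimulationConfig(
                n_genes=150, n_disease_genes=25, expression_effect_size=0.0,
                n_cells_per_type=10, rng_seed=500 + seed,
            )
            truth = make_truth(cfg)
            expr, truth = simulate_expression(cfg, truth)
            pct = celltype_percentiles(expr)
            res = compare_gene_sets(pct, truth.disease_genes, set(expr.genes))
            if (res.p_adj.dropna() >= 0.05).all():
                clean += 1
        assert clean >= int(0.9 * n_rep)


def test_full_study_is_deterministic_and_coherent():
    s1 = simulate_study(SimulationConfig(n_genes=120, n_disease_genes=12, n_samples=40, rng_seed=13))
    s2 = simulate_study(SimulationConfig(n_genes=120, n_disease_genes=12, n_samples=40, rng_seed=13))
    assert [v.variant_id for v in s1.variants] == [v.variant_id for v in s2.variants]
    assert s1.network.edges() == s2.network.edges()
    assert s1.truth.disease_genes == s2.truth.disease_genes
    assert s1.truth.disease_genes <= set(s1.network.nodes)
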