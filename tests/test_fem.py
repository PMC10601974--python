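import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from conftest import weighted_graph
from epimodules.datatypes import GeneRegion
from epimodules.fem import (
    FEMParams,
    FunctionalEpigeneticModules,
    Module,
    NodeStat,
    build_weighted_graph,
    concordant_genes,
    deduplicate_modules,
    greedy_module_search,
    hypergeometric_ora,
    integrate_node_stats,
    module_pvalue,
    region_meth_statistic,
    select_seeds,
)
from oracles import greedy_reference, hypergeom_tail_brute, random_connected_graph


def dmp_frame(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "beta_case", "beta_ctrl", "meth_diff", "p"]
    )
    df["q"] = df["p"]
    df["status"] = "ns"
    return df


class TestRegionStatistic:
    region = [GeneRegion("gA", "chr1", 0, 1000, "+", "promoter")]

    def test_single_cpg_probit(self):
        cpgs = dmp_frame([("chr1", 10, 0.9, 0.4, 0.5, 0.05)])
        z = region_meth_statistic(cpgs, self.region, "promoter")
        assert z["gA"] == pytest.approx(st.norm.isf(0.025), rel=1e-6)

    def test_opposite_signs_cancel(self):
        cpgs = dmp_frame(
            [
                ("chr1", 10, 0.9, 0.4, 0.5, 0.01),
                ("chr1", 20, 0.1, 0.6, -0.5, 0.01),
            ]
        )
        z = region_meth_statistic(cpgs, self.region, "promoter")
        assert z["gA"] == pytest.approx(0.0, abs=1e-12)

    def test_gene_without_cpgs_gets_zero(self):
        cpgs = dmp_frame([("chr2", 10, 0.9, 0.4, 0.5, 0.01)])
        z = region_meth_statistic(cpgs, self.region, "promoter")
        assert z["gA"] == 0.0

    def test_tiny_pvalues_capped(self):
        cpgs = dmp_frame([("chr1", 10, 1.0, 0.0, 1.0, 0.0)])
        z = region_meth_statistic(cpgs, self.region, "promoter")
        assert z["gA"] == pytest.approx(8.0)

    def test_stouffer_scaling_with_n(self):
        cpgs = dmp_frame(
            [("chr1", 10 * i, 0.9, 0.4, 0.5, 0.05) for i in range(1, 5)]
        )
        z = region_meth_statistic(cpgs, self.region, "promoter")
        assert z["gA"] == pytest.approx(
            4 * st.norm.isf(0.025) / np.sqrt(4), rel=1e-6
        )


def de_frame(entries):
    return pd.DataFrame(
        [
            {"gene_id": g, "lfc": l, "se": s, "p": p, "padj": p,
             "mean_expr": 10.0}
            for g, l, s, p in entries
        ]
    )


class TestIntegration:
    def graph(self, genes):
        g = nx.Graph()
        for i in range(len(genes) - 1):
            g.add_edge(genes[i], genes[i + 1], score=500)
        return g

    def test_extreme_gene_gets_weight_one(self):
        genes = [f"g{i}" for i in range(5)]
        z = {g: 0.1 * i for i, g in enumerate(genes)}
        de = de_frame([(g, 0.1 * i, 1.0, 0.5) for i, g in enumerate(genes)])
        stats_, _ = integrate_node_stats(z, de, self.graph(genes))
        top = next(s for s in stats_ if s.gene_id == "g4")
        assert top.weight == pytest.approx(1.0)

    def test_all_zero_statistics_tie_at_mean_rank(self):
        genes = [f"g{i}" for i in range(4)]
        z = dict.fromkeys(genes, 0.0)
        de = de_frame([(g, 0.0, 1.0, 1.0) for g in genes])
        stats_, _ = integrate_node_stats(z, de, self.graph(genes))
        weights = [s.weight for s in stats_]
        assert weights == pytest.approx([(4 + 1) / (2 * 4)] * 4)

    def test_states_carried_from_calls(self):
        genes = ["gA", "gB", "gC"]
        z = dict.fromkeys(genes, 0.0)
        de = de_frame([(g, 0.0, 1.0, 1.0) for g in genes])
        dmg = pd.DataFrame(
            [{"gene_id": "gA", "region_kind": "promoter", "n_dmps": 6,
              "n_hyper": 6, "n_hypo": 0, "direction": "hyper"}]
        )
        stats_, _ = integrate_node_stats(
            z, de, self.graph(genes), dmg_table=dmg,
            deg_sets=({"gB"}, {"gA"}),
        )
        by = {s.gene_id: s for s in stats_}
        assert by["gA"].meth_state == "hyper"
        assert by["gA"].expr_state == "down"
        assert by["gB"].expr_state == "up"
        assert by["gC"].meth_state == "none"

    def test_genes_absent_from_graph_counted(self):
        genes = ["gA", "gB", "gC"]
        z = {"gA": 1.0, "gX": 5.0}
        de = de_frame([(g, 0.0, 1.0, 1.0) for g in genes + ["gY"]])
        _, n_excluded = integrate_node_stats(z, de, self.graph(genes))
        assert n_excluded == 2


class TestWeightedGraphAndSeeds:
    def test_edge_weight_is_endpoint_average(self):
        g = nx.Graph()
        g.add_edge("a", "b", score=900)
        stats_ = [
            NodeStat("a", 0, 0, 0, 0, 0.2), NodeStat("b", 0, 0, 0, 0, 0.4)
        ]
        wg = build_weighted_graph(g, stats_)
        assert wg["a"]["b"]["weight"] == pytest.approx(0.3)
        assert wg["b"]["a"]["weight"] == pytest.approx(0.3)

    def test_zero_endpoints_zero_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b", score=900)
        stats_ = [NodeStat("a", 0, 0, 0, 0, 0.0), NodeStat("b", 0, 0, 0, 0, 0.0)]
        wg = build_weighted_graph(g, stats_)
        assert wg["a"]["b"]["weight"] == 0.0

    def test_missing_node_stat_errors(self):
        g = nx.Graph()
        g.add_edge("a", "b", score=900)
        with pytest.raises(ValueError, match="b"):
            build_weighted_graph(g, [NodeStat("a", 0, 0, 0, 0, 0.1)])

    def test_seed_selection_and_ties(self):
        stats_ = [
            NodeStat("A", 0, 0, 0, 0, 0.9),
            NodeStat("B", 0, 0, 0, 0, 0.5),
            NodeStat("C", 0, 0, 0, 0, 0.1),
        ]
        assert select_seeds(stats_, 2) == ["A", "B"]
        tied = [NodeStat("B", 0, 0, 0, 0, 0.5), NodeStat("A", 0, 0, 0, 0, 0.5)]
        assert select_seeds(tied, 1) == ["A"]
        assert select_seeds(stats_, 0) == []


class TestGreedySearch:
    def test_path_stops_before_weak_edge(self, weighted_path_graph):
        params = FEMParams(gain_tolerance=1.0, min_module_size=2)
        module = greedy_module_search(weighted_path_graph, "A", params)
        assert module.members == {"A", "B"}
        assert module.modularity == pytest.approx(0.9)

    def test_uniform_triangle_fully_absorbed(self):
        g = weighted_graph(
            {"A": 0.4, "B": 0.4, "C": 0.4},
            [("A", "B", 0.4), ("B", "C", 0.4), ("A", "C", 0.4)],
        )
        params = FEMParams(gain_tolerance=1.0, min_module_size=2)
        module = greedy_module_search(g, "B", params)
        assert module.members == {"A", "B", "C"}
        assert module.modularity == pytest.approx(0.4)

    def test_star_rejects_weak_spokes(self):
        g = weighted_graph(
            {"c": 0.9, "s1": 0.9, "s2": 0.7, "s3": 0.1},
            [("c", "s1", 0.9), ("c", "s2", 0.8), ("c", "s3", 0.1)],
        )
        params = FEMParams(gain_tolerance=1.0, min_module_size=2)
        module = greedy_module_search(g, "c", params)
        assert module.members == {"c", "s1"}
        assert module.modularity == pytest.approx(0.9)

    def test_isolated_seed_flagged_not_raised(self):
        g = weighted_graph({"a": 0.5, "b": 0.5, "x": 0.9}, [("a", "b", 0.5)])
        module = greedy_module_search(g, "x", FEMParams())
        assert module.degenerate
        assert module.members == {"x"}

    def test_matches_independent_reference_on_random_graphs(self):
        rng = np.random.default_rng(0)
        params = FEMParams(min_module_size=3, max_module_size=6,
                           gain_tolerance=1.05)
        for _ in range(30):
            g = random_connected_graph(rng)
            seed = sorted(g.nodes)[0]
            module = greedy_module_search(g, seed, params)
            ref_members, ref_m, ref_peak = greedy_reference(
                g, seed, min_module_size=3, max_module_size=6,
                gain_tolerance=1.05,
            )
            assert module.members == ref_members
            assert module.modularity == pytest.approx(ref_m)
            assert module.peak_modularity == pytest.approx(ref_peak)

    def test_invariant_to_node_insertion_order(self):
        rng = np.random.default_rng(1)
        g = random_connected_graph(rng, max_nodes=8)
        shuffled = nx.Graph()
        order = sorted(g.nodes, reverse=True)
        for n in order:
            shuffled.add_node(n, **g.nodes[n])
        for u, v, d in sorted(g.edges(data=True), reverse=True):
            shuffled.add_edge(u, v, **d)
        seed = sorted(g.nodes)[0]
        m1 = greedy_module_search(g, seed, FEMParams())
        m2 = greedy_module_search(shuffled, seed, FEMParams())
        assert m1.members == m2.members
        assert m1.modularity == pytest.approx(m2.modularity)


class TestModulePvalue:
    def test_lower_bound_one_over_b_plus_one(self):
        g = weighted_graph(
            {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0, "e": 0.0, "f": 0.0},
            [("a", "b", 1.0), ("b", "c", 0.5), ("c", "d", 0.0),
             ("d", "e", 0.0), ("e", "f", 0.0)],
        )
        params = FEMParams(n_permutations=49, min_module_size=2, rng_seed=0)
        module = greedy_module_search(g, "a", params)
        p = module_pvalue(g, "a", module.peak_modularity, params)
        assert p >= 1 / 50

    def test_constant_weights_give_no_signal(self):
        g = weighted_graph(
            {n: 0.5 for n in "abcdef"},
            [("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5),
             ("d", "e", 0.5), ("e", "f", 0.5), ("a", "f", 0.5)],
        )
        params = FEMParams(n_permutations=49, min_module_size=2, rng_seed=1)
        module = greedy_module_search(g, "a", params)
        p = module_pvalue(g, "a", module.peak_modularity, params)
        assert p >= 0.5

    def test_null_pvalues_super_uniform(self):
        """Permutation p-values on i.i.d.-uniform node weights should not
        exceed the nominal level by more than Monte-Carlo noise."""
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            g = nx.barabasi_albert_graph(25, 2, seed=seed)
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            stats_ = [
                NodeStat(n, 0, 0, 0, 0, float(rng.uniform()))
                for n in sorted(g.nodes)
            ]
            for u, v in g.edges:
                g[u][v]["score"] = 500
            wg = build_weighted_graph(g, stats_)
            seed_gene = max(
                stats_, key=lambda s: (s.weight, s.gene_id)
            ).gene_id
            params = FEMParams(n_permutations=99, rng_seed=seed)
            module = greedy_module_search(wg, seed_gene, params)
            pvals.append(
                module_pvalue(wg, seed_gene, module.peak_modularity, params)
            )
        assert np.mean(np.array(pvals) <= 0.05) <= 0.12


def module_of(members, seeds=None, m=0.5, p=0.04):
    members = frozenset(members)
    return Module(
        seeds=frozenset(seeds or [sorted(members)[0]]),
        members=members,
        modularity=m,
        p_perm=p,
        node_stats={},
        edges=(),
    )


class TestDeduplication:
    def test_identical_sets_merge_with_union_of_seeds(self):
        mods = [
            module_of("abcde", seeds=["a"], m=0.5, p=0.04),
            module_of("abcde", seeds=["b"], m=0.6, p=0.02),
        ]
        (merged,) = deduplicate_modules(mods, 0.9)
        assert merged.seeds == {"a", "b"}
        assert merged.p_perm == 0.02
        assert merged.modularity == 0.6

    def test_disjoint_sets_unchanged(self):
        mods = [module_of("abc"), module_of("xyz")]
        assert len(deduplicate_modules(mods, 0.9)) == 2

    def test_jaccard_threshold_inclusive(self):
        a = module_of(set("abcdefghi"))  # 9 members
        b = module_of(set("abcdefghij"))  # 10 members, J = 9/10
        assert len(deduplicate_modules([a, b], 0.9)) == 1
        assert len(deduplicate_modules([a, b], 0.95)) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        mods = []
        pool = [f"g{i}" for i in range(30)]
        for i in range(12):
            members = rng.choice(pool, size=8, replace=False)
            mods.append(module_of(members, m=float(rng.uniform())))
        once = deduplicate_modules(mods, 0.6)
        twice = deduplicate_modules(once, 0.6)
        assert [m.members for m in once] == [m.members for m in twice]
        assert [m.seeds for m in once] == [m.seeds for m in twice]


class TestConcordance:
    dmg = pd.DataFrame(
        [
            {"gene_id": "gHyperDown", "region_kind": "promoter", "n_dmps": 6,
             "n_hyper": 6, "n_hypo": 0, "direction": "hyper"},
            {"gene_id": "gHyperUp", "region_kind": "promoter", "n_dmps": 6,
             "n_hyper": 6, "n_hypo": 0, "direction": "hyper"},
            {"gene_id": "gHypoUp", "region_kind": "promoter", "n_dmps": 5,
             "n_hyper": 0, "n_hypo": 5, "direction": "hypo"},
        ]
    )
    degs = ({"gHyperUp", "gHypoUp"}, {"gHyperDown"})

    def test_anticorrelated_convention(self):
        got = concordant_genes(self.degs, self.dmg, "anticorrelated")
        assert got == {"gHyperDown", "gHypoUp"}

    def test_any_convention(self):
        got = concordant_genes(self.degs, self.dmg, "any")
        assert got == {"gHyperDown", "gHyperUp", "gHypoUp"}

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            concordant_genes(self.degs, self.dmg, "whatever")


class TestOra:
    background = [f"g{i}" for i in range(20)]

    def test_full_overlap_closed_form(self):
        from math import comb

        sets = {"s": self.background[:5]}
        table = hypergeometric_ora(self.background[:5], self.background, sets)
        assert table["p"][0] == pytest.approx(1 / comb(20, 5))

    def test_zero_overlap_p_one(self):
        sets = {"s": self.background[:5]}
        table = hypergeometric_ora(self.background[15:], self.background, sets)
        assert table["p"][0] == pytest.approx(1.0)

    def test_query_equals_background_saturates(self):
        sets = {"s": self.background[:7], "t": self.background[3:9]}
        table = hypergeometric_ora(self.background, self.background, sets)
        assert table["p"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_matches_brute_tail(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_set = int(rng.integers(1, 10))
            n_query = int(rng.integers(1, 10))
            members = list(rng.choice(self.background, n_set, replace=False))
            query = list(rng.choice(self.background, n_query, replace=False))
            table = hypergeometric_ora(query, self.background, {"s": members})
            overlap = len(set(members) & set(query))
            assert table["p"][0] == pytest.approx(
                hypergeom_tail_brute(overlap, 20, n_set, n_query)
            )

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_ora(["zz"], self.background, {})


class TestEndToEndFit:
    def test_modules_are_connected_and_contain_their_seed(self):
        from epimodules.expression import NegativeBinomialDE
        from epimodules.io import collapse_symmetric_cpgs
        from epimodules.methylation import DifferentialMethylation
        from epimodules.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(n_genes=80, n_modules=1,
                               module_size_range=(10, 10), rng_seed=5)
        ann, graph, truth, matrix, case, ctrl = simulate_study(cfg)
        de = NegativeBinomialDE(matrix).fit()
        dm = DifferentialMethylation(
            collapse_symmetric_cpgs(case), collapse_symmetric_cpgs(ctrl)
        ).fit()
        fem = FunctionalEpigeneticModules(
            graph, de.table, dm.table, ann.regions,
            params=FEMParams(n_seeds=10, n_permutations=49, rng_seed=5),
        )
        res = fem.fit()
        assert res.modules
        for module in res.modules:
            assert module.seeds & module.members
            assert nx.is_connected(graph.subgraph(module.members))
            assert 0.0 <= module.modularity <= 1.0
            assert module.p_perm >= 1 / 50
        assert "Functional epigenetic module" in res.summary()
        report = res.module_report()
        assert {"seeds", "size", "modularity", "p_perm", "members"} <= set(
            report.columns
        )
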