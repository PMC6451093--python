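"""Subnetwork construction, permutation enrichment and ranked expansion."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from g2screen import network_enrichment as ne


def clique_graph(k=5, n_universe=100, extra_edges=()):
    universe = [f"G{i:03d}" for i in range(n_universe)]
    edges = [(a, b, 0.9) for a, b in itertools.combinations(universe[:k], 2)]
    edges += [(universe[i], universe[j], 0.5) for i, j in extra_edges]
    return universe, ne.build_network(edges, universe=universe)


class TestBuildSubnetwork:
    def test_clique_edge_count(self):
        universe, g = clique_graph(k=5)
        sub = ne.build_subnetwork(universe[:5], g)
        assert sub.number_of_edges() == 10  # C(5,2)

    def test_no_internal_edges_gives_edgeless_graph(self):
        universe, g = clique_graph(k=5)
        sub = ne.build_subnetwork(universe[10:15], g)
        assert sub.number_of_edges() == 0
        assert sub.number_of_nodes() == 5

    def test_duplicate_and_self_edges_dropped(self):
        edges = [("A", "B", 1.0), ("B", "A", 0.8), ("A", "A", 1.0), ("B", "C", 0.9)]
        g = ne.build_network(edges)
        assert g.number_of_edges() == 2
        assert not any(a == b for a, b in g.edges)

    def test_unmatched_symbols_logged(self):
        _, g = clique_graph()
        sub = ne.build_subnetwork(["G000", "MISSING"], g)
        assert sub.graph["unmatched"] == ("MISSING",)

    def test_edge_list_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("gene_a\tgene_b\tscore\nA\tB\t0.7\nB\tC\t0.9\n")
        df = ne.read_edge_list(path)
        g = ne.build_network(df)
        assert g.number_of_edges() == 2
        assert g["A"]["B"]["score"] == pytest.approx(0.7)


class TestLargestComponent:
    def test_larger_component_wins(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C")])  # 3 nodes, 2 edges
        g.add_edges_from(
            [("D", "E"), ("E", "F"), ("F", "G"), ("G", "H"), ("D", "F")]
        )  # 5 nodes, 5 edges
        assert ne.largest_component_stats(g) == (5, 5)

    def test_triangle(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A")])
        assert ne.largest_component_stats(g) == (3, 3)

    def test_edgeless_graph_reports_singleton(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        assert ne.largest_component_stats(g) == (1, 0)

    def test_empty_graph(self):
        assert ne.largest_component_stats(nx.Graph()) == (0, 0)


class TestEnrichmentPvalue:
    def test_zero_edges_gives_p_one(self):
        universe, g = clique_graph()
        res = ne.enrichment_pvalue(universe[20:25], g, seed=1, n_permutations=1000)
        assert res.pvalue == 1.0

    def test_clique_attains_minimum_p(self):
        # no random 5-set can exceed the clique's 10 edges
        universe, g = clique_graph(k=5, n_universe=100)
        R = 100_000
        res = ne.enrichment_pvalue(universe[:5], g, n_permutations=R, seed=1)
        assert res.pvalue == pytest.approx(1 / (R + 1))

    def test_selected_larger_than_half_universe_rejected(self):
        universe, g = clique_graph(n_universe=8)
        with pytest.raises(ValueError):
            ne.enrichment_pvalue(universe[:5], g, seed=0)

    def test_permutation_matches_exact_enumeration(self):
        # brute-force oracle over all equal-size subsets of a <=12-gene universe
        rng = np.random.default_rng(42)
        universe = [f"G{i:02d}" for i in range(12)]
        edges = [
            (universe[i], universe[j], 1.0)
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.25
        ]
        g = ne.build_network(edges, universe=universe)
        selected = universe[:4]
        R = 100_000
        exact = ne.enrichment_pvalue_exact(selected, g, universe)
        perm = ne.enrichment_pvalue(
            selected, g, n_permutations=R, seed=3, mode="permutation"
        )
        se = np.sqrt(exact * (1 - exact) / R)
        assert abs(perm.pvalue - exact) < 3 * se + 1 / (R + 1)

    def test_analytic_agrees_with_permutation_for_moderate_p(self):
        rng = np.random.default_rng(7)
        universe = [f"G{i:03d}" for i in range(60)]
        edges = [
            (universe[i], universe[j], 1.0)
            for i in range(60)
            for j in range(i + 1, 60)
            if rng.random() < 0.1
        ]
        g = ne.build_network(edges, universe=universe)
        selected = universe[:8]
        perm = ne.enrichment_pvalue(selected, g, n_permutations=50_000, seed=5)
        ana = ne.enrichment_pvalue(
            selected, g, n_permutations=50_000, seed=5, mode="analytic"
        )
        if perm.pvalue >= 0.001:
            assert ana.pvalue == pytest.approx(perm.pvalue, rel=0.5)

    def test_p_nonincreasing_in_observed_edges(self):
        # more internal edges (same null) can only shrink the p-value
        universe = [f"G{i:03d}" for i in range(80)]
        sets = []
        for n_edges in (2, 6, 10):
            edges = [
                (a, b, 1.0)
                for a, b in itertools.combinations(universe[:5], 2)
            ][:n_edges]
            g = ne.build_network(edges, universe=universe)
            res = ne.enrichment_pvalue(universe[:5], g, n_permutations=20_000, seed=9)
            sets.append(res.pvalue)
        assert sets[0] >= sets[1] >= sets[2]

    def test_pvalues_in_unit_interval(self):
        universe, g = clique_graph()
        for seed in range(3):
            res = ne.enrichment_pvalue(
                universe[:5], g, n_permutations=1000, seed=seed
            )
            assert 0 < res.pvalue <= 1
            assert res.pvalue >= 1 / 1001


class TestIterativeExpansion:
    def _wired_universe(self):
        # 6-gene core clique; first candidate group wired into it, second isolated;
        # background edges among the rest keep the null non-degenerate
        universe = [f"G{i:03d}" for i in range(60)]
        core = universe[:6]
        wired = universe[6:16]
        rng = np.random.default_rng(11)
        edges = [(a, b, 1.0) for a, b in itertools.combinations(core, 2)]
        edges += [(w, rng.choice(core), 1.0) for w in wired for _ in range(3)]
        rest = universe[26:]
        edges += [
            (rest[i], rest[j], 1.0)
            for i in range(len(rest))
            for j in range(i + 1, len(rest))
            if rng.random() < 0.05
        ]
        g = ne.build_network(edges, universe=universe)
        return universe, core, g

    def test_exactly_one_group_added(self):
        # the wired group keeps the cumulative set far more enriched than
        # after the isolated group dilutes it; a threshold placed between
        # those oracle p-values must admit exactly the first group
        universe, core, g = self._wired_universe()
        wired, isolated = universe[6:16], universe[16:26]
        seed = 21
        p_wired = ne.enrichment_pvalue(
            core + wired, g, n_permutations=20_000, seed=seed + 1, mode="analytic"
        ).pvalue
        p_diluted = ne.enrichment_pvalue(
            core + wired + isolated, g, n_permutations=20_000, seed=seed + 2,
            mode="analytic",
        ).pvalue
        assert p_wired < p_diluted
        threshold = float(np.sqrt(p_wired * p_diluted))
        config = ne.EnrichmentConfig(
            seed=seed, threshold=threshold, n_permutations=20_000, mode="analytic"
        )
        res = ne.iterative_expansion(core, wired + isolated, g, config)
        assert res.n_added == 10
        assert set(res.final_genes) == set(core) | set(wired)
        assert res.trace["accepted"].tolist() == [True, True, False]

    def test_edgeless_candidates_return_core(self):
        universe, core, g = self._wired_universe()
        isolated = universe[16:26]
        seed = 4
        p_core = ne.enrichment_pvalue(
            core, g, n_permutations=20_000, seed=seed, mode="analytic"
        ).pvalue
        p_with = ne.enrichment_pvalue(
            core + isolated, g, n_permutations=20_000, seed=seed + 1, mode="analytic"
        ).pvalue
        assert p_core < p_with  # dilution can only weaken enrichment
        threshold = float(np.sqrt(p_core * p_with))
        config = ne.EnrichmentConfig(
            seed=seed, threshold=threshold, n_permutations=20_000, mode="analytic"
        )
        res = ne.iterative_expansion(core, isolated, g, config)
        assert set(res.final_genes) == set(core)
        assert res.n_added == 0

    def test_empty_candidates_return_core_with_p(self):
        universe, core, g = self._wired_universe()
        config = ne.EnrichmentConfig(seed=2, threshold=0.5)
        res = ne.iterative_expansion(core, [], g, config)
        assert set(res.final_genes) == set(core)
        assert len(res.trace) == 1

    def test_group_size_one_is_greedy(self):
        universe, core, g = self._wired_universe()
        config = ne.EnrichmentConfig(
            seed=5, group_size=1, threshold=1e-3, n_permutations=5_000
        )
        res = ne.iterative_expansion(core, universe[6:10], g, config)
        steps = res.trace["n_genes"].diff().dropna()
        assert (steps == 1).all()

    def test_trace_reproducible_for_fixed_seed(self):
        universe, core, g = self._wired_universe()
        config = ne.EnrichmentConfig(seed=8, threshold=1e-3, n_permutations=10_000)
        a = ne.iterative_expansion(core, universe[6:26], g, config)
        b = ne.iterative_expansion(core, universe[6:26], g, config)
        pd.testing.assert_frame_equal(a.trace, b.trace)
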