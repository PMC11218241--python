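from __future__ import annotations

import random

import networkx as nx
import pytest

from panrefine.ffdcj_ilp import IlpError, formulate, pairwise_refine, solve
from panrefine.rearrangement_graphs import (
    brute_force_ffdcj_indel,
    build_gs_graph,
    evaluate_matching,
    gs_components,
    make_matching,
)
from panrefine.similarity import WeightedEdge

from conftest import make_genome, unit_edges


def random_instance(rng, max_genes=5, p_edge=0.5):
    na, nb = rng.randint(1, max_genes), rng.randint(1, max_genes)
    a = make_genome("A", [(f"a{i}", rng.choice("+-")) for i in range(na)])
    b = make_genome("B", [(f"b{i}", rng.choice("+-")) for i in range(nb)])
    edges = [
        WeightedEdge(f"a{i}", f"b{j}", round(rng.uniform(0.6, 1.0), 3))
        for i in range(na)
        for j in range(nb)
        if rng.random() < p_edge
    ]
    return a, b, edges


def independent_cycle_count(order_a, order_b):
    """Cycle count of two identically-labelled signed circular orders,
    computed with networkx connected components over extremity nodes —
    independent of the traversal in build_adjacency_graph."""
    g = nx.Graph()

    def add_genome(tag, order):
        k = len(order)
        for i in range(k):
            gene, s = order[i]
            gene_n, s_n = order[(i + 1) % k]
            right = (tag, gene, "h") if s == "+" else (tag, gene, "t")
            left_n = (tag, gene_n, "t") if s_n == "+" else (tag, gene_n, "h")
            g.add_edge(right, left_n)

    add_genome("A", order_a)
    add_genome("B", order_b)
    for gene, _ in order_a:
        g.add_edge(("A", gene, "h"), ("B", gene, "h"))
        g.add_edge(("A", gene, "t"), ("B", gene, "t"))
    return nx.number_connected_components(g)


class TestFormulate:
    def test_single_edge_component_objective(self):
        a = make_genome("A", [("a1", "+")])
        b = make_genome("B", [("b1", "+")])
        gs = build_gs_graph(a, b, [WeightedEdge("a1", "b1", 0.8)])
        for alpha in (0.0, 0.5, 1.0):
            sol = solve(formulate(gs.instance, alpha=alpha))
            assert sol.status == "optimal"
            assert sol.distance == pytest.approx((1 - alpha) * (1 - 0.8))

    def test_identical_component_distance_zero(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        sol = solve(formulate(gs.instance, alpha=0.5))
        assert sol.distance == pytest.approx(0.0)
        assert sol.stats.cycles == sol.matching.size == 3

    def test_empty_component_rejected(self, identical_pair):
        a, b, _ = identical_pair
        gs = build_gs_graph(a, b, [])
        with pytest.raises(IlpError):
            formulate(gs.instance, alpha=0.5)

    def test_alpha_out_of_range_rejected(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        with pytest.raises(IlpError):
            formulate(gs.instance, alpha=1.5)

    def test_lp_dump_contains_variables(self, identical_pair):
        a, b, edges = identical_pair
        ilp = formulate(build_gs_graph(a, b, edges).instance, alpha=0.5)
        text = ilp.to_lp_text()
        assert "Minimize" in text and "x_a1__b1" in text


class TestSolveAgainstOracle:
    def test_oracle_equivalence_quick(self):
        rng = random.Random(23)
        checked = 0
        for _ in range(40):
            a, b, edges = random_instance(rng)
            gs = build_gs_graph(a, b, edges)
            if not gs.instance.edges:
                continue
            for alpha in (0.0, 0.5, 1.0):
                d_bf, _ = brute_force_ffdcj_indel(a, b, gs, alpha)
                sol = solve(formulate(gs.instance, alpha=alpha), time_limit_s=60)
                assert sol.status == "optimal"
                assert sol.distance == pytest.approx(d_bf, abs=1e-6)
                checked += 1
        assert checked >= 60

    def test_alpha_one_reduces_to_classical_dcj(self):
        # one-to-one unit-weight instances: distance must equal |M| - c with
        # c from an independent cycle-counting implementation
        rng = random.Random(31)
        for _ in range(15):
            n = rng.randint(2, 6)
            order_a = [(f"g{i}", rng.choice("+-")) for i in range(n)]
            perm = list(range(n))
            rng.shuffle(perm)
            order_b = [(f"g{i}", rng.choice("+-")) for i in perm]
            a = make_genome("A", [(f"a{g[1:]}", s) for g, s in order_a])
            b = make_genome("B", [(f"b{g[1:]}", s) for g, s in order_b])
            gs = build_gs_graph(a, b, unit_edges([(f"a{i}", f"b{i}") for i in range(n)]))
            sol = solve(formulate(gs.instance, alpha=1.0))
            c_indep = independent_cycle_count(
                [(g[1:], s) for g, s in order_a], [(g[1:], s) for g, s in order_b]
            )
            assert sol.distance == pytest.approx(n - c_indep, abs=1e-6)

    def test_alpha_zero_maximizes_weight_among_maximum_matchings(self):
        rng = random.Random(47)
        for _ in range(10):
            a, b, edges = random_instance(rng, p_edge=0.7)
            gs = build_gs_graph(a, b, edges)
            if not gs.instance.edges:
                continue
            sol = solve(formulate(gs.instance, alpha=0.0))
            # independent route: max-weight matching with a large per-edge
            # bonus forces maximum cardinality first
            g = nx.Graph()
            for ga, gb, w in gs.instance.edges:
                g.add_edge(ga, gb, weight=w + 100.0)
            mwm = nx.max_weight_matching(g)
            best_w = sum(gs.edges[(x, y) if (x, y) in gs.edges else (y, x)] for x, y in mwm)
            assert len(mwm) == sol.matching.size
            assert sol.stats.omega == pytest.approx(best_w, abs=1e-6)

    def test_matching_cardinality_is_maximum(self):
        rng = random.Random(3)
        for _ in range(10):
            a, b, edges = random_instance(rng, p_edge=0.6)
            gs = build_gs_graph(a, b, edges)
            if not gs.instance.edges:
                continue
            sol = solve(formulate(gs.instance, alpha=0.5))
            g = nx.Graph((x, y) for x, y, _ in gs.instance.edges)
            top = {x for x, _, _ in gs.instance.edges}
            hk = nx.bipartite.hopcroft_karp_matching(g, top_nodes=top)
            assert sol.matching.size == len(hk) // 2


class TestPairwiseRefine:
    def test_identical_genomes_all_trivial(self, identical_pair):
        a, b, edges = identical_pair
        hp = pairwise_refine(a, b, edges)
        assert hp.pairs == frozenset({("a1", "b1"), ("a2", "b2"), ("a3", "b3")})
        assert set(hp.source.values()) == {"trivial"}
        assert hp.ilp_stats["n_ilp"] == 0
        assert hp.distance == pytest.approx(0.0)

    def test_isolated_gene_contributes_double_indel_penalty(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+")])
        b = make_genome("B", [("b1", "+")])
        for alpha in (0.25, 0.5, 1.0):
            hp = pairwise_refine(a, b, unit_edges([("a1", "b1")]), alpha=alpha)
            assert hp.distance == pytest.approx(2 * alpha)

    def test_synteny_beats_marginal_weight_gain(self):
        # one A-gene with two B-candidates: the lower-weight but
        # order-consistent candidate must win at alpha=0.5
        a = make_genome("A", [("a1", "+"), ("a2", "+"), ("a3", "+")])
        b = make_genome("B", [("b1", "+"), ("b2", "+"), ("b3", "+"), ("b4", "+")])
        edges = [
            WeightedEdge("a1", "b1", 1.0),
            WeightedEdge("a3", "b3", 1.0),
            WeightedEdge("a2", "b2", 0.61),
            WeightedEdge("a2", "b4", 0.62),
        ]
        hp = pairwise_refine(a, b, edges, alpha=0.5)
        assert ("a2", "b2") in hp.pairs and ("a2", "b4") not in hp.pairs

    def test_empty_edges_give_empty_pairs(self, identical_pair):
        a, b, _ = identical_pair
        hp = pairwise_refine(a, b, [])
        assert hp.pairs == frozenset()

    def test_decomposed_matches_full_instance_on_small_inputs(self):
        rng = random.Random(11)
        for _ in range(8):
            a = make_genome("A", [(f"a{i}", rng.choice("+-")) for i in range(4)])
            b = make_genome("B", [(f"b{i}", rng.choice("+-")) for i in range(4)])
            edges = [
                WeightedEdge(f"a{i}", f"b{j}", round(rng.uniform(0.6, 1.0), 3))
                for i in range(4)
                for j in range(4)
                if rng.random() < 0.4
            ]
            full = pairwise_refine(a, b, edges, decompose=False)
            dec = pairwise_refine(a, b, edges, decompose=True)
            # decomposition is exact when every component is solved optimally
            # against frozen context and components do not interact
            assert dec.distance >= full.distance - 1e-9

    def test_longer_time_limit_never_worsens_distance(self):
        rng = random.Random(13)
        a, b, edges = random_instance(rng, max_genes=5, p_edge=0.8)
        d_short = pairwise_refine(a, b, edges, time_limit_s=0.05).distance
        d_long = pairwise_refine(a, b, edges, time_limit_s=60).distance
        assert d_short >= d_long - 1e-9

    def test_deterministic_resolution(self):
        rng = random.Random(29)
        a, b, edges = random_instance(rng, max_genes=5, p_edge=0.8)
        hp1 = pairwise_refine(a, b, edges)
        hp2 = pairwise_refine(a, b, edges)
        assert hp1.pairs == hp2.pairs and hp1.distance == hp2.distance
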