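from __future__ import annotations

import random

import pytest

from panrefine.rearrangement_graphs import (
    BRUTE_FORCE_MAX_GENES,
    GraphError,
    brute_force_ffdcj_indel,
    build_adjacency_graph,
    build_gs_graph,
    evaluate_matching,
    gs_components,
    is_trivial_component,
    make_matching,
    reduce_genomes,
)
from panrefine.similarity import WeightedEdge

from conftest import make_genome, unit_edges


def full_matching(gs, pairs):
    return make_matching(gs.instance, pairs)


class TestGsGraph:
    def test_vertices_and_edges(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        assert len(gs.instance.a_genes) == 3 and len(gs.instance.b_genes) == 3
        assert len(gs.edges) == 3

    def test_isolated_gene_retained(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+")])
        b = make_genome("B", [("b1", "+")])
        gs = build_gs_graph(a, b, unit_edges([("a1", "b1")]))
        assert "a2" in gs.instance.a_genes

    def test_duplicate_edge_keeps_max_weight(self, identical_pair):
        a, b, _ = identical_pair
        gs = build_gs_graph(a, b, [WeightedEdge("a1", "b1", 0.7), WeightedEdge("a1", "b1", 0.9)])
        assert gs.edges[("a1", "b1")] == 0.9

    def test_unknown_gene_rejected(self, identical_pair):
        a, b, _ = identical_pair
        with pytest.raises(GraphError):
            build_gs_graph(a, b, [WeightedEdge("a1", "nope", 0.8)])


class TestReduceGenomes:
    def test_singleton_removed(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+"), ("a3", "+")])
        b = make_genome("B", [("b1", "+"), ("b3", "+")])
        gs = build_gs_graph(a, b, unit_edges([("a1", "b1"), ("a3", "b3")]))
        m = full_matching(gs, [("a1", "b1"), ("a3", "b3")])
        red_a, red_b = reduce_genomes(gs.instance, m)
        assert red_a == ((("a1", "+"), ("a3", "+")),)
        assert red_b == ((("b1", "+"), ("b3", "+")),)

    def test_identity_when_no_singletons(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        m = full_matching(gs, [("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        red_a, red_b = reduce_genomes(gs.instance, m)
        assert red_a == gs.instance.orders_a and red_b == gs.instance.orders_b

    def test_all_singletons_empty(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        m = full_matching(gs, [])
        assert reduce_genomes(gs.instance, m) == ((), ())


class TestAdjacencyGraph:
    def test_identical_genomes_all_fixed(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        m = full_matching(gs, [("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        ag = build_adjacency_graph(*reduce_genomes(gs.instance, m), m)
        assert ag.cycles == 3
        assert ag.fixed_components == 3

    def test_middle_inversion_gives_two_cycles(self, inverted_pair):
        a, b, edges = inverted_pair
        gs = build_gs_graph(a, b, edges)
        m = full_matching(gs, [("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        ag = build_adjacency_graph(*reduce_genomes(gs.instance, m), m)
        assert ag.cycles == 2
        assert sorted(ag.cycle_lengths) == [2, 4]

    def test_cycle_lengths_sum_to_total_adjacencies(self):
        rng = random.Random(5)
        for _ in range(20):
            n = rng.randint(1, 6)
            a = make_genome("A", [(f"a{i}", rng.choice("+-")) for i in range(n)])
            b_perm = list(range(n))
            rng.shuffle(b_perm)
            b = make_genome("B", [(f"b{i}", rng.choice("+-")) for i in b_perm])
            gs = build_gs_graph(a, b, unit_edges([(f"a{i}", f"b{i}") for i in range(n)]))
            m = full_matching(gs, [(f"a{i}", f"b{i}") for i in range(n)])
            ag = build_adjacency_graph(*reduce_genomes(gs.instance, m), m)
            assert sum(ag.cycle_lengths) == len(ag.a_adjacencies) + len(ag.b_adjacencies)
            assert ag.cycles <= m.size

    def test_single_gene_contig_self_adjacency(self):
        a = make_genome("A", [("a1", "+")])
        b = make_genome("B", [("b1", "+")])
        gs = build_gs_graph(a, b, unit_edges([("a1", "b1")]))
        m = full_matching(gs, [("a1", "b1")])
        ag = build_adjacency_graph(*reduce_genomes(gs.instance, m), m)
        assert ag.cycles == 1 and len(ag.a_adjacencies) == 1


class TestComponents:
    def test_component_split(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+")])
        b = make_genome("B", [("b1", "+"), ("b2", "+"), ("b3", "+")])
        edges = [
            WeightedEdge("a1", "b1", 0.9),
            WeightedEdge("a1", "b2", 0.8),
            WeightedEdge("a2", "b3", 0.7),
        ]
        comps = gs_components(build_gs_graph(a, b, edges))
        assert len(comps) == 2
        sizes = sorted(len(c.a_genes) + len(c.b_genes) for c in comps)
        assert sizes == [2, 3]

    def test_no_edges_all_singleton_components(self, identical_pair):
        a, b, _ = identical_pair
        comps = gs_components(build_gs_graph(a, b, []))
        assert len(comps) == 6
        assert all(c.n_edges == 0 for c in comps)

    def test_dense_bipartite_is_one_component(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+")])
        b = make_genome("B", [("b1", "+"), ("b2", "+")])
        edges = [WeightedEdge(x, y, 0.8) for x in ("a1", "a2") for y in ("b1", "b2")]
        comps = gs_components(build_gs_graph(a, b, edges))
        assert len(comps) == 1

    def test_trivial_detection(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+")])
        b = make_genome("B", [("b1", "+"), ("b2", "+")])
        edges = [
            WeightedEdge("a1", "b1", 0.9),
            WeightedEdge("a2", "b1", 0.8),
        ]
        comps = gs_components(build_gs_graph(a, b, edges))
        by_key = {c.key: c for c in comps}
        assert not is_trivial_component(by_key["a1"])  # a1,a2 share b1
        assert not is_trivial_component(by_key["b2"])  # isolated gene
        single = gs_components(build_gs_graph(a, b, [WeightedEdge("a1", "b1", 0.9)]))
        assert is_trivial_component(by_key := next(c for c in single if c.n_edges == 1))


class TestBruteForce:
    def test_identical_genomes_distance_zero(self, identical_pair):
        a, b, edges = identical_pair
        gs = build_gs_graph(a, b, edges)
        for alpha in (0.0, 0.3, 0.5, 1.0):
            d, m = brute_force_ffdcj_indel(a, b, gs, alpha)
            assert d == pytest.approx(0.0)
            assert m.size == 3

    def test_single_inversion_distance_one(self, inverted_pair):
        a, b, edges = inverted_pair
        gs = build_gs_graph(a, b, edges)
        d, _ = brute_force_ffdcj_indel(a, b, gs, alpha=1.0)
        assert d == pytest.approx(1.0)

    def test_forced_singleton_double_penalty(self):
        a = make_genome("A", [("a1", "+"), ("a2", "+"), ("a3", "+")])
        b = make_genome("B", [("b1", "+"), ("b3", "+")])
        gs = build_gs_graph(a, b, unit_edges([("a1", "b1"), ("a3", "b3")]))
        d, m = brute_force_ffdcj_indel(a, b, gs, alpha=0.5)
        assert d == pytest.approx(1.0)  # S=1, I=1, c=|M|=2 -> 0.5*(2-2+1+1)
        stats = evaluate_matching(gs.instance, m)
        assert stats.singletons == 1 and stats.blocks == 1

    def test_distance_nonnegative_on_random_instances(self):
        rng = random.Random(17)
        for _ in range(25):
            na, nb = rng.randint(1, 4), rng.randint(1, 4)
            a = make_genome("A", [(f"a{i}", rng.choice("+-")) for i in range(na)])
            b = make_genome("B", [(f"b{i}", rng.choice("+-")) for i in range(nb)])
            edges = [
                WeightedEdge(f"a{i}", f"b{j}", round(rng.uniform(0.6, 1.0), 3))
                for i in range(na)
                for j in range(nb)
                if rng.random() < 0.5
            ]
            gs = build_gs_graph(a, b, edges)
            for alpha in (0.0, 0.5, 1.0):
                d, _ = brute_force_ffdcj_indel(a, b, gs, alpha)
                assert d >= -1e-12

    def test_guard_on_large_instances(self):
        n = BRUTE_FORCE_MAX_GENES + 1
        a = make_genome("A", [(f"a{i}", "+") for i in range(n)])
        b = make_genome("B", [(f"b{i}", "+") for i in range(n)])
        gs = build_gs_graph(a, b, unit_edges([(f"a{i}", f"b{i}") for i in range(n)]))
        with pytest.raises(GraphError, match="ILP"):
            brute_force_ffdcj_indel(a, b, gs, 0.5)

    def test_simulated_operations_bound_distance(self):
        # applying k inversions never pushes the alpha=1 distance above k
        from panrefine.synthetic import SimConfig, simulate_genome_pair

        for k in (1, 2):
            for seed in (3, 4, 5):
                cfg = SimConfig(
                    genes_per_genome=6, inversions=k, default_tier=(1.0, 1.0), seed=seed
                )
                ga, gb, edges, _ = simulate_genome_pair(cfg)
                gs = build_gs_graph(ga, gb, edges)
                d, _ = brute_force_ffdcj_indel(ga, gb, gs, alpha=1.0)
                assert d <= k + 1e-9
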