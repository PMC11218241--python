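"""Gene similarity graphs, matchings, adjacency graphs and a brute-force oracle.

The pairwise comparison of two genomes A (n genes) and B (m genes) is driven
by three structures:

* the **gene similarity graph** GS(A, B): a bipartite graph whose edges carry
  normalized similarity weights sigma in (0, 1];
* a **matching** M on GS: a degree-<=1 subgraph pairing putative homologs;
  genes left unmatched are *singletons*;
* the **adjacency graph** AG(A^M, B^M) over the reduced genomes (singletons
  removed): every gene has two extremities (head = 5' end, tail = 3' end), an
  adjacency is the pair of extremities facing each other between consecutive
  genes on a circular contig, and edges link an A-adjacency with a
  B-adjacency sharing a matched extremity. With all contigs circular every
  vertex has degree two, so the graph decomposes into cycles; 2-cycles
  ("fixed components") mark locally identical gene context.

The family-free DCJ-indel distance of a matching M is

    d(M) = alpha * (|M| - c + I + S) + (1 - alpha) * (|M| - omega(M))

where c is the number of adjacency-graph cycles, S the number of singletons,
I the number of *indel blocks* (maximal runs of consecutive singletons on a
circular contig, counted per contig), and omega(M) the summed edge weights.
Indels are deliberately penalized twice (once per singleton, once per
block): penalizing only singletons overestimates indels, penalizing only
blocks lets the optimizer declare each genome one giant indel.

:func:`brute_force_ffdcj_indel` minimizes d(M) over *all* maximum-cardinality
matchings by explicit enumeration — it is the independent oracle that the
ILP in :mod:`panrefine.ffdcj_ilp` is verified against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genome_io import Genome
from .similarity import WeightedEdge

#: hard guard for the exponential oracle
BRUTE_FORCE_MAX_GENES = 8

Extremity = tuple[str, str]  # (gene_id, 'h' | 't')
SignedGene = tuple[str, str]  # (gene_id, '+' | '-')


class GraphError(ValueError):
    pass


def left_extremity(gene_id: str, strand: str) -> Extremity:
    """Extremity exposed on the lower-coordinate side of the gene.

    A '+' gene is traversed tail->head, so its tail faces the previous gene;
    a '-' gene exposes its head on the left.
    """
    return (gene_id, "t") if strand == "+" else (gene_id, "h")


def right_extremity(gene_id: str, strand: str) -> Extremity:
    return (gene_id, "h") if strand == "+" else (gene_id, "t")


@dataclass(frozen=True)
class RearrangementInstance:
    """Circular gene orders of two genomes plus their similarity edges.

    ``orders_a``/``orders_b`` hold one ``[(gene_id, strand), ...]`` list per
    contig; all contigs are circular. Used both for full genome pairs and for
    component sub-instances (where the order is the full order restricted to
    component genes, i.e. outside context contracted away).
    """

    orders_a: tuple[tuple[SignedGene, ...], ...]
    orders_b: tuple[tuple[SignedGene, ...], ...]
    edges: tuple[tuple[str, str, float], ...]  # (gene_a, gene_b, weight), deduped

    @property
    def a_genes(self) -> list[str]:
        return [g for contig in self.orders_a for g, _ in contig]

    @property
    def b_genes(self) -> list[str]:
        return [g for contig in self.orders_b for g, _ in contig]

    @property
    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {(a, b): w for a, b, w in self.edges}

    def restrict(self, genes: set[str]) -> "RearrangementInstance":
        """Sub-instance over ``genes``; non-member genes are contracted out
        of the circular orders (their matched context is frozen)."""
        return RearrangementInstance(
            orders_a=tuple(
                t
                for t in (tuple(sg for sg in contig if sg[0] in genes) for contig in self.orders_a)
                if t
            ),
            orders_b=tuple(
                t
                for t in (tuple(sg for sg in contig if sg[0] in genes) for contig in self.orders_b)
                if t
            ),
            edges=tuple((a, b, w) for a, b, w in self.edges if a in genes and b in genes),
        )


def genome_orders(genome: Genome) -> tuple[tuple[SignedGene, ...], ...]:
    return tuple(
        tuple((g.gene_id, g.strand) for g in genome.contigs[cid]) for cid in genome.contigs
    )


def instance_from_genomes(
    genome_a: Genome, genome_b: Genome, edges: Iterable[WeightedEdge]
) -> RearrangementInstance:
    known_a, known_b = set(genome_a.gene_ids()), set(genome_b.gene_ids())
    dedup: dict[tuple[str, str], float] = {}
    for e in edges:
        a, b = e.gene_a, e.gene_b
        if a in known_b and b in known_a:  # edge given in (b, a) orientation
            a, b = b, a
        if a not in known_a or b not in known_b:
            raise GraphError(f"edge ({e.gene_a!r}, {e.gene_b!r}) references unknown gene")
        key = (a, b)
        dedup[key] = max(dedup.get(key, 0.0), e.weight)
    return RearrangementInstance(
        orders_a=genome_orders(genome_a),
        orders_b=genome_orders(genome_b),
        edges=tuple(sorted((a, b, w) for (a, b), w in dedup.items())),
    )


@dataclass
class GeneSimilarityGraph:
    """Bipartite similarity graph GS(A, B); isolated genes are retained."""

    genome_a: Genome
    genome_b: Genome
    instance: RearrangementInstance

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        return self.instance.edge_weights


def build_gs_graph(
    genome_a: Genome, genome_b: Genome, weighted_edges: Iterable[WeightedEdge]
) -> GeneSimilarityGraph:
    """Assemble GS(A, B). Duplicate edges keep the max weight; edges must
    reference genes of the two genomes (either orientation)."""
    inst = instance_from_genomes(genome_a, genome_b, weighted_edges)
    return GeneSimilarityGraph(genome_a=genome_a, genome_b=genome_b, instance=inst)


@dataclass
class Matching:
    """A degree-<=1 pairing of genes across the two genomes."""

    pairs: frozenset[tuple[str, str]]
    unmatched_a: frozenset[str]
    unmatched_b: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.pairs)

    def weight(self, edge_weights: Mapping[tuple[str, str], float]) -> float:
        return sum(edge_weights[p] for p in self.pairs)


def make_matching(instance: RearrangementInstance, pairs: Iterable[tuple[str, str]]) -> Matching:
    pairs = frozenset(pairs)
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    weights = instance.edge_weights
    for a, b in pairs:
        if (a, b) not in weights:
            raise GraphError(f"pair ({a!r}, {b!r}) is not a similarity edge")
        if a in seen_a or b in seen_b:
            raise GraphError(f"gene matched twice in pair ({a!r}, {b!r})")
        seen_a.add(a)
        seen_b.add(b)
    return Matching(
        pairs=pairs,
        unmatched_a=frozenset(g for g in instance.a_genes if g not in seen_a),
        unmatched_b=frozenset(g for g in instance.b_genes if g not in seen_b),
    )


def reduce_genomes(
    instance: RearrangementInstance, matching: Matching
) -> tuple[tuple[tuple[SignedGene, ...], ...], tuple[tuple[SignedGene, ...], ...]]:
    """Remove singletons, preserving circular order per contig (A^M, B^M)."""
    matched = {a for a, _ in matching.pairs} | {b for _, b in matching.pairs}
    red_a = tuple(
        t
        for t in (tuple(sg for sg in contig if sg[0] in matched) for contig in instance.orders_a)
        if t
    )
    red_b = tuple(
        t
        for t in (tuple(sg for sg in contig if sg[0] in matched) for contig in instance.orders_b)
        if t
    )
    return red_a, red_b


def _adjacencies(orders: Sequence[Sequence[SignedGene]]) -> list[tuple[Extremity, Extremity]]:
    """One adjacency per consecutive gene pair on each circular contig.

    A single-gene contig yields the self-adjacency (head, tail) of its gene.
    """
    adjacencies: list[tuple[Extremity, Extremity]] = []
    for contig in orders:
        k = len(contig)
        for i in range(k):
            g, s = contig[i]
            gn, sn = contig[(i + 1) % k]
            adjacencies.append((right_extremity(g, s), left_extremity(gn, sn)))
    return adjacencies


@dataclass
class AdjacencyGraph:
    """AG(A^M, B^M): adjacencies of both reduced genomes, linked through the
    matching, decomposed into cycles."""

    a_adjacencies: list[tuple[Extremity, Extremity]]
    b_adjacencies: list[tuple[Extremity, Extremity]]
    cycles: int
    cycle_lengths: list[int] = field(default_factory=list)

    @property
    def fixed_components(self) -> int:
        return sum(1 for length in self.cycle_lengths if length == 2)


def build_adjacency_graph(
    reduced_a: Sequence[Sequence[SignedGene]],
    reduced_b: Sequence[Sequence[SignedGene]],
    matching: Matching,
) -> AdjacencyGraph:
    """Build AG over reduced genomes and count its cycles by traversal.

    All reduced genes must be matched. Cycle length is counted in
    adjacency-graph edges (= matched-extremity links), so a fixed component
    has length 2.
    """
    adj_a = _adjacencies(reduced_a)
    adj_b = _adjacencies(reduced_b)

    match_map: dict[Extremity, Extremity] = {}
    for a, b in matching.pairs:
        match_map[(a, "h")] = (b, "h")
        match_map[(b, "h")] = (a, "h")
        match_map[(a, "t")] = (b, "t")
        match_map[(b, "t")] = (a, "t")

    adj_map: dict[Extremity, Extremity] = {}
    for x, y in adj_a + adj_b:
        adj_map[x] = y
        adj_map[y] = x

    for ext in adj_map:
        if ext not in match_map:
            raise GraphError(f"reduced genomes contain unmatched gene {ext[0]!r}")

    unvisited = set(adj_map)
    cycles = 0
    lengths: list[int] = []
    while unvisited:
        start = min(unvisited)
        e = start
        steps = 0
        while True:
            unvisited.discard(e)
            m = match_map[e]
            unvisited.discard(m)
            steps += 1
            e = adj_map[m]
            if e == start:
                break
        cycles += 1
        lengths.append(steps)
    return AdjacencyGraph(a_adjacencies=adj_a, b_adjacencies=adj_b, cycles=cycles, cycle_lengths=sorted(lengths))


def _count_blocks(orders: Sequence[Sequence[SignedGene]], singletons: set[str]) -> int:
    """Number of maximal runs of consecutive singletons, per circular contig.

    An all-singleton contig is one single wrap-around block.
    """
    blocks = 0
    for contig in orders:
        flags = [g in singletons for g, _ in contig]
        if all(flags):
            blocks += 1
            continue
        k = len(contig)
        blocks += sum(1 for i in range(k) if flags[i] and not flags[(i + 1) % k])
    return blocks


@dataclass(frozen=True)
class MatchingStats:
    """All Eq.-ingredients of one matching, plus the distance evaluator."""

    size: int  # |M|
    cycles: int  # c
    omega: float  # summed matched-edge weights
    singletons: int  # S
    blocks: int  # I
    fixed_components: int

    def distance(self, alpha: float, indel: bool = True) -> float:
        rearr = self.size - self.cycles
        if indel:
            rearr += self.blocks + self.singletons
        return alpha * rearr + (1.0 - alpha) * (self.size - self.omega)


def evaluate_matching(instance: RearrangementInstance, matching: Matching) -> MatchingStats:
    """Independently recompute |M|, c, omega, S and I for a matching."""
    red_a, red_b = reduce_genomes(instance, matching)
    if matching.size == 0:
        cycles, lengths = 0, []
    else:
        ag = build_adjacency_graph(red_a, red_b, matching)
        cycles, lengths = ag.cycles, ag.cycle_lengths
    singles = set(matching.unmatched_a) | set(matching.unmatched_b)
    blocks = _count_blocks(instance.orders_a, singles) + _count_blocks(instance.orders_b, singles)
    return MatchingStats(
        size=matching.size,
        cycles=cycles,
        omega=matching.weight(instance.edge_weights),
        singletons=len(singles),
        blocks=blocks,
        fixed_components=sum(1 for length in lengths if length == 2),
    )


@dataclass
class Component:
    """A connected component of the similarity graph, as a sub-instance.

    The sub-instance's circular orders are the parent orders restricted to
    component genes: adjacencies to genes outside the component are
    contracted, freezing the surrounding matched context.
    """

    a_genes: tuple[str, ...]
    b_genes: tuple[str, ...]
    instance: RearrangementInstance

    @property
    def n_edges(self) -> int:
        return len(self.instance.edges)

    @property
    def key(self) -> str:
        return min(self.a_genes + self.b_genes)


def gs_components(gs_graph: GeneSimilarityGraph) -> list[Component]:
    """Split GS(A, B) into connected components (isolated genes included as
    singleton components). Deterministic order by smallest member gene id."""
    inst = gs_graph.instance
    graph = nx.Graph()
    graph.add_nodes_from(inst.a_genes)
    graph.add_nodes_from(inst.b_genes)
    graph.add_edges_from((a, b) for a, b, _ in inst.edges)
    comps = []
    for nodes in nx.connected_components(graph):
        sub = inst.restrict(set(nodes))
        comps.append(
            Component(
                a_genes=tuple(g for g in sub.a_genes),
                b_genes=tuple(g for g in sub.b_genes),
                instance=sub,
            )
        )
    return sorted(comps, key=lambda c: c.key)


def is_trivial_component(component: Component) -> bool:
    """True iff the component is one gene of A linked to one gene of B by a
    single edge — a direct one-to-one mapping needing no optimization.
    Isolated genes are forced singletons, not trivial mappings."""
    return (
        len(component.a_genes) == 1
        and len(component.b_genes) == 1
        and component.n_edges == 1
    )


def max_matching_size(instance: RearrangementInstance) -> int:
    """Maximum-cardinality bipartite matching size (Hopcroft-Karp)."""
    if not instance.edges:
        return 0
    graph = nx.Graph()
    a_nodes = {a for a, _, _ in instance.edges}
    graph.add_nodes_from(a_nodes, bipartite=0)
    graph.add_nodes_from({b for _, b, _ in instance.edges}, bipartite=1)
    graph.add_edges_from((a, b) for a, b, _ in instance.edges)
    matching = nx.bipartite.hopcroft_karp_matching(graph, top_nodes=a_nodes)
    return len(matching) // 2


def enumerate_maximum_matchings(instance: RearrangementInstance) -> Iterable[Matching]:
    """Yield every maximum-cardinality matching of the similarity graph."""
    target = max_matching_size(instance)
    nbrs: dict[str, list[str]] = {}
    for a, b, _ in instance.edges:
        nbrs.setdefault(a, []).append(b)
    a_list = sorted(nbrs)
    for a in a_list:
        nbrs[a].sort()

    def rec(i: int, used_b: set[str], current: list[tuple[str, str]]):
        if len(current) + (len(a_list) - i) < target:
            return
        if i == len(a_list):
            if len(current) == target:
                yield make_matching(instance, current)
            return
        a = a_list[i]
        yield from rec(i + 1, used_b, current)  # a stays singleton
        for b in nbrs[a]:
            if b not in used_b:
                used_b.add(b)
                current.append((a, b))
                yield from rec(i + 1, used_b, current)
                current.pop()
                used_b.remove(b)

    yield from rec(0, set(), [])


def brute_force_ffdcj_indel(
    genome_a: Genome,
    genome_b: Genome,
    gs_graph: GeneSimilarityGraph | None = None,
    alpha: float = 0.5,
    indel: bool = True,
    instance: RearrangementInstance | None = None,
) -> tuple[float, Matching]:
    """Exact family-free DCJ(-indel) distance by exhaustive enumeration.

    Considers every maximum-cardinality matching, evaluates the distance via
    :func:`evaluate_matching`, and returns the minimum. Ties are broken by
    larger omega(M), then by lexicographically smallest pair set. Guarded to
    at most ``BRUTE_FORCE_MAX_GENES`` genes per genome; larger instances must
    go through the ILP.
    """
    if instance is None:
        if gs_graph is None:
            gs_graph = build_gs_graph(genome_a, genome_b, [])
        instance = gs_graph.instance
    if len(instance.a_genes) > BRUTE_FORCE_MAX_GENES or len(instance.b_genes) > BRUTE_FORCE_MAX_GENES:
        raise GraphError(
            f"brute force guarded to <= {BRUTE_FORCE_MAX_GENES} genes per genome; "
            "use the ILP for larger instances"
        )
    best: tuple[float, float, tuple] | None = None
    best_matching: Matching | None = None
    for m in enumerate_maximum_matchings(instance):
        stats = evaluate_matching(instance, m)
        d = stats.distance(alpha, indel=indel)
        key = (round(d, 12), -stats.omega, tuple(sorted(m.pairs)))
        if best is None or key < best:
            best = key
            best_matching = m
    assert best is not None and best_matching is not None  # empty matching always enumerated
    return best[0], best_matching


def adjacency_graph_dot(ag: AdjacencyGraph) -> str:
    """DOT-format dump of an adjacency graph, for debugging."""

    def fmt(adj: tuple[Extremity, Extremity]) -> str:
        (g1, e1), (g2, e2) = adj
        return f"{g1}{e1}|{g2}{e2}"

    lines = ["graph AG {"]
    for side, adjs in (("A", ag.a_adjacencies), ("B", ag.b_adjacencies)):
        for adj in adjs:
            lines.append(f'  "{side}:{fmt(adj)}";')
    lines.append("}")
    return "\n".join(lines)
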