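from __future__ import annotations

import pytest

from panrefine.genome_io import GeneFeature, Genome
from panrefine.similarity import WeightedEdge


def make_genome(genome_id: str, order, contig: str = "c1") -> Genome:
    """Build a one-contig circular genome from [(gene_id, strand), ...]."""
    genes = [
        GeneFeature(
            gene_id=gid,
            genome_id=genome_id,
            contig_id=contig,
            start=100 * i + 1,
            end=100 * i + 90,
            strand=strand,
        )
        for i, (gid, strand) in enumerate(order)
    ]
    return Genome(genome_id=genome_id, contigs={contig: genes})


def unit_edges(pairs) -> list[WeightedEdge]:
    return [WeightedEdge(a, b, 1.0) for a, b in pairs]


@pytest.fixture
def identical_pair():
    """Two genomes with identical circular gene order and 1:1 unit edges."""
    a = make_genome("A", [("a1", "+"), ("a2", "+"), ("a3", "+")])
    b = make_genome("B", [("b1", "+"), ("b2", "+"), ("b3", "+")])
    edges = unit_edges([("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
    return a, b, edges


@pytest.fixture
def inverted_pair():
    """Same as identical_pair but with the middle gene of B inverted."""
    a = make_genome("A", [("a1", "+"), ("a2", "+"), ("a3", "+")])
    b = make_genome("B", [("b1", "+"), ("b2", "-"), ("b3", "+")])
    edges = unit_edges([("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
    return a, b, edges
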