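"""High-stringency scaffold clusters and lower-threshold annotation clusterings.

The scaffold partition plays the role of an external pangenome clustering at
95% sequence similarity: single-linkage connected components over normalized
similarity edges at or above the threshold. Lowering the threshold can only
merge, never split, clusters (single-linkage nesting), which is what makes
the 60/70/80/90% clusterings useful purely as annotation columns — only the
0.95 clustering (or an external cluster file) feeds the group computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .genome_io import ScaffoldClusters
from .similarity import WeightedEdge

DEFAULT_SCAFFOLD_THRESHOLD = 0.95
ANNOTATION_THRESHOLDS = (0.60, 0.70, 0.80, 0.90, 0.95)


class ClusteringError(ValueError):
    pass


@dataclass
class ThresholdClusterings:
    """Clusterings at 0.60/0.70/0.80/0.90/0.95, for output annotation only."""

    by_threshold: dict[float, ScaffoldClusters]

    def __getitem__(self, threshold: float) -> ScaffoldClusters:
        return self.by_threshold[threshold]

    @property
    def thresholds(self) -> list[float]:
        return sorted(self.by_threshold)


def cluster_genes(
    weighted_edges: Iterable[WeightedEdge],
    threshold: float = DEFAULT_SCAFFOLD_THRESHOLD,
    all_genes: Sequence[str] | None = None,
) -> ScaffoldClusters:
    """Single-linkage clusters over edges with weight >= threshold.

    ``all_genes`` lists the full gene universe so that genes without strong
    edges still appear, as singleton clusters. Cluster ids are deterministic:
    named after the lexicographically smallest member gene.
    """
    if not 0.0 < threshold <= 1.0:
        raise ClusteringError(f"threshold must lie in (0,1], got {threshold}")
    graph = nx.Graph()
    if all_genes:
        graph.add_nodes_from(all_genes)
    for e in weighted_edges:
        graph.add_node(e.gene_a)
        graph.add_node(e.gene_b)
        if e.weight >= threshold:
            graph.add_edge(e.gene_a, e.gene_b)
    clusters = {min(comp): set(comp) for comp in nx.connected_components(graph)}
    return ScaffoldClusters(clusters=clusters, provenance="internal", threshold=threshold)


def multi_threshold_annotation(
    weighted_edges: Iterable[WeightedEdge],
    all_genes: Sequence[str] | None = None,
    thresholds: Sequence[float] = ANNOTATION_THRESHOLDS,
) -> ThresholdClusterings:
    """Clusterings at every annotation threshold (nested by construction)."""
    edges = list(weighted_edges)
    return ThresholdClusterings(
        by_threshold={t: cluster_genes(edges, t, all_genes) for t in thresholds}
    )


def write_threshold_clusters(clusterings: ThresholdClusterings, out_dir: str | Path) -> list[Path]:
    """One TSV per threshold: cluster_id <TAB> comma-joined member genes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in clusterings.thresholds:
        path = out_dir / f"clusters_{int(round(t * 100))}.tsv"
        with open(path, "w") as fh:
            fh.write("cluster_id\tgenes\n")
            for cid in sorted(clusterings[t].clusters):
                fh.write(f"{cid}\t{','.join(sorted(clusterings[t].clusters[cid]))}\n")
        paths.append(path)
    return paths
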