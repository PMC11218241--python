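"""Merging scaffold clusters with pairwise homology into pan-genome groups.

Scaffold clusters (high-stringency, 95%) are treated as pre-grouped genes;
every homolog pair whose genes fall into different clusters merges those
clusters (union-find), so synteny-supported homologs of lower sequence
similarity end up in one group. Genomes contributing two or more genes to a
merged group mark paralogs: one representative per genome is kept in the
parent group, chosen by a tie-breaking ladder —

1. most homology-pair connections into the rest of the group,
2. largest originating scaffold cluster,
3. gene name matching the majority name in the group (placeholder names
   such as "hypothetical protein" carry no evidence and are ignored),
4. lexicographically smallest gene id (determinism fallback).

The remaining paralogs seed subgroups (ids ``groupN.1``, ``groupN.2``, ...):
leftover genes connected to each other by homology pairs stay together, and
subgroups are re-resolved recursively when several genomes carry paralogs.

A group is *core* when it covers at least ``ceil(core_perc / 100 * n)`` of
the ``n`` input genomes (default 100%: present in every genome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .genome_io import GeneFeature, Genome, ScaffoldClusters, write_group_outputs, write_manifest
from .ffdcj_ilp import HomologyPairs
from .scaffold_clustering import ThresholdClusterings, write_threshold_clusters

PLACEHOLDER_NAMES = {"hypothetical protein", "hypothetical", "", None}


class GroupingError(ValueError):
    pass


@dataclass
class PanGroup:
    """One refined group: at most one member gene per genome."""

    group_id: str
    members: dict[str, str]  # genome_id -> gene_id
    parent: str | None = None
    provenance: set[str] = field(default_factory=set)
    core: bool = False
    representative_name: str | None = None
    representative_product: str | None = None

    @property
    def is_subgroup(self) -> bool:
        return self.parent is not None


@dataclass
class GroupTable:
    groups: list[PanGroup]
    genomes: list[str]
    core_perc: float = 100.0
    threshold_annotation: dict[float, dict[str, int]] = field(default_factory=dict)
    gene_lookup: dict[str, GeneFeature] | None = None

    @property
    def presence(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group_id": g.group_id, **{gid: int(gid in g.members) for gid in self.genomes}}
                for g in self.groups
            ]
        ).set_index("group_id")

    @property
    def core_groups(self) -> list[PanGroup]:
        return [g for g in self.groups if g.core]


def _pair_set(all_pairs: Iterable[HomologyPairs]) -> set[frozenset[str]]:
    return {frozenset(p) for hp in all_pairs for p in hp.pairs}


def merge_clusters(
    scaffold: ScaffoldClusters,
    all_homology_pairs: Iterable[HomologyPairs],
    all_genes: Sequence[str],
) -> list[set[str]]:
    """Union-find merge of scaffold clusters through homology pairs.

    Genes absent from every cluster join through their pairs or stay as
    singleton groups. Returns preliminary groups (gene-id sets), sorted by
    smallest member.
    """
    uf = nx.utils.UnionFind(all_genes)
    for members in scaffold.clusters.values():
        members = sorted(members)
        for g in members[1:]:
            uf.union(members[0], g)
    for pair in sorted(_pair_set(all_homology_pairs), key=sorted):
        a, b = sorted(pair)
        uf.union(a, b)
    groups = [set(s) for s in uf.to_sets()]
    return sorted(groups, key=min)


def _majority_name(names: Iterable[str | None]) -> str | None:
    counts: dict[str, int] = {}
    for n in names:
        if n in PLACEHOLDER_NAMES:
            continue
        counts[n] = counts.get(n, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    winners = sorted(n for n, c in counts.items() if c == best)
    return winners[0] if len(winners) == 1 else None


def _pick_representative(
    candidates: Sequence[str],
    group_rest: set[str],
    pairs: set[frozenset[str]],
    cluster_of: Mapping[str, str],
    cluster_sizes: Mapping[str, int],
    gene_names: Mapping[str, str | None],
) -> str:
    """Tie-breaking ladder for one genome's paralog set."""
    conn = {
        g: sum(1 for m in group_rest if frozenset((g, m)) in pairs) for g in candidates
    }
    best = max(conn.values())
    shortlist = sorted(g for g in candidates if conn[g] == best)
    if len(shortlist) == 1:
        return shortlist[0]

    size = {g: cluster_sizes.get(cluster_of.get(g, ""), 1) for g in shortlist}
    best = max(size.values())
    shortlist = sorted(g for g in shortlist if size[g] == best)
    if len(shortlist) == 1:
        return shortlist[0]

    majority = _majority_name(gene_names.get(m) for m in group_rest)
    if majority is not None:
        named = [g for g in shortlist if gene_names.get(g) == majority]
        if len(named) == 1:
            return named[0]
    return shortlist[0]


def resolve_paralogs(
    members: set[str],
    pairs: set[frozenset[str]],
    gene_genome: Mapping[str, str],
    cluster_of: Mapping[str, str],
    cluster_sizes: Mapping[str, int],
    gene_names: Mapping[str, str | None],
) -> list[set[str]]:
    """Split a preliminary group into a parent plus paralog subgroups.

    Returns member sets; the first is the parent (<=1 gene per genome), the
    rest are subgroups in deterministic order. Each genome with k paralogs
    contributes k-1 leftover genes; leftovers connected by homology pairs
    form one subgroup together and are re-resolved recursively.
    """
    by_genome: dict[str, list[str]] = {}
    for g in sorted(members):
        by_genome.setdefault(gene_genome[g], []).append(g)
    paralog_genomes = sorted(gid for gid, lst in by_genome.items() if len(lst) > 1)
    if not paralog_genomes:
        return [set(members)]

    kept = set(members)
    leftovers: list[str] = []
    for gid in paralog_genomes:
        candidates = by_genome[gid]
        rest = kept - set(candidates)
        rep = _pick_representative(candidates, rest, pairs, cluster_of, cluster_sizes, gene_names)
        for g in candidates:
            if g != rep:
                kept.discard(g)
                leftovers.append(g)

    graph = nx.Graph()
    graph.add_nodes_from(leftovers)
    leftover_set = set(leftovers)
    for pair in pairs:
        a, b = sorted(pair)
        if a in leftover_set and b in leftover_set:
            graph.add_edge(a, b)
    result = [kept]
    for comp in sorted(nx.connected_components(graph), key=min):
        result.extend(
            resolve_paralogs(set(comp), pairs, gene_genome, cluster_of, cluster_sizes, gene_names)
        )
    return result


def build_group_table(
    genomes: Sequence[Genome],
    scaffold: ScaffoldClusters,
    all_homology_pairs: Iterable[HomologyPairs],
    core_perc: float = 100.0,
    threshold_clusterings: ThresholdClusterings | None = None,
) -> GroupTable:
    """Full grouping pass: merge, resolve paralogs, number groups, flag core.

    Group ids are assigned by sorting top-level groups by their smallest
    member gene id, so identical inputs always yield identical ids
    regardless of genome or cluster file order.
    """
    if not 0.0 < core_perc <= 100.0:
        raise GroupingError(f"core_perc must lie in (0,100], got {core_perc}")
    all_pairs = list(all_homology_pairs)
    pairs = _pair_set(all_pairs)
    gene_genome: dict[str, str] = {}
    gene_lookup: dict[str, GeneFeature] = {}
    for genome in genomes:
        for gene in genome.genes():
            gene_genome[gene.gene_id] = genome.genome_id
            gene_lookup[gene.gene_id] = gene
    gene_names = {g: f.gene_name for g, f in gene_lookup.items()}

    cluster_of = scaffold.cluster_of()
    cluster_sizes = {cid: len(m) for cid, m in scaffold.clusters.items()}

    preliminary = merge_clusters(scaffold, all_pairs, sorted(gene_genome))

    genome_ids = [g.genome_id for g in genomes]
    groups: list[PanGroup] = []
    resolved: list[tuple[set[str], list[set[str]]]] = []
    for members in preliminary:
        parts = resolve_paralogs(
            members, pairs, gene_genome, cluster_of, cluster_sizes, gene_names
        )
        resolved.append((members, parts))
    resolved.sort(key=lambda t: min(t[1][0]) if t[1][0] else min(t[0]))

    n_genomes = len(genome_ids)
    needed = math.ceil(core_perc / 100.0 * n_genomes)
    for idx, (_members, parts) in enumerate(resolved, start=1):
        parent_id = f"group{idx}"
        for k, part in enumerate(parts):
            gid = parent_id if k == 0 else f"{parent_id}.{k}"
            member_map = {gene_genome[g]: g for g in sorted(part)}
            name_counts = [gene_names.get(g) for g in sorted(part)]
            grp = PanGroup(
                group_id=gid,
                members=member_map,
                parent=None if k == 0 else parent_id,
                provenance={cluster_of[g] for g in part if g in cluster_of},
                representative_name=_majority_name(name_counts)
                or next((n for n in name_counts if n), None),
                representative_product=next(
                    (gene_lookup[g].product for g in sorted(part) if gene_lookup[g].product), None
                ),
            )
            grp.core = len(grp.members) >= needed
            groups.append(grp)

    annotation: dict[float, dict[str, int]] = {}
    if threshold_clusterings is not None:
        for t in threshold_clusterings.thresholds:
            c_of = threshold_clusterings[t].cluster_of()
            annotation[t] = {
                g.group_id: len({c_of[m] for m in g.members.values() if m in c_of})
                for g in groups
            }

    return GroupTable(
        groups=groups,
        genomes=genome_ids,
        core_perc=core_perc,
        threshold_annotation=annotation,
        gene_lookup=gene_lookup,
    )


def extract_core(group_table: GroupTable, core_perc: float = 100.0) -> list[PanGroup]:
    """Groups covering at least ceil(core_perc/100 * n_genomes) genomes."""
    if not 0.0 < core_perc <= 100.0:
        raise GroupingError(f"core_perc must lie in (0,100], got {core_perc}")
    needed = math.ceil(core_perc / 100.0 * len(group_table.genomes))
    return [g for g in group_table.groups if len(g.members) >= needed]


def summarize(
    group_table: GroupTable,
    out_dir: str | Path,
    threshold_clusterings: ThresholdClusterings | None = None,
    pocp_matrix: pd.DataFrame | None = None,
    params: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the output bundle: group TSV, presence/absence, per-group FASTA,
    per-threshold cluster TSVs, POCP matrix and a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_group_outputs(group_table, out_dir)
    if threshold_clusterings is not None:
        for p in write_threshold_clusters(threshold_clusterings, out_dir / "clusters"):
            paths[p.stem] = p
    if pocp_matrix is not None:
        pocp_path = out_dir / "pocp_matrix.tsv"
        pocp_matrix.round(2).to_csv(pocp_path, sep="\t", float_format="%.2f")
        paths["pocp"] = pocp_path
    manifest = {
        "n_genomes": len(group_table.genomes),
        "n_groups": len(group_table.groups),
        "n_core": len(group_table.core_groups),
        "core_perc": group_table.core_perc,
    }
    if params:
        manifest.update(params)
    manifest_path = out_dir / "manifest.json"
    write_manifest(manifest_path, manifest)
    paths["manifest"] = manifest_path
    return paths
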