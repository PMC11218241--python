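"""Seeded synthetic genomes with known rearrangements and truth orthology.

Two generators cover the two scales the package is tested at:

* :func:`simulate_genome_pair` — genome B is derived from genome A by a
  configured number of inversions, transpositions, deletions, insertions and
  duplications, with similarity weights drawn per true ortholog pair from a
  divergence tier and decoy edges kept below the matching threshold. This
  exercises the rearrangement machinery with a known operation count.

* :func:`simulate_pangenome` — an ancestral family pool is propagated into
  several genomes (core families everywhere, accessory families at random),
  with per-family divergence tiers controlling whether high-stringency
  scaffold clustering keeps a family together or splits it. This exercises
  clustering, merging and core extraction end to end.

Two fidelity levels exist: weights can be emitted directly (fast unit
tests), or gene sequences can be realized as mutated copies of an ancestral
sequence and run through the internal aligner (end-to-end tests). Everything
is deterministic under ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GeneFeature, Genome, HitRecord, write_hit_table
from .similarity import WeightedEdge

_DNA = np.array(list("ACGT"))
#: uniform alignment span (bp) used when emitting tabular hits from weights
_HIT_SPAN = 900


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_genomes: int = 5
    genes_per_genome: int = 20
    core_fraction: float = 0.9
    accessory_presence: float = 0.5
    inversions: int = 0
    transpositions: int = 0
    deletions: int = 0
    insertions: int = 0
    duplications: int = 0
    #: weight range for ortholog pairs of an average family
    default_tier: tuple[float, float] = (0.96, 1.0)
    #: per-family weight ranges overriding the default (e.g. a diverged family)
    tier_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: decoy (non-ortholog) edges per genome pair, weights in [0.2, 0.55]
    decoy_edges: int = 0
    sequences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "genes_per_genome", "inversions", "transpositions",
                     "deletions", "insertions", "duplications", "decoy_edges"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise SimulationError("core_fraction must lie in [0,1]")
        for lo, hi in [self.default_tier, *self.tier_overrides.values()]:
            if not 0.0 <= lo <= hi <= 1.0:
                raise SimulationError(f"divergence tier ({lo},{hi}) outside [0,1]")
        if self.deletions > self.genes_per_genome:
            raise SimulationError("cannot delete more genes than the genome holds")


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated data."""

    pairs: dict[tuple[str, str], frozenset[tuple[str, str]]]
    families: dict[str, tuple[str, ...]]
    operations: list[str] = field(default_factory=list)

    def pairs_for(self, genome_a: str, genome_b: str) -> frozenset[tuple[str, str]]:
        if (genome_a, genome_b) in self.pairs:
            return self.pairs[(genome_a, genome_b)]
        return frozenset((b, a) for a, b in self.pairs.get((genome_b, genome_a), frozenset()))


def _build_genome(genome_id: str, order: Sequence[tuple[str, str]], sequences=None) -> Genome:
    genes = []
    for i, (gene_id, strand) in enumerate(order):
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id="chr",
                start=1000 * i + 1,
                end=1000 * i + _HIT_SPAN,
                strand=strand,
                gene_name=gene_id.split("|")[-1] if "|" in gene_id else None,
                sequence=None if sequences is None else sequences.get(gene_id),
            )
        )
    return Genome(genome_id=genome_id, contigs={"chr": genes})


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    arr[hit] = _DNA[rng.integers(0, 4, hit.sum())]
    return "".join(arr)


def _apply_inversion(order: list, rng: np.random.Generator) -> str:
    k = len(order)
    if k < 2:
        return "inversion[noop]"
    i = int(rng.integers(0, k))
    length = int(rng.integers(2, max(3, k // 2 + 1)))
    j = min(i + length, k)
    seg = [(g, "-" if s == "+" else "+") for g, s in reversed(order[i:j])]
    order[i:j] = seg
    return f"inversion[{i}:{j}]"


def _apply_transposition(order: list, rng: np.random.Generator) -> str:
    k = len(order)
    if k < 3:
        return "transposition[noop]"
    i = int(rng.integers(0, k - 1))
    length = int(rng.integers(1, max(2, k // 3 + 1)))
    j = min(i + length, k)
    seg = order[i:j]
    del order[i:j]
    pos = int(rng.integers(0, len(order) + 1))
    if pos == i:  # reinsertion at the excision point would be a no-op
        pos = (i + 1) % (len(order) + 1)
    order[pos:pos] = seg
    return f"transposition[{i}:{j}]->{pos}"


def simulate_genome_pair(config: SimConfig) -> tuple[Genome, Genome, list[WeightedEdge], TruthSet]:
    """Derive genome B from genome A by seeded rearrangement operations.

    Returns both genomes, the similarity edges (true-pair weights from the
    divergence tier, decoys in [0.2, 0.55]) and the truth set. With
    ``config.sequences`` the genes additionally carry mutated DNA sequences.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genes_per_genome
    a_order = [(f"A_g{i:03d}", "+" if rng.random() < 0.7 else "-") for i in range(n)]
    partner = {f"A_g{i:03d}": f"B_g{i:03d}" for i in range(n)}
    b_order = [(partner[g], s) for g, s in a_order]
    ops: list[str] = []

    for _ in range(config.inversions):
        ops.append(_apply_inversion(b_order, rng))
    for _ in range(config.transpositions):
        ops.append(_apply_transposition(b_order, rng))
    for _ in range(config.deletions):
        idx = int(rng.integers(0, len(b_order)))
        ops.append(f"deletion[{b_order[idx][0]}]")
        del b_order[idx]
    for k in range(config.insertions):
        pos = int(rng.integers(0, len(b_order) + 1))
        b_order.insert(pos, (f"B_ins{k:03d}", "+" if rng.random() < 0.5 else "-"))
        ops.append(f"insertion[B_ins{k:03d}]")
    dup_edges: list[tuple[str, str]] = []
    for k in range(config.duplications):
        idx = int(rng.integers(0, len(b_order)))
        src, strand = b_order[idx]
        dup_id = f"{src}_d{k}"
        pos = int(rng.integers(0, len(b_order) + 1))
        b_order.insert(pos, (dup_id, strand))
        ops.append(f"duplication[{src}->{dup_id}]")
        for a_gene, b_gene in partner.items():
            if b_gene == src:
                dup_edges.append((a_gene, dup_id))

    present_b = {g for g, _ in b_order}
    true_pairs = frozenset(
        (a, b) for a, b in partner.items() if b in present_b
    )

    lo, hi = config.default_tier
    edges = [
        WeightedEdge(a, b, float(rng.uniform(lo, hi))) for a, b in sorted(true_pairs)
    ]
    edges += [WeightedEdge(a, b, float(rng.uniform(lo, hi))) for a, b in sorted(dup_edges)]
    a_ids = [g for g, _ in a_order]
    b_ids = [g for g, _ in b_order]
    existing = {(e.gene_a, e.gene_b) for e in edges}
    for _ in range(config.decoy_edges):
        for _attempt in range(50):
            a = a_ids[int(rng.integers(0, len(a_ids)))]
            b = b_ids[int(rng.integers(0, len(b_ids)))]
            if (a, b) not in existing:
                edges.append(WeightedEdge(a, b, float(rng.uniform(0.2, 0.55))))
                existing.add((a, b))
                break

    sequences = None
    if config.sequences:
        rate = max(0.0, 1.0 - (lo + hi) / 2.0)
        sequences = {}
        for a_gene in a_ids:
            anc = "".join(rng.choice(_DNA, 300))
            sequences[a_gene] = anc
            if partner[a_gene] in present_b:
                sequences[partner[a_gene]] = _mutate(anc, rate, rng)
        for a_gene, dup in dup_edges:
            sequences[dup] = _mutate(sequences[a_gene], rate, rng)
        for g in b_ids:
            if g not in sequences:
                sequences[g] = "".join(rng.choice(_DNA, 300))

    genome_a = _build_genome("A", a_order, sequences)
    genome_b = _build_genome("B", b_order, sequences)
    truth = TruthSet(pairs={("A", "B"): true_pairs}, families={}, operations=ops)
    return genome_a, genome_b, edges, truth


def simulate_pangenome(
    config: SimConfig,
) -> tuple[list[Genome], list[HitRecord], list[WeightedEdge], TruthSet]:
    """Multi-genome dataset with core/accessory families and divergence tiers.

    Families are named ``F000, F001, ...``; gene ids are ``<genome>|<family>``
    (duplicates get a ``_d`` suffix). Returns the genomes, a tabular-style
    hit list (self-hits included, bitscores chosen so normalization
    reproduces the drawn weights exactly), the weighted edge list, and truth.
    """
    rng = np.random.default_rng(config.seed)
    n_fam = config.genes_per_genome
    fam_ids = [f"F{i:03d}" for i in range(n_fam)]
    n_core = int(round(config.core_fraction * n_fam))
    core = set(fam_ids[:n_core])
    fam_strand = {f: "+" if rng.random() < 0.7 else "-" for f in fam_ids}

    genome_ids = [f"G{i}" for i in range(config.n_genomes)]
    orders: dict[str, list[tuple[str, str]]] = {}
    fam_members: dict[str, list[str]] = {f: [] for f in fam_ids}
    ops: list[str] = []
    for gi, gid in enumerate(genome_ids):
        order = []
        for f in fam_ids:
            if f in core or rng.random() < config.accessory_presence:
                gene_id = f"{gid}|{f}"
                order.append((gene_id, fam_strand[f]))
                fam_members[f].append(gene_id)
        for _ in range(config.inversions):
            if len(order) >= 3:
                ops.append(f"{gid}:{_apply_inversion(order, rng)}")
        orders[gid] = order

    for k in range(config.duplications):
        gid = genome_ids[int(rng.integers(0, len(genome_ids)))]
        core_positions = [i for i, (g, _) in enumerate(orders[gid]) if g.split("|")[1] in core]
        i = core_positions[int(rng.integers(0, len(core_positions)))]
        src, strand = orders[gid][i]
        fam = src.split("|")[1]
        dup_id = f"{src}_d{k}"
        orders[gid].insert(int(rng.integers(0, len(orders[gid]) + 1)), (dup_id, strand))
        fam_members[fam].append(dup_id)
        ops.append(f"{gid}:duplication[{src}->{dup_id}]")

    def tier(fam: str) -> tuple[float, float]:
        return config.tier_overrides.get(fam, config.default_tier)

    edges: list[WeightedEdge] = []
    pair_truth: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for f in fam_ids:
        members = fam_members[f]
        lo, hi = tier(f)
        for i, ga in enumerate(members):
            for gb in members[i + 1 :]:
                genome_a, genome_b = ga.split("|")[0], gb.split("|")[0]
                if genome_a == genome_b:
                    continue
                edges.append(WeightedEdge(ga, gb, float(rng.uniform(lo, hi))))
                if "_d" in ga or "_d" in gb:  # duplicates are paralogs, not truth pairs
                    continue
                key = tuple(sorted((genome_a, genome_b)))
                a_first = ga if ga.startswith(key[0] + "|") else gb
                b_second = gb if a_first == ga else ga
                pair_truth.setdefault(key, set()).add((a_first, b_second))

    all_gene_ids = [g for gid in genome_ids for g, _ in orders[gid]]
    gene_id_set = set(all_gene_ids)
    for ka in range(len(genome_ids)):
        for kb in range(ka + 1, len(genome_ids)):
            added = 0
            guard = 0
            while added < config.decoy_edges and guard < 200:
                guard += 1
                ga = f"{genome_ids[ka]}|{fam_ids[int(rng.integers(0, n_fam))]}"
                gb = f"{genome_ids[kb]}|{fam_ids[int(rng.integers(0, n_fam))]}"
                if ga.split("|")[1] == gb.split("|")[1]:
                    continue
                if ga in gene_id_set and gb in gene_id_set:
                    edges.append(WeightedEdge(ga, gb, float(rng.uniform(0.2, 0.55))))
                    added += 1

    sequences = None
    if config.sequences:
        sequences = {}
        for f in fam_ids:
            anc = "".join(rng.choice(_DNA, 300))
            lo, hi = tier(f)
            rate = max(0.0, 1.0 - (lo + hi) / 2.0)
            for member in fam_members[f]:
                sequences[member] = _mutate(anc, rate / 2.0, rng)

    genomes = [_build_genome(gid, orders[gid], sequences) for gid in genome_ids]

    hits: list[HitRecord] = []
    for g in all_gene_ids:
        hits.append(HitRecord(g, g, 100.0, _HIT_SPAN, 1e-180, float(_HIT_SPAN)))
    for e in edges:
        hits.append(
            HitRecord(
                e.gene_a,
                e.gene_b,
                round(100.0 * e.weight, 4),
                _HIT_SPAN,
                1e-30,
                round(e.weight * _HIT_SPAN, 6),
            )
        )

    truth = TruthSet(
        pairs={k: frozenset(v) for k, v in pair_truth.items()},
        families={f: tuple(m) for f, m in fam_members.items() if m},
        operations=ops,
    )
    return genomes, hits, edges, truth


def write_dataset(
    genomes: Sequence[Genome],
    hits: Sequence[HitRecord],
    truth: TruthSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit GFF3 + FASTA per genome, the m8 hit table and a truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome in genomes:
        gff = out_dir / f"{genome.genome_id}.gff"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in genome.genes():
                attrs = f"ID={gene.gene_id}"
                if gene.gene_name:
                    attrs += f";gene={gene.gene_name}"
                fh.write(
                    f"{gene.contig_id}\tpanrefine-sim\t{gene.feature_type}\t{gene.start}\t"
                    f"{gene.end}\t.\t{gene.strand}\t0\t{attrs}\n"
                )
        paths[f"{genome.genome_id}.gff"] = gff
        if any(g.sequence for g in genome.genes()):
            fasta = out_dir / f"{genome.genome_id}.fasta"
            with open(fasta, "w") as fh:
                for gene in genome.genes():
                    if gene.sequence:
                        fh.write(f">{gene.gene_id}\n{gene.sequence}\n")
            paths[f"{genome.genome_id}.fasta"] = fasta
    m8 = out_dir / "hits.m8"
    write_hit_table(hits, m8)
    paths["hits.m8"] = m8
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "pairs": {f"{a}::{b}": sorted(map(list, v)) for (a, b), v in truth.pairs.items()},
                "families": {f: list(m) for f, m in truth.families.items()},
                "operations": truth.operations,
            },
            fh,
            indent=2,
        )
    paths["truth.json"] = truth_path
    return paths
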