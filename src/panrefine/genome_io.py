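"""Readers and writers for annotated genomes, similarity hit tables and cluster files.

Genomes are modelled as ordered, oriented gene lists per contig. Bacterial
replicons are circular, so every contig is treated as an independent circular
chromosome unless flagged otherwise. Coordinates follow GFF3 conventions
(1-based, inclusive); gene order within a contig is determined solely by
``(start, end, gene_id)`` so that parsing is insensitive to record order in
the file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_TYPES = frozenset({"CDS", "tRNA", "rRNA"})

#: column names of the 12-column tabular hit format (BLAST outfmt 6 / m8)
M8_COLUMNS = (
    "query_id",
    "target_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_openings",
    "q_start",
    "q_end",
    "t_start",
    "t_end",
    "evalue",
    "bitscore",
)


class GenomeIOError(ValueError):
    """Raised for malformed annotation, hit-table or cluster files."""


@dataclass
class GeneFeature:
    """A single annotated gene (CDS, tRNA or rRNA) on a contig.

    ``start``/``end`` are 1-based inclusive base-pair coordinates; ``strand``
    is ``'+'`` or ``'-'``. ``sequence`` holds residues when they could be
    resolved from an accompanying FASTA (nucleotide slice of the contig, or a
    per-gene record).
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    gene_name: str | None = None
    product: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class Genome:
    """Ordered, oriented gene lists per (circular) contig."""

    genome_id: str
    contigs: dict[str, list[GeneFeature]] = field(default_factory=dict)
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.contigs:
            self.circular.setdefault(cid, True)
        seen: set[str] = set()
        for gene in self.genes():
            if gene.gene_id in seen:
                raise GenomeIOError(f"duplicate gene_id {gene.gene_id!r} in genome {self.genome_id!r}")
            seen.add(gene.gene_id)

    def genes(self) -> Iterator[GeneFeature]:
        for cid in self.contigs:
            yield from self.contigs[cid]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.contigs.values())

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes()]


@dataclass
class HitRecord:
    """One line of a 12-column tabular similarity search result."""

    query_id: str
    target_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise GenomeIOError(
                f"hit {self.query_id}->{self.target_id}: pct_identity {self.pct_identity} outside [0,100]"
            )
        if self.aln_length < 0 or self.bitscore < 0:
            raise GenomeIOError(
                f"hit {self.query_id}->{self.target_id}: negative aln_length or bitscore"
            )


@dataclass
class ScaffoldClusters:
    """A partition of (a subset of) all genes into similarity clusters."""

    clusters: dict[str, set[str]]
    provenance: str = "internal"  # or "external-file"
    threshold: float | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cid, members in self.clusters.items():
            for g in members:
                if g in seen:
                    raise GenomeIOError(
                        f"gene {g!r} appears in clusters {seen[g]!r} and {cid!r}"
                    )
                seen[g] = cid

    def cluster_of(self) -> dict[str, str]:
        """Map gene_id -> cluster_id."""
        return {g: cid for cid, members in self.clusters.items() for g in members}


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_annotated_genome(
    gff3_path: str | Path,
    fasta_path: str | Path | None = None,
    feature_types: Iterable[str] = DEFAULT_FEATURE_TYPES,
    genome_id: str | None = None,
) -> Genome:
    """Read a Prokka-style GFF3 (plus optional FASTA) into a :class:`Genome`.

    The FASTA may either be the genomic nucleotide sequence (records keyed by
    contig id; gene sequences are sliced and reverse-complemented for minus
    strand) or a per-gene FASTA (records keyed by gene id, e.g. protein
    translations). Features with strand ``'.'`` are accepted as ``'+'``.
    """
    gff3_path = Path(gff3_path)
    feature_types = set(feature_types)
    if genome_id is None:
        genome_id = gff3_path.stem

    features: list[GeneFeature] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeIOError(
                    f"{gff3_path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            contig_id, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomeIOError(f"{gff3_path}:{lineno}: non-integer coordinates") from exc
            if strand == ".":
                logger.warning(
                    "%s:%d: unoriented feature treated as '+' strand", gff3_path, lineno
                )
                strand = "+"
            attrs = _parse_gff3_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
            if gene_id is None:
                raise GenomeIOError(f"{gff3_path}:{lineno}: feature lacks ID/locus_tag/Name")
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type=ftype,
                    gene_name=attrs.get("gene") or attrs.get("Name"),
                    product=attrs.get("product"),
                )
            )

    contigs: dict[str, list[GeneFeature]] = {}
    for feat in features:
        contigs.setdefault(feat.contig_id, []).append(feat)
    for cid in contigs:
        contigs[cid].sort(key=lambda g: (g.start, g.end, g.gene_id))
    # contig order itself is deterministic: lexicographic
    contigs = {cid: contigs[cid] for cid in sorted(contigs)}
    genome = Genome(genome_id=genome_id, contigs=contigs)

    if fasta_path is not None:
        records = {rec.id: rec for rec in SeqIO.parse(str(fasta_path), "fasta")}
        for gene in genome.genes():
            if gene.gene_id in records:
                gene.sequence = str(records[gene.gene_id].seq)
            elif gene.contig_id in records:
                sub = records[gene.contig_id].seq[gene.start - 1 : gene.end]
                if gene.strand == "-":
                    sub = Seq(str(sub)).reverse_complement()
                gene.sequence = str(sub)
    return genome


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file (BLAST outfmt 6 / MMseqs2 m8).

    Self-hits are retained; they are needed for bitscore normalization.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise GenomeIOError(
                    f"{path}:{lineno}: expected >=12 columns, got {len(fields)}"
                )
            extra = dict(zip(M8_COLUMNS[4:10], fields[4:10]))
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    target_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    extra=extra,
                )
            )
    return hits


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits back out in the 12-column tabular dialect."""
    with open(path, "w") as fh:
        for h in hits:
            mid = [h.extra.get(c, "0") for c in M8_COLUMNS[4:10]]
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.target_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        *mid,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.3f}",
                    ]
                )
                + "\n"
            )


def read_scaffold_clusters(path: str | Path) -> ScaffoldClusters:
    """Read a Roary ``clustered_proteins``-style file (``name: id1\\tid2...``)."""
    clusters: dict[str, set[str]] = {}
    owner: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if ":" not in line:
                raise GenomeIOError(f"{path}:{lineno}: missing ':' cluster separator")
            name, _, rest = line.partition(":")
            name = name.strip()
            members = [tok for tok in rest.strip().split("\t") if tok]
            if len(members) == 1:
                members = rest.strip().split()
            for g in members:
                if g in owner:
                    raise GenomeIOError(
                        f"{path}:{lineno}: gene {g!r} already in cluster {owner[g]!r}, "
                        f"also listed in {name!r}"
                    )
                owner[g] = name
            clusters[name] = set(members)
    return ScaffoldClusters(clusters=clusters, provenance="external-file")


def write_group_outputs(group_table, out_dir: str | Path) -> dict[str, Path]:
    """Write the group TSV, presence/absence matrix and per-group FASTA.

    ``group_table`` is a :class:`panrefine.grouping.GroupTable`. Returns a map
    of artifact name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes = list(group_table.genomes)
    thresholds = sorted(group_table.threshold_annotation) if group_table.threshold_annotation else []

    rows = []
    for grp in group_table.groups:
        row: dict[str, object] = {
            "group_id": grp.group_id,
            "gene_name": grp.representative_name or "NA",
            "product": grp.representative_product or "NA",
        }
        for gid in genomes:
            row[gid] = grp.members.get(gid, "NA")
        row["n_genomes"] = len(grp.members)
        row["core"] = int(grp.core)
        for thr in thresholds:
            row[f"clusters_{int(round(thr * 100))}"] = group_table.threshold_annotation[thr].get(
                grp.group_id, 0
            )
        rows.append(row)
    groups_df = pd.DataFrame(rows)
    groups_path = out_dir / "groups.tsv"
    groups_df.to_csv(groups_path, sep="\t", index=False)

    presence = pd.DataFrame(
        [
            {"group_id": grp.group_id, **{gid: int(gid in grp.members) for gid in genomes}}
            for grp in group_table.groups
        ]
    ).set_index("group_id")
    presence_path = out_dir / "presence_absence.tsv"
    presence.to_csv(presence_path, sep="\t")

    fasta_dir = out_dir / "group_fasta"
    fasta_dir.mkdir(exist_ok=True)
    gene_lookup = group_table.gene_lookup or {}
    for grp in group_table.groups:
        recs = []
        for gid in genomes:
            gene_id = grp.members.get(gid)
            if gene_id is None:
                continue
            gene = gene_lookup.get(gene_id)
            if gene is not None and gene.sequence:
                recs.append((f"{gene_id} {gid}", gene.sequence))
        if recs:
            safe = grp.group_id.replace("/", "_")
            with open(fasta_dir / f"{safe}.fasta", "w") as fh:
                for header, seq in recs:
                    fh.write(f">{header}\n{seq}\n")

    return {"groups": groups_path, "presence": presence_path, "fasta_dir": fasta_dir}


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Re-read a presence/absence TSV written by :func:`write_group_outputs`."""
    return pd.read_csv(path, sep="\t", index_col="group_id")


def write_manifest(path: str | Path, params: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        json.dump(dict(params), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
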