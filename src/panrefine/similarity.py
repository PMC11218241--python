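"""Similarity weights, an internal local aligner, and POCP genome similarity.

Raw bitscores from an all-vs-all search are normalized into inter-gene
weights sigma in [0, 1] by dividing the cross-hit bitscore by the larger of
the two self-hit bitscores. Weights below an edge threshold (default 0.6)
are discarded: the downstream matching model only considers gene pairs of at
least 60% normalized similarity.

POCP (percentage of conserved proteins) between genomes A and B is

    POCP = 100 * (C_A + C_B) / (T_A + T_B)

where C_X counts proteins of X with at least one hit into the other genome
passing e-value < 1e-5, identity > 40% and alignable fraction > 50% (strict
inequalities), and T_X is the total protein count. ~50% POCP has been
proposed as a genus boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, HitRecord

GENUS_POCP_BOUNDARY = 50.0

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class WeightedEdge:
    """Normalized similarity between two genes of different genomes."""

    gene_a: str
    gene_b: str
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise SimilarityError(f"weight {self.weight} outside [0,1]")


@dataclass(frozen=True)
class PocpResult:
    genome_a: str
    genome_b: str
    conserved_a: int
    conserved_b: int
    total_a: int
    total_b: int

    @property
    def pocp(self) -> float:
        return 100.0 * (self.conserved_a + self.conserved_b) / (self.total_a + self.total_b)


def _looks_like_protein(seq: str) -> bool:
    letters = set(seq.upper())
    return not letters <= set("ACGTUN") and letters <= _PROTEIN_ALPHABET | {"X", "*"}


def toy_align(seq_a: str, seq_b: str, scoring: str | None = None) -> HitRecord:
    """Local alignment of two sequences, reported as a :class:`HitRecord`.

    A stand-in for an external all-vs-all search so the pipeline runs
    self-contained. Nucleotide sequences use match=2/mismatch=-3/gap open -5
    extend -2; proteins use BLOSUM62 with gap open -11 extend -1. The score
    is reported in the ``bitscore`` slot (raw, not bit-scaled); ``evalue`` is
    set to 0.0 as a sentinel meaning "not estimated".
    """
    if not seq_a or not seq_b:
        raise SimilarityError("toy_align requires non-empty sequences")
    if scoring is None:
        scoring = "protein" if (_looks_like_protein(seq_a) or _looks_like_protein(seq_b)) else "dna"

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    else:
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2

    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return HitRecord(
            query_id="a", target_id="b", pct_identity=0.0, aln_length=0, evalue=0.0, bitscore=0.0
        )
    aln = next(iter(aligner.align(seq_a, seq_b)))
    a_aln, b_aln = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a_aln, b_aln) if x == y and x != "-")
    aln_len = len(a_aln)
    return HitRecord(
        query_id="a",
        target_id="b",
        pct_identity=100.0 * matches / aln_len if aln_len else 0.0,
        aln_length=aln_len,
        evalue=0.0,
        bitscore=float(score),
    )


def all_vs_all(genomes: Sequence[Genome], scoring: str | None = None) -> list[HitRecord]:
    """Internal all-vs-all comparison (including self-hits) via :func:`toy_align`.

    Quadratic in total gene number; intended for small, self-contained runs.
    """
    genes = [g for genome in genomes for g in genome.genes()]
    for g in genes:
        if not g.sequence:
            raise SimilarityError(f"gene {g.gene_id!r} has no sequence; cannot align internally")
    hits: list[HitRecord] = []
    for i, ga in enumerate(genes):
        for gb in genes[i:]:
            rec = toy_align(ga.sequence, gb.sequence, scoring)
            if rec.bitscore <= 0 and ga.gene_id != gb.gene_id:
                continue
            hits.append(
                HitRecord(
                    query_id=ga.gene_id,
                    target_id=gb.gene_id,
                    pct_identity=rec.pct_identity,
                    aln_length=rec.aln_length,
                    evalue=0.0,
                    bitscore=rec.bitscore,
                )
            )
    return hits


def normalize_weights(
    hits: Iterable[HitRecord],
    gene_genome: Mapping[str, str],
    edge_threshold: float = 0.6,
) -> list[WeightedEdge]:
    """Turn raw bitscores into normalized inter-gene weights.

    weight(a, b) = bitscore(a, b) / max(bitscore(a, a), bitscore(b, b)),
    clipped to [0, 1]. Reciprocal hits are collapsed to one undirected edge
    using the larger raw bitscore. Same-genome pairs (including self-hits)
    never become edges. Edges below ``edge_threshold`` are dropped.

    ``gene_genome`` maps gene_id -> genome_id; a gene participating in a
    cross-hit without a self-hit raises an error naming the gene.
    """
    self_scores: dict[str, float] = {}
    cross: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.target_id:
            self_scores[h.query_id] = max(self_scores.get(h.query_id, 0.0), h.bitscore)
            continue
        ga = gene_genome.get(h.query_id)
        gb = gene_genome.get(h.target_id)
        if ga is None or gb is None:
            unknown = h.query_id if ga is None else h.target_id
            raise SimilarityError(f"hit references unknown gene {unknown!r}")
        if ga == gb:
            continue
        key = (h.query_id, h.target_id) if h.query_id < h.target_id else (h.target_id, h.query_id)
        cross[key] = max(cross.get(key, 0.0), h.bitscore)

    edges: list[WeightedEdge] = []
    for (a, b), score in sorted(cross.items()):
        for g in (a, b):
            if g not in self_scores:
                raise SimilarityError(f"no self-hit for gene {g!r}; cannot normalize its bitscores")
        denom = max(self_scores[a], self_scores[b])
        if denom <= 0:
            continue
        w = min(1.0, score / denom)
        if w >= edge_threshold:
            edges.append(WeightedEdge(a, b, w))
    return edges


def compute_pocp(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    total_a: int,
    total_b: int,
    query_lengths: Mapping[str, int],
    genome_a: str = "A",
    genome_b: str = "B",
    evalue_max: float | None = 1e-5,
    identity_min: float = 40.0,
    aln_frac_min: float = 0.5,
) -> PocpResult:
    """Percentage of conserved proteins between two proteomes.

    A query protein is conserved if at least one of its hits into the other
    genome passes all filters with strict inequality: evalue < evalue_max,
    identity > identity_min (percent), aln_length/query_length > aln_frac_min.
    ``evalue_max=None`` disables the e-value filter (internal toy alignments
    carry no e-value estimate).
    """
    if total_a <= 0 or total_b <= 0:
        raise SimilarityError("POCP undefined for an empty proteome")

    def conserved(hits: Iterable[HitRecord]) -> int:
        passing: set[str] = set()
        for h in hits:
            if evalue_max is not None and not h.evalue < evalue_max:
                continue
            if not h.pct_identity > identity_min:
                continue
            qlen = query_lengths.get(h.query_id)
            if qlen is None:
                raise SimilarityError(f"no query length for {h.query_id!r}")
            if not h.aln_length / qlen > aln_frac_min:
                continue
            passing.add(h.query_id)
        return len(passing)

    return PocpResult(
        genome_a=genome_a,
        genome_b=genome_b,
        conserved_a=conserved(hits_ab),
        conserved_b=conserved(hits_ba),
        total_a=total_a,
        total_b=total_b,
    )


def pocp_matrix(
    genomes: Sequence[Genome],
    hits: Iterable[HitRecord],
    gene_genome: Mapping[str, str],
    evalue_max: float | None = 1e-5,
) -> pd.DataFrame:
    """Square, symmetric matrix of pairwise POCP values (percent).

    Hits are split by (query genome, target genome); gene lengths come from
    attached sequences. The diagonal is 100 by definition.
    """
    hits = list(hits)
    lengths: dict[str, int] = {}
    totals: dict[str, int] = {}
    for genome in genomes:
        totals[genome.genome_id] = genome.n_genes
        for g in genome.genes():
            lengths[g.gene_id] = len(g.sequence) if g.sequence else (g.end - g.start + 1)

    by_pair: dict[tuple[str, str], list[HitRecord]] = {}
    for h in hits:
        ga, gb = gene_genome.get(h.query_id), gene_genome.get(h.target_id)
        if ga is None or gb is None or ga == gb:
            continue
        by_pair.setdefault((ga, gb), []).append(h)
        # tabular searches are directional; mirror so both directions exist
        by_pair.setdefault((gb, ga), []).append(
            HitRecord(h.target_id, h.query_id, h.pct_identity, h.aln_length, h.evalue, h.bitscore)
        )

    ids = [g.genome_id for g in genomes]
    mat = pd.DataFrame(np.full((len(ids), len(ids)), 100.0), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = compute_pocp(
                by_pair.get((a, b), []),
                by_pair.get((b, a), []),
                totals[a],
                totals[b],
                lengths,
                genome_a=a,
                genome_b=b,
                evalue_max=evalue_max,
            )
            mat.loc[a, b] = mat.loc[b, a] = res.pocp
    return mat


def mean_pocp(matrix: pd.DataFrame) -> float:
    """Dataset-average of pairwise POCP values (off-diagonal mean)."""
    vals = matrix.values
    n = vals.shape[0]
    if n < 2:
        raise SimilarityError("need at least two genomes for an average POCP")
    off = vals[~np.eye(n, dtype=bool)]
    return float(off.mean())
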