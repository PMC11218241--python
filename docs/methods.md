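# Methods

## Scope and data model

The package refines a high-stringency pangenome clustering ("scaffold")
into genus-level homologous groups using pairwise, synteny-aware gene
matching. Genomes are ordered, oriented gene lists per contig; every contig
is treated as an independent **circular** replicon. This is the natural
model for bacterial chromosomes and plasmids and keeps the adjacency graph
purely cycle-decomposable (no path/telomere bookkeeping); linear-contig
accounting is a known limitation, not an option.

Coordinates are kept 1-based inclusive as in GFF3; internal gene-order
indices are 0-based. Gene order within a contig is defined by
`(start, end, gene_id)` — the lexicographic tie-break for overlapping
annotations is a determinism choice, since no convention is standard.
Features with strand `.` are accepted as `+` with a warning-level policy:
the model requires oriented genes and unoriented features are rare
annotation artifacts.

## Similarity weights

Raw all-vs-all bitscores are converted to weights
`σ(a,b) = bits(a,b) / max(bits(a,a), bits(b,b))`, clipped to [0, 1].
Normalizing by the *larger* self-score guarantees σ ≤ 1 even for asymmetric
local alignments; normalizing by the mean would not. Reciprocal hits
(a→b and b→a) are collapsed to one undirected edge by the larger raw
bitscore, because the matching model needs a single weight per gene pair.
Edges with σ < 0.6 (tunable `edge_threshold`) are dropped: below that the
evidence is considered noise rather than candidate homology.

The built-in local aligner (Biopython `PairwiseAligner`; match 2 /
mismatch −3 / gap −5/−2 for DNA, BLOSUM62 with gap −11/−1 for protein)
exists so the pipeline runs with no external search tool. It reports a raw
score in the bitscore slot and **no e-value** (sentinel 0.0): proper
e-value statistics require score-distribution calibration that is out of
scope. Consequently POCP on internally aligned data should be run with the
e-value filter disabled (`evalue_max=None`), which the pipeline does
automatically.

## The pairwise distance

For genomes A (n genes) and B (m genes) with similarity edges σ, a
matching M of the bipartite gene similarity graph induces reduced genomes
A^M, B^M (unmatched genes — singletons — removed). Each gene has two
extremities (head/tail, swapped for minus-strand genes); consecutive genes
on a circular contig define an adjacency, and linking A-adjacencies with
B-adjacencies through matched extremities yields the adjacency graph,
which decomposes into `c` cycles (2-cycles are "fixed components": locally
identical context). The distance minimized over all **maximum-cardinality**
matchings is

    d = α (|M| − c + I + S) + (1 − α)(|M| − ω(M))

with S the singleton count, I the number of indel blocks (maximal runs of
consecutive singletons per circular contig; a fully-singleton contig
counts as one block), ω(M) the matched weight sum, α ∈ [0, 1], default 0.5.
Requiring maximum cardinality means an indel is only invoked when a gene
cannot be matched at all. The double indel penalty (S *and* I) is
deliberate: penalizing only singletons overestimates indel events, while
penalizing only blocks admits the degenerate solution "genome A is one
deletion, genome B is one insertion". With α = 1 and unit weights on
one-to-one instances the distance reduces to the classical circular DCJ
distance |M| − c; with α = 0 it reduces to maximum-weight matching among
maximum matchings. Both the indel form and the pure form (without S and I)
are available (`--indel-model/--no-indel-model`).

## ILP encoding

Per instance: binary `x_e` per similarity edge; singleton indicators
`s_g = 1 − Σ x_e(incident)`; the cardinality equality `Σ x_e = |M_max|`
(Hopcroft–Karp size, networkx). Unmatched genes receive a **self-edge**
joining their own two extremities, which splices singletons out of the
genome walk so that the cycle structure of the *reduced* genomes emerges
on the *full* gene order without rebuilding adjacencies per matching.

Cycles are counted with a label/representative scheme (polynomially many
constraints instead of exponential cycle enumeration): each adjacency
vertex gets a continuous label `y_v ≤ index(v)` equalized along active
edges via big-M constraints (M = number of vertices), and a binary
representative `z_v` with `index(v)·z_v ≤ y_v`. Within one cycle all labels
coincide, so at most one vertex (the minimum-index one) can raise its
representative; the objective rewards raising them, hence `Σ z = c` at the
optimum. One subtlety: if *every* gene of a contig is a singleton, the
self-edges close a spurious within-genome cycle. A per-contig indicator
forced to 1 exactly in that situation is subtracted from the cycle count;
it can only bind in full-instance mode since a solved component always
retains matched genes on both sides. Blocks are counted by
`b_g ≥ s_g − s_next(g)` along each circular contig (one block end per
maximal singleton run) plus the per-contig guard
`Σ b ≥ Σ s − (k − 1)` for the all-singleton wrap-around case.

The backend is HiGHS via `scipy.optimize.milp`, run at zero MIP gap with a
per-ILP time limit (default 240 s). Variable order is fixed by the sorted
edge/gene/vertex lists, so identical inputs produce identical solutions.
The reported distance is always **recomputed** from the decoded matching by
the independent graph evaluator and, for optimal solves, asserted against
the solver objective to 1e-6. Exactness is guarded by tests comparing the
ILP optimum to brute-force enumeration over all maximum matchings
(guarded to ≤ 8 genes/genome) across random instances and α values.

## Decomposition and trivial cases

The similarity graph is split into connected components; each becomes its
own sub-ILP. Components that are a single edge (one A-gene, one B-gene,
both degree 1) are accepted directly as homolog pairs without
optimization; isolated genes are forced singletons contributing 2α each.
For the remaining components, the circular orders are restricted to the
component's genes **plus** all trivially matched genes, whose matching
variables are pinned to 1: this "frozen context" lets the cycle structure
see the true neighborhood, so a synteny-consistent candidate can beat a
marginally higher-weight candidate elsewhere in the genome. Genes of other
unsolved components are contracted out of the orders — an approximation
(interactions between two unsolved components are ignored) that parallels
the sub-ILP splitting the method is built on; an exact full-instance mode
(`decompose=False`) exists for small inputs and is used in tests to bound
the approximation. On a solver timeout without an incumbent, a greedy
maximum-weight matching is substituted and flagged
(`source=timeout-fallback`) so downstream users can see which pairs lack
an optimality guarantee.

## Grouping

Scaffold clusters (internally: single-linkage connected components over
edges with σ ≥ 0.95; or an external cluster file, taken verbatim) are
merged via union-find: every homolog pair bridging two clusters merges
them; unclustered genes join through their pairs or stay singleton groups.
Only the 0.95 clustering feeds this step — the 0.60–0.90 clusterings are
written as annotation columns only.

If a genome contributes ≥ 2 genes to a merged group, one representative is
chosen by the ladder: (1) most homology-pair connections to the rest of
the group, (2) largest originating scaffold cluster, (3) gene name
matching the majority name in the group ("hypothetical protein"
placeholders carry no evidence and are excluded from the majority count),
(4) lexicographically smallest gene id. Step 4 is a determinism fallback;
steps 1–3 can all tie. The n−1 leftover genes seed subgroups
(`groupN.K`): leftovers connected to each other by homology pairs stay in
one subgroup, and subgroups are re-resolved recursively when several
genomes carry paralogs. Subgroup membership does not count toward the
parent's genome coverage — after resolution the parent holds at most one
gene per genome.

Group ids are assigned by sorting top-level groups by smallest member gene
id, making ids stable under permutation of genome input order or cluster
file row order. A group is core when it covers at least
`ceil(core_perc/100 × n_genomes)` genomes (ceiling = "at least"
semantics; default 100%). Merging can in principle chain unrelated
clusters through spurious pairs; no guard is applied beyond the 0.6 edge
threshold, which is a known failure mode on very promiscuous families.

## POCP

POCP(A,B) = 100·(C_A + C_B)/(T_A + T_B), where C_X counts proteins of X
with ≥ 1 hit into the other genome passing, with strict inequality,
e-value < 1e−5, identity > 40%, and alignable fraction
(aln_length/query_length) > 50%. The implementation is symmetric and
monotone in each threshold; ~50% is the proposed genus boundary and is
exposed as a constant for reference. A dataset mean over off-diagonal
pairs summarizes input diversity.

## Synthetic data

The generator has two scales. *Genome pairs*: genome B is derived from A
by configured counts of inversions (segment reversal with strand flips),
transpositions (segment excision/reinsertion; note one transposition = two
DCJ operations), deletions, insertions and duplications, applied uniformly
at random under the seed. True ortholog pairs receive weights drawn from a
divergence tier (default U[0.96, 1.0]); decoy edges are drawn in
[0.2, 0.55], i.e. strictly below the 0.6 matching threshold, so truth is
separable by construction. *Pangenomes*: an ancestral pool of families
(one per `genes_per_genome`, default 20 per genome, 5 genomes) is
propagated — core families (default 90%) into every genome, accessory
families with probability 0.5 — with per-family tiers controlling whether
the 95% scaffold keeps a family together; a diverged family uses tier
[0.60, 0.90), mirroring a genus-level ortholog set. Emitted tabular hits
set self-bitscores to a constant so that normalization reproduces the
drawn weights exactly.

Sequences, when requested, are mutated copies of a random ancestral DNA
sequence with substitution rate tied to the tier — adequate for exercising
the aligner, but not a realistic evolutionary model: no codon structure,
no length variation, no HGT, no rate heterogeneity. Passing tests on this
generator therefore validate the *combinatorial* machinery (matching,
cycles, merging, paralog logic) and the pipeline plumbing, not performance
on real sequence divergence, where search sensitivity and annotation
consistency dominate.

## Problem sizes and numerical choices

Verification uses instances of ≤ 5 genes per genome for the
ILP-vs-enumeration study (200 instances × α ∈ {0, 0.5, 1}), 8-gene genomes
for rearrangement recovery (20 replicates), and 3–5 genome pangenomes of
10–20 families for end-to-end runs; these sizes make every check exact or
exhaustively enumerable while exercising all code paths. Distances are
compared at 1e−6; the solver runs at zero MIP gap; ties in the brute-force
oracle are broken by larger ω(M), then lexicographically smallest pair
set. Degenerate inputs: a single-gene circular contig contributes its own
(head, tail) self-adjacency; empty reduced genomes have c = 0; components
without edges are never formulated as ILPs.

## Known limitations

- Circular-only contig model; no linear-chromosome DCJ accounting.
- Component decomposition freezes trivially matched context but ignores
  interactions between two unsolved components.
- The internal aligner has no e-value statistics; POCP from internal
  alignments relies on identity and coverage filters only.
- Union-find merging has no chain-length guard against promiscuous
  families bridging unrelated clusters.
- Roary-style cluster files are consumed, but the internal scaffold is
  single-linkage over normalized weights, not a re-implementation of any
  specific external clustering pipeline.
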