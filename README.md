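# panrefine

Synteny-aware refinement of bacterial pangenome clusters via family-free
DCJ-indel integer linear programming.

## The problem

Pangenome tools cluster annotated genes by sequence similarity at a high
stringency (typically 95% identity). That works within a species, but across
a genus — where orthologs may share only 60–90% similarity — such clustering
shatters genuine gene families into fragments, and the *core genome* (genes
present in every input genome) is drastically underestimated.

`panrefine` keeps the high-stringency clustering as a *scaffold* and then
repairs it using gene order. For every pair of genomes it asks: which
matching of genes best explains both the sequence similarities **and** the
genomic organization? Homolog pairs recovered this way are used to merge
scaffold clusters into *groups* that span the whole input set, with paralogs
split into suffixed subgroups (`group7.1`). It also computes POCP
(percentage of conserved proteins), the standard genus-delimitation metric,
to characterize how diverse the input set is.

## The model

For genomes *A* and *B*, a bipartite **gene similarity graph** carries
normalized similarity weights σ ∈ (0, 1] (cross-hit bitscore divided by the
larger self-hit bitscore; edges below 0.6 are discarded). For a matching
*M* of this graph, the reduced genomes A^M, B^M (unmatched *singletons*
removed) define an **adjacency graph** over gene extremities that, with
circular replicons, decomposes into *c* cycles. The family-free DCJ-indel
distance of the pair is

```
d(A,B) = min over maximum matchings M of
         α·(|M| − c + I + S)  +  (1 − α)·(|M| − ω(M))
```

where S is the number of singletons, I the number of indel *blocks*
(maximal runs of consecutive singletons), ω(M) the summed matched-edge
weights, and α ∈ [0, 1] (default 0.5) balances genome organization against
raw similarity. Indels are deliberately penalized twice — once per singleton
and once per block — which prevents both indel overestimation and the
degenerate "delete genome A, insert genome B" solution. The minimization is
solved exactly as an integer linear program (HiGHS backend) per connected
similarity component, with direct one-to-one components accepted without
optimization and a 240 s time limit per sub-ILP. The optimal matching's
pairs are the homology evidence fed into cluster merging.

## Worked example

Simulate a 4-genome dataset in which two core families are diverged
(pairwise weights 0.60–0.90, i.e. invisible to a 95% scaffold), then refine:

```
$ panrefine simulate --n-genomes 4 --genes-per-genome 10 --core-fraction 0.8 \
    --inversions 1 --low-sim-families 2 --seed 3 --out demo/data
wrote 6 files to demo/data

$ panrefine run -g demo/data/G0.gff -g demo/data/G1.gff \
    -g demo/data/G2.gff -g demo/data/G3.gff \
    --hits demo/data/hits.m8 --out demo/out
INFO parsed 4 genomes, 36 genes
INFO 87 hits -> 51 weighted edges (threshold 0.60)
INFO scaffold: 16 clusters (internal)
INFO G0 vs G1: 8 pairs (trivial 8, ilp 0, timeout 0), distance 2.388
...
INFO 10 groups, 8 core
INFO mean pairwise POCP: 94.43%
10 groups (8 core) -> demo/out
```

The 36 genes fall into 16 scaffold clusters at 95% — the two diverged
families are split — but merging through the pairwise homology evidence
recovers the 10 true families, 8 of which cover all four genomes (core).
`demo/out/groups.tsv` starts:

```
group_id  gene_name  product  G0       G1       G2       G3       n_genomes  core
group1    F000       NA       G0|F000  G1|F000  G2|F000  G3|F000  4          1
group2    F001       NA       G0|F001  G1|F001  G2|F001  G3|F001  4          1
```

Per-genome columns give the member gene id (or `NA`), `core` flags groups
covering at least `--core-perc` (default 100%) of the genomes, and further
columns annotate in how many clusters the group's genes fall at the
60/70/80/90/95% thresholds. The output directory also holds the
presence/absence matrix, per-group FASTA, per-threshold cluster tables, a
symmetric POCP matrix (the ~50% genus boundary is a useful reference
point), and a JSON manifest of all parameters.

Genomes are given as Prokka-style GFF3 (optionally with a FASTA for
sequences); all-vs-all hits as 12-column tabular (`m8`) output of any
BLAST-like search, or computed by the built-in aligner
(`--align-internal`); an external clustering can replace the internal
scaffold via `--roary clustered_proteins`.

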