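"""Integer linear programming of the family-free DCJ-indel distance.

For a (component of a) gene similarity graph the program chooses a
maximum-cardinality matching M minimizing

    d(M) = alpha * (|M| - c + I + S) + (1 - alpha) * (|M| - omega(M)).

Encoding
--------
* one binary ``x_e`` per similarity edge; per gene a singleton indicator
  ``s_g = 1 - sum(x_e incident)``;
* maximum cardinality imposed as the equality ``sum(x_e) = |M_max|``
  (Hopcroft-Karp size) — an indel is only allowed when a gene cannot be
  matched at all;
* every unmatched gene receives a *self-edge* joining its two extremities,
  which splices the singleton out of its genome walk so the adjacency-graph
  cycle structure of the reduced genomes emerges without re-building
  adjacencies per matching;
* cycles are counted by a label scheme: each adjacency vertex ``v`` (the
  extremity pair between consecutive genes of a circular contig) gets a
  continuous label ``y_v <= index(v)`` equalized along active edges via
  big-M constraints, and a binary representative ``z_v`` with
  ``index(v) * z_v <= y_v``; at most one vertex per cycle (the one with the
  minimal index) can raise its representative, and the objective rewards
  doing so, so ``sum(z) = c`` at the optimum;
* a contig whose genes are all singletons would close a spurious
  within-genome cycle through its self-edges; a per-contig indicator forced
  to 1 exactly in that situation cancels it out of the cycle count;
* indel blocks: ``b_g >= s_g - s_next(g)`` along each circular contig counts
  one block end per maximal singleton run (a fully singleton contig is
  caught by the per-contig constraint ``sum(b) >= sum(s) - (k - 1)``).

Singletons and blocks both enter the objective — the deliberate double
penalty for indels. ``|M|`` and ``S`` are constants once the cardinality is
fixed, so the solver effectively maximizes
``alpha * (c - I) + (1 - alpha) * omega``.

The backend is HiGHS via :func:`scipy.optimize.milp`, solved to zero MIP
gap; correctness is guarded by exhaustive-oracle tests against
:func:`panrefine.rearrangement_graphs.brute_force_ffdcj_indel`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .genome_io import Genome
from .rearrangement_graphs import (
    Component,
    GeneSimilarityGraph,
    GraphError,
    Matching,
    MatchingStats,
    RearrangementInstance,
    build_gs_graph,
    evaluate_matching,
    gs_components,
    is_trivial_component,
    left_extremity,
    make_matching,
    max_matching_size,
    right_extremity,
)
from .similarity import WeightedEdge

DEFAULT_TIME_LIMIT_S = 240.0
DEFAULT_ALPHA = 0.5


class IlpError(RuntimeError):
    pass


@dataclass
class IlpInstance:
    """A fully materialized MILP for one similarity-graph (sub-)instance."""

    instance: RearrangementInstance
    alpha: float
    indel: bool
    max_matching_size: int
    edge_list: tuple[tuple[str, str, float], ...]
    n_vars: int
    objective: np.ndarray
    constant: float
    integrality: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    constraints: list[LinearConstraint]
    # bookkeeping for decode / dumps
    x_cols: dict[tuple[str, str], int]
    var_names: list[str] = field(default_factory=list)

    def to_lp_text(self) -> str:
        """Plain LP-style dump (minimize objective, then constraint rows)."""
        lines = ["\\ family-free DCJ-indel instance", "Minimize"]
        terms = [
            f"{c:+g} {self.var_names[i]}" for i, c in enumerate(self.objective) if c != 0
        ]
        lines.append(" obj: " + " ".join(terms) + f" {self.constant:+g}")
        lines.append("Subject To")
        row_no = 0
        for lc in self.constraints:
            mat = lc.A.toarray() if hasattr(lc.A, "toarray") else np.atleast_2d(lc.A)
            lbs = np.atleast_1d(lc.lb)
            ubs = np.atleast_1d(lc.ub)
            for r in range(mat.shape[0]):
                expr = " ".join(
                    f"{mat[r, j]:+g} {self.var_names[j]}" for j in np.nonzero(mat[r])[0]
                )
                lb, ub = float(lbs[r]), float(ubs[r])
                if lb == ub:
                    lines.append(f" c{row_no}: {expr} = {lb:g}")
                else:
                    if np.isfinite(lb):
                        lines.append(f" c{row_no}: {expr} >= {lb:g}")
                    if np.isfinite(ub):
                        lines.append(f" c{row_no}: {expr} <= {ub:g}")
                row_no += 1
        lines.append("Bounds")
        for j, name in enumerate(self.var_names):
            lines.append(f" {self.lower[j]:g} <= {name} <= {self.upper[j]:g}")
        lines.append("Binaries")
        lines.append(" " + " ".join(n for j, n in enumerate(self.var_names) if self.integrality[j]))
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass
class IlpSolution:
    status: str  # optimal | feasible_timeout | infeasible | error
    distance: float
    matching: Matching | None
    stats: MatchingStats | None
    solve_seconds: float
    solver_objective: float | None = None

    @property
    def cycles(self) -> int:
        return self.stats.cycles if self.stats else 0

    @property
    def singletons(self) -> frozenset[str]:
        if self.matching is None:
            return frozenset()
        return self.matching.unmatched_a | self.matching.unmatched_b

    @property
    def blocks(self) -> int:
        return self.stats.blocks if self.stats else 0


@dataclass
class HomologyPairs:
    """Pooled homolog pairs of one genome pair, with per-pair provenance."""

    genome_a: str
    genome_b: str
    pairs: frozenset[tuple[str, str]]
    source: dict[tuple[str, str], str]  # trivial | ilp | timeout-fallback
    distance: float | None = None
    stats: MatchingStats | None = None
    ilp_stats: dict[str, int] = field(default_factory=dict)


def formulate(
    component: Component | RearrangementInstance,
    alpha: float = DEFAULT_ALPHA,
    indel: bool = True,
    forced_edges: frozenset[tuple[str, str]] = frozenset(),
) -> IlpInstance:
    """Materialize the MILP for a component (or a full pair instance).

    ``forced_edges`` pins matching variables to 1 — used to freeze the
    trivially matched context genes around a component so that the cycle
    structure sees the true neighborhood.
    """
    if not 0.0 <= alpha <= 1.0:
        raise IlpError(f"alpha must lie in [0,1], got {alpha}")
    inst = component.instance if isinstance(component, Component) else component
    if not inst.edges:
        raise IlpError("cannot formulate an ILP for a component without similarity edges")

    edge_list = inst.edges
    genes: list[tuple[str, str]] = []  # (gene_id, side)
    contigs: list[tuple[str, tuple[tuple[str, str], ...]]] = []  # (side, contig)
    for side, orders in (("A", inst.orders_a), ("B", inst.orders_b)):
        for contig in orders:
            contigs.append((side, contig))
            genes.extend((g, side) for g, _ in contig)
    gene_ids = [g for g, _ in genes]
    gene_col_offset: dict[str, int] = {}

    # adjacency vertices: one per consecutive gene pair of each circular contig
    ext_vertex: dict[tuple[str, str], int] = {}
    n_vertices = 0
    for _side, contig in contigs:
        k = len(contig)
        for i in range(k):
            g, s = contig[i]
            gn, sn = contig[(i + 1) % k]
            v = n_vertices
            n_vertices += 1
            ext_vertex[right_extremity(g, s)] = v
            ext_vertex[left_extremity(gn, sn)] = v

    n_edges = len(edge_list)
    n_genes = len(genes)
    n_contigs = len(contigs)
    # columns: x | s | b | y | z | contig-all-singleton
    off_x = 0
    off_s = off_x + n_edges
    off_b = off_s + n_genes
    off_y = off_b + n_genes
    off_z = off_y + n_vertices
    off_ac = off_z + n_vertices
    n_vars = off_ac + n_contigs
    for i, g in enumerate(gene_ids):
        gene_col_offset[g] = i

    var_names = (
        [f"x_{a}__{b}" for a, b, _ in edge_list]
        + [f"s_{g}" for g in gene_ids]
        + [f"b_{g}" for g in gene_ids]
        + [f"y_{v}" for v in range(n_vertices)]
        + [f"z_{v}" for v in range(n_vertices)]
        + [f"w_{ci}" for ci in range(n_contigs)]
    )

    lower = np.zeros(n_vars)
    upper = np.ones(n_vars)
    for ei, (a, b, _w) in enumerate(edge_list):
        if (a, b) in forced_edges:
            lower[ei] = 1.0
    integrality = np.zeros(n_vars)
    integrality[off_x : off_s + n_genes] = 1  # x and s binary
    integrality[off_z : off_z + n_vertices] = 1  # z binary
    for v in range(n_vertices):
        upper[off_y + v] = v + 1  # 1-based label bound

    rows: list[tuple[dict[int, float], float, float]] = []  # (coeffs, lb, ub)
    big_m = float(n_vertices)

    # s_g + sum x_e = 1 per gene
    incident: dict[str, list[int]] = {g: [] for g in gene_ids}
    for ei, (a, b, _w) in enumerate(edge_list):
        incident[a].append(ei)
        incident[b].append(ei)
    for gi, g in enumerate(gene_ids):
        coeffs = {off_s + gi: 1.0}
        for ei in incident[g]:
            coeffs[off_x + ei] = coeffs.get(off_x + ei, 0.0) + 1.0
        rows.append((coeffs, 1.0, 1.0))

    # maximum-cardinality equality
    msize = max_matching_size(inst)
    rows.append(({off_x + ei: 1.0 for ei in range(n_edges)}, float(msize), float(msize)))

    # blocks: b_g - s_g + s_next >= 0 per gene; per contig sum(b) - sum(s) >= -(k-1)
    gi = 0
    for _side, contig in contigs:
        k = len(contig)
        base = gi
        for i in range(k):
            nxt = base + (i + 1) % k
            if nxt != base + i:
                rows.append(
                    (
                        {off_b + base + i: 1.0, off_s + base + i: -1.0, off_s + nxt: 1.0},
                        0.0,
                        np.inf,
                    )
                )
        rows.append(
            (
                {
                    **{off_b + base + i: 1.0 for i in range(k)},
                    **{off_s + base + i: -1.0 for i in range(k)},
                },
                -float(k - 1),
                np.inf,
            )
        )
        gi += k

    # label equalization along matching links (head-head, tail-tail) ...
    def add_link(u: int, v: int, act_col: int) -> None:
        if u == v:
            return
        rows.append(({off_y + u: 1.0, off_y + v: -1.0, act_col: big_m}, -np.inf, big_m))
        rows.append(({off_y + v: 1.0, off_y + u: -1.0, act_col: big_m}, -np.inf, big_m))

    for ei, (a, b, _w) in enumerate(edge_list):
        add_link(ext_vertex[(a, "h")], ext_vertex[(b, "h")], off_x + ei)
        add_link(ext_vertex[(a, "t")], ext_vertex[(b, "t")], off_x + ei)
    # ... and along self-edges of singletons
    for gi2, g in enumerate(gene_ids):
        add_link(ext_vertex[(g, "h")], ext_vertex[(g, "t")], off_s + gi2)

    # representative may rise only to a vertex attaining its own index
    for v in range(n_vertices):
        rows.append(({off_y + v: 1.0, off_z + v: -float(v + 1)}, 0.0, np.inf))

    # all-singleton contig indicator: sum(s) - a_C <= k - 1
    gi = 0
    for ci, (_side, contig) in enumerate(contigs):
        k = len(contig)
        rows.append(
            (
                {**{off_s + gi + i: -1.0 for i in range(k)}, off_ac + ci: 1.0},
                -float(k - 1),
                np.inf,
            )
        )
        gi += k

    # objective: minimize -(1-a) w x + a b - a z + a a_C (+ constant)
    objective = np.zeros(n_vars)
    for ei, (_a, _b, w) in enumerate(edge_list):
        objective[off_x + ei] = -(1.0 - alpha) * w
    if indel:
        objective[off_b : off_b + n_genes] = alpha
    objective[off_z : off_z + n_vertices] = -alpha
    objective[off_ac : off_ac + n_contigs] = alpha

    n_singletons = n_genes - 2 * msize
    constant = alpha * msize + (1.0 - alpha) * msize
    if indel:
        constant += alpha * n_singletons

    data, ri, ci_idx, lbs, ubs = [], [], [], [], []
    for r, (coeffs, lb, ub) in enumerate(rows):
        for col, val in coeffs.items():
            ri.append(r)
            ci_idx.append(col)
            data.append(val)
        lbs.append(lb)
        ubs.append(ub)
    mat = csr_matrix((data, (ri, ci_idx)), shape=(len(rows), n_vars))
    constraints = [LinearConstraint(mat, np.array(lbs), np.array(ubs))]

    return IlpInstance(
        instance=inst,
        alpha=alpha,
        indel=indel,
        max_matching_size=msize,
        edge_list=edge_list,
        n_vars=n_vars,
        objective=objective,
        constant=constant,
        integrality=integrality,
        lower=lower,
        upper=upper,
        constraints=constraints,
        x_cols={(a, b): off_x + ei for ei, (a, b, _w) in enumerate(edge_list)},
        var_names=var_names,
    )


def solve(ilp: IlpInstance, time_limit_s: float = DEFAULT_TIME_LIMIT_S) -> IlpSolution:
    """Run the MILP and decode the matching; the reported distance is always
    recomputed from the decoded matching with the independent evaluator, and
    for optimal solves asserted against the solver objective (1e-6)."""
    t0 = time.perf_counter()
    res = milp(
        c=ilp.objective,
        constraints=ilp.constraints,
        integrality=ilp.integrality,
        bounds=Bounds(ilp.lower, ilp.upper),
        options={"time_limit": float(time_limit_s), "mip_rel_gap": 0.0},
    )
    elapsed = time.perf_counter() - t0

    if res.status == 2:
        return IlpSolution("infeasible", float("nan"), None, None, elapsed)
    if res.x is None:
        status = "feasible_timeout" if res.status == 1 else "error"
        return IlpSolution(status, float("nan"), None, None, elapsed)

    pairs = [key for key, col in ilp.x_cols.items() if res.x[col] > 0.5]
    matching = make_matching(ilp.instance, pairs)
    stats = evaluate_matching(ilp.instance, matching)
    distance = stats.distance(ilp.alpha, indel=ilp.indel)
    status = "optimal" if res.status == 0 else "feasible_timeout"
    solver_obj = float(res.fun) + ilp.constant
    if status == "optimal" and abs(solver_obj - distance) > 1e-6:
        raise IlpError(
            f"solver objective {solver_obj} disagrees with recomputed distance {distance}"
        )
    return IlpSolution(status, distance, matching, stats, elapsed, solver_objective=solver_obj)


def _greedy_matching(component: Component) -> list[tuple[str, str]]:
    """Maximum-weight greedy fallback when the solver returns no incumbent."""
    chosen: list[tuple[str, str]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for a, b, _w in sorted(component.instance.edges, key=lambda e: (-e[2], e[0], e[1])):
        if a not in used_a and b not in used_b:
            chosen.append((a, b))
            used_a.add(a)
            used_b.add(b)
    return chosen


def pairwise_refine(
    genome_a: Genome,
    genome_b: Genome,
    weighted_edges: Iterable[WeightedEdge],
    alpha: float = DEFAULT_ALPHA,
    time_limit_s: float = DEFAULT_TIME_LIMIT_S,
    indel: bool = True,
    decompose: bool = True,
    keep_ilps_dir: str | Path | None = None,
) -> HomologyPairs:
    """Derive homolog pairs between two genomes.

    The similarity graph is split into connected components; single-edge
    components are accepted directly ("trivial"), isolated genes are forced
    singletons, and every other component is solved as its own sub-ILP with
    the surrounding context frozen. With ``decompose=False`` the whole graph
    is solved as one ILP (exact, but only practical for small instances).

    The reported ``distance`` is the full-pair distance of the pooled
    matching, evaluated on the complete (undecomposed) instance.
    """
    gs = build_gs_graph(genome_a, genome_b, weighted_edges)
    full_inst = gs.instance
    pooled: list[tuple[str, str]] = []
    source: dict[tuple[str, str], str] = {}
    counters = {"n_trivial": 0, "n_ilp": 0, "n_timeout": 0, "n_singleton_components": 0}

    components = gs_components(gs)
    if not decompose:
        nontrivial = [c for c in components if c.n_edges > 0]
        counters["n_singleton_components"] = len(components) - len(nontrivial)
        if nontrivial:
            merged_genes = {g for c in nontrivial for g in c.a_genes + c.b_genes}
            whole = full_inst.restrict(merged_genes)
            ilp = formulate(whole, alpha=alpha, indel=indel)
            _maybe_dump(ilp, keep_ilps_dir, "full")
            sol = solve(ilp, time_limit_s=time_limit_s)
            counters["n_ilp"] += 1
            if sol.matching is not None:
                for p in sorted(sol.matching.pairs):
                    pooled.append(p)
                    source[p] = "ilp"
            else:
                counters["n_timeout"] += 1
    else:
        # first pass: direct one-to-one mappings become the frozen context
        nontrivial: list[Component] = []
        frozen: set[tuple[str, str]] = set()
        for comp in components:
            if comp.n_edges == 0:
                counters["n_singleton_components"] += 1
            elif is_trivial_component(comp):
                pair = (comp.instance.edges[0][0], comp.instance.edges[0][1])
                pooled.append(pair)
                source[pair] = "trivial"
                frozen.add(pair)
                counters["n_trivial"] += 1
            else:
                nontrivial.append(comp)
        context_genes = {g for pair in frozen for g in pair}
        # second pass: each sub-ILP keeps the trivially matched neighbors as
        # pinned anchors; genes of other unsolved components are contracted
        for comp in nontrivial:
            comp_genes = set(comp.a_genes) | set(comp.b_genes)
            comp_edges = {(a, b) for a, b, _w in comp.instance.edges}
            sub = full_inst.restrict(comp_genes | context_genes)
            ilp = formulate(sub, alpha=alpha, indel=indel, forced_edges=frozenset(frozen))
            _maybe_dump(ilp, keep_ilps_dir, comp.key)
            sol = solve(ilp, time_limit_s=time_limit_s)
            counters["n_ilp"] += 1
            if sol.matching is not None:
                tag = "ilp" if sol.status == "optimal" else "timeout-fallback"
                if sol.status != "optimal":
                    counters["n_timeout"] += 1
                for p in sorted(sol.matching.pairs):
                    if p in comp_edges:
                        pooled.append(p)
                        source[p] = tag
            else:
                counters["n_timeout"] += 1
                for p in _greedy_matching(comp):
                    pooled.append(p)
                    source[p] = "timeout-fallback"

    matching = make_matching(full_inst, pooled)
    stats = evaluate_matching(full_inst, matching)
    return HomologyPairs(
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        pairs=frozenset(pooled),
        source=source,
        distance=stats.distance(alpha, indel=indel),
        stats=stats,
        ilp_stats=counters,
    )


def _maybe_dump(ilp: IlpInstance, out_dir: str | Path | None, tag: str) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    safe = "".join(ch if ch.isalnum() or ch in "-._" else "_" for ch in tag)
    (out_dir / f"component_{safe}.lp").write_text(ilp.to_lp_text())
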