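"""One-to-one ortholog assignment between two genomes.

Candidate gene pairs come from tabular similarity hits filtered by E-value
(<= 1e-3), percent identity (> 30) and COG-category compatibility.  Among the
candidates a one-to-one matching is chosen that maximizes

    sum over chosen pairs of a * s(pair)
      - b * (number of distinct operons of genome B touched)
      - c * (number of distinct operons of genome A touched)

where ``s`` is the hit score normalised by the best candidate score of the
genome pair (configurable to the raw score).  The operon terms reward
matchings whose orthologs are grouped into few operons - the structural
parsimony constraint.  Genes outside any annotated operon count as singleton
operon units.  Default weights are a=1.0, b=0.5, c=0.5.

The solver decomposes the candidate graph (similarity edges plus operon
co-membership) into connected components.  Components touching few operons
are solved exactly by enumerating operon-activation subsets with a maximum
weight bipartite matching per subset; larger components are solved by local
search (add/drop/replace/2-swap moves) seeded from the unconstrained optimal
matching.  ``brute_force_orthologs`` enumerates all matchings and is the
test oracle for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genome_model import AnnotatedGenome, SimilarityHit

_EPS = 1e-12


@dataclass(frozen=True)
class OrthoWeights:
    """Objective weights: similarity scale ``a``, operon penalties ``b, c``."""

    a: float = 1.0
    b: float = 0.5
    c: float = 0.5

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0 or self.c < 0:
            raise ValueError("weights must satisfy a > 0, b >= 0, c >= 0")


@dataclass
class OrthologMap:
    """A one-to-one gene pairing between two genomes with its evidence."""

    genome_a_id: str
    genome_b_id: str
    pairs: list[tuple[str, str]]
    evidence: dict[tuple[str, str], SimilarityHit] = field(default_factory=dict)
    objective_value: float = 0.0

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs)
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("ortholog map is not one-to-one")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def genes_of(self, genome_id: str) -> set[str]:
        if genome_id == self.genome_a_id:
            return {p[0] for p in self.pairs}
        if genome_id == self.genome_b_id:
            return {p[1] for p in self.pairs}
        raise KeyError(genome_id)

    def swapped(self) -> "OrthologMap":
        return OrthologMap(
            genome_a_id=self.genome_b_id,
            genome_b_id=self.genome_a_id,
            pairs=[(b, a) for a, b in self.pairs],
            evidence={(b, a): h for (a, b), h in self.evidence.items()},
            objective_value=self.objective_value,
        )


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def candidate_hits(
    hits: Iterable[SimilarityHit],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    *,
    evalue_max: float = 1e-3,
    min_identity: Optional[float] = 30.0,
    cog_filter: bool = True,
) -> list[SimilarityHit]:
    """Filter hits to candidate ortholog pairs.

    Keeps hits with E-value <= ``evalue_max`` and identity > ``min_identity``
    (pass ``min_identity=None`` to disable the identity cut); drops hits whose
    genes carry two *different* COG categories (genes without a COG annotation
    always pass the COG filter).  One best-scoring hit per gene pair is kept.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.evalue > evalue_max:
            continue
        if min_identity is not None and h.identity <= min_identity:
            continue
        ga = genome_a.gene(h.gene_a)
        gb = genome_b.gene(h.gene_b)
        if cog_filter and ga.cog and gb.cog and ga.cog != gb.cog:
            continue
        key = (h.gene_a, h.gene_b)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# Objective bookkeeping
# ---------------------------------------------------------------------------

def _edge_scores(
    candidates: Sequence[SimilarityHit], weights: OrthoWeights, score_mode: str
) -> dict[tuple[str, str], float]:
    if score_mode not in ("normalized", "raw"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    if not candidates:
        return {}
    if score_mode == "normalized":
        max_score = max(h.score for h in candidates)
        return {(h.gene_a, h.gene_b): h.score / max_score for h in candidates}
    return {(h.gene_a, h.gene_b): h.score for h in candidates}


def matching_objective(
    pairs: Iterable[tuple[str, str]],
    scores: Mapping[tuple[str, str], float],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    weights: OrthoWeights,
) -> float:
    """Objective value of an arbitrary one-to-one pair set."""
    pairs = list(pairs)
    sim = sum(weights.a * scores[p] for p in pairs)
    ops_a = {genome_a.operon_of(p[0]) for p in pairs}
    ops_b = {genome_b.operon_of(p[1]) for p in pairs}
    return sim - weights.b * len(ops_b) - weights.c * len(ops_a)


# ---------------------------------------------------------------------------
# Exact solution of one component by operon-activation enumeration
# ---------------------------------------------------------------------------

def _lap_max(
    a_genes: Sequence[str],
    b_genes: Sequence[str],
    edges: Mapping[tuple[str, str], float],
) -> tuple[float, list[tuple[str, str]]]:
    """Maximum-weight bipartite matching over the given edges (scores > 0)."""
    if not edges:
        return 0.0, []
    mat = np.zeros((len(a_genes), len(b_genes)))
    ai = {g: i for i, g in enumerate(a_genes)}
    bi = {g: i for i, g in enumerate(b_genes)}
    for (ga, gb), s in edges.items():
        mat[ai[ga], bi[gb]] = s
    rows, cols = linear_sum_assignment(mat, maximize=True)
    pairs = [
        (a_genes[r], b_genes[c]) for r, c in zip(rows, cols) if mat[r, c] > 0.0
    ]
    total = float(sum(mat[r, c] for r, c in zip(rows, cols)))
    return total, pairs


def _solve_component_exact(
    a_genes: list[str],
    b_genes: list[str],
    edges: dict[tuple[str, str], float],
    op_a: Mapping[str, str],
    op_b: Mapping[str, str],
    weights: OrthoWeights,
) -> tuple[float, list[tuple[str, str]]]:
    """Enumerate operon-activation subsets; exact for any component.

    For activation sets (SA, SB) the best matching restricted to genes whose
    operons are activated, minus b*|SB| + c*|SA|, lower-bounds the true
    objective of that matching; the maximum over all subsets equals the global
    optimum because the optimal matching's own touched-operon sets appear in
    the enumeration.
    """
    ops_a = sorted({op_a[g] for g in a_genes})
    ops_b = sorted({op_b[g] for g in b_genes})
    best_obj, best_pairs, best_n = 0.0, [], 0
    for mask_a in range(1 << len(ops_a)):
        sa = {ops_a[i] for i in range(len(ops_a)) if mask_a >> i & 1}
        pen_a = weights.c * len(sa)
        allowed_a = [g for g in a_genes if op_a[g] in sa]
        for mask_b in range(1 << len(ops_b)):
            sb = {ops_b[i] for i in range(len(ops_b)) if mask_b >> i & 1}
            sub = {
                (ga, gb): weights.a * s
                for (ga, gb), s in edges.items()
                if op_a[ga] in sa and op_b[gb] in sb
            }
            if not sub and (sa or sb):
                continue
            allowed_b = [g for g in b_genes if op_b[g] in sb]
            total, pairs = _lap_max(allowed_a, allowed_b, sub)
            obj = total - weights.b * len(sb) - pen_a
            key = (obj, len(pairs))
            if key > (best_obj + _EPS, best_n) or (
                abs(obj - best_obj) <= _EPS and len(pairs) > best_n
            ):
                best_obj, best_pairs, best_n = obj, pairs, len(pairs)
    return best_obj, sorted(best_pairs)


# ---------------------------------------------------------------------------
# Local search for large components
# ---------------------------------------------------------------------------

class _SearchState:
    """Incremental matching state with operon occupancy counters."""

    def __init__(self, op_a, op_b, weights):
        self.op_a, self.op_b, self.w = op_a, op_b, weights
        self.match_a: dict[str, str] = {}
        self.match_b: dict[str, str] = {}
        self.occ_a: dict[str, int] = {}
        self.occ_b: dict[str, int] = {}
        self.sim = 0.0
        self.pen = 0.0

    @property
    def objective(self) -> float:
        return self.sim - self.pen

    def delta_add(self, ga: str, gb: str, s: float) -> float:
        d = self.w.a * s
        if self.occ_a.get(self.op_a[ga], 0) == 0:
            d -= self.w.c
        if self.occ_b.get(self.op_b[gb], 0) == 0:
            d -= self.w.b
        return d

    def delta_drop(self, ga: str, gb: str, s: float) -> float:
        d = -self.w.a * s
        if self.occ_a[self.op_a[ga]] == 1:
            d += self.w.c
        if self.occ_b[self.op_b[gb]] == 1:
            d += self.w.b
        return d

    def add(self, ga: str, gb: str, s: float) -> None:
        self.sim += self.w.a * s
        oa, ob = self.op_a[ga], self.op_b[gb]
        if self.occ_a.get(oa, 0) == 0:
            self.pen += self.w.c
        if self.occ_b.get(ob, 0) == 0:
            self.pen += self.w.b
        self.occ_a[oa] = self.occ_a.get(oa, 0) + 1
        self.occ_b[ob] = self.occ_b.get(ob, 0) + 1
        self.match_a[ga] = gb
        self.match_b[gb] = ga

    def drop(self, ga: str, gb: str, s: float) -> None:
        self.sim -= self.w.a * s
        oa, ob = self.op_a[ga], self.op_b[gb]
        self.occ_a[oa] -= 1
        self.occ_b[ob] -= 1
        if self.occ_a[oa] == 0:
            self.pen -= self.w.c
        if self.occ_b[ob] == 0:
            self.pen -= self.w.b
        del self.match_a[ga]
        del self.match_b[gb]


def _solve_component_local(
    a_genes: list[str],
    b_genes: list[str],
    edges: dict[tuple[str, str], float],
    op_a: Mapping[str, str],
    op_b: Mapping[str, str],
    weights: OrthoWeights,
    max_passes: int = 20,
) -> tuple[float, list[tuple[str, str]]]:
    """First-improvement local search seeded from the unconstrained optimum.

    Add moves also accept zero-delta steps (pair count grows, so no cycling),
    which keeps fully tied instances - e.g. identical genomes with uniform
    self-hit scores - at the complete matching rather than the empty one.
    """
    _, seed_pairs = _lap_max(a_genes, b_genes, edges)
    state = _SearchState(op_a, op_b, weights)
    for ga, gb in seed_pairs:
        state.add(ga, gb, edges[(ga, gb)])

    edge_list = sorted(edges)
    for _ in range(max_passes):
        improved = False
        # drop strictly improving pairs
        for ga, gb in sorted(state.match_a.items()):
            if state.delta_drop(ga, gb, edges[(ga, gb)]) > _EPS:
                state.drop(ga, gb, edges[(ga, gb)])
                improved = True
        # drop a whole operon's pairs when the group jointly fails to pay
        # for the operons it opens (single-pair drops cannot see this)
        for side in ("A", "B"):
            groups: dict[str, list[tuple[str, str]]] = {}
            for ga, gb in state.match_a.items():
                op = op_a[ga] if side == "A" else op_b[gb]
                groups.setdefault(op, []).append((ga, gb))
            for op in sorted(groups):
                before = state.objective
                for ga, gb in groups[op]:
                    state.drop(ga, gb, edges[(ga, gb)])
                if state.objective > before + _EPS:
                    improved = True
                else:
                    for ga, gb in groups[op]:
                        state.add(ga, gb, edges[(ga, gb)])
        # add free edges (ties accepted: prefer larger matchings)
        for ga, gb in edge_list:
            if ga not in state.match_a and gb not in state.match_b:
                if state.delta_add(ga, gb, edges[(ga, gb)]) >= -_EPS:
                    state.add(ga, gb, edges[(ga, gb)])
                    improved = True
        # replace: route a matched gene to a better partner
        for ga, gb in edge_list:
            s_new = edges[(ga, gb)]
            if ga in state.match_a and state.match_a[ga] != gb and gb not in state.match_b:
                old = state.match_a[ga]
                d = state.delta_drop(ga, old, edges[(ga, old)])
                state.drop(ga, old, edges[(ga, old)])
                d += state.delta_add(ga, gb, s_new)
                if d > _EPS:
                    state.add(ga, gb, s_new)
                    improved = True
                else:
                    state.add(ga, old, edges[(ga, old)])
            elif gb in state.match_b and state.match_b[gb] != ga and ga not in state.match_a:
                old = state.match_b[gb]
                d = state.delta_drop(old, gb, edges[(old, gb)])
                state.drop(old, gb, edges[(old, gb)])
                d += state.delta_add(ga, gb, s_new)
                if d > _EPS:
                    state.add(ga, gb, s_new)
                    improved = True
                else:
                    state.add(old, gb, edges[(old, gb)])
        # 2-swap partner exchange
        matched = sorted(state.match_a.items())
        for (a1, b1), (a2, b2) in itertools.combinations(matched, 2):
            if a1 not in state.match_a or a2 not in state.match_a:
                continue
            if state.match_a[a1] != b1 or state.match_a[a2] != b2:
                continue
            if (a1, b2) in edges and (a2, b1) in edges:
                before = state.objective
                state.drop(a1, b1, edges[(a1, b1)])
                state.drop(a2, b2, edges[(a2, b2)])
                state.add(a1, b2, edges[(a1, b2)])
                state.add(a2, b1, edges[(a2, b1)])
                if state.objective > before + _EPS:
                    improved = True
                else:
                    state.drop(a1, b2, edges[(a1, b2)])
                    state.drop(a2, b1, edges[(a2, b1)])
                    state.add(a1, b1, edges[(a1, b1)])
                    state.add(a2, b2, edges[(a2, b2)])
        if not improved:
            break
    return state.objective, sorted(state.match_a.items())


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------

def _components(
    edges: Mapping[tuple[str, str], float],
    op_a: Mapping[str, str],
    op_b: Mapping[str, str],
):
    """Connected components of the candidate graph; operon co-membership
    couples genes through the penalty terms and therefore joins components."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    by_op_a: dict[str, list[str]] = {}
    by_op_b: dict[str, list[str]] = {}
    for ga, gb in edges:
        union(("A", ga), ("B", gb))
        by_op_a.setdefault(op_a[ga], []).append(ga)
        by_op_b.setdefault(op_b[gb], []).append(gb)
    for members in by_op_a.values():
        for g in members[1:]:
            union(("A", members[0]), ("A", g))
    for members in by_op_b.values():
        for g in members[1:]:
            union(("B", members[0]), ("B", g))

    comps: dict[tuple[str, str], dict] = {}
    for (ga, gb) in edges:
        root = find(("A", ga))
        comp = comps.setdefault(root, {"a": set(), "b": set(), "edges": {}})
        comp["a"].add(ga)
        comp["b"].add(gb)
        comp["edges"][(ga, gb)] = edges[(ga, gb)]
    return [comps[k] for k in sorted(comps)]


def assign_orthologs(
    candidates: Sequence[SimilarityHit],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    weights: OrthoWeights = OrthoWeights(),
    *,
    score_mode: str = "normalized",
    exact_operon_limit: int = 12,
    method: str = "auto",
) -> OrthologMap:
    """Solve the constrained assignment over pre-filtered candidates.

    ``method``: "auto" (exact per component when the component touches at
    most ``exact_operon_limit`` operons, local search otherwise), "exact",
    or "local".
    """
    scores = _edge_scores(candidates, weights, score_mode)
    evidence = {(h.gene_a, h.gene_b): h for h in candidates}
    op_a = {h.gene_a: genome_a.operon_of(h.gene_a) for h in candidates}
    op_b = {h.gene_b: genome_b.operon_of(h.gene_b) for h in candidates}

    if weights.b == 0.0 and weights.c == 0.0:
        # pure maximum-weight matching; operon structure is irrelevant
        a_genes = sorted({h.gene_a for h in candidates})
        b_genes = sorted({h.gene_b for h in candidates})
        total, pairs = _lap_max(
            a_genes, b_genes, {k: weights.a * s for k, s in scores.items()}
        )
        return OrthologMap(
            genome_a.id, genome_b.id, pairs,
            evidence={p: evidence[p] for p in pairs},
            objective_value=total,
        )

    objective = 0.0
    all_pairs: list[tuple[str, str]] = []
    for comp in _components(scores, op_a, op_b):
        a_genes = sorted(comp["a"])
        b_genes = sorted(comp["b"])
        n_ops = len({op_a[g] for g in a_genes}) + len({op_b[g] for g in b_genes})
        use_exact = method == "exact" or (method == "auto" and n_ops <= exact_operon_limit)
        solver = _solve_component_exact if use_exact else _solve_component_local
        obj, pairs = solver(a_genes, b_genes, comp["edges"], op_a, op_b, weights)
        objective += obj
        all_pairs.extend(pairs)

    return OrthologMap(
        genome_a.id, genome_b.id, all_pairs,
        evidence={p: evidence[p] for p in all_pairs},
        objective_value=objective,
    )


def greedy_orthologs(
    candidates: Sequence[SimilarityHit],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    weights: OrthoWeights = OrthoWeights(),
    *,
    score_mode: str = "normalized",
) -> OrthologMap:
    """Greedy best-score-first matching (baseline; used in property tests)."""
    scores = _edge_scores(candidates, weights, score_mode)
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for (ga, gb) in sorted(scores, key=lambda k: (-scores[k], k)):
        if ga not in used_a and gb not in used_b:
            pairs.append((ga, gb))
            used_a.add(ga)
            used_b.add(gb)
    obj = matching_objective(pairs, scores, genome_a, genome_b, weights)
    evidence = {(h.gene_a, h.gene_b): h for h in candidates}
    return OrthologMap(genome_a.id, genome_b.id, pairs,
                       evidence={p: evidence[p] for p in pairs},
                       objective_value=obj)


def brute_force_orthologs(
    candidates: Sequence[SimilarityHit],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    weights: OrthoWeights = OrthoWeights(),
    *,
    score_mode: str = "normalized",
    max_genes: int = 8,
) -> OrthologMap:
    """Globally optimal matching by exhaustive enumeration (test oracle).

    Enumerates every one-to-one matching over the candidate edges; only
    feasible for instances with at most ``max_genes`` genes per side.
    """
    scores = _edge_scores(candidates, weights, score_mode)
    a_genes = sorted({h.gene_a for h in candidates})
    b_genes = sorted({h.gene_b for h in candidates})
    if len(a_genes) > max_genes or len(b_genes) > max_genes:
        raise ValueError(
            f"instance too large for brute force ({len(a_genes)}x{len(b_genes)})"
        )
    adj: dict[str, list[str]] = {ga: [] for ga in a_genes}
    for ga, gb in sorted(scores):
        adj[ga].append(gb)

    best = {"obj": 0.0, "n": 0, "pairs": []}

    def recurse(i: int, used_b: set[str], pairs: list[tuple[str, str]]):
        if i == len(a_genes):
            obj = matching_objective(pairs, scores, genome_a, genome_b, weights)
            if (obj > best["obj"] + _EPS
                    or (abs(obj - best["obj"]) <= _EPS and len(pairs) > best["n"])):
                best.update(obj=obj, n=len(pairs), pairs=list(pairs))
            return
        ga = a_genes[i]
        recurse(i + 1, used_b, pairs)  # leave ga unmatched
        for gb in adj[ga]:
            if gb not in used_b:
                used_b.add(gb)
                pairs.append((ga, gb))
                recurse(i + 1, used_b, pairs)
                pairs.pop()
                used_b.remove(gb)

    recurse(0, set(), [])
    evidence = {(h.gene_a, h.gene_b): h for h in candidates}
    return OrthologMap(genome_a.id, genome_b.id, best["pairs"],
                       evidence={p: evidence[p] for p in best["pairs"]},
                       objective_value=best["obj"])


# ---------------------------------------------------------------------------
# Panel-level bookkeeping
# ---------------------------------------------------------------------------

def ortholog_count_table(
    panel: Sequence[AnnotatedGenome],
    maps: Mapping[tuple[str, str], OrthologMap],
) -> dict[tuple[str, str], int]:
    """For every gene, the number of other panel genomes in which it has an
    ortholog (range 0 .. panel size - 1).  Keys are (genome_id, gene_id)."""
    counts = {(g.id, gene.id): 0 for g in panel for gene in g.genes}
    ids = sorted(g.id for g in panel)
    for ga, gb in itertools.combinations(ids, 2):
        if (ga, gb) not in maps:
            raise KeyError(f"missing ortholog map for pair ({ga}, {gb})")
        m = maps[(ga, gb)]
        for gene_a, gene_b in m.pairs:
            counts[(m.genome_a_id, gene_a)] += 1
            counts[(m.genome_b_id, gene_b)] += 1
    return counts


def write_ortholog_map(m: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for ga, gb in m.pairs:
            h = m.evidence.get((ga, gb))
            fh.write(f"{ga}\t{gb}\t{h.score:g}\n" if h else f"{ga}\t{gb}\t\n")
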