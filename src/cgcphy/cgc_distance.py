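"""Conserved orthologous gene clusters and the CGC distance.

A conserved cluster is a chain of ortholog pairs whose gene indices advance
by +1 on genome A and by +1 (forward) or -1 (inverted) on genome B, except
that a bounded number of insertion/deletion events may be absorbed: at most
``max_gap_events`` times per cluster, one side may jump over up to
``max_gap_len`` genes while the other side stays consecutive.  Orientation is
uniform within a cluster and chains shorter than ``min_cluster_size`` are
discarded.

Chains are found by optimal segmentation of the A-sorted pair list with
dynamic programming: maximize the number of orthologous genes covered by
clusters; ties favour fewer gap events, then fewer clusters.  (A simple
greedy left-to-right scan is not used: on the canonical 16-gene worked
example it would absorb the start of the second indel cluster into the first
and strand its tail below the minimum size, under-counting the clustered
genes.)

The pairwise distance is D_cgc(X,Y) = -log10(N_cgc), where N_cgc is the
total number of orthologous genes lying in conserved clusters; more shared
collinear genes means a smaller (more negative) distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_model import AnnotatedGenome
from .orthology import OrthologMap


@dataclass(frozen=True)
class ClusterParams:
    """Chain tolerance parameters.

    Defaults (gap of at most 2 genes, one gap event per cluster, minimum
    cluster size 2) are the smallest values consistent with the published
    worked example of two 16-gene genomes with 14 orthologs in 4 clusters.
    """

    max_gap_len: int = 2
    max_gap_events: int = 1
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if self.max_gap_len < 0 or self.max_gap_events < 0 or self.min_cluster_size < 1:
            raise ValueError("cluster parameters must be non-negative")


@dataclass
class ConservedCluster:
    pairs: list[tuple[str, str]]
    orientation: str  # "forward" | "inverted"
    gap_events: int


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    #: clustered-ortholog counts per unordered pair, when built from maps
    counts: Optional[dict[tuple[str, str], int]] = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon list")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def _step_kind(da: int, db: int, orient: int, max_gap: int) -> Optional[str]:
    """Classify a step between consecutive chain pairs.

    ``orient`` is +1 (forward) or -1 (inverted); db is signed.  Returns
    "consec", "gap" or None (invalid).  A gap means one side jumps over
    1..max_gap genes while the other advances by exactly one.
    """
    if orient * db <= 0:
        return None
    step_b = orient * db
    if da == 1 and step_b == 1:
        return "consec"
    if da == 1 and 2 <= step_b <= max_gap + 1:
        return "gap"
    if step_b == 1 and 2 <= da <= max_gap + 1:
        return "gap"
    return None


def conserved_clusters(
    omap: OrthologMap,
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    params: ClusterParams = ClusterParams(),
) -> list[ConservedCluster]:
    """Detect conserved clusters in a one-to-one ortholog map.

    The segmentation is run along both genomes (chains must be contiguous in
    the walking order, and interleaved rearrangements can make one order see
    chains the other cannot); the cover with more clustered genes wins, with
    symmetric tie-breaks, so the result is independent of which genome is
    called A.
    """
    if not omap.pairs:
        return []
    indexed = [
        (genome_a.gene(ga).index, genome_b.gene(gb).index, ga, gb)
        for ga, gb in omap.pairs
    ]
    a_first = genome_a.id <= genome_b.id

    def canon(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
        return sorted(pairs if a_first else [(gb, ga) for ga, gb in pairs])

    walk_a = _segment_cover(sorted(indexed), params)
    walk_b = _segment_cover(
        sorted((bi, ai, gb, ga) for ai, bi, ga, gb in indexed), params
    )
    # swap walk-B clusters back into (gene_a, gene_b) orientation
    walk_b = (walk_b[0], [
        ConservedCluster(pairs=[(ga, gb) for gb, ga in c.pairs],
                         orientation=c.orientation, gap_events=c.gap_events)
        for c in walk_b[1]
    ])
    candidates = []
    for rank, (score, clusters) in enumerate((walk_a, walk_b)):
        covered = canon([p for c in clusters for p in c.pairs])
        primary = (rank == 0) == a_first
        candidates.append((score, covered, primary, clusters))
    # max score; then the lexicographically smaller canonical cover; then the
    # walk along the genome whose id sorts first - all order-independent
    c1, c2 = candidates
    if c1[0] != c2[0]:
        best = c1 if c1[0] > c2[0] else c2
    elif c1[1] != c2[1]:
        best = c1 if c1[1] < c2[1] else c2
    else:
        best = c1 if c1[2] else c2
    return best[3]


def _segment_cover(
    idx_pairs: list[tuple[int, int, str, str]], params: ClusterParams
) -> tuple[tuple[int, int, int], list[ConservedCluster]]:
    """Optimal segmentation of one sorted pair list; returns the score
    (covered, -events, -clusters) and the clusters."""
    n = len(idx_pairs)
    ai = [p[0] for p in idx_pairs]
    bi = [p[1] for p in idx_pairs]

    # max_end[s]: longest valid chain starting at pair s over the contiguous
    # run of the sorted list; events[s][l] = gap events of chain s..s+l
    max_end = [s + 1 for s in range(n)]
    events: list[list[int]] = [[0] for _ in range(n)]
    for s in range(n):
        orient = 0
        ev = 0
        t = s
        while t + 1 < n:
            da = ai[t + 1] - ai[t]
            db = bi[t + 1] - bi[t]
            use_orient = orient if orient != 0 else (1 if db > 0 else -1)
            kind = _step_kind(da, db, use_orient, params.max_gap_len)
            if kind is None:
                break
            if kind == "gap":
                if ev + 1 > params.max_gap_events:
                    break
                ev += 1
            orient = use_orient
            t += 1
            events[s].append(ev)
        max_end[s] = t + 1

    # DP over the sorted pair list: score = (covered genes, -gap events,
    # -cluster count), maximized lexicographically
    NEG = (-1, 0, 0)
    best: list[tuple[int, int, int]] = [NEG] * (n + 1)
    back: list[Optional[tuple[int, bool]]] = [None] * (n + 1)
    best[0] = (0, 0, 0)
    for i in range(n):
        if best[i] == NEG:
            continue
        cov, negev, negcl = best[i]
        # leave pair i unclustered
        if (cov, negev, negcl) > best[i + 1]:
            best[i + 1] = (cov, negev, negcl)
            back[i + 1] = (i, False)
        # close a cluster [i, j)
        for j in range(i + params.min_cluster_size, max_end[i] + 1):
            ev = events[i][j - i - 1]
            cand = (cov + (j - i), negev - ev, negcl - 1)
            if cand > best[j]:
                best[j] = cand
                back[j] = (i, True)

    # reconstruct
    clusters: list[ConservedCluster] = []
    j = n
    while j > 0:
        i, is_cluster = back[j]
        if is_cluster:
            chain = idx_pairs[i:j]
            orient = 1
            for t in range(len(chain) - 1):
                db = chain[t + 1][1] - chain[t][1]
                if db != 0:
                    orient = 1 if db > 0 else -1
                    break
            clusters.append(
                ConservedCluster(
                    pairs=[(ga, gb) for _, _, ga, gb in chain],
                    orientation="forward" if orient > 0 else "inverted",
                    gap_events=events[i][j - i - 1],
                )
            )
        j = i
    clusters.reverse()
    return best[n], clusters


def n_cgc(clusters: Sequence[ConservedCluster]) -> int:
    """Total number of orthologous genes in conserved clusters."""
    return sum(len(c.pairs) for c in clusters)


def cgcd(n: int, *, zero_sentinel: float = 1.0) -> float:
    """CGC distance -log10(n); the sentinel (default +1.0, one decade beyond
    a single shared gene) is returned for n = 0 where the log is undefined."""
    if n < 0:
        raise ValueError("gene count must be non-negative")
    if n == 0:
        return zero_sentinel
    return -math.log10(n)


def distance_matrix(
    panel: Sequence[AnnotatedGenome],
    maps: Mapping[tuple[str, str], OrthologMap],
    params: ClusterParams = ClusterParams(),
    *,
    zero_sentinel: float = 1.0,
) -> DistanceMatrix:
    """Symmetric CGCD matrix over a panel; diagonal fixed at 0."""
    genomes = {g.id: g for g in panel}
    taxa = sorted(genomes)
    n = len(taxa)
    d = np.zeros((n, n))
    counts: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(n), 2):
        key = (taxa[i], taxa[j])
        if key not in maps:
            raise KeyError(f"missing ortholog map for pair {key}")
        m = maps[key]
        ga, gb = genomes[m.genome_a_id], genomes[m.genome_b_id]
        clusters = conserved_clusters(m, ga, gb, params)
        counts[key] = n_cgc(clusters)
        d[i, j] = d[j, i] = cgcd(counts[key], zero_sentinel=zero_sentinel)
    return DistanceMatrix(taxa=taxa, d=d, counts=counts)


def count_distance_matrix(
    panel: Sequence[AnnotatedGenome],
    maps: Mapping[tuple[str, str], OrthologMap],
    *,
    zero_sentinel: float = 1.0,
) -> DistanceMatrix:
    """-log10 of the raw ortholog count per pair (the degenerate case where
    every ortholog is its own cluster; used by the no-cluster ablation arm)."""
    taxa = sorted(g.id for g in panel)
    n = len(taxa)
    d = np.zeros((n, n))
    counts: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(n), 2):
        m = maps[(taxa[i], taxa[j])]
        counts[(taxa[i], taxa[j])] = m.n_pairs
        d[i, j] = d[j, i] = cgcd(m.n_pairs, zero_sentinel=zero_sentinel)
    return DistanceMatrix(taxa=taxa, d=d, counts=counts)


# ---------------------------------------------------------------------------
# Phylip square-matrix interchange
# ---------------------------------------------------------------------------

def write_phylip(dm: DistanceMatrix, path, *, relaxed: bool = False) -> None:
    """Write the classic Phylip square distance format.  In strict mode
    taxon names are truncated/padded to the 10-character field; ``relaxed``
    keeps full names separated by whitespace."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa):5d}\n")
        for i, name in enumerate(dm.taxa):
            label = f"{name}  " if relaxed else f"{name[:10]:<10s}"
            row = "  ".join(f"{v:.6f}" for v in dm.d[i])
            fh.write(f"{label}{row}\n")


def read_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    taxa: list[str] = []
    d = np.zeros((n, n))
    pos = 1
    for i in range(n):
        taxa.append(tokens[pos])
        pos += 1
        for j in range(n):
            d[i, j] = float(tokens[pos])
            pos += 1
    return DistanceMatrix(taxa=taxa, d=d)
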