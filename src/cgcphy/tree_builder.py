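"""Neighbor-joining tree construction and Newick interchange.

The Saitou-Nei agglomeration is implemented directly (rather than shelling
out to an external package) so that tie-breaking is deterministic: among
joins with equal Q-criterion the pair whose clusters contain the
lexicographically smallest leaf labels is chosen.  CGC distances are
legitimately negative (more shared clustered genes -> more negative), which
NJ handles without transformation; estimated negative branch lengths are
kept by default (logged) or clamped to zero on request.

Trees are dendropy ``Tree`` objects; NJ output is unrooted, represented with
a trifurcating seed node.
"""

from __future__ import annotations

import logging
from typing import Optional

import dendropy
import numpy as np

from .cgc_distance import DistanceMatrix

logger = logging.getLogger(__name__)


class TreeBuildError(ValueError):
    pass


def neighbor_joining(
    dm: DistanceMatrix, *, clamp_negative: bool = False
) -> dendropy.Tree:
    """Build an unrooted NJ tree from a symmetric zero-diagonal matrix."""
    n = len(dm.taxa)
    if n < 3:
        raise TreeBuildError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.d, dtype=float)
    if not np.allclose(d, d.T, atol=1e-9):
        raise TreeBuildError("distance matrix is not symmetric")

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # smallest contained leaf label, for tie-breaking
    for name in dm.taxa:
        taxon = ns.new_taxon(name)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        keys.append(name)

    active = list(range(n))
    D = d.copy()
    negative_seen = False

    def set_edge(node: dendropy.Node, length: float) -> float:
        nonlocal negative_seen
        if length < 0:
            negative_seen = True
            if clamp_negative:
                length = 0.0
        node.edge.length = float(length)
        return length

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = None
        for ii, jj in ties:
            if ii >= jj:
                continue
            cand = tuple(sorted((keys[active[ii]], keys[active[jj]])))
            if best is None or cand < best[0]:
                best = (cand, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = D[i, j]
        li = 0.5 * dij + (row_sums[ii] - row_sums[jj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        set_edge(nodes[i], li)
        set_edge(nodes[j], lj)

        # distances from the new node to all other active nodes
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # terminal join of the last three nodes around one internal node
    a, b, c = active
    root = dendropy.Node()
    for node in (nodes[a], nodes[b], nodes[c]):
        root.add_child(node)
    set_edge(nodes[a], 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    set_edge(nodes[b], 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    set_edge(nodes[c], 0.5 * (D[a, c] + D[b, c] - D[a, b]))

    tree.seed_node = root
    tree.is_rooted = False
    if negative_seen and not clamp_negative:
        logger.info("neighbor_joining: negative branch length(s) retained")
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# Newick interchange
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
    )


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises various parse errors
        raise TreeBuildError(f"malformed Newick in {path}: {exc}") from exc


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", real_value_format_specifier=".6f", suppress_rooting=True
    )


def tree_from_newick(s: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=s, schema="newick")
    except Exception as exc:
        raise TreeBuildError(f"malformed Newick string: {exc}") from exc


# ---------------------------------------------------------------------------
# Comparison helpers
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartition_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each edge's leaf-set bipartition (the smaller side, normalized)
    to its branch length; used for topology/length comparison."""
    all_leaves = frozenset(leaf_labels(tree))
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - below
        key = min(below, other, key=lambda s: (len(s), sorted(s)))
        length = node.edge.length or 0.0
        out[key] = out.get(key, 0.0) + length  # root-adjacent edges merge
    return out


def same_unrooted_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Unrooted topology equality via nontrivial bipartition sets."""
    if leaf_labels(t1) != leaf_labels(t2):
        return False
    b1 = {k for k in bipartition_lengths(t1) if 1 < len(k)}
    b2 = {k for k in bipartition_lengths(t2) if 1 < len(k)}
    return b1 == b2


def path_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(taxa=labels, d=d)
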