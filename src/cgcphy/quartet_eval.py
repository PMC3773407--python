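"""Quartet-topology agreement between an inferred tree and a reference.

The reference is typically a multifurcating rank tree built from Bergey-style
dotted codes (one internal node per distinct code prefix).  A quartet
{a,b,c,d} is *effective* when the reference resolves it, i.e. some reference
edge separates one pair from the other; star quartets are skipped.  Accuracy
is the fraction of effective quartets whose split matches the inferred tree.

Topologies are read off LCA depths: rooting a tree anywhere, the quartet is
ab|cd exactly when depth(lca(a,b)) + depth(lca(c,d)) strictly exceeds the
two crossing pairings' sums (which are always equal to each other); a
three-way tie means the quartet is unresolved.  Pairwise LCA depths are
precomputed in O(n^2), after which each quartet costs O(1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .genome_model import BergeyCode

_PAIRINGS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))


class QuartetError(ValueError):
    pass


@dataclass
class QuartetResult:
    n_effective: int
    n_agreed: int
    mode: str  # "exact" | "sampled"
    n_sampled: Optional[int] = None
    seed: Optional[int] = None

    @property
    def accuracy(self) -> Optional[float]:
        """Agreement over effective quartets; None when the reference
        resolves no quartet (never reported as 0/0)."""
        if self.n_effective == 0:
            return None
        return self.n_agreed / self.n_effective


# ---------------------------------------------------------------------------
# Reference taxonomy tree
# ---------------------------------------------------------------------------

def taxonomy_tree(codes: Sequence[tuple[str, BergeyCode]]) -> dendropy.Tree:
    """Build the multifurcating rank trie from (taxon, code) records.

    One internal node per distinct code prefix; taxa sharing a full code
    become siblings under that code's node.
    """
    seen = set()
    for taxon, _ in codes:
        if taxon in seen:
            raise QuartetError(f"duplicate taxon {taxon!r}")
        seen.add(taxon)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    prefix_nodes: dict[tuple, dendropy.Node] = {(): root}
    for taxon, code in sorted(codes):
        path = code.lineage()
        for depth in range(1, len(path) + 1):
            prefix = path[:depth]
            if prefix not in prefix_nodes:
                node = dendropy.Node()
                prefix_nodes[prefix[:-1]].add_child(node)
                prefix_nodes[prefix] = node
        leaf = dendropy.Node(taxon=ns.new_taxon(taxon))
        prefix_nodes[path].add_child(leaf)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# LCA depth machinery
# ---------------------------------------------------------------------------

def _lca_depth_matrix(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    """Pairwise topological LCA depths (root depth 0) for the given leaf
    label order.  Computed per internal node over child-subtree leaf sets."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth_of: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth_of[node] = 0 if parent is None else depth_of[parent] + 1
    mat = np.zeros((n, n), dtype=np.int32)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or node.taxon.label not in index:
                raise QuartetError("tree has an unlabeled or unexpected leaf")
            node._leafset = [index[node.taxon.label]]
            continue
        child_sets = [ch._leafset for ch in node.child_nodes()]
        d = depth_of[node]
        for s1, s2 in itertools.combinations(child_sets, 2):
            for i in s1:
                mat[i, s2] = d
                mat[np.asarray(s2), i] = d
        merged = [i for s in child_sets for i in s]
        node._leafset = merged
    for i in range(n):
        mat[i, i] = 0
    return mat


def _quartet_split(mat: np.ndarray, i: int, j: int, k: int, l: int) -> Optional[int]:
    """Index into _PAIRINGS of the resolved split, or None for a star."""
    s = (
        mat[i, j] + mat[k, l],
        mat[i, k] + mat[j, l],
        mat[i, l] + mat[j, k],
    )
    m = max(s)
    winners = [t for t in range(3) if s[t] == m]
    if len(winners) != 1:
        return None
    return winners[0]


def quartet_topology(
    tree: dendropy.Tree, taxa: Sequence[str]
) -> Optional[frozenset]:
    """Induced quartet split of four taxa: a frozenset of two frozenset
    pairs, or None when the induced subtree is a star."""
    if len(taxa) != 4 or len(set(taxa)) != 4:
        raise QuartetError("need four distinct taxa")
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    for t in taxa:
        if t not in labels:
            raise QuartetError(f"unknown taxon {t!r}")
    mat = _lca_depth_matrix(tree, labels)
    pos = [labels.index(t) for t in taxa]
    win = _quartet_split(mat, *pos)
    if win is None:
        return None
    a, b, c, d = _PAIRINGS[win]
    return frozenset(
        {frozenset({taxa[a], taxa[b]}), frozenset({taxa[c], taxa[d]})}
    )


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def quartet_accuracy(
    inferred: dendropy.Tree,
    reference: dendropy.Tree,
    *,
    mode: str = "exact",
    n_sampled: int = 10000,
    seed: int = 0,
    max_exact: int = 60,
) -> QuartetResult:
    """Score an inferred tree against a reference over effective quartets.

    ``exact`` enumerates all C(n,4) quartets (guarded to n <= ``max_exact``);
    ``sampled`` draws quartets uniformly with a seeded RNG, counting only
    those the reference resolves toward the denominator.
    """
    inf_labels = sorted(lf.taxon.label for lf in inferred.leaf_node_iter())
    ref_labels = sorted(lf.taxon.label for lf in reference.leaf_node_iter())
    if inf_labels != ref_labels:
        raise QuartetError("leaf sets of inferred and reference trees differ")
    labels = inf_labels
    n = len(labels)
    if n < 4:
        raise QuartetError("need at least 4 taxa")
    mi = _lca_depth_matrix(inferred, labels)
    mr = _lca_depth_matrix(reference, labels)

    if mode == "exact":
        if n > max_exact:
            raise QuartetError(
                f"{n} taxa exceeds the exact-enumeration guard ({max_exact}); "
                "use mode='sampled'"
            )
        n_eff = n_agree = 0
        for i, j, k, l in itertools.combinations(range(n), 4):
            ref_win = _quartet_split(mr, i, j, k, l)
            if ref_win is None:
                continue
            n_eff += 1
            if _quartet_split(mi, i, j, k, l) == ref_win:
                n_agree += 1
        return QuartetResult(n_effective=n_eff, n_agreed=n_agree, mode="exact")

    if mode == "sampled":
        rng = np.random.default_rng(seed)
        n_eff = n_agree = 0
        for _ in range(n_sampled):
            i, j, k, l = rng.choice(n, size=4, replace=False)
            ref_win = _quartet_split(mr, i, j, k, l)
            if ref_win is None:
                continue
            n_eff += 1
            if _quartet_split(mi, i, j, k, l) == ref_win:
                n_agree += 1
        return QuartetResult(
            n_effective=n_eff, n_agreed=n_agree, mode="sampled",
            n_sampled=n_sampled, seed=seed,
        )

    raise QuartetError(f"unknown mode {mode!r}")
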