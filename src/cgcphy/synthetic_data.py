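"""Synthetic clades of annotated genomes evolved along a known tree.

The generator produces exactly the inputs the pipeline consumes - gene
tables with COG labels, operon structure, genome sequences, and pairwise
similarity hits - together with a truth record (generating topology, true
ortholog pairs, planted horizontally transferred genes) for scoring.

Sequence evolution is deliberately a *similarity* model, not a substitution
simulator: downstream stages consume tabular hits, so only two aspects of
real sequence matter and both are modelled directly.

* Pairwise similarity of a vertically inherited gene decays exponentially
  with tree path length ``d``: identity = 100 * exp(-r_g d).  The per-gene
  rate r_g is parameterised through a "detectability horizon" t_g (the path
  length at which identity crosses the 30% reporting floor), drawn from an
  exponential distribution.  Then the number of detectable orthologs between
  two genomes decays as a power of 10 in d, so -log10 of the ortholog count
  - the pipeline's distance - is affine in path length in expectation, and a
  clock-like (ultrametric) generating tree yields a recoverable metric.

* Nucleotide composition matters only through the 4-mer barcode, so genome
  sequence is emitted from per-region GC-parameterised i.i.d. draws; foreign
  (HGT) segments use a shifted GC.

Horizontal transfer is modelled as insertion of cassettes drawn from a small
pool of foreign donors: independent insertions of the same donor cassette
into unrelated lineages create the high-identity cross-lineage hits that
confound phylogenies, which the barcode filter is designed to remove.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from .genome_model import AnnotatedGenome, Gene, Operon, SimilarityHit, attach_operons

_LN_10_3 = math.log(10.0 / 3.0)  # identity 100*exp(-r t) hits 30% at t = this/r
_COG_LETTERS = "CDEFGHIJKLMNOPQRSTUV"
_IDENTITY_FLOOR = 25.0  # below this no hit is reported at all


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------

def _leaf_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def random_ultrametric_tree(
    n_leaves: int, *, depth: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """A random clock-like tree: coalescent-style random joins with merge
    times spread over (0, depth] (uniform gaps, so no two internal nodes
    coincide)."""
    if n_leaves < 3:
        raise SyntheticError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    active: list[tuple[dendropy.Node, float]] = []
    for name in _leaf_names(n_leaves):
        node = dendropy.Node(taxon=ns.new_taxon(name))
        active.append((node, 0.0))
    gaps = rng.uniform(0.7, 1.3, size=n_leaves - 1)
    times = np.cumsum(gaps) / gaps.sum() * depth
    for t in times:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (na, ta), (nb, tb) = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = float(t - ta)
        nb.edge.length = float(t - tb)
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append((parent, float(t)))
    tree.seed_node = active[0][0]
    tree.is_rooted = True
    return tree


def random_additive_tree(
    n_leaves: int, *, seed: int = 0, min_bl: float = 0.05, max_bl: float = 1.0
) -> dendropy.Tree:
    """A random binary tree with independent uniform branch lengths (not
    clock-like); its path-length matrix is additive by construction."""
    if n_leaves < 3:
        raise SyntheticError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    active = [dendropy.Node(taxon=ns.new_taxon(name)) for name in _leaf_names(n_leaves)]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(active[i])
        parent.add_child(active[j])
        active[i].edge.length = float(rng.uniform(min_bl, max_bl))
        active[j].edge.length = float(rng.uniform(min_bl, max_bl))
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in active:
        root.add_child(node)
        node.edge.length = float(rng.uniform(min_bl, max_bl))
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Parameters and truth
# ---------------------------------------------------------------------------

@dataclass
class CladeParams:
    """Study conditions for one synthetic clade.

    Rates are per unit branch length.  ``divergence_decay`` is the expected
    number of base-10 decades by which the detectable ortholog count shrinks
    per unit path length (it sets the scale of the per-gene horizon
    distribution).  ``foreign_gc_shift`` offsets the GC content of
    horizontally acquired segments relative to the host background.
    """

    tree: Union[dendropy.Tree, str]
    n_genes: int = 150
    mean_operon_len: float = 3.0
    gene_len_bp: int = 900
    intergenic_len: int = 100
    loss_rate: float = 0.1
    inversion_rate: float = 0.3
    indel_rate: float = 0.2
    hgt_insert_rate: float = 0.0
    foreign_gc_shift: float = 0.2
    host_gc: float = 0.5
    divergence_decay: float = 0.3
    n_donor_cassettes: int = 3
    cassette_len_range: tuple[int, int] = (4, 6)
    hgt_scope: Optional[frozenset] = None  # leaf labels; None = whole tree
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.loss_rate, self.inversion_rate, self.indel_rate,
                     self.hgt_insert_rate):
            if rate < 0:
                raise SyntheticError("event rates must be non-negative")
        if self.n_genes < 4:
            raise SyntheticError("need at least 4 ancestral genes")
        if not -0.3 <= self.foreign_gc_shift <= 0.3:
            raise SyntheticError("foreign_gc_shift outside [-0.3, 0.3]")

    def resolved_tree(self) -> dendropy.Tree:
        if isinstance(self.tree, dendropy.Tree):
            return self.tree
        return dendropy.Tree.get(data=self.tree, schema="newick")


@dataclass(frozen=True)
class _SimGene:
    """One gene instance in a simulated lineage."""

    lineage_id: str           # shared by vertical descendants
    origin: str               # "vertical" | "hgt" | "novel"
    operon_key: str
    cog: str
    horizon: float            # path length at which identity crosses 30%
    gc: float
    strand: str = "+"
    donor_ref: Optional[tuple[int, int]] = None  # (cassette, gene) for HGT


@dataclass
class TruthRecord:
    """Generating topology plus per-leaf gene provenance."""

    tree: dendropy.Tree
    seed: int
    leaf_genes: dict[str, list[_SimGene]]
    clade_tag: str = ""
    _distances: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        labels = sorted(taxa)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                self._distances[frozenset((a, b))] = float(
                    pdm.patristic_distance(taxa[a], taxa[b])
                )

    def leaves(self) -> list[str]:
        return sorted(self.leaf_genes)

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        try:
            return self._distances[frozenset((a, b))]
        except KeyError:
            raise SyntheticError(f"genomes {a!r}/{b!r} not from this clade") from None

    def gene_id(self, leaf: str, g: _SimGene) -> str:
        return f"{leaf}_{g.lineage_id}"

    def hgt_genes(self, leaf: str) -> set[str]:
        """Gene ids of planted horizontally transferred genes in a leaf."""
        return {self.gene_id(leaf, g) for g in self.leaf_genes[leaf]
                if g.origin == "hgt"}

    def true_pairs(self, leaf_a: str, leaf_b: str) -> list[tuple[str, str]]:
        """Vertically orthologous gene-id pairs between two leaves."""
        by_lineage = {g.lineage_id: g for g in self.leaf_genes[leaf_b]}
        pairs = []
        for g in self.leaf_genes[leaf_a]:
            other = by_lineage.get(g.lineage_id)
            if other is not None:
                pairs.append((self.gene_id(leaf_a, g), self.gene_id(leaf_b, other)))
        return sorted(pairs)


# ---------------------------------------------------------------------------
# Clade generation
# ---------------------------------------------------------------------------

def generate_clade(params: CladeParams) -> tuple[list[AnnotatedGenome], TruthRecord]:
    """Evolve one clade; returns leaf genomes (sorted by id) and the truth.

    The single RNG stream (from ``params.seed``) is consumed in a fixed
    order: ancestral genome, donor cassette pool, then per branch in
    preorder: losses, inversions, indels, HGT insertions; finally leaf
    sequences in sorted leaf order.
    """
    tree = params.resolved_tree()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) <= 2:
        raise SyntheticError("degenerate tree: need more than 2 leaves")
    rng = np.random.default_rng(params.seed)

    # ancestral genome: operon sizes ~ geometric(1/mean_operon_len), COGs uniform
    genes: list[_SimGene] = []
    op_idx = 0
    lam = params.divergence_decay * math.log(10.0)
    while len(genes) < params.n_genes:
        size = min(
            int(rng.geometric(1.0 / params.mean_operon_len)),
            8,
            params.n_genes - len(genes),
        )
        op_key = f"aop{op_idx:04d}"
        op_idx += 1
        for _ in range(size):
            genes.append(_SimGene(
                lineage_id=f"anc{len(genes):04d}",
                origin="vertical",
                operon_key=op_key,
                cog=str(rng.choice(list(_COG_LETTERS))),
                horizon=float(rng.exponential(1.0 / lam)),
                gc=params.host_gc,
            ))

    # foreign donor pool: reused across insertion events
    cassettes: list[list[_SimGene]] = []
    lo, hi = params.cassette_len_range
    for ci in range(params.n_donor_cassettes):
        clen = int(rng.integers(lo, hi + 1))
        cassettes.append([
            _SimGene(
                lineage_id="",  # assigned per insertion event
                origin="hgt",
                operon_key="",
                cog=str(rng.choice(list(_COG_LETTERS))),
                horizon=float(rng.exponential(1.0 / lam)),
                gc=min(1.0, max(0.0, params.host_gc + params.foreign_gc_shift)),
                donor_ref=(ci, gi),
            )
            for gi in range(clen)
        ])

    counters = {"novel": 0, "hgt": 0}
    leaf_genes: dict[str, list[_SimGene]] = {}

    def evolve_branch(state: list[_SimGene], bl: float,
                      hgt_allowed: bool) -> list[_SimGene]:
        out = list(state)
        # gene loss
        if params.loss_rate > 0 and out:
            p_loss = 1.0 - math.exp(-params.loss_rate * bl)
            keep = rng.random(len(out)) >= p_loss
            out = [g for g, k in zip(out, keep) if k]
        # segmental inversions
        for _ in range(rng.poisson(params.inversion_rate * bl)):
            if len(out) < 2:
                break
            start = int(rng.integers(0, len(out)))
            seg = int(rng.integers(2, 7))
            end = min(start + seg, len(out))
            flipped = [
                replace(g, strand="-" if g.strand == "+" else "+")
                for g in reversed(out[start:end])
            ]
            out = out[:start] + flipped + out[end:]
        # short indels: deletion or lineage-specific gene gain
        for _ in range(rng.poisson(params.indel_rate * bl)):
            if rng.random() < 0.5 and out:
                start = int(rng.integers(0, len(out)))
                out = out[:start] + out[start + int(rng.integers(1, 4)):]
            else:
                pos = int(rng.integers(0, len(out) + 1))
                k = counters["novel"]
                counters["novel"] += 1
                novel = [
                    _SimGene(
                        lineage_id=f"nov{k:04d}_{t}",
                        origin="novel",
                        operon_key=f"nop{k:04d}",
                        cog=str(rng.choice(list(_COG_LETTERS))),
                        horizon=float(rng.exponential(1.0 / lam)),
                        gc=params.host_gc,
                    )
                    for t in range(int(rng.integers(1, 4)))
                ]
                out = out[:pos] + novel + out[pos:]
        # horizontal cassette insertion from the donor pool
        if not hgt_allowed:
            return out
        for _ in range(rng.poisson(params.hgt_insert_rate * bl)):
            ci = int(rng.integers(0, len(cassettes)))
            pos = int(rng.integers(0, len(out) + 1))
            ev = counters["hgt"]
            counters["hgt"] += 1
            copy = [
                replace(g, lineage_id=f"hgt{ev:04d}_{t}", operon_key=f"hop{ev:04d}")
                for t, g in enumerate(cassettes[ci])
            ]
            out = out[:pos] + copy + out[pos:]
        return out

    def walk(node: dendropy.Node, state: list[_SimGene]) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            # transfers may be confined to a clade (e.g. a transfer-exposed
            # analysis set inside a clean reference universe)
            if params.hgt_scope is None:
                allowed = True
            else:
                below = {lf.taxon.label for lf in child.leaf_iter()}
                allowed = below <= set(params.hgt_scope)
            child_state = evolve_branch(state, bl, allowed)
            if child.is_leaf():
                leaf_genes[child.taxon.label] = child_state
            else:
                walk(child, child_state)

    walk(tree.seed_node, genes)

    tag = hashlib.md5(
        (str(params.seed) + tree.as_string(schema="newick")).encode()
    ).hexdigest()[:12]
    truth = TruthRecord(tree=tree, seed=params.seed, leaf_genes=leaf_genes,
                        clade_tag=tag)

    genomes = []
    for leaf in sorted(leaf_genes):
        genome = _emit_genome(leaf, leaf_genes[leaf], truth, params, rng)
        genome.clade_tag = tag  # provenance stamp for hit generation
        genomes.append(genome)
    return genomes, truth


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _emit_genome(
    leaf: str,
    sim_genes: Sequence[_SimGene],
    truth: TruthRecord,
    params: CladeParams,
    rng: np.random.Generator,
) -> AnnotatedGenome:
    chunks: list[str] = []
    gene_rows: list[Gene] = []
    pos = 1
    for g in sim_genes:
        chunks.append(_random_seq(rng, params.intergenic_len, params.host_gc))
        pos += params.intergenic_len
        chunks.append(_random_seq(rng, params.gene_len_bp, g.gc))
        gene_rows.append(Gene(
            id=truth.gene_id(leaf, g),
            start=pos,
            end=pos + params.gene_len_bp - 1,
            strand=g.strand,
            cog=g.cog,
        ))
        pos += params.gene_len_bp
    chunks.append(_random_seq(rng, params.intergenic_len, params.host_gc))
    genome = AnnotatedGenome.from_genes(
        leaf, gene_rows, name=leaf, sequence="".join(chunks)
    )
    # operons: maximal contiguous runs sharing an ancestral operon unit
    declared: list[tuple[str, list[str]]] = []
    run: list[str] = []
    run_key = None
    for g, row in zip(sim_genes, gene_rows):
        if g.operon_key == run_key and run:
            run.append(row.id)
        else:
            if len(run) > 1:
                declared.append((f"op{len(declared):04d}", run))
            run, run_key = [row.id], g.operon_key
    if len(run) > 1:
        declared.append((f"op{len(declared):04d}", run))
    return attach_operons(genome, declared)


# ---------------------------------------------------------------------------
# Similarity hits
# ---------------------------------------------------------------------------

def _identity_to_hit(ga: str, gb: str, identity: float) -> SimilarityHit:
    identity = float(min(100.0, identity))
    evalue = 0.0 if identity >= 99.999 else 10.0 ** (-identity / 5.0)
    return SimilarityHit(ga, gb, score=2.0 * identity, evalue=evalue,
                         identity=identity)


def similarity_hits(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    truth: TruthRecord,
    *,
    spurious_fraction: float = 0.05,
    noise_sd: float = 0.5,
) -> list[SimilarityHit]:
    """Synthesise the tabular hits an all-against-all search would produce.

    True ortholog pairs decay in identity with tree distance (per-gene
    horizons, small seeded Gaussian noise); copies of one donor cassette
    inserted by different HGT events hit each other at near-full identity
    regardless of host distance; a ``spurious_fraction`` of paralog-like
    random hits is added.  Deterministic per (clade seed, genome pair),
    independent of argument order.
    """
    a, b = genome_a.id, genome_b.id
    if a > b:  # canonical order, then swap back
        return [
            SimilarityHit(h.gene_b, h.gene_a, score=h.score, evalue=h.evalue,
                          identity=h.identity)
            for h in similarity_hits(genome_b, genome_a, truth,
                                     spurious_fraction=spurious_fraction,
                                     noise_sd=noise_sd)
        ]
    leaves = truth.leaves()
    if a not in truth.leaf_genes or b not in truth.leaf_genes:
        raise SyntheticError(f"genomes {a!r}/{b!r} not from this clade")
    for g in (genome_a, genome_b):
        tag = getattr(g, "clade_tag", None)
        if tag is not None and tag != truth.clade_tag:
            raise SyntheticError(
                f"genome {g.id!r} was generated by a different clade than "
                "this truth record"
            )
    rng = np.random.default_rng(
        np.random.SeedSequence((truth.seed, leaves.index(a), leaves.index(b)))
    )
    d = truth.distance(a, b)
    hits: list[SimilarityHit] = []

    by_lineage_b = {g.lineage_id: g for g in truth.leaf_genes[b]}
    for g in truth.leaf_genes[a]:
        other = by_lineage_b.get(g.lineage_id)
        if other is None:
            continue
        if d == 0.0:
            identity = 100.0
        else:
            rate = _LN_10_3 / g.horizon
            identity = 100.0 * math.exp(-rate * d) + rng.normal(0.0, noise_sd)
        if identity >= _IDENTITY_FLOOR:
            hits.append(_identity_to_hit(
                truth.gene_id(a, g), truth.gene_id(b, other), identity
            ))

    # xenologs: same donor gene, different insertion events
    donors_b: dict[tuple[int, int], list[_SimGene]] = {}
    for g in truth.leaf_genes[b]:
        if g.donor_ref is not None:
            donors_b.setdefault(g.donor_ref, []).append(g)
    for g in truth.leaf_genes[a]:
        if g.donor_ref is None:
            continue
        for other in donors_b.get(g.donor_ref, []):
            if other.lineage_id == g.lineage_id:
                continue  # same event: already a vertical pair
            identity = 99.0 + rng.normal(0.0, noise_sd / 2.0)
            hits.append(_identity_to_hit(
                truth.gene_id(a, g), truth.gene_id(b, other), identity
            ))

    n_true = len(hits)
    if spurious_fraction > 0 and n_true:
        existing = {(h.gene_a, h.gene_b) for h in hits}
        n_spur = int(rng.binomial(n_true, spurious_fraction))
        ga_list = truth.leaf_genes[a]
        gb_list = truth.leaf_genes[b]
        for _ in range(n_spur):
            g = ga_list[int(rng.integers(0, len(ga_list)))]
            other = gb_list[int(rng.integers(0, len(gb_list)))]
            key = (truth.gene_id(a, g), truth.gene_id(b, other))
            if key in existing:
                continue
            existing.add(key)
            hits.append(_identity_to_hit(*key, identity=float(rng.uniform(25, 50))))
    return sorted(hits, key=lambda h: (h.gene_a, h.gene_b))


def write_truth(truth: TruthRecord, out_dir) -> None:
    """Serialise a truth record: the generating tree (Newick), the true
    ortholog pairs per genome pair (TSV) and the planted HGT genes (TSV)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "true_tree.nwk", "w") as fh:
        fh.write(truth.tree.as_string(schema="newick",
                                      real_value_format_specifier=".6f",
                                      suppress_rooting=True))
    leaves = truth.leaves()
    with open(out / "true_pairs.tsv", "w") as fh:
        fh.write("genome_a\tgenome_b\tgene_a\tgene_b\n")
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                for ga, gb in truth.true_pairs(a, b):
                    fh.write(f"{a}\t{b}\t{ga}\t{gb}\n")
    with open(out / "hgt_genes.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\n")
        for leaf in leaves:
            for gid in sorted(truth.hgt_genes(leaf)):
                fh.write(f"{leaf}\t{gid}\n")


def all_pairwise_hits(
    genomes: Sequence[AnnotatedGenome],
    truth: TruthRecord,
    *,
    spurious_fraction: float = 0.05,
    noise_sd: float = 0.5,
) -> dict[tuple[str, str], list[SimilarityHit]]:
    """Hits for every unordered genome pair, keyed by sorted id pair."""
    by_id = {g.id: g for g in genomes}
    ids = sorted(by_id)
    out = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out[(a, b)] = similarity_hits(
                by_id[a], by_id[b], truth,
                spurious_fraction=spurious_fraction, noise_sd=noise_sd,
            )
    return out
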