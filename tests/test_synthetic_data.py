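"""The synthetic clade generator and its truth record."""

import numpy as np
import pytest

from cgcphy.barcode import anomaly_profile, compute_barcode
from cgcphy.synthetic_data import (CladeParams, SyntheticError,
                                   all_pairwise_hits, generate_clade,
                                   random_ultrametric_tree, similarity_hits)
from cgcphy.tree_builder import tree_from_newick


def _params(**kw):
    defaults = dict(
        tree=random_ultrametric_tree(5, depth=0.4, seed=kw.pop("tree_seed", 0)),
        n_genes=60, seed=0,
        loss_rate=0.0, inversion_rate=0.0, indel_rate=0.0, hgt_insert_rate=0.0,
    )
    defaults.update(kw)
    return CladeParams(**defaults)


class TestGenerateClade:
    def test_event_free_leaves_share_gene_order_and_full_orthology(self):
        genomes, truth = generate_clade(_params())
        orders = [[g.id.split("_", 1)[1] for g in gen.genes] for gen in genomes]
        assert all(o == orders[0] for o in orders)
        a, b = genomes[0].id, genomes[1].id
        assert len(truth.true_pairs(a, b)) == 60

    def test_same_seed_gives_identical_output(self):
        g1, t1 = generate_clade(_params())
        g2, t2 = generate_clade(_params())
        assert [g.sequence for g in g1] == [g.sequence for g in g2]
        assert [[(x.id, x.start, x.end, x.strand, x.cog) for x in g.genes]
                for g in g1] == \
               [[(x.id, x.start, x.end, x.strand, x.cog) for x in g.genes]
                for g in g2]
        h1 = similarity_hits(g1[0], g1[1], t1)
        h2 = similarity_hits(g2[0], g2[1], t2)
        assert h1 == h2

    def test_loss_rate_shrinks_gene_complement(self):
        genomes, truth = generate_clade(_params(loss_rate=1.5))
        assert any(g.n_genes < 60 for g in genomes)

    def test_inversions_flip_strand_and_order(self):
        genomes, _ = generate_clade(_params(inversion_rate=8.0))
        assert any(x.strand == "-" for g in genomes for x in g.genes)

    def test_degenerate_tree_rejected(self):
        with pytest.raises(SyntheticError):
            generate_clade(_params(tree=tree_from_newick("(a:1,b:1);")))

    def test_truth_serialisation_writes_tree_pairs_and_hgt(self, tmp_path):
        from cgcphy.synthetic_data import write_truth
        from cgcphy.tree_builder import read_newick, same_unrooted_topology
        genomes, truth = generate_clade(_params(hgt_insert_rate=2.0,
                                                tree_seed=1))
        write_truth(truth, tmp_path)
        back = read_newick(tmp_path / "true_tree.nwk")
        assert same_unrooted_topology(back, truth.tree)
        pair_lines = (tmp_path / "true_pairs.tsv").read_text().splitlines()[1:]
        a, b = genomes[0].id, genomes[1].id
        expected = {(a, b, ga, gb) for ga, gb in truth.true_pairs(a, b)}
        written = {tuple(line.split("\t")) for line in pair_lines}
        assert expected <= written
        hgt_lines = (tmp_path / "hgt_genes.tsv").read_text().splitlines()[1:]
        planted = {tuple(line.split("\t")) for line in hgt_lines}
        assert planted == {(g.id, gid) for g in genomes
                           for gid in truth.hgt_genes(g.id)}

    def test_operons_are_contiguous_runs(self):
        genomes, _ = generate_clade(_params(inversion_rate=2.0, indel_rate=1.0))
        for g in genomes:
            idx = {x.id: x.index for x in g.genes}
            for op in g.operons:
                ranks = [idx[gid] for gid in op.gene_ids]
                assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))


class TestSimilarityHits:
    def test_zero_distance_pair_is_perfect(self):
        # two sibling leaves at zero branch length
        tree = tree_from_newick("((a:0.0,b:0.0):0.5,(c:0.25,d:0.25):0.25);")
        genomes, truth = generate_clade(_params(tree=tree))
        by = {g.id: g for g in genomes}
        hits = similarity_hits(by["a"], by["b"], truth, spurious_fraction=0.0)
        assert len(hits) == 60
        assert all(h.identity == 100.0 and h.evalue == 0.0 for h in hits)

    def test_without_spurious_hits_exactly_the_detectable_true_pairs(self):
        # noiseless hits are exactly the true pairs whose decayed identity
        # clears the reporting floor (recomputed here from the horizons)
        import math
        from cgcphy.synthetic_data import _IDENTITY_FLOOR, _LN_10_3
        genomes, truth = generate_clade(_params())
        a, b = genomes[0], genomes[1]
        d = truth.distance(a.id, b.id)
        expected = set()
        by_lineage = {g.lineage_id: g for g in truth.leaf_genes[b.id]}
        for g in truth.leaf_genes[a.id]:
            other = by_lineage.get(g.lineage_id)
            if other is None:
                continue
            identity = 100.0 * math.exp(-_LN_10_3 / g.horizon * d)
            if identity >= _IDENTITY_FLOOR:
                expected.add((truth.gene_id(a.id, g), truth.gene_id(b.id, other)))
        hits = similarity_hits(a, b, truth, spurious_fraction=0.0, noise_sd=0.0)
        assert {(h.gene_a, h.gene_b) for h in hits} == expected
        assert expected <= set(truth.true_pairs(a.id, b.id))

    def test_spurious_fraction_adds_binomial_extras(self):
        genomes, truth = generate_clade(_params())
        a, b = genomes[0], genomes[1]
        base = similarity_hits(a, b, truth, spurious_fraction=0.0)
        with_spur = similarity_hits(a, b, truth, spurious_fraction=0.2)
        extra = len(with_spur) - len(base)
        # 60 true pairs, p=0.2: far outside [0, 30] would be broken sampling
        assert 0 < extra <= 30

    def test_identity_decays_with_tree_distance(self):
        genomes, truth = generate_clade(_params(tree_seed=3))
        ids = sorted(g.id for g in genomes)
        by = {g.id: g for g in genomes}
        mean_id = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                hits = similarity_hits(by[a], by[b], truth,
                                       spurious_fraction=0.0, noise_sd=0.0)
                mean_id[(a, b)] = np.mean([h.identity for h in hits])
        pairs = sorted(mean_id, key=lambda k: truth.distance(*k))
        dists = [truth.distance(*k) for k in pairs]
        means = [mean_id[k] for k in pairs]
        for (d1, m1), (d2, m2) in zip(zip(dists, means), zip(dists[1:], means[1:])):
            if d2 > d1 + 1e-9:
                assert m2 <= m1 + 1e-9

    def test_argument_order_does_not_matter(self):
        genomes, truth = generate_clade(_params())
        a, b = genomes[0], genomes[2]
        fwd = similarity_hits(a, b, truth)
        rev = similarity_hits(b, a, truth)
        assert {(h.gene_a, h.gene_b, h.score) for h in fwd} == \
            {(h.gene_b, h.gene_a, h.score) for h in rev}

    def test_foreign_genome_rejected(self):
        genomes, truth = generate_clade(_params())
        others, _ = generate_clade(_params(tree_seed=9))
        with pytest.raises(SyntheticError):
            similarity_hits(genomes[0], others[0], truth)


class TestPlantedHgt:
    def test_planted_fragments_are_barcode_outliers(self):
        params = _params(hgt_insert_rate=2.0, foreign_gc_shift=0.25,
                         tree_seed=1)
        genomes, truth = generate_clade(params)
        checked = 0
        for g in genomes:
            planted = truth.hgt_genes(g.id)
            if not planted:
                continue
            prof = anomaly_profile(compute_barcode(g))
            med = np.median(prof.dis)
            by_id = {x.id: x for x in g.genes}
            for gid in planted:
                gene = by_id[gid]
                frag = (gene.start - 1) // 1000
                if frag < prof.n_fragments:
                    checked += 1
                    assert prof.dis[frag] > med
        assert checked > 0

    def test_xenolog_hits_between_independent_insertions(self):
        tree = random_ultrametric_tree(6, depth=1.0, seed=2)
        params = CladeParams(tree=tree, n_genes=60, seed=2,
                             hgt_insert_rate=2.0, foreign_gc_shift=0.25)
        genomes, truth = generate_clade(params)
        hits = all_pairwise_hits(genomes, truth, spurious_fraction=0.0)
        xeno = 0
        for (a, b), pair_hits in hits.items():
            true = set(truth.true_pairs(a, b))
            for h in pair_hits:
                if (h.gene_a, h.gene_b) not in true and h.identity > 95:
                    xeno += 1
        assert xeno > 0  # repeated donor cassettes create cross-lineage hits
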