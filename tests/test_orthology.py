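"""Candidate filtering and the constrained one-to-one ortholog assignment."""

import numpy as np
import pytest

from cgcphy.genome_model import SimilarityHit, attach_operons
from cgcphy.orthology import (OrthoWeights, assign_orthologs,
                              brute_force_orthologs, candidate_hits,
                              greedy_orthologs, ortholog_count_table)

from conftest import make_genome, self_hits


def random_instance(seed, max_genes=6, cog_pool="JKL"):
    """A random small instance: genomes with random contiguous operons,
    ~50%-dense candidate edges, random weights."""
    rng = np.random.default_rng(seed)
    n_a, n_b = rng.integers(3, max_genes + 1, 2)

    def mk(gid, n, prefix):
        g = make_genome(gid, n, prefix,
                        cogs=[str(rng.choice(list(cog_pool))) for _ in range(n)])
        declared, i, k = [], 0, 0
        while i < n:
            size = int(rng.integers(1, 4))
            declared.append((f"{prefix}op{k}",
                             [f"{prefix}{j + 1}" for j in range(i, min(i + size, n))]))
            i += size
            k += 1
        return attach_operons(g, declared)

    a, b = mk("A", n_a, "a"), mk("B", n_b, "b")
    hits = [
        SimilarityHit(f"a{i + 1}", f"b{j + 1}", score=float(rng.uniform(10, 100)),
                      evalue=1e-9, identity=float(rng.uniform(35, 99)))
        for i in range(n_a) for j in range(n_b) if rng.random() < 0.5
    ]
    w = OrthoWeights(a=1.0, b=float(rng.uniform(0.2, 1.2)),
                     c=float(rng.uniform(0.2, 1.2)))
    return a, b, hits, w


class TestCandidateHits:
    def _genomes(self):
        a = make_genome("A", 2, "a", cogs=["J", None])
        b = make_genome("B", 2, "b", cogs=["J", "K"])
        return a, b

    def test_evalue_above_cutoff_dropped(self):
        a, b = self._genomes()
        hits = [SimilarityHit("a1", "b1", 50, 1e-2, 80.0)]
        assert candidate_hits(hits, a, b) == []

    def test_matching_cog_good_hit_kept(self):
        a, b = self._genomes()
        hits = [SimilarityHit("a1", "b1", 50, 1e-5, 40.0)]
        assert candidate_hits(hits, a, b) == hits

    def test_cog_mismatch_dropped_missing_cog_passes(self):
        a, b = self._genomes()
        mismatch = SimilarityHit("a1", "b2", 50, 1e-5, 40.0)  # J vs K
        nocog = SimilarityHit("a2", "b2", 50, 1e-5, 40.0)     # None vs K
        assert candidate_hits([mismatch, nocog], a, b) == [nocog]

    def test_identity_cut_is_strict_and_toggleable(self):
        a, b = self._genomes()
        low = SimilarityHit("a1", "b1", 50, 1e-5, 30.0)
        assert candidate_hits([low], a, b) == []
        assert candidate_hits([low], a, b, min_identity=None) == [low]


class TestAssignment:
    def test_identical_genomes_full_identity_matching(self):
        a = make_genome("A", 5, "a")
        b = make_genome("B", 5, "b")
        m = assign_orthologs(self_hits(a, b, score=100.0), a, b)
        assert m.n_pairs == 5
        assert m.pairs == [(f"a{i}", f"b{i}") for i in range(1, 6)]

    def test_single_candidate_hit_gives_that_pair(self):
        a = make_genome("A", 3, "a")
        b = make_genome("B", 3, "b")
        hit = SimilarityHit("a2", "b3", 80, 1e-9, 70.0)
        m = assign_orthologs([hit], a, b)
        assert m.pairs == [("a2", "b3")]
        assert m.evidence[("a2", "b3")] is hit

    def test_empty_candidates_empty_map_zero_objective(self):
        a = make_genome("A", 2, "a")
        b = make_genome("B", 2, "b")
        m = brute_force_orthologs([], a, b)
        assert m.pairs == [] and m.objective_value == 0.0

    def test_operon_penalty_forces_operon_coherent_matching(self):
        # b2..b4 form one operon; a2 prefers the stray b1 by raw score, but
        # opening b1's singleton operon costs more than the score gain
        a = make_genome("A", 4, "a", operon_sizes=[1, 3])
        b = make_genome("B", 4, "b", operon_sizes=[1, 3])
        hits = [
            SimilarityHit("a2", "b1", 100, 1e-9, 90.0),  # stray, best score
            SimilarityHit("a2", "b2", 95, 1e-9, 85.0),
            SimilarityHit("a3", "b3", 90, 1e-9, 85.0),
            SimilarityHit("a4", "b4", 90, 1e-9, 85.0),
        ]
        w = OrthoWeights(a=1.0, b=0.5, c=0.5)
        solved = assign_orthologs(hits, a, b, w, score_mode="normalized")
        oracle = brute_force_orthologs(hits, a, b, w, score_mode="normalized")
        assert solved.objective_value == pytest.approx(oracle.objective_value)
        assert ("a2", "b2") in solved.pairs and ("a2", "b1") not in solved.pairs

    @pytest.mark.parametrize("seed", range(40))
    def test_solver_matches_exhaustive_oracle(self, seed):
        a, b, hits, w = random_instance(seed)
        solved = assign_orthologs(hits, a, b, w)
        oracle = brute_force_orthologs(hits, a, b, w)
        assert solved.objective_value == pytest.approx(oracle.objective_value)

    @pytest.mark.parametrize("seed", range(20))
    def test_solver_at_least_greedy_and_symmetric(self, seed):
        a, b, hits, w = random_instance(seed + 1000)
        w = OrthoWeights(a=w.a, b=w.b, c=w.b)  # b == c for role symmetry
        fwd = assign_orthologs(hits, a, b, w)
        assert fwd.objective_value >= \
            greedy_orthologs(hits, a, b, w).objective_value - 1e-9
        swapped_hits = [SimilarityHit(h.gene_b, h.gene_a, score=h.score,
                                      evalue=h.evalue, identity=h.identity)
                        for h in hits]
        rev = assign_orthologs(swapped_hits, b, a, w)
        assert {(x, y) for x, y in fwd.pairs} == {(y, x) for x, y in rev.pairs}

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_operon_penalties_never_opens_more_operons(self, seed):
        a, b, hits, _ = random_instance(seed + 2000)
        if not hits:
            pytest.skip("empty instance")
        prev = None
        for pen in (0.0, 0.3, 0.6, 1.0, 1.5):
            m = assign_orthologs(hits, a, b, OrthoWeights(1.0, pen, pen))
            touched = len({a.operon_of(x) for x, _ in m.pairs}) + \
                len({b.operon_of(y) for _, y in m.pairs})
            if prev is not None:
                assert touched <= prev
            prev = touched

    def test_local_search_never_beaten_by_greedy(self):
        for seed in range(15):
            a, b, hits, w = random_instance(seed + 3000)
            loc = assign_orthologs(hits, a, b, w, method="local")
            gre = greedy_orthologs(hits, a, b, w)
            assert loc.objective_value >= gre.objective_value - 1e-9

    def test_brute_force_guard_on_large_instances(self):
        a = make_genome("A", 9, "a")
        b = make_genome("B", 9, "b")
        with pytest.raises(ValueError, match="too large"):
            brute_force_orthologs(self_hits(a, b), a, b)


class TestCountTable:
    def test_identical_panel_every_gene_seen_everywhere(self):
        panel = [make_genome(f"G{i}", 4, f"g{i}_") for i in range(3)]
        maps = {}
        for i in range(3):
            for j in range(i + 1, 3):
                maps[(f"G{i}", f"G{j}")] = assign_orthologs(
                    self_hits(panel[i], panel[j]), panel[i], panel[j])
        counts = ortholog_count_table(panel, maps)
        assert set(counts.values()) == {2}

    def test_gene_without_hits_counts_zero(self):
        a = make_genome("A", 2, "a")
        b = make_genome("B", 2, "b")
        maps = {("A", "B"): assign_orthologs(
            [SimilarityHit("a1", "b1", 50, 1e-9, 80.0)], a, b)}
        counts = ortholog_count_table([a, b], maps)
        assert counts[("A", "a2")] == 0 and counts[("A", "a1")] == 1

    def test_missing_pair_raises(self):
        panel = [make_genome(f"G{i}", 2, f"g{i}_") for i in range(3)]
        with pytest.raises(KeyError):
            ortholog_count_table(panel, {})
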