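"""ROG statistics, three-sigma calibration and HGT-gene elimination."""

import numpy as np
import pytest

from cgcphy.barcode import anomaly_profile, compute_barcode
from cgcphy.hgt_filter import (OSS, SSS, Calibration, FilterError, RogStats,
                               apply_elimination, calibrate_mean_rog,
                               calibrate_std_rge, classify_set,
                               eliminate_barcode_genes, eliminate_conserved,
                               rog, std_rge)
from cgcphy.orthology import OrthologMap, assign_orthologs
from cgcphy.synthetic_data import (CladeParams, generate_clade,
                                   random_ultrametric_tree)

from conftest import make_genome, self_hits


class TestRog:
    def test_identity_and_disjoint_bounds(self):
        assert rog(100, 100, 100) == 1.0
        assert rog(0, 100, 150) == 0.0

    def test_mid_value(self):
        assert rog(50, 100, 150) == pytest.approx(0.4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(FilterError):
            rog(10, 0, 100)
        with pytest.raises(FilterError):
            rog(120, 100, 150)

    def test_symmetric_and_bounded_on_random_panels(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_g, n_h = rng.integers(50, 500, 2)
            n_o = rng.integers(0, min(n_g, n_h) + 1)
            v = rog(int(n_o), int(n_g), int(n_h))
            assert 0.0 <= v <= 1.0
            assert v == rog(int(n_o), int(n_h), int(n_g))


def _cal(mu=0.5, sigma=0.1, kind="mean_rog", tail="two_sided"):
    return Calibration(mu=mu, sigma=sigma, m=100, set_size=5, seed=0,
                       statistic_kind=kind, tail=tail)


class TestClassification:
    def test_statistic_at_the_mean_is_ordinary(self):
        assert classify_set(0.5, _cal()) == OSS

    def test_three_sigma_boundary_is_inclusive_both_sides(self):
        cal = _cal()
        assert classify_set(cal.mu + 3 * cal.sigma, cal) == OSS
        assert classify_set(cal.mu - 3 * cal.sigma, cal) == OSS
        eps = 1e-9
        assert classify_set(cal.mu + 3 * cal.sigma + eps, cal) == SSS
        assert classify_set(cal.mu - 3 * cal.sigma - eps, cal) == SSS

    def test_std_rge_upper_tail_only(self):
        cal = _cal(kind="std_rge", tail="upper")
        assert classify_set(cal.mu + 4 * cal.sigma, cal) == SSS
        assert classify_set(cal.mu - 4 * cal.sigma, cal) == OSS

    def test_text_round_trip(self, tmp_path):
        cal = _cal()
        path = tmp_path / "cal.txt"
        cal.to_text(path)
        assert Calibration.from_text(path) == cal


class TestCalibrate:
    def _rog_stats(self, n=12):
        panel = [make_genome(f"G{i:02d}", 4, f"g{i}_") for i in range(n)]
        maps = {}
        for i in range(n):
            for j in range(i + 1, n):
                key = (f"G{i:02d}", f"G{j:02d}")
                maps[key] = assign_orthologs(
                    self_hits(panel[i], panel[j]), panel[i], panel[j])
        return RogStats.from_maps(panel, maps)

    def test_constant_statistic_gives_zero_sigma(self):
        stats = self._rog_stats()
        cal = calibrate_mean_rog(stats, m=100, set_size=4, seed=0)
        assert cal.mu == pytest.approx(1.0)
        assert cal.sigma == 0.0

    def test_same_seed_reproduces_calibration(self):
        rng = np.random.default_rng(3)
        rge = {f"G{i:02d}": float(v) for i, v in enumerate(rng.uniform(0.5, 0.9, 40))}
        c1 = calibrate_std_rge(rge, m=500, set_size=8, seed=7)
        c2 = calibrate_std_rge(rge, m=500, set_size=8, seed=7)
        assert c1 == c2
        c3 = calibrate_std_rge(rge, m=500, set_size=8, seed=8)
        assert c3 != c1

    def test_monte_carlo_mean_consistent_across_m(self):
        rng = np.random.default_rng(4)
        rge = {f"G{i:02d}": float(v) for i, v in enumerate(rng.uniform(0.5, 0.9, 40))}
        small = calibrate_std_rge(rge, m=1000, set_size=10, seed=0)
        big = calibrate_std_rge(rge, m=5000, set_size=10, seed=1)
        assert abs(small.mu - big.mu) <= 3 * big.sigma / np.sqrt(1000)

    def test_set_size_larger_than_pool_rejected(self):
        rge = {"a": 1.0, "b": 2.0}
        with pytest.raises(FilterError):
            calibrate_std_rge(rge, m=10, set_size=3, seed=0)

    def test_pool_restriction_uses_only_named_genomes(self):
        rge = {"a": 0.1, "b": 0.1, "c": 0.1, "x": 9.9, "y": 9.9}
        cal = calibrate_std_rge(rge, m=50, set_size=2, seed=0,
                                pool_ids=["a", "b", "c"])
        assert cal.mu == pytest.approx(0.0)


class TestEliminateConserved:
    def test_special_sets_keep_everything(self):
        counts = {("G", f"g{i}"): 9 for i in range(10)}
        assert eliminate_conserved(counts, n_as=10, set_class=SSS) == set()

    def test_threshold_is_085_of_panel(self):
        counts = {("G", "hi"): 9, ("G", "lo"): 8}
        out = eliminate_conserved(counts, n_as=10, set_class=OSS)
        assert out == {("G", "hi")}  # 9 >= 8.5, 8 < 8.5

    def test_invalid_fraction_rejected(self):
        with pytest.raises(FilterError):
            eliminate_conserved({}, 10, OSS, frac=1.5)


class TestEliminateBarcodeGenes:
    def _genome_with_shifted_tail(self, n_genes=20, shifted=4, seed=0):
        # one gene per 1 kb fragment; the last `shifted` fragments are
        # GC-shifted, standing in for a foreign cassette
        rng = np.random.default_rng(seed)
        def block(gc):
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            return "".join(np.array(list("ACGT"))[rng.choice(4, size=1000, p=p)])
        seq = "".join(block(0.5) for _ in range(n_genes - shifted))
        seq += "".join(block(0.85) for _ in range(shifted))
        g = make_genome("G", n_genes, "g", gene_len=900, spacing=100,
                        sequence=seq)
        return g

    def test_ordinary_sets_keep_everything(self):
        g = self._genome_with_shifted_tail()
        prof = anomaly_profile(compute_barcode(g))
        assert eliminate_barcode_genes(g, prof, OSS) == set()

    def test_exactly_floor_frac_genes_removed(self):
        g = self._genome_with_shifted_tail(n_genes=20, shifted=6)
        prof = anomaly_profile(compute_barcode(g))
        out = eliminate_barcode_genes(g, prof, SSS, frac=0.2)
        assert len(out) == 4  # floor(0.2 * 20)

    def test_shifted_fragment_genes_eliminated_first(self):
        g = self._genome_with_shifted_tail(n_genes=20, shifted=4)
        prof = anomaly_profile(compute_barcode(g))
        out = eliminate_barcode_genes(g, prof, SSS, frac=0.2)
        assert out == {"g17", "g18", "g19", "g20"}

    def test_missing_sequence_rejected(self):
        g = make_genome("G", 10, "g")
        with pytest.raises(FilterError):
            eliminate_barcode_genes(g, None, SSS)


class TestApplyElimination:
    def _maps(self):
        a = make_genome("A", 4, "a")
        b = make_genome("B", 4, "b")
        m = assign_orthologs(self_hits(a, b), a, b)
        return {("A", "B"): m}

    def test_empty_elimination_is_identity(self):
        maps = self._maps()
        out = apply_elimination(maps, {})
        assert out[("A", "B")].pairs == maps[("A", "B")].pairs

    def test_eliminating_whole_genome_empties_its_maps(self):
        maps = self._maps()
        out = apply_elimination(maps, {"A": {f"a{i}" for i in range(1, 5)}})
        assert out[("A", "B")].pairs == []

    def test_partial_elimination_bounded_and_one_to_one(self):
        maps = self._maps()
        out = apply_elimination(maps, {"A": {"a1", "a3"}})
        m = out[("A", "B")]
        assert m.n_pairs == 2
        a_side = [p[0] for p in m.pairs]
        assert len(set(a_side)) == len(a_side)


class TestPlantedHgtRecovery:
    def test_planted_genes_enriched_among_flagged(self):
        """Across seeded replicates, barcode elimination is enriched >= 2x
        for planted foreign genes, with precision >= 0.5 (heavy-transfer
        regime: about a fifth of each genome is foreign)."""
        enrichments, precisions = [], []
        for seed in range(10):
            tree = random_ultrametric_tree(6, depth=1.0, seed=seed)
            params = CladeParams(tree=tree, n_genes=120, seed=seed,
                                 hgt_insert_rate=3.0, foreign_gc_shift=0.25)
            genomes, truth = generate_clade(params)
            for g in genomes:
                planted = truth.hgt_genes(g.id)
                if len(planted) < 5:
                    continue
                prof = anomaly_profile(compute_barcode(g))
                flagged = eliminate_barcode_genes(g, prof, SSS, frac=0.2)
                if not flagged:
                    continue
                base_rate = len(planted) / g.n_genes
                hit_rate = len(flagged & planted) / len(flagged)
                enrichments.append(hit_rate / base_rate)
                precisions.append(hit_rate)
        assert np.mean(enrichments) >= 2.0
        assert np.mean(precisions) >= 0.5
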