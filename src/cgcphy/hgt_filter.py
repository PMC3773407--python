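"""Elimination of putative horizontally transferred genes.

Two complementary screens precede the distance computation:

* **Highly conserved genes.**  The ratio of orthologous genes between two
  genomes is Rog(G,H) = 2*N_O / (N_G + N_H).  Species sets whose mean Rog is
  ordinary (within three sigma of a random-set calibration) have their
  near-universally conserved genes removed - genes orthologous in at least
  85% of the reference panel are disproportionately transfer-prone ribosomal
  machinery.  Sets flagged special (e.g. all members from one phylum, where
  high conservation reflects vertical descent) skip this elimination.

* **Abnormal-barcode genes.**  Per-genome genomic-evolution values r_ge
  (from the 4-mer barcode anomaly profile) are summarised per species set by
  their standard deviation; sets in the upper three-sigma tail of the
  random-set calibration are special, and in those sets the 20% of each
  genome's genes lying on the most anomalous fragments are removed.

Both calibrations draw m random subsets of a reference panel (the analysis
set's universe), compute the set-level statistic per subset, and fit mu and
sigma; classification then applies the three-sigma rule - two-sided for mean
Rog, upper-tail only for std r_ge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .barcode import AnomalyProfile, abnormal_fragments
from .genome_model import AnnotatedGenome
from .orthology import OrthologMap

OSS = "oss"  # ordinary species set
SSS = "sss"  # special species set


class FilterError(ValueError):
    pass


def rog(n_orth: int, n_g: int, n_h: int) -> float:
    """Ratio of orthologous genes: 2*N_O/(N_G+N_H), in [0, 1]."""
    if n_g <= 0 or n_h <= 0:
        raise FilterError("genome gene counts must be positive")
    if n_orth < 0 or n_orth > min(n_g, n_h):
        raise FilterError("ortholog count outside [0, min(N_G, N_H)]")
    return 2.0 * n_orth / (n_g + n_h)


@dataclass
class RogStats:
    """Pairwise Rog values over a genome panel."""

    ids: list[str]
    matrix: np.ndarray  # symmetric, diagonal 1

    @classmethod
    def from_maps(
        cls,
        panel: Sequence[AnnotatedGenome],
        maps: Mapping[tuple[str, str], OrthologMap],
    ) -> "RogStats":
        sizes = {g.id: g.n_genes for g in panel}
        ids = sorted(sizes)
        n = len(ids)
        mat = np.ones((n, n))
        for i, j in itertools.combinations(range(n), 2):
            m = maps[(ids[i], ids[j])]
            mat[i, j] = mat[j, i] = rog(m.n_pairs, sizes[ids[i]], sizes[ids[j]])
        return cls(ids=ids, matrix=mat)

    def mean_rog(self, subset: Optional[Sequence[int]] = None) -> float:
        """Average pairwise Rog over a subset of panel indices (default all)."""
        idx = np.arange(len(self.ids)) if subset is None else np.asarray(subset)
        if idx.size < 2:
            raise FilterError("mean Rog needs at least two genomes")
        sub = self.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        return float(sub[iu].mean())

    def mean_rog_of_ids(self, ids: Sequence[str]) -> float:
        lookup = {g: i for i, g in enumerate(self.ids)}
        return self.mean_rog([lookup[g] for g in ids])


@dataclass
class Calibration:
    """Random-set calibration of a set-level statistic."""

    mu: float
    sigma: float
    m: int
    set_size: int
    seed: int
    statistic_kind: str  # "mean_rog" | "std_rge"
    tail: str            # "two_sided" | "upper"

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for k in ("mu", "sigma", "m", "set_size", "seed",
                      "statistic_kind", "tail"):
                fh.write(f"{k}\t{getattr(self, k)}\n")

    @classmethod
    def from_text(cls, path) -> "Calibration":
        vals: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    k, v = line.rstrip("\n").split("\t")
                    vals[k] = v
        return cls(
            mu=float(vals["mu"]), sigma=float(vals["sigma"]), m=int(vals["m"]),
            set_size=int(vals["set_size"]), seed=int(vals["seed"]),
            statistic_kind=vals["statistic_kind"], tail=vals["tail"],
        )


def _calibrate(
    pool: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    *,
    m: int,
    set_size: int,
    seed: int,
    kind: str,
    tail: str,
) -> Calibration:
    if set_size > pool.size:
        raise FilterError(f"set_size {set_size} exceeds pool size {pool.size}")
    if m < 2:
        raise FilterError("need at least 2 random sets")
    rng = np.random.default_rng(seed)
    values = np.empty(m)
    for t in range(m):
        subset = rng.choice(pool, size=set_size, replace=False)
        values[t] = statistic(subset)
    return Calibration(
        mu=float(values.mean()), sigma=float(values.std(ddof=1)),
        m=m, set_size=set_size, seed=seed, statistic_kind=kind, tail=tail,
    )


def calibrate_mean_rog(
    stats: RogStats, *, m: int = 10000, set_size: int, seed: int = 0,
    pool_ids: Optional[Sequence[str]] = None,
) -> Calibration:
    """Calibrate the mean-Rog statistic over m random subsets.

    ``pool_ids`` restricts the sampling pool (e.g. to an external reference
    panel); default is every genome in the stats matrix.
    """
    lookup = {g: i for i, g in enumerate(stats.ids)}
    pool = (np.arange(len(stats.ids)) if pool_ids is None
            else np.array(sorted(lookup[g] for g in pool_ids)))
    return _calibrate(
        pool, stats.mean_rog, m=m, set_size=set_size, seed=seed,
        kind="mean_rog", tail="two_sided",
    )


def calibrate_std_rge(
    rge_values: Mapping[str, float], *, m: int = 10000, set_size: int,
    seed: int = 0, pool_ids: Optional[Sequence[str]] = None,
) -> Calibration:
    """Calibrate the std-r_ge statistic over m random subsets (optionally
    restricted to a sampling pool, as for mean Rog)."""
    ids = sorted(rge_values)
    vec = np.array([rge_values[g] for g in ids])
    lookup = {g: i for i, g in enumerate(ids)}
    pool = (np.arange(len(ids)) if pool_ids is None
            else np.array(sorted(lookup[g] for g in pool_ids)))
    if set_size < 2:
        raise FilterError("std r_ge needs subsets of at least 2 genomes")

    def stat(subset: np.ndarray) -> float:
        return float(vec[subset].std(ddof=1))

    return _calibrate(
        pool, stat, m=m, set_size=set_size, seed=seed,
        kind="std_rge", tail="upper",
    )


def std_rge(rge_values: Mapping[str, float], ids: Sequence[str]) -> float:
    vec = np.array([rge_values[g] for g in ids])
    if vec.size < 2:
        raise FilterError("std r_ge needs at least 2 genomes")
    return float(vec.std(ddof=1))


def classify_set(stat_value: float, cal: Calibration) -> str:
    """Three-sigma classification; the closed interval boundary is ordinary.

    mean_rog: special iff |stat - mu| > 3 sigma (both tails).
    std_rge:  special iff stat > mu + 3 sigma (upper tail only; unusually
    homogeneous sets are not special for the barcode screen).
    """
    if cal.tail == "two_sided":
        return SSS if abs(stat_value - cal.mu) > 3.0 * cal.sigma else OSS
    if cal.tail == "upper":
        return SSS if stat_value > cal.mu + 3.0 * cal.sigma else OSS
    raise FilterError(f"unknown tail {cal.tail!r}")


# ---------------------------------------------------------------------------
# Eliminations
# ---------------------------------------------------------------------------

def eliminate_conserved(
    counts: Mapping[tuple[str, str], int],
    n_as: int,
    set_class: str,
    frac: float = 0.15,
) -> set[tuple[str, str]]:
    """Highly conserved gene elimination.

    For ordinary sets, genes orthologous in at least (1-frac) of the n_as
    panel species (count >= (1-frac)*n_as) are eliminated; special sets keep
    everything.  Keys are (genome_id, gene_id).
    """
    if not 0.0 < frac < 1.0:
        raise FilterError("frac must lie in (0, 1)")
    if set_class == SSS:
        return set()
    threshold = (1.0 - frac) * n_as
    return {key for key, cnt in counts.items() if cnt >= threshold}


def eliminate_barcode_genes(
    genome: AnnotatedGenome,
    profile: AnomalyProfile,
    set_class: str,
    frac: float = 0.2,
) -> set[str]:
    """Abnormal-barcode gene elimination for one genome.

    For special sets, fragments are walked in decreasing anomaly order,
    collecting every gene overlapping each fragment (any bp overlap, genes
    within a fragment in ascending index order) until floor(frac * N_g)
    genes are collected; the collection is truncated to exactly that count,
    so overflow from the last fragment drops its highest-index genes.
    Ordinary sets keep everything.
    """
    if genome.sequence is None:
        raise FilterError(f"genome {genome.id!r} has no sequence")
    if set_class == OSS:
        return set()
    cap = int(frac * genome.n_genes)
    if cap == 0:
        return set()
    collected: list[str] = []
    seen: set[str] = set()
    for frag in abnormal_fragments(profile):
        f_start = int(frag) * profile.L + 1
        f_end = (int(frag) + 1) * profile.L
        for g in genome.genes:  # genes already in ascending index order
            if g.id not in seen and g.overlaps(f_start, f_end):
                collected.append(g.id)
                seen.add(g.id)
        if len(collected) >= cap:
            break
    return set(collected[:cap])


def apply_elimination(
    maps: Mapping[tuple[str, str], OrthologMap],
    eliminated: Mapping[str, set[str]],
) -> dict[tuple[str, str], OrthologMap]:
    """Remove every ortholog pair touching an eliminated gene."""
    out: dict[tuple[str, str], OrthologMap] = {}
    for key, m in maps.items():
        gone_a = eliminated.get(m.genome_a_id, set())
        gone_b = eliminated.get(m.genome_b_id, set())
        pairs = [
            (ga, gb) for ga, gb in m.pairs
            if ga not in gone_a and gb not in gone_b
        ]
        out[key] = OrthologMap(
            genome_a_id=m.genome_a_id,
            genome_b_id=m.genome_b_id,
            pairs=pairs,
            evidence={p: m.evidence[p] for p in pairs if p in m.evidence},
            objective_value=m.objective_value,
        )
    return out
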