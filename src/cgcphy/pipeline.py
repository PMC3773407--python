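"""End-to-end orchestration of the four pipeline stages.

Stage 1 assigns orthologs for every genome pair (candidate filtering plus
the constrained matching).  Stage 2 optionally eliminates putative HGT
genes: the highly conserved screen (Rog classification against a random-set
calibration, occupancy-threshold elimination) and the barcode screen
(std-r_ge classification, anomalous-fragment gene elimination).  Stage 3
computes the conserved-gene-cluster distance matrix (or the raw
-log10(ortholog count) when clustering is disabled, the natural degenerate
case in which every ortholog is its own cluster).  Stage 4 builds the
neighbor-joining tree; a reference taxonomy, when supplied, is scored by
quartet agreement.

Calibrations and occupancy counts are computed over a *reference panel*: the
analysis set itself by default, or the analysis set plus extra reference
genomes when supplied.  A broad external panel mirrors the original design,
where every analysis set was a subset of a 617-genome universe; with a
self-panel, homogeneous analysis sets cannot be recognised as special (their
statistic sits at the calibration mean by construction), which is worth
remembering when interpreting the conserved-gene screen.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import dendropy

from . import barcode as bc
from . import hgt_filter as hf
from .cgc_distance import (ClusterParams, DistanceMatrix, count_distance_matrix,
                           distance_matrix)
from .genome_model import AnnotatedGenome, BergeyCode, SimilarityHit
from .orthology import (OrthoWeights, OrthologMap, assign_orthologs,
                        candidate_hits, ortholog_count_table)
from .quartet_eval import QuartetResult, quartet_accuracy, taxonomy_tree
from .tree_builder import neighbor_joining

logger = logging.getLogger(__name__)

ARMS = ("1", "1+2", "1+3", "1+2+3")


@dataclass
class PipelineOptions:
    """Tunable knobs for one pipeline run (defaults follow the method)."""

    weights: OrthoWeights = field(default_factory=OrthoWeights)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    # raw scores mirror the published configuration: bit-score-like values
    # dwarf the 0.5 operon penalties, which then act as tie-breakers only.
    # Per-pair normalisation ("normalized") makes the penalties dominant and
    # starves distant genome pairs of orthologs.
    score_mode: str = "raw"
    evalue_max: float = 1e-3
    min_identity: Optional[float] = 30.0
    cog_filter: bool = True
    rog_filter: bool = True
    barcode_filter: bool = True
    use_clusters: bool = True
    conserved_frac: float = 0.15
    barcode_frac: float = 0.2
    calibration_m: int = 10000
    calibration_set_size: Optional[int] = None
    # "panel": random calibration sets are drawn from the whole panel
    # (analysis + reference; the original design, where analysis sets are a
    # negligible fraction of a 617-genome universe).  "reference": drawn from
    # the external reference only - the appropriate null at desk scale,
    # where an anomalous analysis set would otherwise dominate its own
    # calibration and mask itself.
    calibration_scope: str = "panel"
    fragment_len: int = 1000
    zero_sentinel: float = 1.0
    clamp_negative: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    analysis_ids: list[str]
    maps: dict[tuple[str, str], OrthologMap]            # stage-1, panel-wide
    filtered_maps: dict[tuple[str, str], OrthologMap]   # analysis pairs
    eliminated: dict[str, set[str]]                     # union of both screens
    eliminated_by_reason: dict[str, dict[str, set[str]]]  # reason -> genome -> genes
    rog_calibration: Optional[hf.Calibration]
    rge_calibration: Optional[hf.Calibration]
    rog_class: Optional[str]
    rge_class: Optional[str]
    distance_matrix: DistanceMatrix
    tree: dendropy.Tree
    quartets: Optional[QuartetResult]
    log: list[dict]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def compute_stage1_maps(
    genomes: Sequence[AnnotatedGenome],
    hits: Mapping[tuple[str, str], Sequence[SimilarityHit]],
    options: PipelineOptions,
) -> dict[tuple[str, str], OrthologMap]:
    """Candidate filtering + constrained assignment for every genome pair."""
    by_id = {g.id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise ValueError("duplicate genome ids in panel")
    maps: dict[tuple[str, str], OrthologMap] = {}
    for a, b in itertools.combinations(sorted(by_id), 2):
        key = (a, b)
        if key not in hits:
            raise KeyError(f"missing similarity hits for genome pair {key}")
        cands = candidate_hits(
            hits[key], by_id[a], by_id[b],
            evalue_max=options.evalue_max,
            min_identity=options.min_identity,
            cog_filter=options.cog_filter,
        )
        maps[key] = assign_orthologs(
            cands, by_id[a], by_id[b], options.weights,
            score_mode=options.score_mode,
        )
    return maps


def _default_set_size(n_analysis: int, n_panel: int) -> int:
    """Calibration subsets the size of the analysis set (so the classified
    statistic is compared with like-sized random sets), shrunk when the
    panel is no larger than the analysis set."""
    if n_analysis < n_panel:
        return n_analysis
    return max(2, n_panel // 2)


def run_pipeline(
    analysis: Sequence[AnnotatedGenome],
    hits: Mapping[tuple[str, str], Sequence[SimilarityHit]],
    *,
    reference: Sequence[AnnotatedGenome] = (),
    options: PipelineOptions = PipelineOptions(),
    taxonomy: Optional[Mapping[str, BergeyCode]] = None,
    reference_tree: Optional[dendropy.Tree] = None,
    stage1_maps: Optional[Mapping[tuple[str, str], OrthologMap]] = None,
) -> PipelineResult:
    """Run the full pipeline on the analysis set.

    ``hits`` must cover every unordered pair of the panel (analysis plus
    reference genomes) when the Rog filter is active, and every analysis
    pair otherwise.  ``reference_tree`` or ``taxonomy`` enables quartet
    scoring.  Precomputed ``stage1_maps`` may be passed to share stage-1
    output across runs (stage toggles never alter stage-1 results).
    """
    analysis = list(analysis)
    panel = analysis + list(reference)
    analysis_ids = sorted(g.id for g in analysis)
    log: list[dict] = []

    if stage1_maps is not None:
        maps = dict(stage1_maps)
    elif options.rog_filter:
        maps = compute_stage1_maps(panel, hits, options)
    else:
        maps = compute_stage1_maps(analysis, hits, options)
    for key in itertools.combinations(analysis_ids, 2):
        log.append({"stage": "orthology", "pair": key, "n_pairs": maps[key].n_pairs})

    eliminated: dict[str, set[str]] = {g.id: set() for g in analysis}
    by_reason: dict[str, dict[str, set[str]]] = {
        "conserved": {g.id: set() for g in analysis},
        "barcode": {g.id: set() for g in analysis},
    }
    rog_cal = rge_cal = None
    rog_class = rge_class = None

    if options.calibration_scope not in ("panel", "reference"):
        raise ValueError(f"unknown calibration_scope {options.calibration_scope!r}")
    if options.calibration_scope == "reference" and not reference:
        raise ValueError("calibration_scope='reference' requires reference genomes")
    pool_ids = (sorted(g.id for g in reference)
                if options.calibration_scope == "reference" else None)
    n_pool = len(pool_ids) if pool_ids is not None else len(panel)

    if options.rog_filter:
        stats = hf.RogStats.from_maps(panel, maps)
        set_size = options.calibration_set_size or min(
            _default_set_size(len(analysis_ids), len(panel)), n_pool
        )
        rog_cal = hf.calibrate_mean_rog(
            stats, m=options.calibration_m, set_size=set_size,
            seed=options.seed, pool_ids=pool_ids,
        )
        rog_class = hf.classify_set(stats.mean_rog_of_ids(analysis_ids), rog_cal)
        counts = ortholog_count_table(panel, maps)
        conserved = hf.eliminate_conserved(
            counts, n_as=len(panel), set_class=rog_class,
            frac=options.conserved_frac,
        )
        for gid, gene in conserved:
            if gid in eliminated:
                eliminated[gid].add(gene)
                by_reason["conserved"][gid].add(gene)
        log.append({"stage": "rog_filter", "class": rog_class,
                    "n_eliminated": len(conserved)})

    if options.barcode_filter:
        profiles: dict[str, bc.AnomalyProfile] = {}
        for g in panel:
            bm = bc.compute_barcode(g, L=options.fragment_len)
            profiles[g.id] = bc.anomaly_profile(bm)
        rge_values = {gid: p.r_ge for gid, p in profiles.items()}
        set_size = options.calibration_set_size or min(
            _default_set_size(len(analysis_ids), len(panel)), n_pool
        )
        rge_cal = hf.calibrate_std_rge(
            rge_values, m=options.calibration_m, set_size=max(2, set_size),
            seed=options.seed + 1, pool_ids=pool_ids,
        )
        rge_class = hf.classify_set(hf.std_rge(rge_values, analysis_ids), rge_cal)
        by_id = {g.id: g for g in analysis}
        for gid in analysis_ids:
            removed = hf.eliminate_barcode_genes(
                by_id[gid], profiles[gid], rge_class, frac=options.barcode_frac,
            )
            eliminated[gid] |= removed
            by_reason["barcode"][gid] |= removed
            log.append({"stage": "barcode_filter", "genome": gid,
                        "class": rge_class, "n_eliminated": len(removed)})

    analysis_maps = {
        key: maps[key] for key in itertools.combinations(analysis_ids, 2)
    }
    filtered = hf.apply_elimination(analysis_maps, eliminated)

    if options.use_clusters:
        dm = distance_matrix(
            analysis, filtered, options.cluster_params,
            zero_sentinel=options.zero_sentinel,
        )
    else:
        dm = count_distance_matrix(
            analysis, filtered, zero_sentinel=options.zero_sentinel
        )
    for i, j in itertools.combinations(range(len(dm.taxa)), 2):
        key = (dm.taxa[i], dm.taxa[j])
        log.append({"stage": "distance", "pair": key,
                    "n_cgc": dm.counts[key], "d": float(dm.d[i, j])})

    tree = neighbor_joining(dm, clamp_negative=options.clamp_negative)

    quartets = None
    ref_tree = reference_tree
    if ref_tree is None and taxonomy is not None:
        ref_tree = taxonomy_tree(sorted((t, c) for t, c in taxonomy.items()
                                        if t in analysis_ids))
    if ref_tree is not None:
        mode = "exact" if len(analysis_ids) <= 60 else "sampled"
        quartets = quartet_accuracy(tree, ref_tree, mode=mode, seed=options.seed)
        log.append({"stage": "quartets", "mode": mode,
                    "accuracy": quartets.accuracy})

    return PipelineResult(
        analysis_ids=analysis_ids, maps=maps, filtered_maps=filtered,
        eliminated=eliminated, eliminated_by_reason=by_reason,
        rog_calibration=rog_cal, rge_calibration=rge_cal,
        rog_class=rog_class, rge_class=rge_class, distance_matrix=dm, tree=tree,
        quartets=quartets, log=log,
    )


def ablation(
    analysis: Sequence[AnnotatedGenome],
    hits: Mapping[tuple[str, str], Sequence[SimilarityHit]],
    *,
    reference: Sequence[AnnotatedGenome] = (),
    options: PipelineOptions = PipelineOptions(),
    taxonomy: Optional[Mapping[str, BergeyCode]] = None,
    reference_tree: Optional[dendropy.Tree] = None,
    arms: Sequence[str] = ARMS,
) -> dict[str, PipelineResult]:
    """Run selected stage combinations on identical stage-1 output.

    Arms: "1" orthologs only (count distance), "1+2" add HGT-gene
    elimination, "1+3" add cluster distance, "1+2+3" the full method.
    """
    if taxonomy is None and reference_tree is None:
        raise ValueError("ablation needs a taxonomy or a reference tree")
    for arm in arms:
        if arm not in ARMS:
            raise ValueError(f"unknown ablation arm {arm!r}")
    base = replace(options, rog_filter=True, barcode_filter=True)
    panel = list(analysis) + list(reference)
    stage1 = compute_stage1_maps(panel, hits, base)
    out: dict[str, PipelineResult] = {}
    for arm in arms:
        opts = replace(
            options,
            rog_filter="2" in arm,
            barcode_filter="2" in arm,
            use_clusters="3" in arm,
        )
        out[arm] = run_pipeline(
            analysis, hits, reference=reference, options=opts,
            taxonomy=taxonomy, reference_tree=reference_tree,
            stage1_maps=stage1,
        )
    return out


def write_ablation_table(results: Mapping[str, PipelineResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("arm\tn_effective\tn_agreed\taccuracy\n")
        for arm in sorted(results):
            q = results[arm].quartets
            acc = "" if q is None or q.accuracy is None else f"{q.accuracy:.4f}"
            fh.write(f"{arm}\t{q.n_effective}\t{q.n_agreed}\t{acc}\n")


def write_log(log: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in log:
            fields = "\t".join(f"{k}={v}" for k, v in rec.items())
            fh.write(fields + "\n")


def write_eliminated(result: PipelineResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\treason\n")
        for reason in sorted(result.eliminated_by_reason):
            per_genome = result.eliminated_by_reason[reason]
            for gid in sorted(per_genome):
                for gene in sorted(per_genome[gid]):
                    fh.write(f"{gid}\t{gene}\t{reason}\n")
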