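"""End-to-end orchestration: hits -> anchors -> chains -> pan-genome ->
haplotypes -> divergence track -> introgression blocks.

This is the programmatic equivalent of the ``run-all`` CLI subcommand; each
stage is an ordinary call into the corresponding module, so any intermediate
can be inspected or recomputed with different thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .anchors import TandemCluster, anchors_from_best_hits, best_hits, collapse_tandem
from .chaining import ChainParams, SyntelogPairSet, chain_anchors, call_syntelogs
from .haplotypes import (
    HaplotypeAssignment,
    HaplotypeCatalog,
    HdgTrack,
    assign_ancestral,
    build_haplotypes,
    hdg_track,
)
from .introgression import (
    ClusterTestResult,
    IntrogressionBlock,
    block_summary,
    cluster_test,
    low_hdg_mask,
    merge_blocks,
    significant_blocks,
)
from .io import GenomeAnnotation, GroupConfig, HitRecord
from .pangenome import PanGenome, classify_occupancy, merge_pairwise

__all__ = ["PipelineResult", "run_all", "annotation_span", "planted_recovery"]


def annotation_span(ann: GenomeAnnotation) -> int:
    """Approximate assembly length: summed rightmost gene end per chromosome."""
    return sum(max(g.end for g in genes) for genes in ann.genes_by_chrom.values())


@dataclass
class PipelineResult:
    pan: PanGenome
    occupancy: dict[str, str]
    catalogs: dict[str, HaplotypeCatalog]
    assignments: list[HaplotypeAssignment]
    track: HdgTrack
    mask: np.ndarray
    blocks: list[IntrogressionBlock]
    cluster_results: dict[str, ClusterTestResult]
    significant: list[IntrogressionBlock]
    summary: dict[str, float]
    pair_sets: list[SyntelogPairSet] = field(default_factory=list)
    tandem_clusters: dict[str, list[TandemCluster]] = field(default_factory=dict)
    annotations: dict[str, GenomeAnnotation] = field(default_factory=dict)


def run_all(
    annotations: Mapping[str, GenomeAnnotation],
    hits_by_pair: Mapping[tuple[str, str], Sequence[HitRecord]],
    groups: GroupConfig,
    pop_a_labels: Sequence[str],
    pop_b_labels: Sequence[str],
    order: Sequence[str] | None = None,
    chain_params: ChainParams = ChainParams(),
    best_hit_mode: str = "per_query",
    max_tandem_gap: int = 1,
    soft_core_frac: float = 0.90,
    min_dominant_freq: int = 3,
    min_presence_total: int = 10,
    hdg_threshold: float = 0.5,
    min_block_sgs: int = 10,
    window: int = 10,
    step: int = 1,
    n_reps: int = 100_000,
    alpha: float = 0.01,
    gap_tolerance: int = 0,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full pipeline with the reference default thresholds."""
    if order is None:
        order = list(annotations)
    order = list(order)
    framework = order[0]

    # per-pair best hits
    best_by_pair: dict[tuple[str, str], list[HitRecord]] = {}
    for key, hits in hits_by_pair.items():
        ga, gb = key
        if ga not in annotations or gb not in annotations:
            continue
        best_by_pair[key] = best_hits(list(hits), best_hit_mode)

    # one collapse pass per genome, pooling its query-side best hits
    pooled: dict[str, list[HitRecord]] = {g: [] for g in order}
    for (ga, gb), best in best_by_pair.items():
        for h in best:
            if h.query_gene in annotations[ga]:
                pooled[ga].append(h)
            elif h.query_gene in annotations[gb]:
                pooled[gb].append(h)
    collapsed: dict[str, GenomeAnnotation] = {}
    clusters: dict[str, list[TandemCluster]] = {}
    for g in order:
        collapsed[g], clusters[g] = collapse_tandem(
            annotations[g], pooled[g], max_tandem_gap
        )
    retained = {g: {gene.gene_id for gene in collapsed[g]} for g in order}

    # chain each genome pair and call syntelogs
    pair_sets: list[SyntelogPairSet] = []
    for ga, gb in itertools.combinations(order, 2):
        best = best_by_pair.get((ga, gb), best_by_pair.get((gb, ga)))
        if best is None:
            continue
        best = [
            h
            for h in best
            if (h.query_gene in retained[ga] or h.query_gene in retained[gb])
            and (h.subject_gene in retained[ga] or h.subject_gene in retained[gb])
        ]
        anchors = anchors_from_best_hits(collapsed[ga], collapsed[gb], best)
        anchors.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))
        chains = []
        for _key, group in itertools.groupby(
            anchors, key=lambda a: (a.chrom_a, a.chrom_b)
        ):
            chains.extend(chain_anchors(list(group), chain_params, ga, gb))
        pair_sets.append(call_syntelogs(chains, ga, gb))

    pan = merge_pairwise(collapsed, pair_sets, order)
    occupancy = classify_occupancy(pan, soft_core_frac)

    proteins = {g: collapsed[g].proteins for g in order}
    catalogs = {sg.sg_id: build_haplotypes(sg, proteins) for sg in pan.sgs}
    hap_groups = GroupConfig(dict(groups.assignment), list(groups.priority[:5]))
    assignments = [
        assign_ancestral(catalogs[sg.sg_id], hap_groups, min_dominant_freq, order)
        for sg in pan.sgs
    ]

    track = hdg_track(
        pan, catalogs, groups, pop_a_labels, pop_b_labels, min_presence_total
    )
    mask = low_hdg_mask(track, hdg_threshold)
    blocks = merge_blocks(mask, track, min_block_sgs, gap_tolerance)

    # permutation clustering test per chromosome
    rng = np.random.default_rng(seed)
    chroms: dict[str, list[int]] = {}
    for i, entry in enumerate(track.entries):
        chroms.setdefault(entry[1], []).append(i)
    results: dict[str, ClusterTestResult] = {}
    for chrom in sorted(chroms):
        idx = chroms[chrom]
        local_low = [k for k, i in enumerate(idx) if mask[i]]
        results[chrom] = cluster_test(
            len(idx),
            local_low,
            window=window,
            step=step,
            n_reps=n_reps,
            seed=int(rng.integers(2**31)),
            chrom=chrom,
        )
    significant = significant_blocks(blocks, results, alpha)
    summary = block_summary(blocks, annotation_span(annotations[framework]))

    return PipelineResult(
        pan=pan,
        occupancy=occupancy,
        catalogs=catalogs,
        assignments=assignments,
        track=track,
        mask=mask,
        blocks=blocks,
        cluster_results=results,
        significant=significant,
        summary=summary,
        pair_sets=pair_sets,
        tandem_clusters=clusters,
        annotations=collapsed,
    )


def planted_recovery(truth, pan: PanGenome, blocks: Sequence[IntrogressionBlock]):
    """Compare detected blocks with a simulation's planted truth.

    Returns (recovered_fraction, false_inclusion_fraction): the fraction of
    planted SG indices inside detected blocks, and the fraction of detected
    SG indices lying outside any planted block.
    """
    sg_to_truth = truth.truth_index_of_pan_sg(pan)
    detected: set[int] = set()
    for blk in blocks:
        for sg_id in blk.sg_ids:
            t = sg_to_truth.get(sg_id)
            if t is not None:
                detected.add(int(t))
    planted: set[int] = set()
    for arr in truth.planted_sg_indices:
        planted.update(int(x) for x in arr)
    recovered = len(detected & planted) / len(planted) if planted else float("nan")
    false_incl = (
        len(detected - planted) / len(detected) if detected else 0.0
    )
    return recovered, false_incl
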