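"""Iterative merge of pairwise syntelog sets into a pan-genome of syntelog
groups (SGs), plus occupancy classification and composition analyses.

The merge is strictly incremental: genomes are added one at a time to a
framework genome. Each incoming gene that is syntenic (via any available
pairwise syntelog pair) to genes of exactly one existing SG joins that SG;
a gene linking to several SGs goes with the SG gathering the majority of its
links (ties: earliest-created SG); a gene linking to none founds a new SG.
SGs are never retroactively fused, so every gene belongs to exactly one SG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chaining import SyntelogPairSet
from .io import GenomeAnnotation, GroupConfig

__all__ = [
    "SyntelogGroup",
    "PanGenome",
    "pan_from_matrix",
    "merge_pairwise",
    "classify_occupancy",
    "subpopulation_composition",
    "pan_growth_curve",
    "pav_bias",
]

_EPS = 1e-9


@dataclass
class SyntelogGroup:
    sg_id: str
    members: dict[str, str] = field(default_factory=dict)  # genome_id -> gene_id
    framework_anchor: tuple[str, int, int, int] | None = None  # chrom, start, end, rank

    @property
    def occupancy(self) -> int:
        return len(self.members)


@dataclass
class PanGenome:
    """All SGs, ordered by framework coordinates; SGs without a framework
    member are appended after the anchored ones."""

    sgs: list[SyntelogGroup]
    framework_id: str
    genomes: list[str]

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def presence_matrix(self) -> pd.DataFrame:
        """Boolean SG x genome presence matrix."""
        data = np.zeros((len(self.sgs), self.n_genomes), dtype=bool)
        col = {g: k for k, g in enumerate(self.genomes)}
        for i, sg in enumerate(self.sgs):
            for g in sg.members:
                data[i, col[g]] = True
        return pd.DataFrame(data, index=[sg.sg_id for sg in self.sgs], columns=self.genomes)

    def total_genes(self) -> int:
        return sum(sg.occupancy for sg in self.sgs)


def pan_from_matrix(
    genomes: Sequence[str],
    rows: Sequence[tuple[str, dict[str, str]]],
    annotations: Mapping[str, GenomeAnnotation],
    framework_id: str | None = None,
) -> PanGenome:
    """Rebuild a PanGenome from a pan-matrix (as read by io.read_pan_matrix),
    restoring framework anchors from the framework annotation."""
    framework_id = framework_id or genomes[0]
    fw = annotations.get(framework_id)
    sgs = []
    for sg_id, members in rows:
        anchor = None
        gid = members.get(framework_id)
        if fw is not None and gid is not None and gid in fw:
            g = fw.gene(gid)
            anchor = (g.chrom, g.start, g.end, g.rank)
        sgs.append(SyntelogGroup(sg_id, dict(members), anchor))
    return PanGenome(sgs, framework_id, list(genomes))


def merge_pairwise(
    annotations: Mapping[str, GenomeAnnotation],
    pair_sets: Sequence[SyntelogPairSet],
    order: Sequence[str],
) -> PanGenome:
    """Merge pairwise syntelog sets over ``order`` (framework genome first).

    ``annotations`` must contain every genome in ``order`` (post tandem
    collapse); ``pair_sets`` hold the syntelog pairs available between any
    already-merged genome and each incoming genome.
    """
    if not order:
        raise ValueError("empty merge order")
    framework_id = order[0]
    for g in order:
        if g not in annotations:
            raise ValueError(f"no annotation for genome {g!r}")

    # index pairs by (incoming genome) -> partner gene links
    # links[new_genome][new_gene] = list of partner gene ids
    links: dict[str, dict[str, list[str]]] = {g: {} for g in order}
    pos = {g: i for i, g in enumerate(order)}
    for ps in pair_sets:
        if ps.genome_a not in pos or ps.genome_b not in pos:
            raise ValueError(f"pair set references unknown genome {ps.genome_a}/{ps.genome_b}")
        # later genome in the merge order is the incoming side
        if pos[ps.genome_a] < pos[ps.genome_b]:
            old_g, new_g, flip = ps.genome_a, ps.genome_b, False
        else:
            old_g, new_g, flip = ps.genome_b, ps.genome_a, True
        ann_old = annotations[old_g]
        ann_new = annotations[new_g]
        for a, b in ps.pairs:
            old_gene, new_gene = (b, a) if flip else (a, b)
            if old_gene not in ann_old or new_gene not in ann_new:
                raise ValueError(
                    f"pair ({a}, {b}) references gene absent from annotations"
                )
            links[new_g].setdefault(new_gene, []).append(old_gene)

    sgs: list[SyntelogGroup] = []
    sg_of_gene: dict[str, int] = {}  # gene_id -> sg creation index

    fw = annotations[framework_id]
    for g in fw:
        idx = len(sgs)
        sgs.append(
            SyntelogGroup(
                sg_id=f"tmp{idx}",
                members={framework_id: g.gene_id},
                framework_anchor=(g.chrom, g.start, g.end, g.rank),
            )
        )
        sg_of_gene[g.gene_id] = idx

    merged_rank = {framework_id: 0}
    for step, new_g in enumerate(order[1:], 1):
        ann = annotations[new_g]
        glinks = links[new_g]
        for gene in ann:  # deterministic chromosome/rank order
            gid = gene.gene_id
            votes: dict[int, int] = {}
            for partner in glinks.get(gid, ()):
                sg_idx = sg_of_gene.get(partner)
                if sg_idx is not None:
                    votes[sg_idx] = votes.get(sg_idx, 0) + 1
            target = None
            if votes:
                best = max(votes.values())
                target = min(i for i, v in votes.items() if v == best)
                if new_g in sgs[target].members:
                    # SG already holds a gene of this genome; treat as unlinked
                    target = None
            if target is None:
                idx = len(sgs)
                sgs.append(SyntelogGroup(sg_id=f"tmp{idx}", members={new_g: gid}))
                sg_of_gene[gid] = idx
            else:
                sgs[target].members[new_g] = gid
                sg_of_gene[gid] = target
        merged_rank[new_g] = step

    # final ordering: framework-anchored SGs by coordinates, then the rest by
    # (merge step of earliest member, that member's coordinates)
    def sort_key(item: tuple[int, SyntelogGroup]):
        idx, sg = item
        if sg.framework_anchor is not None:
            chrom, start, _end, _rank = sg.framework_anchor
            return (0, chrom, start, idx)
        g0 = min(sg.members, key=lambda g: merged_rank[g])
        gene = annotations[g0].gene(sg.members[g0])
        return (1, merged_rank[g0], gene.chrom, gene.start, idx)

    ordered = [sg for _, sg in sorted(enumerate(sgs), key=sort_key)]
    width = len(str(max(len(ordered), 1)))
    for i, sg in enumerate(ordered):
        sg.sg_id = f"SG{i:0{width}d}"
    return PanGenome(ordered, framework_id, list(order))


def soft_core_lower_bound(n_genomes: int, soft_core_frac: float = 0.90) -> int:
    """Smallest occupancy counted as soft-core (ceil of frac * n)."""
    return math.ceil(soft_core_frac * n_genomes - _EPS)


def classify_occupancy(pan: PanGenome, soft_core_frac: float = 0.90) -> dict[str, str]:
    """Label each SG core / soft-core / dispensable / private.

    core: present in all genomes; soft-core: >= ceil(frac*n) but not all;
    private: one genome; dispensable: the rest (2 .. ceil(frac*n)-1).
    """
    n = pan.n_genomes
    if n < 2:
        raise ValueError("need at least 2 genomes to classify occupancy")
    lo = soft_core_lower_bound(n, soft_core_frac)
    out = {}
    for sg in pan.sgs:
        occ = sg.occupancy
        if occ == n:
            lab = "core"
        elif occ >= lo:
            lab = "soft-core"
        elif occ == 1:
            lab = "private"
        else:
            lab = "dispensable"
        out[sg.sg_id] = lab
    return out


def subpopulation_composition(
    pan: PanGenome,
    groups: GroupConfig,
    subset: Iterable[str],
    soft_core_frac: float = 0.90,
) -> tuple[dict[str, str], dict[str, int]]:
    """Reclassify SGs by occupancy within a sub-population.

    ``subset`` is a set of group labels; SGs absent from every subset genome
    are labelled ``absent``. Returns (per-SG labels, class counts).
    """
    genomes = groups.genomes_in(subset)
    genomes = [g for g in genomes if g in pan.genomes]
    if not genomes:
        raise ValueError("empty sub-population")
    n = len(genomes)
    lo = soft_core_lower_bound(n, soft_core_frac)
    gset = set(genomes)
    labels: dict[str, str] = {}
    counts = {"core": 0, "soft-core": 0, "dispensable": 0, "private": 0, "absent": 0}
    for sg in pan.sgs:
        occ = sum(1 for g in sg.members if g in gset)
        if occ == 0:
            lab = "absent"
        elif occ == n:
            lab = "core"
        elif occ >= lo and n > 1:
            lab = "soft-core"
        elif occ == 1:
            lab = "private"
        else:
            lab = "dispensable"
        labels[sg.sg_id] = lab
        counts[lab] += 1
    return labels, counts


def pan_growth_curve(
    pan: PanGenome,
    n_orders: int = 100,
    seed: int | None = None,
    return_raw: bool = False,
):
    """Pan and core SG counts as genomes accumulate, over random orderings.

    Returns a DataFrame (k, pan_mean, pan_sd, core_mean, core_sd); with
    ``return_raw`` also the per-order (n_orders, n_genomes) count arrays.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    pres = pan.presence_matrix().to_numpy()  # sgs x genomes
    n = pan.n_genomes
    pan_sizes = np.zeros((n_orders, n), dtype=np.int64)
    core_sizes = np.zeros((n_orders, n), dtype=np.int64)
    for o in range(n_orders):
        perm = rng.permutation(n)
        cum_any = np.logical_or.accumulate(pres[:, perm], axis=1)
        cum_all = np.logical_and.accumulate(pres[:, perm], axis=1)
        pan_sizes[o] = cum_any.sum(axis=0)
        core_sizes[o] = cum_all.sum(axis=0)
    df = pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_mean": pan_sizes.mean(axis=0),
            "pan_sd": pan_sizes.std(axis=0, ddof=0),
            "core_mean": core_sizes.mean(axis=0),
            "core_sd": core_sizes.std(axis=0, ddof=0),
        }
    )
    if return_raw:
        return df, pan_sizes, core_sizes
    return df


def pav_bias(
    pan: PanGenome,
    groups: GroupConfig,
    group_a: str,
    group_b: str,
    min_diff: float = 0.6,
) -> list[str]:
    """SGs whose presence frequency differs by >= ``min_diff`` between two
    groups (inclusive threshold)."""
    ga = [g for g in groups.genomes_in([group_a]) if g in pan.genomes]
    gb = [g for g in groups.genomes_in([group_b]) if g in pan.genomes]
    if not ga or not gb:
        raise ValueError("both groups must contain at least one genome in the pan-genome")
    sa, sb = set(ga), set(gb)
    out = []
    for sg in pan.sgs:
        fa = sum(1 for g in sg.members if g in sa) / len(ga)
        fb = sum(1 for g in sg.members if g in sb) / len(gb)
        if abs(fa - fb) >= min_diff - _EPS:
            out.append(sg.sg_id)
    return out
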