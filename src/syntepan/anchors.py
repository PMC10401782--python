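"""Best-hit filtering and tandem-duplicate collapsing.

Raw all-vs-all protein hits are reduced to anchor material in two steps:
keep only each query's best hit(s), then collapse runs of near-adjacent genes
that are individual-specific tandem duplicates (they share a best-hit subject
in the partner genome) down to a single representative gene. Without the
collapse, a duplicated gene on one side makes the pairwise search asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .io import GeneModel, GenomeAnnotation, HitRecord

__all__ = ["AnchorPair", "TandemCluster", "best_hits", "collapse_tandem"]


@dataclass(frozen=True)
class AnchorPair:
    """A retained best hit between two genomes, with the positional context
    (rank and bp midpoint on each genome) that chaining needs.

    ``score`` is the bitscore normalised by twice the query protein length,
    i.e. roughly the fraction of a perfect self-hit (~2 bits/residue); the
    chainer caps it at its maximum match score.
    """

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    mid_a: float
    mid_b: float
    score: float = 1.0


@dataclass(frozen=True)
class TandemCluster:
    genome_id: str
    chrom: str
    member_gene_ids: tuple[str, ...]
    representative: str


def best_hits(
    hits: Sequence[HitRecord], mode: Literal["per_query", "reciprocal"] = "per_query"
) -> list[HitRecord]:
    """Keep, per query gene, the hit(s) with maximal bitscore (ties all kept).

    ``reciprocal`` additionally requires (q, s) to be best in both directions,
    i.e. s is among q's best subjects and q is among s's best subjects over
    the rows where each acts as the query.
    """
    if mode not in ("per_query", "reciprocal"):
        raise ValueError(f"unknown mode {mode!r}")
    best_score: dict[str, float] = {}
    for h in hits:
        prev = best_score.get(h.query_gene)
        if prev is None or h.bitscore > prev:
            best_score[h.query_gene] = h.bitscore
    kept = [h for h in hits if h.bitscore == best_score[h.query_gene]]
    if mode == "per_query":
        return kept
    best_subjects: dict[str, set[str]] = {}
    for h in kept:
        best_subjects.setdefault(h.query_gene, set()).add(h.subject_gene)
    return [
        h
        for h in kept
        if h.query_gene in best_subjects.get(h.subject_gene, ())
    ]


def _primary_subjects(best: Iterable[HitRecord]) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Best-hit subject set and top bitscore per query gene."""
    subjects: dict[str, set[str]] = {}
    top: dict[str, float] = {}
    for h in best:
        subjects.setdefault(h.query_gene, set()).add(h.subject_gene)
        if h.bitscore > top.get(h.query_gene, -1.0):
            top[h.query_gene] = h.bitscore
    return subjects, top


def collapse_tandem(
    annotation: GenomeAnnotation,
    best: Sequence[HitRecord],
    max_tandem_gap: int = 1,
) -> tuple[GenomeAnnotation, list[TandemCluster]]:
    """Collapse runs of near-adjacent genes sharing a best-hit subject.

    Genes on the same chromosome whose ranks differ by at most
    ``max_tandem_gap`` and whose best-hit subject sets intersect are treated
    as one tandem cluster; the member with the highest best-hit bitscore
    (ties: smallest rank) represents the cluster. Returns the collapsed
    annotation (ranks recomputed) and the clusters found. With no tandems the
    transform is the identity.
    """
    subjects, top = _primary_subjects(best)
    keep: set[str] = set()
    clusters: list[TandemCluster] = []
    for chrom, genes in annotation.genes_by_chrom.items():
        run: list[GeneModel] = []
        run_subjects: set[str] = set()

        def flush() -> None:
            if not run:
                return
            if len(run) == 1:
                keep.add(run[0].gene_id)
            else:
                rep = max(run, key=lambda g: (top.get(g.gene_id, -1.0), -g.rank))
                keep.add(rep.gene_id)
                clusters.append(
                    TandemCluster(
                        annotation.genome_id,
                        chrom,
                        tuple(g.gene_id for g in run),
                        rep.gene_id,
                    )
                )

        for g in genes:
            subs = subjects.get(g.gene_id, set())
            if (
                run
                and subs
                and run_subjects & subs
                and g.rank - run[-1].rank <= max_tandem_gap
            ):
                run.append(g)
                run_subjects &= subs
            else:
                flush()
                run = [g]
                run_subjects = set(subs)
        flush()
    collapsed = annotation.subset(keep)
    return collapsed, clusters


def anchors_from_best_hits(
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    best: Sequence[HitRecord],
) -> list[AnchorPair]:
    """Orient best hits (either direction) into AnchorPairs from ``ann_a`` to
    ``ann_b``; hits touching genes absent from either annotation are dropped
    and duplicate (gene_a, gene_b) pairs are merged keeping the higher score."""
    pairs: dict[tuple[str, str], float] = {}
    for h in best:
        if h.query_gene in ann_a and h.subject_gene in ann_b:
            ga, gb = h.query_gene, h.subject_gene
            qlen = len(ann_a.proteins.get(ga, "")) or h.align_len
        elif h.query_gene in ann_b and h.subject_gene in ann_a:
            ga, gb = h.subject_gene, h.query_gene
            qlen = len(ann_b.proteins.get(h.query_gene, "")) or h.align_len
        else:
            continue
        score = h.bitscore / (2.0 * qlen) if qlen else 1.0
        key = (ga, gb)
        if score > pairs.get(key, -1.0):
            pairs[key] = score
    out = []
    for (ga, gb), score in pairs.items():
        a = ann_a.gene(ga)
        b = ann_b.gene(gb)
        out.append(
            AnchorPair(
                ga, gb, a.chrom, b.chrom, a.rank, b.rank, a.midpoint, b.midpoint, score
            )
        )
    out.sort(key=lambda p: (p.chrom_a, p.rank_a, p.chrom_b, p.rank_b))
    return out
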