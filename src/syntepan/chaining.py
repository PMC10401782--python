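"""Collinear anchor chaining by dynamic programming.

Anchors between one chromosome pair form a DAG: anchor j can precede anchor i
when both rank coordinates move strictly in the chain's direction (ascending
for same-orientation synteny, descending on genome B for inversions) and the
bp distance between the two anchor midpoints is within the distance cap D on
*both* genomes. The chain score is the sum of per-anchor match scores, each
capped at Z, minus a gap penalty of g per skipped gene on either genome.
Chains shorter than the minimum anchor count A are discarded, and accepted
chains are extracted greedily by descending score with non-overlapping
anchors.

Defaults follow the reference configuration: Z = 12, D = 200 kb, g = 1,
A = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .anchors import AnchorPair
from .io import GenomeAnnotation

__all__ = [
    "ChainParams",
    "SyntenyChain",
    "SyntelogPairSet",
    "chain_anchors",
    "optimal_chain_score",
    "call_syntelogs",
    "synteny_kinship",
]


@dataclass(frozen=True)
class ChainParams:
    """Chaining parameters.

    max_match_score: cap Z on each anchor's contribution (score units).
    max_dist: cap D on the bp distance between consecutive anchors, applied
        on both genomes.
    gap_penalty: cost g per gene skipped between consecutive anchors.
    min_aligned_pairs: minimum number A of anchors per accepted chain.
    """

    max_match_score: float = 12.0
    max_dist: int = 200_000
    gap_penalty: float = 1.0
    min_aligned_pairs: int = 5

    def __post_init__(self) -> None:
        if self.min_aligned_pairs < 2:
            raise ValueError("min_aligned_pairs must be >= 2")
        if self.max_dist <= 0 or self.max_match_score <= 0 or self.gap_penalty < 0:
            raise ValueError("invalid chain parameters")

    def match(self, anchor: AnchorPair) -> float:
        """Per-anchor match score: bitscore-derived, capped at Z."""
        return min(anchor.score * self.max_match_score, self.max_match_score)


@dataclass
class SyntenyChain:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "ascending" | "descending"
    anchors: list[AnchorPair]
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class SyntelogPairSet:
    genome_a: str
    genome_b: str
    pairs: set[tuple[str, str]] = field(default_factory=set)


def _check_single_chrom_pair(anchors: Sequence[AnchorPair]) -> None:
    pairs = {(a.chrom_a, a.chrom_b) for a in anchors}
    if len(pairs) > 1:
        raise ValueError(f"anchors span multiple chromosome pairs: {sorted(pairs)}")


def _dp(
    ra: np.ndarray,
    rb: np.ndarray,
    ma: np.ndarray,
    mb: np.ndarray,
    match: np.ndarray,
    D: float,
    g: float,
    active: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Highest-scoring-path DP over anchors sorted by (ra, rb) ascending.

    Returns (dp, parent); dp[i] is the best chain score ending at i,
    parent[i] the predecessor index or -1. Inactive anchors get dp = -inf.
    """
    n = len(ra)
    dp = np.full(n, -np.inf)
    parent = np.full(n, -1, dtype=np.int64)
    # midpoints are only approximately monotone in rank (long genes can
    # overtake short neighbours), so the searchsorted window is taken on the
    # running max and the distance re-checked exactly below
    macum = np.maximum.accumulate(ma)
    for i in range(n):
        if not active[i]:
            continue
        dp[i] = match[i]
        # candidate predecessors: strictly smaller on both axes, within D
        lo = int(np.searchsorted(macum, ma[i] - D, side="left"))
        if lo >= i:
            continue
        j = np.arange(lo, i)
        ok = (
            active[j]
            & (ra[j] < ra[i])
            & (rb[j] < rb[i])
            & (np.abs(ma[i] - ma[j]) <= D)
            & (np.abs(mb[i] - mb[j]) <= D)
        )
        if not ok.any():
            continue
        jj = j[ok]
        gap = g * ((ra[i] - ra[jj] - 1) + (rb[i] - rb[jj] - 1))
        cand = dp[jj] - gap
        k = int(np.argmax(cand))
        if cand[k] > 0:
            dp[i] = match[i] + cand[k]
            parent[i] = jj[k]
    return dp, parent


def _backtrack(parent: np.ndarray, i: int) -> list[int]:
    path = []
    while i >= 0:
        path.append(i)
        i = int(parent[i])
    path.reverse()
    return path


def chain_anchors(
    anchors: Sequence[AnchorPair],
    params: ChainParams = ChainParams(),
    genome_a: str = "",
    genome_b: str = "",
) -> list[SyntenyChain]:
    """Chain anchors from one (chrom_a, chrom_b) pair into syntenic chains.

    Both orientations are searched; accepted chains have at least
    ``params.min_aligned_pairs`` anchors and share no anchors (greedy
    extraction by descending score, ties broken by leftmost start).
    """
    if not anchors:
        return []
    _check_single_chrom_pair(anchors)
    order = sorted(range(len(anchors)), key=lambda k: (anchors[k].rank_a, anchors[k].rank_b))
    arr = [anchors[k] for k in order]
    ra = np.array([a.rank_a for a in arr], dtype=np.int64)
    rb = np.array([a.rank_b for a in arr], dtype=np.int64)
    ma = np.array([a.mid_a for a in arr], dtype=np.float64)
    mb = np.array([a.mid_b for a in arr], dtype=np.float64)
    match = np.array([params.match(a) for a in arr], dtype=np.float64)
    chrom_a, chrom_b = arr[0].chrom_a, arr[0].chrom_b

    chains: list[SyntenyChain] = []
    used = np.zeros(len(arr), dtype=bool)
    while True:
        best: tuple[float, int, int, str, list[int]] | None = None
        for orientation in ("ascending", "descending"):
            if orientation == "ascending":
                dp, parent = _dp(ra, rb, ma, mb, match, params.max_dist, params.gap_penalty, ~used)
            else:
                # inversions: rank_b strictly decreasing <=> chain on -rank_b.
                # Re-sort by (ra, -rb) so predecessors precede successors.
                sub = sorted(range(len(arr)), key=lambda k: (ra[k], -rb[k]))
                sub = np.array(sub, dtype=np.int64)
                dp_s, parent_s = _dp(
                    ra[sub], -rb[sub], ma[sub], mb[sub], match[sub],
                    params.max_dist, params.gap_penalty, ~used[sub],
                )
                dp = np.full(len(arr), -np.inf)
                parent = np.full(len(arr), -1, dtype=np.int64)
                dp[sub] = dp_s
                parent[sub] = np.where(parent_s >= 0, sub[parent_s], -1)
            for i in np.argsort(-dp):
                i = int(i)
                if not np.isfinite(dp[i]):
                    break
                path = _backtrack(parent, i)
                if len(path) < params.min_aligned_pairs:
                    continue
                key = (-dp[i], int(ra[path[0]]), int(rb[path[0]]), orientation)
                if best is None or key < (-best[0], best[1], best[2], best[3]):
                    best = (float(dp[i]), int(ra[path[0]]), int(rb[path[0]]), orientation, path)
                break  # only the top surviving path per orientation per round
        if best is None:
            break
        score, _, _, orientation, path = best
        chains.append(
            SyntenyChain(
                genome_a, genome_b, chrom_a, chrom_b, orientation,
                [arr[k] for k in path], score,
            )
        )
        used[path] = True
    return chains


def optimal_chain_score(
    anchors: Sequence[AnchorPair], params: ChainParams = ChainParams()
) -> float:
    """Best single-chain score over both orientations, ignoring the minimum
    anchor count (0.0 if there are no anchors). This is the quantity the
    exhaustive-enumeration oracle reproduces on small instances."""
    if not anchors:
        return 0.0
    _check_single_chrom_pair(anchors)
    arr = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    ra = np.array([a.rank_a for a in arr], dtype=np.int64)
    rb = np.array([a.rank_b for a in arr], dtype=np.int64)
    ma = np.array([a.mid_a for a in arr], dtype=np.float64)
    mb = np.array([a.mid_b for a in arr], dtype=np.float64)
    match = np.array([params.match(a) for a in arr], dtype=np.float64)
    active = np.ones(len(arr), dtype=bool)
    best = -np.inf
    dp, _ = _dp(ra, rb, ma, mb, match, params.max_dist, params.gap_penalty, active)
    best = max(best, float(dp.max()))
    sub = sorted(range(len(arr)), key=lambda k: (ra[k], -rb[k]))
    sub = np.array(sub, dtype=np.int64)
    dp, _ = _dp(
        ra[sub], -rb[sub], ma[sub], mb[sub], match[sub],
        params.max_dist, params.gap_penalty, active,
    )
    best = max(best, float(dp.max()))
    return best


def call_syntelogs(
    chains: Iterable[SyntenyChain], genome_a: str = "", genome_b: str = ""
) -> SyntelogPairSet:
    """Union of anchors over accepted chains, one-to-one per genome pair; a
    gene claimed by two chains goes with the higher-scoring chain."""
    chains = sorted(
        chains,
        key=lambda c: (-c.score, c.anchors[0].rank_a if c.anchors else 0),
    )
    if chains:
        genome_a = genome_a or chains[0].genome_a
        genome_b = genome_b or chains[0].genome_b
    used_a: set[str] = set()
    used_b: set[str] = set()
    out = SyntelogPairSet(genome_a, genome_b)
    for c in chains:
        for a in c.anchors:
            if a.gene_a in used_a or a.gene_b in used_b:
                continue
            used_a.add(a.gene_a)
            used_b.add(a.gene_b)
            out.pairs.add((a.gene_a, a.gene_b))
    return out


def synteny_kinship(pairs: SyntelogPairSet, ref_annotation: GenomeAnnotation) -> float:
    """Proportion of the reference genome's annotated genes that have a
    syntelog in the partner genome."""
    n_ref = len(ref_annotation)
    if n_ref == 0:
        raise ValueError("reference annotation is empty")
    ref_genes = {a for a, _ in pairs.pairs if a in ref_annotation}
    return len(ref_genes) / n_ref
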