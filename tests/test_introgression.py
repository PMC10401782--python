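import itertools
import math

import numpy as np
import pytest

from syntepan import (
    block_summary,
    cluster_test,
    low_hdg_mask,
    merge_blocks,
    significant_blocks,
)
from syntepan.haplotypes import HdgTrack


def _track(values, chrom="chr4", start0=0, span=1000):
    entries = [
        (f"SG{i}", chrom, start0 + i * span, start0 + i * span + span // 2, v)
        for i, v in enumerate(values)
    ]
    return HdgTrack(entries, ("a",), ("b",))


def exact_window_p(n, low, window=10, step=1):
    """Oracle: exact P per window by complete enumeration of C(n, k) placements."""
    k = len(low)
    obs = np.zeros(n, dtype=int)
    obs[list(low)] = 1
    starts = list(range(0, n - window + 1, step)) if n > window else [0]
    w = min(window, n)
    observed = [obs[s : s + w].sum() for s in starts]
    total = math.comb(n, k)
    exceed = [0] * len(starts)
    for combo in itertools.combinations(range(n), k):
        ind = np.zeros(n, dtype=int)
        ind[list(combo)] = 1
        for wi, s in enumerate(starts):
            if ind[s : s + w].sum() > observed[wi]:
                exceed[wi] += 1
    return np.array(starts), np.array([e / total for e in exceed])


class TestLowHdgMask:
    def test_strict_threshold_and_na(self):
        track = _track([0.49, 0.50, None, 0.0])
        assert low_hdg_mask(track).tolist() == [True, False, False, True]

    def test_all_zero_track(self):
        assert low_hdg_mask(_track([0.0] * 5)).all()


class TestMergeBlocks:
    def test_single_run(self):
        track = _track([0.1] * 12)
        blocks = merge_blocks(low_hdg_mask(track), track)
        assert len(blocks) == 1 and blocks[0].n_sgs == 12
        assert blocks[0].start == 0 and blocks[0].end == 11 * 1000 + 500

    def test_run_of_nine_dropped(self):
        track = _track([0.1] * 9 + [0.9])
        assert merge_blocks(low_hdg_mask(track), track) == []

    def test_single_high_sg_breaks_runs(self):
        track = _track([0.1] * 10 + [0.9] + [0.1] * 10)
        blocks = merge_blocks(low_hdg_mask(track), track)
        assert [b.n_sgs for b in blocks] == [10, 10]

    def test_gap_tolerance_bridges_single_interruption(self):
        track = _track([0.1] * 10 + [0.9] + [0.1] * 10)
        blocks = merge_blocks(low_hdg_mask(track), track, gap_tolerance=1)
        assert len(blocks) == 1 and blocks[0].n_sgs == 20

    def test_block_ids_numbered_by_descending_length(self):
        values = [0.1] * 10 + [0.9] * 3 + [0.1] * 15
        track = _track(values)
        blocks = merge_blocks(low_hdg_mask(track), track)
        by_id = {b.block_id: b.n_sgs for b in blocks}
        assert by_id == {"chr4#1": 15, "chr4#2": 10}

    def test_chromosome_change_breaks_run(self):
        e1 = _track([0.1] * 10, chrom="chr1").entries
        e2 = _track([0.1] * 10, chrom="chr2").entries
        track = HdgTrack(e1 + e2, ("a",), ("b",))
        blocks = merge_blocks(low_hdg_mask(track), track)
        assert sorted(b.block_id for b in blocks) == ["chr1#1", "chr2#1"]


class TestClusterTest:
    def test_all_low_gives_zero_p(self):
        res = cluster_test(20, list(range(20)), n_reps=500, seed=1)
        assert (res.p == 0).all()

    def test_empty_window_near_one(self):
        # all 6 low SGs at the right end; left windows hold none
        res = cluster_test(40, list(range(34, 40)), n_reps=2000, seed=1)
        assert res.p[0] > 0.8

    def test_exact_enumeration_agreement(self):
        n, low = 12, [0, 3, 7]
        starts, exact = exact_window_p(n, low)
        res = cluster_test(n, low, n_reps=100_000, seed=9)
        assert (res.window_starts == starts).all()
        se = np.sqrt(exact * (1 - exact) / res.n_replicates)
        assert (np.abs(res.p - exact) <= 3 * se + 1e-12).all()

    def test_deterministic_given_seed(self):
        a = cluster_test(50, [1, 2, 3, 10, 11], n_reps=3000, seed=77)
        b = cluster_test(50, [1, 2, 3, 10, 11], n_reps=3000, seed=77)
        assert (a.p == b.p).all() and (a.observed == b.observed).all()

    def test_tie_inclusive_mode_is_validly_calibrated(self):
        """Counting count >= observed yields a super-uniform P value under a
        uniform null: at most ~5% of null windows fall below 0.05."""
        rng = np.random.default_rng(55)
        n, k = 200, 30
        total = hits = 0
        for _ in range(30):
            low = rng.choice(n, size=k, replace=False).tolist()
            res = cluster_test(
                n, low, n_reps=2000, seed=int(rng.integers(2**31)),
                include_ties=True, pseudocount=True,
            )
            hits += int((res.p < 0.05).sum())
            total += len(res.p)
        assert hits / total <= 0.07  # 0.05 plus Monte-Carlo slack

    def test_strict_rule_never_exceeds_tie_inclusive_p(self):
        res_strict = cluster_test(40, [0, 1, 2, 3, 20], n_reps=3000, seed=4)
        res_ties = cluster_test(40, [0, 1, 2, 3, 20], n_reps=3000, seed=4,
                                include_ties=True)
        assert (res_strict.p <= res_ties.p).all()

    def test_pseudocount_mode(self):
        res = cluster_test(20, list(range(20)), n_reps=100, seed=0, pseudocount=True)
        assert res.p.min() == pytest.approx(1 / 101)

    def test_too_many_low_indices_rejected(self):
        with pytest.raises(ValueError):
            cluster_test(5, list(range(6)))


class TestSignificantBlocks:
    def _blocks_and_results(self, p_value):
        track = _track([0.1] * 12 + [0.9] * 20)
        blocks = merge_blocks(low_hdg_mask(track), track)
        n = len(track.entries)
        starts = np.arange(0, n - 10 + 1)
        p = np.ones(len(starts))
        p[0] = p_value
        from syntepan.introgression import ClusterTestResult

        res = ClusterTestResult("chr4", 10, 1, starts, np.zeros(len(starts)), p, 1000)
        return blocks, {"chr4": res}

    def test_kept_and_dropped(self):
        blocks, results = self._blocks_and_results(0.0001)
        assert len(significant_blocks(blocks, results)) == 1
        blocks, results = self._blocks_and_results(0.5)
        assert significant_blocks(blocks, results) == []

    def test_alpha_boundary_inclusive(self):
        blocks, results = self._blocks_and_results(0.01)
        kept = significant_blocks(blocks, results, alpha=0.01)
        assert len(kept) == 1 and kept[0].min_window_p == 0.01


class TestBlockSummary:
    def test_totals(self):
        from syntepan.introgression import IntrogressionBlock

        blocks = [
            IntrogressionBlock("c#1", "c", 0, 1_000_000, ["x"], [0], 0.1),
            IntrogressionBlock("c#2", "c", 2_000_000, 4_000_000, ["y"], [5], 0.2),
        ]
        s = block_summary(blocks, 100e6)
        assert s == {"n_blocks": 2, "total_bp": 3e6, "fraction": pytest.approx(0.03)}

    def test_no_blocks(self):
        s = block_summary([], 1e6)
        assert s["n_blocks"] == 0 and s["total_bp"] == 0 and s["fraction"] == 0
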