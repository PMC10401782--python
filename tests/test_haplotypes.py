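import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syntepan import (
    GroupConfig,
    SyntelogGroup,
    assign_ancestral,
    build_haplotypes,
    hdg,
)
from syntepan.haplotypes import HaplotypeCatalog


def _catalog(keys: dict[str, int], seqs=None) -> HaplotypeCatalog:
    n = max(keys.values()) + 1 if keys else 0
    seqs = seqs or [f"SEQ{k}" for k in range(n)]
    return HaplotypeCatalog("SG0", dict(keys), seqs)


def pairwise_hdg(cat, pop_a, pop_b):
    """Oracle: enumerate every cross-population pair of present members."""
    ka = [cat.hap_of[g] for g in pop_a if g in cat.hap_of]
    kb = [cat.hap_of[g] for g in pop_b if g in cat.hap_of]
    pairs = [(x, y) for x in ka for y in kb]
    if not pairs:
        return None
    return sum(1 for x, y in pairs if x != y) / len(pairs)


class TestBuildHaplotypes:
    def _sg(self, members):
        return SyntelogGroup("SG0", members)

    def test_identical_proteins_one_key(self):
        sg = self._sg({f"g{i}": f"g{i}_x" for i in range(5)})
        prot = {f"g{i}": {f"g{i}_x": "MKVA"} for i in range(5)}
        cat = build_haplotypes(sg, prot)
        assert set(cat.hap_of.values()) == {0}

    def test_single_substitution_makes_new_key(self):
        sg = self._sg({"g0": "x0", "g1": "x1"})
        prot = {"g0": {"x0": "MKVA"}, "g1": {"x1": "MKLA"}}
        cat = build_haplotypes(sg, prot)
        assert cat.hap_of["g0"] != cat.hap_of["g1"]

    def test_keys_ordered_by_frequency_then_sequence(self):
        sg = self._sg({"g0": "x0", "g1": "x1", "g2": "x2"})
        prot = {"g0": {"x0": "BBB"}, "g1": {"x1": "BBB"}, "g2": {"x2": "AAA"}}
        cat = build_haplotypes(sg, prot)
        assert cat.key_sequences == ["BBB", "AAA"]

    def test_missing_protein_rejected(self):
        sg = self._sg({"g0": "x0"})
        with pytest.raises(ValueError):
            build_haplotypes(sg, {"g0": {}})

    def test_matches_pairwise_equality_oracle(self, rng):
        for _ in range(20):
            seq_pool = ["MA", "MB", "MC", "MD"]
            members = {f"g{i}": f"x{i}" for i in range(10)}
            prot = {
                f"g{i}": {f"x{i}": seq_pool[rng.integers(0, 4)]} for i in range(10)
            }
            cat = build_haplotypes(SyntelogGroup("SG0", members), prot)
            for a, b in itertools.combinations(members, 2):
                same_seq = prot[a][members[a]] == prot[b][members[b]]
                assert (cat.hap_of[a] == cat.hap_of[b]) == same_seq


class TestAssignAncestral:
    GROUPS = GroupConfig(
        {**{f"t{i}": "tmp" for i in range(6)}, **{f"x{i}": "XI1A" for i in range(6)}},
        ["tmp", "XI1A"],
    )

    def test_dominant_key_takes_first_label(self):
        keys = {**{f"t{i}": 0 for i in range(5)}, "t5": 1}
        asg = assign_ancestral(_catalog(keys), self.GROUPS)
        assert asg.defined_labels["hapI"] == 0
        assert asg.label_of["t0"] == "hapI"
        assert asg.label_of["t5"] == "hapR"

    def test_shared_dominant_skips_second_label(self):
        keys = {**{f"t{i}": 0 for i in range(5)}, **{f"x{i}": 0 for i in range(5)}}
        asg = assign_ancestral(_catalog(keys), self.GROUPS)
        assert "hapII" not in asg.defined_labels
        assert asg.label_of["x0"] == "hapI"

    def test_min_dominant_frequency(self):
        keys = {"t0": 0, "t1": 0, **{f"x{i}": 1 for i in range(4)}}
        asg = assign_ancestral(_catalog(keys), self.GROUPS)
        # tmp dominant frequency 2 < 3: hapI undefined, members fall to hapR
        assert "hapI" not in asg.defined_labels
        assert asg.label_of["t0"] == "hapR"
        assert asg.defined_labels["hapII"] == 1

    def test_absent_genomes_labelled_absent(self):
        keys = {f"t{i}": 0 for i in range(4)}
        asg = assign_ancestral(_catalog(keys), self.GROUPS)
        assert asg.label_of["x0"] == "absent"

    def test_no_key_bound_twice_and_at_most_five_labels(self, rng):
        groups = GroupConfig(
            {f"g{i}_{j}": f"G{i}" for i in range(5) for j in range(5)},
            [f"G{i}" for i in range(5)],
        )
        for _ in range(20):
            keys = {
                f"g{i}_{j}": int(rng.integers(0, 3))
                for i in range(5)
                for j in range(5)
            }
            asg = assign_ancestral(_catalog(keys), groups)
            bound = list(asg.defined_labels.values())
            assert len(bound) == len(set(bound))
            assert len(bound) <= 5

    def test_invalid_priority_configurations_rejected(self):
        with pytest.raises(ValueError):
            assign_ancestral(_catalog({"t0": 0}), GroupConfig({"t0": "tmp"}, []))
        many = GroupConfig(
            {f"g{i}": f"G{i}" for i in range(6)}, [f"G{i}" for i in range(6)]
        )
        with pytest.raises(ValueError):
            assign_ancestral(_catalog({"g0": 0}), many)


class TestHdg:
    POP_A = [f"a{i}" for i in range(3)]
    POP_B = [f"b{i}" for i in range(3)]

    def test_monomorphic_same_key_is_zero(self):
        cat = _catalog({g: 0 for g in self.POP_A + self.POP_B + ["c0", "c1", "c2", "c3"]})
        assert hdg(cat, self.POP_A, self.POP_B) == 0.0

    def test_fixed_different_keys_is_one(self):
        keys = {g: 0 for g in self.POP_A} | {g: 1 for g in self.POP_B}
        keys |= {f"c{i}": 0 for i in range(4)}
        assert hdg(_catalog(keys), self.POP_A, self.POP_B) == 1.0

    def test_mixed_example_five_ninths(self):
        keys = {"a0": 0, "a1": 0, "a2": 1, "b0": 0, "b1": 1, "b2": 1}
        keys |= {f"c{i}": 0 for i in range(4)}
        value = hdg(_catalog(keys), self.POP_A, self.POP_B)
        assert value == pytest.approx(5 / 9)

    def test_presence_filter_returns_na(self):
        keys = {"a0": 0, "b0": 1}
        assert hdg(_catalog(keys), self.POP_A, self.POP_B) is None
        keys = {f"c{i}": 0 for i in range(12)}
        assert hdg(_catalog(keys), self.POP_A, self.POP_B) is None  # empty pops

    def test_overlapping_populations_rejected(self):
        with pytest.raises(ValueError):
            hdg(_catalog({"a0": 0}), ["a0"], ["a0"])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_closed_form_equals_pairwise_oracle(self, data):
        na = data.draw(st.integers(2, 8))
        nb = data.draw(st.integers(2, 8))
        keys = {}
        for i in range(na):
            keys[f"a{i}"] = data.draw(st.integers(0, 3))
        for i in range(nb):
            keys[f"b{i}"] = data.draw(st.integers(0, 3))
        cat = _catalog(keys)
        pa = [f"a{i}" for i in range(na)]
        pb = [f"b{i}" for i in range(nb)]
        got = hdg(cat, pa, pb, min_presence_total=1)
        assert got == pytest.approx(pairwise_hdg(cat, pa, pb), abs=1e-12)
        # symmetry and key-relabelling invariance
        assert hdg(cat, pb, pa, min_presence_total=1) == pytest.approx(got)
        relabelled = _catalog({g: 3 - k for g, k in keys.items()})
        assert hdg(relabelled, pa, pb, min_presence_total=1) == pytest.approx(got)


class TestHdgTrack:
    def test_monomorphic_panel_is_all_zero_and_ordered(self, small_panel):
        _, annotations, groups, truth, hits = small_panel
        from syntepan import run_all

        res = run_all(annotations, hits, groups, ["popA"], ["popB"], n_reps=10, seed=0)
        order = [e[0] for e in res.track.entries]
        anchored = [sg.sg_id for sg in res.pan.sgs if sg.framework_anchor is not None]
        assert order == anchored
        values = [e[4] for e in res.track.entries if e[4] is not None]
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_planted_region_lowers_divergence(self, small_panel):
        cfg, annotations, groups, truth, hits = small_panel
        from syntepan import run_all

        res = run_all(
            annotations, hits, groups, ["popA"], ["popB"],
            n_reps=10, min_presence_total=8, seed=0,
        )
        t2i = truth.truth_index_of_pan_sg(res.pan)
        planted = set(int(x) for arr in truth.planted_sg_indices for x in arr)
        inside, outside = [], []
        for sg_id, _c, _s, _e, v in res.track.entries:
            if v is None or sg_id not in t2i:
                continue
            (inside if t2i[sg_id] in planted else outside).append(v)
        assert np.mean(inside) < np.mean(outside)
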