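"""Per-SG haplotypes, ancestral haplotype labels, and inter-population
haplotype divergence (HDG).

A haplotype here is a distinct predicted protein sequence among an SG's
members: all coding variation within a gene is compressed to one state, and
identity is exact string equality (parameter free). Ancestral labels
hapI..hapV are bound, in a fixed group-priority order, to the dominant
haplotype of each designated group; all other observed haplotypes are pooled
as hapR for display. HDG between two populations is the probability that a
random present member of one and a random present member of the other carry
different haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GroupConfig
from .pangenome import PanGenome, SyntelogGroup

__all__ = [
    "HaplotypeCatalog",
    "HaplotypeAssignment",
    "HdgTrack",
    "ANCESTRAL_LABELS",
    "build_haplotypes",
    "assign_ancestral",
    "hdg",
    "hdg_track",
]

ANCESTRAL_LABELS = ("hapI", "hapII", "hapIII", "hapIV", "hapV")


@dataclass
class HaplotypeCatalog:
    """Raw haplotype keys for one SG: key k <-> the k-th most frequent
    distinct protein sequence (ties broken by lexicographic sequence)."""

    sg_id: str
    hap_of: dict[str, int]  # genome_id -> raw key; absent genomes omitted
    key_sequences: list[str]  # raw key -> protein sequence

    @property
    def n_present(self) -> int:
        return len(self.hap_of)


@dataclass
class HaplotypeAssignment:
    sg_id: str
    label_of: dict[str, str]  # genome_id -> hapI..hapV | hapR | absent
    defined_labels: dict[str, int] = field(default_factory=dict)  # label -> raw key


@dataclass
class HdgTrack:
    """Ordered per-SG HDG values along the framework coordinate system."""

    entries: list[tuple[str, str, int, int, float | None]]  # sg_id, chrom, start, end, hdg
    pop_a: tuple[str, ...]
    pop_b: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["sg_id", "chrom", "start", "end", "hdg"]
        )


def build_haplotypes(
    sg: SyntelogGroup, proteins: Mapping[str, Mapping[str, str]]
) -> HaplotypeCatalog:
    """Assign raw haplotype keys by exact protein identity.

    ``proteins`` maps genome_id -> {gene_id: sequence}. Keys are numbered by
    descending frequency, ties by lexicographically smaller sequence.
    """
    seq_of: dict[str, str] = {}
    for genome, gene in sg.members.items():
        try:
            seq_of[genome] = proteins[genome][gene]
        except KeyError:
            raise ValueError(
                f"{sg.sg_id}: missing protein for member {gene!r} of {genome!r}"
            ) from None
    counts: dict[str, int] = {}
    for s in seq_of.values():
        counts[s] = counts.get(s, 0) + 1
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    key_of_seq = {s: k for k, s in enumerate(ordered)}
    return HaplotypeCatalog(
        sg.sg_id, {g: key_of_seq[s] for g, s in seq_of.items()}, ordered
    )


def assign_ancestral(
    cat: HaplotypeCatalog,
    groups: GroupConfig,
    min_dominant_freq: int = 3,
    all_genomes: Iterable[str] | None = None,
) -> HaplotypeAssignment:
    """Bind ancestral labels to dominant haplotypes in group-priority order.

    The i-th priority group is offered the i-th label. Its dominant raw key
    (most frequent among the group's present members; ties -> smaller
    sequence) takes the label only if its in-group frequency reaches
    ``min_dominant_freq`` and it is not already bound to an earlier label;
    otherwise that label stays undefined for this SG. Present genomes whose
    key carries no label become hapR; absent genomes get ``absent``.
    """
    if not groups.priority:
        raise ValueError("group priority list is empty")
    if len(groups.priority) > len(ANCESTRAL_LABELS):
        raise ValueError(
            f"at most {len(ANCESTRAL_LABELS)} priority groups supported, "
            f"got {len(groups.priority)}"
        )
    known = set(groups.assignment.values())
    for p in groups.priority:
        if p not in known:
            raise ValueError(f"unknown group {p!r} in priority list")
    bound: dict[int, str] = {}  # raw key -> label
    defined: dict[str, int] = {}
    for label, grp in zip(ANCESTRAL_LABELS, groups.priority):
        members = [
            g for g, lab in groups.assignment.items() if lab == grp and g in cat.hap_of
        ]
        if not members:
            continue
        freq: dict[int, int] = {}
        for g in members:
            k = cat.hap_of[g]
            freq[k] = freq.get(k, 0) + 1
        dominant = min(freq, key=lambda k: (-freq[k], cat.key_sequences[k]))
        if freq[dominant] < min_dominant_freq:
            continue
        if dominant in bound:
            continue  # label skipped: dominant already owned by a former group
        bound[dominant] = label
        defined[label] = dominant
    universe = set(all_genomes) if all_genomes is not None else set(groups.assignment)
    label_of: dict[str, str] = {}
    for g in sorted(universe | set(cat.hap_of)):
        if g not in cat.hap_of:
            label_of[g] = "absent"
        else:
            label_of[g] = bound.get(cat.hap_of[g], "hapR")
    return HaplotypeAssignment(cat.sg_id, label_of, defined)


def hdg(
    cat: HaplotypeCatalog,
    pop_a: Iterable[str],
    pop_b: Iterable[str],
    min_presence_total: int = 10,
) -> float | None:
    """Inter-population haplotype divergence for one SG.

    The mean, over all cross-population pairs of present members, of the
    indicator that the two haplotypes differ; computed in the equivalent
    closed form 1 - sum_k f_a(k) f_b(k) over within-population key
    frequencies. Returns None (NA) when the SG is present in fewer than
    ``min_presence_total`` genomes overall or either population has no
    present member.
    """
    pa, pb = set(pop_a), set(pop_b)
    if pa & pb:
        raise ValueError("populations overlap")
    if cat.n_present < min_presence_total:
        return None
    keys_a = [cat.hap_of[g] for g in pa if g in cat.hap_of]
    keys_b = [cat.hap_of[g] for g in pb if g in cat.hap_of]
    if not keys_a or not keys_b:
        return None
    fa: dict[int, float] = {}
    for k in keys_a:
        fa[k] = fa.get(k, 0.0) + 1.0 / len(keys_a)
    fb: dict[int, float] = {}
    for k in keys_b:
        fb[k] = fb.get(k, 0.0) + 1.0 / len(keys_b)
    same = sum(fa[k] * fb.get(k, 0.0) for k in fa)
    return 1.0 - same


def hdg_track(
    pan: PanGenome,
    catalogs: Mapping[str, HaplotypeCatalog],
    groups: GroupConfig,
    pop_a_labels: Sequence[str],
    pop_b_labels: Sequence[str],
    min_presence_total: int = 10,
) -> HdgTrack:
    """HDG per framework-anchored SG, in framework coordinate order; NA
    entries are retained so the track keeps the full adjacency structure."""
    pop_a = groups.genomes_in(pop_a_labels)
    pop_b = groups.genomes_in(pop_b_labels)
    entries: list[tuple[str, str, int, int, float | None]] = []
    for sg in pan.sgs:
        if sg.framework_anchor is None:
            continue
        chrom, start, end, _rank = sg.framework_anchor
        cat = catalogs.get(sg.sg_id)
        value = (
            hdg(cat, pop_a, pop_b, min_presence_total) if cat is not None else None
        )
        entries.append((sg.sg_id, chrom, start, end, value))
    return HdgTrack(entries, tuple(pop_a), tuple(pop_b))
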