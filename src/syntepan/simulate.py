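"""Synthetic multi-genome panels with known ground truth.

The generator emulates the statistical structure of a multi-genome crop
panel: an ancestral ordered proteome, a core/soft-core/dispensable/private
occupancy spectrum, per-population haplotype (protein allele) frequencies,
individual-specific tandem duplicates, and planted introgression blocks in
which every population draws the donor population's haplotypes (forcing low
cross-population divergence). Fabricated all-vs-all hit tables stand in for
a protein aligner, with configurable false-positive / false-negative /
paralog noise.

Design notes (see docs/methods.md for the full rationale):

* Protein alleles differ from the ancestor by uniform random substitutions
  over the 20-letter alphabet; no indels by default, since haplotype
  identity downstream is exact string equality.
* Gene coordinates are non-overlapping, with intergenic spacing drawn from a
  geometric distribution, so the bp distance cap of the chainer is
  exercisable.
* Tandem duplicates are planted only on SGs shared by at least two genomes:
  an individual-specific duplicate of a shared gene is what creates the
  pairwise best-hit asymmetry the collapse step exists for, while a
  duplicate of a fully private gene yields no cross-genome hit at all.
* Planted-block SGs are forced to core/soft-core occupancy and always
  include the framework genome: a detected block lives on framework
  coordinates over SGs that pass the divergence presence filter, so a
  planted truth block must be measurable there to be detectable even in
  principle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, GenomeAnnotation, GroupConfig, HitRecord

__all__ = ["SimConfig", "HitNoise", "TruthTable", "simulate_panel", "simulate_hits"]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass(frozen=True)
class HitNoise:
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    paralog_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.fp_rate, self.fn_rate, self.paralog_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("noise rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Panel configuration; ``seed`` is mandatory.

    group_sizes: genomes per population group, in priority order.
    mixture: (core, soft-core, dispensable, private) SG proportions.
    background_major_freq: within-group frequency of each group's own
        favoured allele outside planted blocks.
    mutation_rate: substitutions/site used to derive each allele's distance
        from the ancestral protein.
    planted_blocks: (chrom, lo, hi, donor_group) with [lo, hi) chromosome-
        local SG index ranges; inside a block every group draws haplotypes
        from the donor group's frequencies.
    mean_spacing: mean intergenic spacing in bp (geometric distribution).
    """

    seed: int
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"popA": 15, "popB": 15}
    )
    n_sgs: int = 2000
    n_chromosomes: int = 1
    mixture: tuple[float, float, float, float] = (0.08, 0.08, 0.36, 0.48)
    background_major_freq: float = 0.9
    n_extra_alleles: int = 1
    mutation_rate: float = 0.005
    tandem_prob: float = 0.02
    planted_blocks: tuple[tuple[str, int, int, str], ...] = ()
    mean_spacing: int = 2000
    min_protein_len: int = 100
    max_protein_len: int = 500
    soft_core_frac: float = 0.90

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if not self.group_sizes or any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("each group needs at least one genome")
        if not 0.0 < self.background_major_freq <= 1.0:
            raise ValueError("background_major_freq must be in (0, 1]")
        per = self.n_sgs // self.n_chromosomes
        spans: dict[str, list[tuple[int, int]]] = {}
        for chrom, lo, hi, donor in self.planted_blocks:
            if donor not in self.group_sizes:
                raise ValueError(f"unknown donor group {donor!r}")
            if not (0 <= lo < hi <= per):
                raise ValueError(
                    f"planted range [{lo}, {hi}) exceeds the {per} SGs of {chrom}"
                )
            for plo, phi in spans.get(chrom, []):
                if lo < phi and plo < hi:
                    raise ValueError("planted ranges overlap")
            spans.setdefault(chrom, []).append((lo, hi))

    @property
    def genomes(self) -> list[str]:
        return [
            f"{lab}_{i + 1:02d}"
            for lab in self.group_sizes
            for i in range(self.group_sizes[lab])
        ]

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{c + 1}" for c in range(self.n_chromosomes)]


class TruthTable:
    """Ground truth for a simulated panel."""

    def __init__(
        self,
        config: SimConfig,
        gene_table: pd.DataFrame,
        presence: np.ndarray,
        freqs: np.ndarray,
        allele_seqs: list[list[str]],
        sg_chrom: list[str],
        sg_local: np.ndarray,
    ) -> None:
        self.config = config
        self.gene_table = gene_table  # genome, gene_id, chrom, sg_index, allele, is_tandem_dup
        self.presence = presence  # (n_sgs, n_genomes) bool
        self.freqs = freqs  # (n_sgs, n_groups, n_alleles)
        self.allele_seqs = allele_seqs  # per SG: allele index -> protein
        self.sg_chrom = sg_chrom
        self.sg_local = sg_local
        self.genomes = config.genomes
        self.group_labels = list(config.group_sizes)
        self._sg_of_gene = dict(zip(gene_table["gene_id"], gene_table["sg_index"]))

    def sg_of_gene(self, gene_id: str) -> int:
        return self._sg_of_gene[gene_id]

    def expected_hdg(self, group_a: str, group_b: str) -> np.ndarray:
        """Closed-form expected divergence 1 - sum_k f_a(k) f_b(k) per SG."""
        ia = self.group_labels.index(group_a)
        ib = self.group_labels.index(group_b)
        return 1.0 - (self.freqs[:, ia, :] * self.freqs[:, ib, :]).sum(axis=1)

    @property
    def planted_sg_indices(self) -> list[np.ndarray]:
        """Global SG indices of each planted block."""
        per = self.config.n_sgs // self.config.n_chromosomes
        out = []
        for chrom, lo, hi, _donor in self.config.planted_blocks:
            c = self.config.chrom_names.index(chrom)
            out.append(np.arange(c * per + lo, c * per + hi))
        return out

    def truth_index_of_pan_sg(self, pan) -> dict[str, int]:
        """Map pipeline SG ids to ancestral SG indices via their member genes
        (only SGs whose members agree on one ancestral SG are mapped)."""
        out = {}
        for sg in pan.sgs:
            idx = {self._sg_of_gene.get(g) for g in sg.members.values()}
            if len(idx) == 1 and None not in idx:
                out[sg.sg_id] = idx.pop()
        return out

    def matches_partition(self, pan) -> bool:
        """True iff the pipeline SG partition equals the truth exactly:
        a bijection between pipeline SGs and occupied ancestral SGs, with
        identical per-genome presence."""
        seen: dict[int, object] = {}
        for sg in pan.sgs:
            idx = {self._sg_of_gene.get(g) for g in sg.members.values()}
            if len(idx) != 1 or None in idx:
                return False
            t = idx.pop()
            if t in seen:
                return False
            seen[t] = sg
        gi = {g: i for i, g in enumerate(self.genomes)}
        for t, sg in seen.items():
            truth_genomes = {
                self.genomes[j] for j in np.nonzero(self.presence[t])[0]
            }
            if set(sg.members) != truth_genomes:
                return False
        occupied = int(self.presence.any(axis=1).sum())
        return len(seen) == occupied and len(gi) == len(self.genomes)


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in pos:
        cur = out[p]
        choices = _AA[_AA != cur]
        out[p] = rng.choice(choices)
    return out


def simulate_panel(
    config: SimConfig,
) -> tuple[dict[str, GenomeAnnotation], GroupConfig, TruthTable]:
    """Generate a panel: per-genome annotations (with proteins), the group
    configuration, and the ground truth."""
    rng = np.random.default_rng(config.seed)
    genomes = config.genomes
    n_genomes = len(genomes)
    labels = list(config.group_sizes)
    group_of = {
        f"{lab}_{i + 1:02d}": lab
        for lab in labels
        for i in range(config.group_sizes[lab])
    }
    group_idx = {lab: i for i, lab in enumerate(labels)}
    n_groups = len(labels)
    n_alleles = n_groups + config.n_extra_alleles
    framework = genomes[0]
    fw_col = 0

    per_chrom = config.n_sgs // config.n_chromosomes
    if per_chrom * config.n_chromosomes != config.n_sgs:
        raise ValueError("n_sgs must be divisible by n_chromosomes")
    sg_chrom = [config.chrom_names[i // per_chrom] for i in range(config.n_sgs)]
    sg_local = np.arange(config.n_sgs) % per_chrom

    # planted membership per global SG index
    planted_donor: dict[int, str] = {}
    for chrom, lo, hi, donor in config.planted_blocks:
        c = config.chrom_names.index(chrom)
        for i in range(c * per_chrom + lo, c * per_chrom + hi):
            planted_donor[i] = donor

    # ancestral proteome and alleles
    lengths = rng.integers(config.min_protein_len, config.max_protein_len + 1, config.n_sgs)
    allele_seqs: list[list[str]] = []
    for i in range(config.n_sgs):
        anc = rng.choice(_AA, size=int(lengths[i]))
        seqs = [anc]
        texts = {anc.tobytes()}
        for _m in range(1, n_alleles):
            while True:
                n_sub = max(1, int(rng.poisson(config.mutation_rate * lengths[i])))
                cand = _mutate(anc, n_sub, rng)
                if cand.tobytes() not in texts:
                    texts.add(cand.tobytes())
                    seqs.append(cand)
                    break
        allele_seqs.append([s.tobytes().decode() for s in seqs])

    # per-group allele frequencies
    freqs = np.zeros((config.n_sgs, n_groups, n_alleles))
    minor = (1.0 - config.background_major_freq) / max(n_alleles - 1, 1)
    for gidx in range(n_groups):
        freqs[:, gidx, :] = minor
        freqs[:, gidx, gidx] = config.background_major_freq
    for i, donor in planted_donor.items():
        freqs[i, :, :] = freqs[i, group_idx[donor], :][None, :]

    # occupancy spectrum
    soft_lo = math.ceil(config.soft_core_frac * n_genomes - 1e-9)
    classes = rng.choice(4, size=config.n_sgs, p=list(config.mixture))
    core_w, soft_w = config.mixture[0], config.mixture[1]
    p_core = core_w / (core_w + soft_w) if core_w + soft_w > 0 else 1.0
    presence = np.zeros((config.n_sgs, n_genomes), dtype=bool)
    for i in range(config.n_sgs):
        if i in planted_donor:
            cls = 0 if rng.random() < p_core else 1
        else:
            cls = int(classes[i])
        if cls == 0:
            presence[i, :] = True
            continue
        if cls == 1:
            # tiny panels can have ceil(0.9 n) == n; soft-core degenerates
            occ = int(rng.integers(soft_lo, n_genomes)) if soft_lo < n_genomes else n_genomes - 1
        elif cls == 2:
            occ = int(rng.integers(2, max(soft_lo, 3)))
        else:
            occ = 1
        if i in planted_donor:
            others = rng.choice(
                [j for j in range(n_genomes) if j != fw_col], size=occ - 1, replace=False
            )
            cols = np.concatenate(([fw_col], others))
        else:
            cols = rng.choice(n_genomes, size=occ, replace=False)
        presence[i, cols] = True

    # haplotype draws per present genome
    allele_of = np.full((config.n_sgs, n_genomes), -1, dtype=np.int64)
    for i in range(config.n_sgs):
        for j in np.nonzero(presence[i])[0]:
            f = freqs[i, group_idx[group_of[genomes[j]]]]
            allele_of[i, j] = rng.choice(n_alleles, p=f)

    shared = presence.sum(axis=1) >= 2

    # lay out genes and emit annotations
    annotations: dict[str, GenomeAnnotation] = {}
    rows: list[tuple[str, str, str, int, int, bool]] = []
    for j, genome in enumerate(genomes):
        genes: list[GeneModel] = []
        proteins: dict[str, str] = {}
        for c, chrom in enumerate(config.chrom_names):
            cursor = 0
            for i in range(c * per_chrom, (c + 1) * per_chrom):
                if not presence[i, j]:
                    continue
                allele = int(allele_of[i, j])
                seq = allele_seqs[i][allele]
                start = cursor + int(rng.geometric(1.0 / config.mean_spacing))
                end = start + 3 * len(seq)
                gid = f"{genome}_g{i:05d}"
                genes.append(GeneModel(genome, gid, chrom, start, end, "+"))
                proteins[gid] = seq
                rows.append((genome, gid, chrom, i, allele, False))
                cursor = end
                if shared[i] and rng.random() < config.tandem_prob:
                    dstart = cursor + int(rng.geometric(1.0 / config.mean_spacing))
                    dend = dstart + 3 * len(seq)
                    dgid = gid + "d"
                    genes.append(GeneModel(genome, dgid, chrom, dstart, dend, "+"))
                    proteins[dgid] = seq
                    rows.append((genome, dgid, chrom, i, allele, True))
                    cursor = dend
        annotations[genome] = GenomeAnnotation(genome, genes, proteins)

    gene_table = pd.DataFrame(
        rows, columns=["genome", "gene_id", "chrom", "sg_index", "allele", "is_tandem_dup"]
    )
    groups = GroupConfig(dict(group_of), labels)
    truth = TruthTable(
        config, gene_table, presence, freqs, allele_seqs, sg_chrom, sg_local
    )
    return annotations, groups, truth


def _allele_identity(allele_seqs: Sequence[str], a: int, b: int) -> float:
    if a == b:
        return 1.0
    u = np.frombuffer(allele_seqs[a].encode(), dtype=np.uint8)
    v = np.frombuffer(allele_seqs[b].encode(), dtype=np.uint8)
    return float((u == v).mean())


def simulate_hits(
    annotations: Mapping[str, GenomeAnnotation],
    truth: TruthTable,
    noise: HitNoise = HitNoise(),
    seed: int | None = None,
) -> dict[tuple[str, str], list[HitRecord]]:
    """Fabricate per-genome-pair hit tables from the true homology graph.

    With zero noise the emitted hits (both directions per gene pair) are
    exactly the cross-genome same-SG gene pairs, with bitscores decreasing in
    sequence divergence (2 bits/residue at identity 1). False positives and
    paralog hits link genes of different SGs at reduced bitscore; false
    negatives drop true pairs.
    """
    rng = np.random.default_rng(seed if seed is not None else truth.config.seed + 1)
    genomes = [g for g in truth.genomes if g in annotations]
    by_sg: dict[str, dict[int, list[tuple[str, int]]]] = {g: {} for g in genomes}
    gt = truth.gene_table
    for genome, gid, sg_i, allele in zip(
        gt["genome"], gt["gene_id"], gt["sg_index"], gt["allele"]
    ):
        if genome in by_sg and gid in annotations[genome]:
            by_sg[genome].setdefault(int(sg_i), []).append((gid, int(allele)))

    ident_cache: dict[tuple[int, int, int], float] = {}

    def ident(sg: int, a: int, b: int) -> float:
        key = (sg, min(a, b), max(a, b))
        if key not in ident_cache:
            ident_cache[key] = _allele_identity(truth.allele_seqs[sg], a, b)
        return ident_cache[key]

    out: dict[tuple[str, str], list[HitRecord]] = {}
    for ga, gb in itertools.combinations(genomes, 2):
        rows: list[HitRecord] = []
        shared = sorted(set(by_sg[ga]) & set(by_sg[gb]))
        n_true = 0
        for sg in shared:
            for gid_a, al_a in by_sg[ga][sg]:
                for gid_b, al_b in by_sg[gb][sg]:
                    n_true += 1
                    if noise.fn_rate > 0.0 and rng.random() < noise.fn_rate:
                        continue
                    pid = ident(sg, al_a, al_b)
                    alen = len(truth.allele_seqs[sg][al_a])
                    bits = 2.0 * alen * pid
                    rows.append(
                        HitRecord(gid_a, gid_b, 100.0 * pid, alen, 1e-50, bits)
                    )
                    rows.append(
                        HitRecord(gid_b, gid_a, 100.0 * pid, alen, 1e-50, bits)
                    )
        for rate, factor in ((noise.fp_rate, 0.3), (noise.paralog_rate, 0.5)):
            if rate <= 0.0 or n_true == 0:
                continue
            n_extra = rng.binomial(n_true, rate)
            genes_a = [x for sg in by_sg[ga] for x, _ in by_sg[ga][sg]]
            genes_b = [x for sg in by_sg[gb] for x, _ in by_sg[gb][sg]]
            for _ in range(n_extra):
                qa = genes_a[int(rng.integers(len(genes_a)))]
                qb = genes_b[int(rng.integers(len(genes_b)))]
                if truth.sg_of_gene(qa) == truth.sg_of_gene(qb):
                    continue
                alen = len(annotations[ga].proteins[qa])
                bits = factor * 2.0 * alen
                rows.append(HitRecord(qa, qb, 100.0 * factor, alen, 1e-10, bits))
        out[(ga, gb)] = rows
    return out
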