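"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open throughout: GFF3 is converted on
ingest, BED is taken verbatim, and all emitted interval files are BED-like.
Gene order (``rank``) is always recomputed from sorted start coordinates and
never trusted from input order, because all synteny logic downstream operates
on ranks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "GroupConfig",
    "HitRecord",
    "ParseError",
    "ValidationError",
    "read_gene_models",
    "read_protein_fasta",
    "read_hits",
    "read_group_config",
    "write_pan_matrix",
    "read_pan_matrix",
    "write_blocks_bed",
    "write_haplotype_table",
    "read_haplotype_table",
]


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed input that violates a contract (duplicate IDs etc.)."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: half-open genomic interval plus its order along the chromosome."""

    genome_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class GenomeAnnotation:
    """Ordered gene models for one genome plus (optionally) their proteins.

    Genes are stored per chromosome, sorted by (start, gene_id); ``rank`` is
    the 0-based position within its chromosome after that sort.
    """

    def __init__(
        self,
        genome_id: str,
        genes: Iterable[GeneModel] = (),
        proteins: Mapping[str, str] | None = None,
    ) -> None:
        self.genome_id = genome_id
        self.proteins: dict[str, str] = dict(proteins or {})
        self.genes_by_chrom: dict[str, list[GeneModel]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValidationError(
                    f"{genome_id}: duplicate gene_id {g.gene_id!r}"
                )
            seen.add(g.gene_id)
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
            self.genes_by_chrom[chrom] = [
                replace(g, rank=i) for i, g in enumerate(ordered)
            ]
        self._by_id: dict[str, GeneModel] = {
            g.gene_id: g for gs in self.genes_by_chrom.values() for g in gs
        }
        for gid, seq in self.proteins.items():
            if not seq:
                raise ValidationError(f"{genome_id}: empty protein for {gid}")

    def __iter__(self) -> Iterator[GeneModel]:
        for chrom in self.genes_by_chrom:
            yield from self.genes_by_chrom[chrom]

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def subset(self, keep: set[str]) -> "GenomeAnnotation":
        """New annotation restricted to ``keep`` gene_ids; ranks recomputed."""
        genes = [replace(g, rank=-1) for g in self if g.gene_id in keep]
        prot = {gid: s for gid, s in self.proteins.items() if gid in keep}
        return GenomeAnnotation(self.genome_id, genes, prot)


@dataclass
class GroupConfig:
    """Genome-to-population assignment plus the label priority order used for
    ancestral haplotype naming."""

    assignment: dict[str, str]
    priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        unknown = [p for p in self.priority if p not in labels]
        if unknown:
            raise ValidationError(f"priority labels not assigned to any genome: {unknown}")

    def genomes_in(self, labels: Iterable[str]) -> list[str]:
        want = set(labels)
        return sorted(g for g, lab in self.assignment.items() if lab in want)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.assignment.values():
            seen.setdefault(lab)
        return list(seen)


class HitRecord(NamedTuple):
    """One pairwise protein alignment row (standard 12-column tabular layout)."""

    query_gene: str
    subject_gene: str
    pct_identity: float
    align_len: int
    evalue: float
    bitscore: float


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(
    path: str | Path, genome_id: str, id_attr: str = "ID"
) -> GenomeAnnotation:
    """Read gene models from GFF3 (``gene`` features) or BED6.

    Format is chosen by extension (.bed -> BED, otherwise GFF3). GFF3 1-based
    closed coordinates are converted to 0-based half-open; BED is taken as is.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        genes = _read_bed(path, genome_id)
    else:
        genes = _read_gff3(path, genome_id, id_attr)
    if not genes:
        logger.warning("no gene records in %s", path)
        warnings.warn(f"no gene records in {path}", stacklevel=2)
    return GenomeAnnotation(genome_id, genes)


def _read_bed(path: Path, genome_id: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED needs >= 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            genes.append(GeneModel(genome_id, name, chrom, s, e, strand))
    return genes


def _read_gff3(path: Path, genome_id: str, id_attr: str) -> list[GeneModel]:
    # Light line validation first so errors carry line numbers; attribute
    # strings are then parsed with gffutils' parser.
    import gffutils
    from gffutils import feature as gff_feature

    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(f"{path}:{lineno}: GFF3 line does not have 9 fields")
            try:
                feat = gff_feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            if id_attr in attrs:
                gid = attrs[id_attr][0]
            elif "locus_tag" in attrs:
                gid = attrs["locus_tag"][0]
            else:
                raise ParseError(
                    f"{path}:{lineno}: gene feature lacks {id_attr!r}/locus_tag attribute"
                )
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            genes.append(
                GeneModel(genome_id, gid, feat.seqid, feat.start - 1, feat.end, strand)
            )
    _ = gffutils  # imported for its feature parser
    return genes


def write_gene_models_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    """Emit gene features as GFF3 (internal 0-based half-open -> 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann:
            fh.write(
                f"{g.chrom}\t{ann.genome_id}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_gene_models_bed(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ann:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# proteins


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> {gene_id: sequence}; upper-cased, trailing '*' stripped."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in out:
            raise ValidationError(f"{path}: duplicate FASTA header {gid!r}")
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {gid!r}")
        out[gid] = seq
    return out


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in proteins:
            fh.write(f">{gid}\n{proteins[gid]}\n")


# ---------------------------------------------------------------------------
# pairwise hits


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated alignment table; self-hits are dropped."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            q, s = parts[0], parts[1]
            if q == s:
                continue
            try:
                rec = HitRecord(
                    q, s, float(parts[2]), int(parts[3]), float(parts[10]), float(parts[11])
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            if rec.evalue < 0 or rec.bitscore < 0:
                raise ValidationError(f"{path}:{lineno}: negative evalue/bitscore")
            hits.append(rec)
    return hits


def write_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits back out in the 12-column layout (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_gene}\t{h.subject_gene}\t{h.pct_identity:.2f}\t{h.align_len}"
                f"\t0\t0\t1\t{h.align_len}\t1\t{h.align_len}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# group configuration


def read_group_config(path: str | Path) -> GroupConfig:
    """Genome->group configuration.

    YAML files must carry ``assignment`` (mapping) and optionally ``priority``
    (list). TSV files are two columns genome_id<TAB>group; priority defaults to
    the order of first appearance of each group.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "assignment" not in data:
            raise ParseError(f"{path}: YAML group config needs an 'assignment' mapping")
        assignment = {str(k): str(v) for k, v in data["assignment"].items()}
        priority = [str(x) for x in data.get("priority", [])]
        if not priority:
            priority = list(dict.fromkeys(assignment.values()))
        return GroupConfig(assignment, priority)
    assignment = {}
    priority: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: need genome<TAB>group")
            gid, grp = parts[0], parts[1]
            if gid in assignment:
                raise ValidationError(f"{path}:{lineno}: genome {gid!r} listed twice")
            assignment[gid] = grp
            if grp not in priority:
                priority.append(grp)
    return GroupConfig(assignment, priority)


def write_group_config(groups: GroupConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, grp in groups.assignment.items():
            fh.write(f"{gid}\t{grp}\n")


# ---------------------------------------------------------------------------
# pan matrix / blocks / haplotype tables


def write_pan_matrix(pangenome, path: str | Path) -> None:
    """TSV: one SG per row, one genome per column; '.' marks absence."""
    genomes = list(pangenome.genomes)
    with open(path, "w") as fh:
        fh.write("sg_id\t" + "\t".join(genomes) + "\n")
        for sg in pangenome.sgs:
            cells = [sg.members.get(g, ".") for g in genomes]
            fh.write(sg.sg_id + "\t" + "\t".join(cells) + "\n")


def read_pan_matrix(path: str | Path) -> tuple[list[str], list[tuple[str, dict[str, str]]]]:
    """Inverse of :func:`write_pan_matrix`: (genomes, [(sg_id, members), ...])."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sg_id":
            raise ParseError(f"{path}: pan matrix must start with an sg_id column")
        genomes = header[1:]
        rows = []
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: ragged row")
            members = {g: v for g, v in zip(genomes, parts[1:]) if v != "."}
            rows.append((parts[0], members))
    return genomes, rows


def write_blocks_bed(blocks, path: str | Path) -> None:
    """Blocks as BED6: name=block_id, score=round(1000*mean_hdg), strand='.';
    the empirical minimum window P value rides in column 7."""
    with open(path, "w") as fh:
        for b in blocks:
            p = "." if b.min_window_p is None else f"{b.min_window_p:.6g}"
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\t"
                f"{round(1000 * b.mean_hdg)}\t.\t{p}\n"
            )


def write_haplotype_table(assignments, path: str | Path) -> None:
    """TSV of ancestral haplotype labels, one SG per row, one genome per column."""
    assignments = list(assignments)
    genomes: list[str] = []
    for a in assignments:
        for g in a.label_of:
            if g not in genomes:
                genomes.append(g)
    genomes.sort()
    with open(path, "w") as fh:
        fh.write("sg_id\t" + "\t".join(genomes) + "\n")
        for a in assignments:
            fh.write(
                a.sg_id + "\t" + "\t".join(a.label_of.get(g, "absent") for g in genomes) + "\n"
            )


def write_hdg_track(track, path: str | Path) -> None:
    """TSV: sg_id, chrom, start, end, hdg ('NA' where unmeasured)."""
    with open(path, "w") as fh:
        fh.write("sg_id\tchrom\tstart\tend\thdg\n")
        for sg_id, chrom, start, end, value in track.entries:
            v = "NA" if value is None else f"{value:.10g}"
            fh.write(f"{sg_id}\t{chrom}\t{start}\t{end}\t{v}\n")


def read_hdg_track(path: str | Path, pop_a: tuple[str, ...] = (), pop_b: tuple[str, ...] = ()):
    from .haplotypes import HdgTrack

    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["sg_id", "chrom", "start", "end", "hdg"]:
            raise ParseError(f"{path}: not an HDG track file")
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: ragged row")
            value = None if parts[4] == "NA" else float(parts[4])
            entries.append((parts[0], parts[1], int(parts[2]), int(parts[3]), value))
    return HdgTrack(entries, pop_a, pop_b)


def read_haplotype_table(path: str | Path) -> tuple[list[str], list[tuple[str, dict[str, str]]]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sg_id":
            raise ParseError(f"{path}: haplotype table must start with an sg_id column")
        genomes = header[1:]
        rows = []
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: ragged row")
            rows.append((parts[0], dict(zip(genomes, parts[1:]))))
    return genomes, rows
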