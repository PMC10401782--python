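# syntepan

Synteny-aware pan-genome construction, ancestral haplotype assignment and
haplotype-divergence introgression scanning for panels of annotated genomes.

## The problem

Sequence-similarity clustering (Markov clustering of all-vs-all protein
hits) struggles to separate orthologs from recent paralogs in plant genomes
full of tandem and segmental duplications. When every genome in a panel has
an ordered gene annotation, gene *position* resolves the ambiguity: two
genes in different genomes that occupy corresponding positions inside a
collinear block are **syntelogs** (syntenic orthologs). `syntepan` builds a
pan-genome whose unit is the **syntelog group (SG)** — a cross-genome
cluster of syntelogs anchored, where possible, to a framework genome's
coordinates — and then uses the SGs for two population-genetic analyses:

1. **Ancestral haplotype maps.** Within an SG, each distinct predicted
   protein sequence is one haplotype. Labels hapI…hapV are bound, in a
   fixed population-priority order, to the dominant haplotype of each
   designated population (minimum in-group frequency 3); remaining
   haplotypes are pooled as hapR; absence is its own state.
2. **Introgression scanning.** For each SG present in ≥ 10 genomes, the
   inter-population haplotype divergence is

   HDG = 1 − Σₖ f_A(k) · f_B(k),

   the probability that a random present member of population A and one of
   population B carry different haplotypes (equivalently the mean over all
   cross-population pairs of the indicator of haplotype difference). Runs of
   ≥ 10 consecutive framework SGs with HDG < 0.5 become candidate
   introgression blocks, and a permutation test (100,000 resamplings of the
   low-SG positions, 10-SG sliding windows, empirical P per window, cutoff
   P = 0.01) separates genuinely clustered low-divergence runs — the
   signature of gene flow — from the uniform scatter expected under
   incomplete lineage sorting.

The pipeline stages are: per-query best-hit filtering of 12-column tabular
protein hits → collapse of individual-specific tandem duplicates → dynamic-
programming chaining of anchors into collinear blocks (score cap Z = 12,
distance cap D = 200 kb, gap penalty g = 1, minimum A = 5 anchors, both
orientations) → one-to-one syntelog calling → iterative merge of pairwise
syntelog sets into SGs over a framework genome → occupancy classification
(core = all genomes, soft-core ≥ 90 %, dispensable, private) → haplotypes,
HDG and blocks. A seeded synthetic-panel generator with full ground truth
(occupancy spectrum, per-population haplotype frequencies, tandem
duplicates, planted introgression blocks, fabricated hit tables) makes
every stage testable without external data.

## Worked example

`examples/05_introgression_scan.py` simulates two 15-genome populations over
one chromosome of 2,000 SGs with three planted donor blocks (the recipient
population draws the donor's haplotypes inside each block), runs the full
pipeline with zero hit noise, and prints:

```
SG partition equals truth: True
candidate blocks (>=10 adjacent SGs with HDG < 0.5):
  chr1#3: chr1:177024-292107 (40 SGs, mean HDG 0.210)
  chr1#2: chr1:958560-1128570 (60 SGs, mean HDG 0.186)
  chr1#1: chr1:1640075-1924788 (90 SGs, mean HDG 0.201)
blocks significant at P <= 0.01: ['chr1#1', 'chr1#2', 'chr1#3']
planted SG recovery: 100.0%  false inclusion: 0.0%
blocks cover 0.57 Mbp (24.31% of the framework genome)
```

Every gene landed in the syntelog group the simulation planted it in; the
three detected blocks are exactly the planted ones (ids are numbered per
chromosome by descending genomic length); their mean HDG ≈ 0.2 sits far
below the 0.5 merge threshold while the genomic background is ≈ 0.9; and
each block's window-level clustering P value clears the 0.01 cutoff. The
other examples walk the individual capabilities: panel simulation, pairwise
chaining and synteny kinship, pan-genome composition and growth curves, and
haplotype labelling.

## Command line

The same pipeline is scriptable from a shell. `syntepan simulate` writes a
panel directory (GFF3 + protein FASTA per genome, per-pair hit tables,
group config, truth tables); `syntepan run-all` executes everything and
writes the pan matrix, composition, haplotype table, HDG track, candidate
and significant blocks (BED + TSV), window P values and a JSON summary;
`chain`, `merge`, `classify`, `hap`, `hdg`, `blocks` and `test` expose the
stages separately. Every command logs its parameters and seed to a
`manifest.json`, and identical seeds reproduce outputs bit-for-bit.

```bash
syntepan simulate --config sim.yaml --seed 7 --out panel/
syntepan run-all --input-dir panel/ --out run/ --pop-a popA --pop-b popB --seed 3
```

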