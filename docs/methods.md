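# Methods

This note documents the models and procedures implemented in `syntepan`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and gene order

All coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on ingest and BED taken verbatim, so interval output is BED-native
and the GFF → internal → BED round trip is lossless. Gene order rank is
always recomputed per chromosome from sorted start positions (ties broken
by gene id) and never trusted from input order: all synteny logic operates
on ranks, so a stable, reproducible ordering is load-bearing. Strand is
stored but not used by chaining; inversions are handled as descending
chains instead.

## Best hits and tandem collapse

Raw 12-column tabular protein hits are reduced to each query's best hit(s)
by maximal bitscore, ties all kept; a reciprocal mode additionally requires
the pair to be best in both directions. Because an individual-specific
tandem duplicate makes the pairwise search asymmetric (the duplicated side
"uses up" two queries on one subject), runs of same-chromosome genes whose
ranks differ by at most `max_tandem_gap` (default 1, i.e. adjacent) and
whose best-hit subject sets intersect are collapsed to a single
representative — the member with the highest best-hit bitscore, ties to
the smallest rank — before chaining and merging. The subject-set
intersection rule is the multi-partner generalisation of "share the same
best-hit subject": the pipeline collapses each genome exactly once, pooling
its query-side best hits over all partner genomes, so that the gene
universe entering the pan-genome merge is partner-independent. Collapsing
is idempotent and removes exactly `cluster_size − 1` genes per cluster.

## Anchor chaining

Anchors (retained best hits with rank and bp-midpoint context on both
genomes) from one chromosome pair form a DAG; the chainer finds
highest-scoring paths by dynamic programming. Defaults: per-anchor match
score capped at Z = 12; transitions allowed only when the bp distance
between consecutive anchor midpoints is ≤ D = 200,000 on *both* genomes;
gap penalty g = 1 per gene skipped on either genome; accepted chains need
A ≥ 5 anchors. Both orientations are searched (ascending, and descending
on genome B for inversions); accepted chains are extracted greedily by
descending score with non-overlapping anchors, ties broken by leftmost
start.

The score cap's interaction with the bitscore is not externally specified,
so the package defines the bitscore-derived match as
`Z · min(bitscore / (2 · query_protein_length), 1)`: a self-hit scores
roughly 2 bits per residue, so a perfect hit saturates at Z and weaker hits
scale proportionally. This is a package convention; the DP optimum is
verified against exhaustive enumeration over all monotone,
distance-feasible anchor subsequences on small instances, and satisfies
orientation symmetry and monotonicity under anchor addition.

Syntelog calling takes the union of anchors over accepted chains with
one-to-one pairing per genome pair; a gene claimed by two chains follows
the higher-scoring chain. Synteny kinship is the fraction of the reference
genome's annotated genes that have a syntelog in the partner.

## Pan-genome merge

Genomes are merged one at a time onto a framework genome (whose genes seed
one SG each, carrying framework coordinates). Each incoming gene that
links — via any available pairwise syntelog pair — to genes of exactly one
existing SG joins it; a gene linking to several SGs joins the SG gathering
the majority of its links, ties resolved to the earliest-created SG; an
unlinked gene founds a new SG. SGs are never retroactively fused and an SG
holds at most one gene per genome (a second same-genome claimant founds a
new SG), so every gene belongs to exactly one SG and occupancies sum to the
total gene count. On conflict-free inputs the partition is invariant to
merge order; this is tested. Framework-anchored SGs are ordered by
framework coordinates; framework-absent SGs are appended, ordered by their
earliest-merged member's coordinates, and are excluded from
adjacency-based block logic (blocks are defined on the framework
coordinate system).

Occupancy classes for n genomes: core = n; soft-core occupies
`ceil(0.9 n) … n−1`; private = 1; dispensable is the remainder. At n = 74
the soft-core band is 67–73 and dispensable 2–66. The `ceil` is taken with
a 1e-9 slack because binary floats can push an exact decimal product (e.g.
0.9 × 70) across the integer boundary; the same slack guards the inclusive
presence-frequency threshold (≥ 0.6) of the PAV-bias screen, where 0.7 −
0.1 in floats falls a ulp short of 0.6. Sub-population composition
reclassifies each SG by occupancy within the chosen groups, with a separate
`absent` state; pan/core growth curves accumulate union and intersection
sizes over random genome orderings.

## Haplotypes and divergence

Within an SG, haplotype identity is exact protein string equality — the
only parameter-free reading of "compressing" coding variation to one state.
Raw keys are numbered by descending frequency, ties by lexicographically
smaller sequence, so numbering is deterministic. Ancestral labels: the i-th
priority group is offered the i-th label (hapI for the first, hapII for the
second, …); the group's dominant key takes it only if its in-group
frequency is ≥ 3 (`min_dominant_freq`) and it is not already bound to an
earlier label — otherwise that label stays undefined for the SG (it is not
passed down). Dominance ties go to the lexicographically smaller sequence.
Unlabelled present members are hapR; absent genomes are `absent`. Label
choice never feeds back into divergence: HDG is computed on raw keys, so
hapR compression is display-only (pooling rare keys before HDG would
spuriously lower divergence).

HDG between disjoint populations A and B is implemented in the closed form
1 − Σₖ f_A(k) f_B(k) over within-population key frequencies among present
members, which equals the mean over all cross-population member pairs of
the indicator of key difference; the equivalence is tested against
brute-force pair enumeration to 1e-12. An SG is NA when present in fewer
than 10 genomes overall (the filter counts all genomes, not only the two
populations — the choice is exposed via `min_presence_total`) or when
either population has no present member. Absent genomes never enter the
pair enumeration: absence is presence/absence variation, measured by the
PAV screen, not divergence.

## Introgression blocks and the clustering test

The HDG track lists framework-anchored SGs in coordinate order, keeping NA
entries so adjacency is well defined. Low SGs are those with HDG strictly
below 0.5; NA is never low. Maximal runs of consecutive low SGs within a
chromosome become candidate blocks; a single high or NA SG breaks a run
(a `gap_tolerance` flag can bridge interruptions but defaults to 0); runs
with fewer than 10 low SGs are dropped. Block spans are
`[min member start, max member end)`; ids are `chrom#k` with k assigned per
chromosome by descending bp length.

The clustering test re-places, per replicate, the chromosome's observed
number of low SGs uniformly at random (without replacement) over its SG
positions, and counts, for each sliding window of 10 SGs (step 1), the
replicates whose window count strictly exceeds the observed count;
P = exceedances / 100,000. Blocks overlapping at least one window with
P ≤ 0.01 are called significant. Identical seeds give bit-identical
results, and the empirical P agrees with exact combinatorial enumeration
within three binomial standard errors on instances small enough to
enumerate.

A calibration caveat is worth stating plainly: the strict-exceedance P
value discards the tie mass P(count = observed), which is large for 10-SG
windows (≈ 0.13 at a null mean of 1.5), so it is *anti-conservative* under
a uniform null — about 17 % of null windows fall below 0.05, not 5 %. This
is a property of the strict definition itself, not of the implementation.
`cluster_test(include_ties=True)` counts `count ≥ observed` instead and,
combined with the `(r+1)/(n+1)` pseudocount, yields a validly calibrated
Monte-Carlo P value (≈ 4 % of null windows below 0.05 in the same
experiment); the strict definition remains the default for fidelity to the
reference procedure, whose downstream cutoff (P = 0.01) was set
empirically against it.

## Synthetic panels

The generator emulates the statistical structure of a multi-genome crop
panel, with every random choice driven by one mandatory seed:

* **Proteome.** An ancestral proteome of `n_sgs` random proteins of
  100–500 aa; per SG, `n_groups + 1` allele variants differing from the
  ancestor by uniform random substitutions (count ~ max(1,
  Poisson(rate × length)), default rate 0.005/site). No indels by default,
  since downstream identity is exact string equality.
* **Occupancy.** Each SG draws a class from the mixture (default core 0.08,
  soft-core 0.08, dispensable 0.36, private 0.48 — approximately the
  SG-wise composition reported for large rice panels); occupancy is then
  uniform within the class band and present genomes are a uniform subset.
* **Haplotype structure.** Each population favours its own allele with
  frequency 0.9 (`background_major_freq`), the remainder spread evenly, so
  the expected background HDG between two populations is ≈ 0.9. Inside a
  planted block every population draws from the donor population's
  frequencies, collapsing expected HDG to ≈ 0.18.
* **Layout.** Genes are non-overlapping and collinear across genomes, with
  geometric intergenic spacing (mean 2 kb) so the 200-kb chaining distance
  cap is exercisable; gene length is 3 × protein length.
* **Tandem duplicates.** With probability 0.02 a present gene gains an
  adjacent identical duplicate, individual-specific by construction.
  Duplicates are planted only on SGs shared by ≥ 2 genomes: a duplicate of
  a fully private gene produces no cross-genome hit, so no hit-based
  collapse rule could ever detect it and truth recovery would be
  unattainable in principle rather than in implementation.
* **Planted blocks.** Block SGs are forced to core/soft-core occupancy and
  always include the framework genome: detected blocks live on framework
  coordinates over SGs that pass the ≥ 10-presence divergence filter, so a
  planted truth block must be measurable there to be detectable at all.
* **Hits.** Fabricated tables emit, per genome pair, both directions of
  every cross-genome same-SG gene pair with bitscore 2 × length ×
  identity; false positives and cross-SG paralog hits are added at
  configurable rates with reduced bitscores, and false negatives drop true
  pairs.

What the generator does **not** emulate: realistic sequence evolution
(codon structure, selection, indels), genomic rearrangements beyond
presence/absence (no translocations or inversions between genomes),
annotation error, and assembly artefacts. Passing the end-to-end tests
therefore shows that the pipeline's logic is correct under its stated
model — exact truth recovery with noise-free hits, planted-block detection
against a divergent background — not that real-panel accuracy matches
these numbers.

## Problem sizes used in the shipped checks

The bundled verification uses panels the pipeline completes in seconds to
minutes on one CPU: the end-to-end scenario is 2 × 15 genomes, one
chromosome, 2,000 SGs and three planted blocks of 40/60/90 SGs; the
chaining oracle uses 200 instances of ≤ 10 anchors (exhaustive enumeration
is exponential in anchor count); the permutation-test calibration uses 100
chromosomes of 200 SGs at 10,000 replicates; merge-order invariance uses a
10-genome, 500-SG conflict-free panel over 20 random orders.

## Known limitations

* The merge is strictly incremental; a gene linking to two SGs is resolved
  by majority link count (ties to the earliest-created SG) and SGs are
  never fused, so pathological late evidence cannot repair an early split.
* Framework-absent SGs carry no coordinates and are invisible to the block
  scan; a block private to non-framework genomes cannot be detected.
* `block_summary`'s genome fraction uses the summed rightmost gene end per
  chromosome as the assembly length when no explicit length is given,
  which underestimates true assembly length by the unannotated tails.
* Haplotype identity at the protein level is blind to synonymous and
  non-coding variation; two diverged genes with identical proteins are one
  haplotype.
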