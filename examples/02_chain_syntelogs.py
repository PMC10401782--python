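"""Chain one genome pair's best protein hits into syntenic chains.

Simulates two genomes, keeps per-query best hits, collapses tandem
duplicates, chains the anchors by dynamic programming (score cap Z=12,
distance cap D=200 kb, gap penalty 1, at least 5 anchors per chain) and
reports the syntelog pairs and the synteny kinship of the pair.
"""

import itertools

from syntepan import SimConfig, simulate_hits, simulate_panel
from syntepan import best_hits, collapse_tandem, call_syntelogs, chain_anchors, synteny_kinship
from syntepan.anchors import anchors_from_best_hits

config = SimConfig(seed=21, group_sizes={"popA": 2}, n_sgs=400, mixture=(0.7, 0.1, 0.1, 0.1))
annotations, _, truth = simulate_panel(config)
hits = simulate_hits(annotations, truth)

(ga, gb), rows = next(iter(hits.items()))
best = best_hits(rows)
ann_a, _ = collapse_tandem(annotations[ga], [h for h in best if h.query_gene in annotations[ga]])
ann_b, _ = collapse_tandem(annotations[gb], [h for h in best if h.query_gene in annotations[gb]])
best = [h for h in best if (h.query_gene in ann_a or h.query_gene in ann_b)
        and (h.subject_gene in ann_a or h.subject_gene in ann_b)]

anchors = anchors_from_best_hits(ann_a, ann_b, best)
anchors.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))
chains = []
for _key, group in itertools.groupby(anchors, key=lambda a: (a.chrom_a, a.chrom_b)):
    chains.extend(chain_anchors(list(group), genome_a=ga, genome_b=gb))

pairs = call_syntelogs(chains, ga, gb)
print(f"{ga} vs {gb}: {len(anchors)} anchors -> {len(chains)} chain(s)")
for c in chains:
    print(f"  {c.chrom_a}:{c.n_anchors} anchors, score {c.score:.1f}, {c.orientation}")
print(f"syntelog pairs: {len(pairs.pairs)}")
# Kinship = fraction of the reference genome's genes with a syntelog;
# close to 1 here because both genomes descend from one ancestral proteome.
print(f"synteny kinship: {synteny_kinship(pairs, ann_a):.3f}")
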