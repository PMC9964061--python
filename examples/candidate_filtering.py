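"""Filter and annotate candidate EMS mutations in a mapped interval.

Builds a synthetic candidate interval containing one causal G-to-A
change at the -1 position of a splice acceptor site (the intron's last
base), 50 polymorphisms shared with a sibling line, and 20
transversions, then runs the filter chain: list near-fixed
non-reference positions in the mutant pool, drop shared variants, keep
EMS-type transitions, and annotate against the gene model.
"""

import numpy as np

from bsamap import (
    CandidateInterval,
    GeneModel,
    MarkerTrack,
    candidate_pipeline,
)

interval = CandidateInterval("chr2", 1_000_000, 1_500_000, 1_200_000, 1e-6)
gene = GeneModel("AtGeneX", "chr2", "+",
                 [(1_200_000, 1_200_500), (1_200_601, 1_201_000)])
causal_pos = 1_200_600  # last base of the intron [1200501, 1200600]

rng = np.random.default_rng(20)
background = sorted(
    int(p) for p in rng.choice(np.arange(1_010_000, 1_490_000), 70, replace=False)
    if p != causal_pos
)
rows = [(causal_pos, "G", "A", 0, 40)]
shared = set()
for i, p in enumerate(background):
    if i < 50:                          # shared with a sibling mutant line
        rows.append((p, "C", "T", 1, 39))
        shared.add(("chr2", p, "C", "T"))
    else:                               # EMS-atypical transversions
        rows.append((p, "G", "T", 0, 40))
rows.sort()
pos, ref, alt, mut_ref, mut_alt = zip(*rows)
n = len(rows)
track = MarkerTrack("chr2", pos, ref, alt, [30] * n, [30] * n, mut_ref, mut_alt)

print(f"positions near-fixed non-reference in the mutant pool: {n}")
survivors = candidate_pipeline(track, interval, [shared], [gene])
print(f"after shared-variant and transition filters: {len(survivors)}")
for c in survivors:
    print(f"  {c.chrom}:{c.pos} {c.ref}>{c.alt}  {c.annotation} "
          f"(offset {c.splice_offset}) in {c.gene_id}")
# The lone survivor is the planted lesion, annotated splice_acceptor at
# offset -1: the conserved G of the intron-terminal AG dinucleotide.
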