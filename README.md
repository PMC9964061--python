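# bsamap

Mapping-by-sequencing of recessive mutations from pooled F2 sequencing
data, with candidate-mutation filtering and a built-in F2 pool-seq
simulator.

## The problem

In a forward genetic screen, a recessive mutation (e.g. EMS-induced) is
crossed to a reference accession and the F2 progeny are pooled by
phenotype: one pool of mutant individuals, one pool of phenotypically
wild-type siblings. Whole-genome sequencing of the two pools gives, at
every segregating SNP marker, read counts for the two alleles in each
pool. Because every mutant F2 plant is homozygous for the causal
allele, markers tightly linked to the causal locus show skewed pooled
allele frequencies — the mutant-parent allele approaches frequency 1 in
the mutant pool and 1/3 in the wild-type pool — while unlinked markers
sit near 0.5 in both pools.

`bsamap` localizes the causal locus from these counts and then filters
the mapped interval down to candidate lesions. It is aimed at plant
(and other model-organism) geneticists running bulked segregant
analysis from a bcftools-style VCF with per-sample allele depths.

## The method

For each biallelic marker with reference/alternative counts
(wt_ref, wt_alt) and (mut_ref, mut_alt):

- **Allele-frequency tracks** — alt-allele frequency per pool, smoothed
  by an unweighted moving average over windows of *k* = 200 adjacent
  markers; the mutant-pool maximum marks the linked region.
- **Fisher's exact tests** — the two-tailed p-value of the 2×2 table
  (pool × allele): p sums the hypergeometric probabilities of all
  tables with the observed margins whose probability ≤ that of the
  observed table. Smoothing uses the depth-weighted geometric mean
  exp(Σᵢ nᵢ ln pᵢ / Σᵢ nᵢ) over the same windows, with nᵢ the total
  read depth at marker *i*. Markers are declared linked below the
  Bonferroni threshold α/n for n tested markers; the contiguous
  sub-threshold run around the smoothed-p minimum (± 100 kb padding)
  is the candidate interval. A p-value-based scan needs no knowledge of
  which parent contributed which allele.
- **Marker selection** — only positions that are credibly heterozygous
  in the experiment are tested: control-pool alt frequency in
  [0.15, 0.85] and control-pool depth in [20, 120]; counts can
  optionally be pooled over non-overlapping 10-marker bins as a
  haplotype-frequency proxy.
- **Candidate filtering** — positions in the interval where the mutant
  pool is near-fixed non-reference (alt fraction ≥ 0.9, depth ≥ 10),
  minus variants shared with control lines (allele-exact match), kept
  only if G→A or C→T (the EMS transition spectrum), annotated against
  GFF3 gene models including splice sites (acceptor −1/−2, donor
  +1/+2 in transcription orientation).
- **Segregation tests** — 1-df Pearson χ² goodness-of-fit of phenotype
  counts to a Mendelian ratio (default 3:1), no continuity correction.
- **Simulator** — F2 gametes as Markov chains along each chromosome
  with Haldane recombination fractions, recessive phenotype assignment
  with configurable penetrance, phenotype pools drawn without
  replacement, and read sampling with zero-truncated Poisson depth and
  binomial allele draws including a per-read error rate.

## Worked example

`python examples/simulate_and_map.py` simulates an experiment with the
default configuration — pools of 87 mutant and 170 wild-type plants
from a 600-plant F2, five chromosomes with ~2000 markers each, ~60×
depth per pool, a causal site at chr2:1,283,497 — and scans it:

```
simulated F2 cohort: 600 plants, 143 mutant phenotype
markers tested: 10000
Bonferroni threshold (alpha 0.05): 5.000e-06
smoothed-p minimum: chr2:1,042,369
true causal site:   chr2:1,283,497
candidate interval: chr2:891,090-6,595,843
offset from truth:  241,128 bp
```

The smoothed-p minimum lands ~240 kb from the true site (markers are
~10 kb apart and the smoothing window spans ~2 Mb, so sub-Mb accuracy
is the expected resolution), and the sub-threshold interval contains
it. `examples/candidate_filtering.py` then shows the filter chain
reducing 71 near-fixed positions in an interval to the single planted
G→A splice-acceptor lesion (offset −1), and
`examples/segregation_tables.py` reproduces χ² goodness-of-fit values
for published-style family counts.

The same stages are available from the shell:

```bash
bsamap simulate --seed 1 --out run/
bsamap map --markers run/markers.tsv --window 200 --out run/scan/ --plot
bsamap candidates --markers run/markers.tsv \
    --interval chr2:1000000-1500000 --gff genes.gff3
bsamap segtest --counts 49,19
```

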