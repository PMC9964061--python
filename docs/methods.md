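# Methods

## Genetic model

The package assumes a single-locus recessive trait mapped in an F2
population from a cross between the mutant line and the reference
accession. Every mutant-phenotype F2 individual is homozygous for the
mutant-parent allele at the causal locus (up to penetrance), so in a
pool of mutants the expected mutant-allele frequency is 1 at the causal
site, decaying with recombination distance; in the wild-type sibling
pool it is 1/3 at the causal site (the wild-type class is 1 AA : 2 Aa);
and at unlinked markers it is 1/2 in both pools. Pooled sequencing
turns these population frequencies into read-count estimates, with two
layers of noise: which individuals enter the pool, and which reads
sample which chromosomes.

## Statistics

**Per-marker test.** Each marker's counts form a 2×2 table
(pool × allele). Under the null of no linkage the allele is independent
of the pool, and with both margins fixed the wild-type-pool reference
count is hypergeometric. The two-tailed Fisher p-value sums the
probabilities of all tables with the observed margins whose probability
is ≤ the observed table's, with a relative tie guard of 1e-7 so exact
ties are not lost to floating point (the convention of the standard
scipy implementation, against which the test suite cross-checks). The
implementation vectorizes the enumeration over a padded support grid
with a shared log-factorial lookup, so a 10,000-marker genome scan
costs milliseconds. A table with an empty margin carries no information
and returns p = 1. A Pearson χ² (no continuity correction) on the same
table is provided as a cheap asymptotic alternative; at pool-seq depths
(total ≥ 200 reads) it tracks the exact test within a factor of ~2 over
the non-extreme p range.

**Smoothing.** Both statistics are noisy per marker and are integrated
over windows of k adjacent markers (default k = 200, the scale at which
single-experiment pool noise averages out while linkage structure
survives). Frequencies use an unweighted moving average; p-values use
the depth-weighted geometric mean exp(Σ wᵢ ln pᵢ / Σ wᵢ) with
wᵢ = combined read depth of both pools at marker i ("the number of
reads covering the marker" — combined depth is the literal reading; the
frequency average is deliberately unweighted). Only full windows are
emitted, anchored at the ⌈k/2⌉-th member's position; there is no edge
shrinking, so chromosomes contribute no anchors within half a window of
their marker ends. P-values are floored at 1e-300 before logs. Ties at
extremes resolve to the smallest genomic position.

**Thresholding and the interval.** The significance line is the
Bonferroni bound α/n with n the number of markers actually tested in
the current run (not a fixed historical count). The candidate interval
is the maximal contiguous run of sub-threshold anchors containing the
global smoothed-p minimum, padded by 100 kb per side and clipped to the
chromosome's marker span; if nothing is sub-threshold the ±100 kb
neighbourhood of the minimum is returned with a warning. Published
intervals are often drawn by eye, so the `map` command accepts an
explicit `--interval` override that is reported verbatim.

## Marker selection and binning

Reliable markers are selected on the **control (wild-type) pool only**:
alt-allele frequency within [0.15, 0.85] and depth within [20, 120],
all bounds inclusive (the least surprising reading of a stated range).
The mutant pool is never consulted — near the causal locus it is
legitimately fixed, and filtering on it would erase the signal. Binning
pools counts over non-overlapping runs of exactly 10 consecutive
markers (trailing remainders are dropped to keep per-bin support
homogeneous); the pooled-count frequency equals the depth-weighted mean
of the member frequencies, an algebraic identity the property suite
checks.

## Candidate filtering

Candidate positions are markers in the interval with mutant-pool depth
≥ 10 and alt fraction ≥ 0.9 — a near-fixation rule matching the
expected homozygosity of the causal site and linked polymorphisms;
both thresholds are exposed as flags since calling conventions differ.
Shared-variant exclusion matches on the exact (chrom, pos, ref, alt)
tuple: two lines sharing a position but not an allele are independent
lesions. The transition filter keeps exactly G→A and C→T (the EMS
spectrum); A→G/T→C are the wrong direction and are dropped. Annotation
classifies a position against every overlapping gene model and keeps
the highest-priority label (splice_acceptor > splice_donor > exonic >
intronic > intergenic, then lexicographic gene id). Splice windows
default to 2 nt — the canonical GT–AG dinucleotides — with offsets in
transcription orientation: −1 is the intron's last transcribed base
(on the minus strand, the lowest genomic coordinate of the intron), +1
its first. Mid-intron offsets report the signed distance to the nearer
boundary, the acceptor side winning ties.

## Simulator

Each F2 individual receives two independent gametes per chromosome;
a gamete is a Markov chain along the ordered markers whose switch
probability between adjacent markers is the Haldane recombination
fraction r = (1 − e^(−2d))/2 for their map distance d (no crossover
interference — irrelevant at the ~100 kb resolution being tested).
Genetic position is proportional to physical position within a
chromosome. Phenotype is mutant iff the individual is homozygous for
the mutant-parent allele at the causal site and a Bernoulli(penetrance)
draw succeeds; a mis-phenotyping rate (default 0) can flip labels to
stress the statistics. Pools are drawn **without replacement** from the
phenotype classes, mirroring the physical pooling of distinct
seedlings. Read depth per marker and pool is zero-truncated
Poisson(λ = 60) — every marker has calls, so the depth filter acts as
it would on real data — and alt reads are Binomial(depth, q(1−ε) +
(1−q)ε) with ε = 0.001 per-read error.

Defaults are the study conditions the package is built around: pools of
87 mutant and 170 wild-type plants; five chromosomes with Arabidopsis-
scale physical (18.6–30.4 Mb) and genetic (98–140 cM) lengths; ~2000
uniformly placed markers per chromosome; a causal G→A site at
chr2:1,283,497. The F2 cohort size (600) is a package choice: pools are
drawn from finite phenotype classes, and 600 plants make a shortfall of
the 87-mutant class vanishingly rare at the Mendelian 1/4 rate.

What the simulator does **not** model: introgression structure (real
mixed-background crosses have very uneven marker density), read-level
artifacts (mapping bias, indels, repetitive-region mis-alignment),
linked selection, and phenotyping structure beyond a flat error rate.
Passing recovery tests therefore demonstrates the statistics behave
correctly under the stated genetic model, not robustness to alignment
pathology.

## Numerical choices and edge cases

- Fisher tie guard 1e-7 (relative, in log space); empty margin → p = 1.
- p floor 1e-300 before logarithms; a smoothing window whose weights
  are all zero falls back to the unweighted geometric mean with a
  warning.
- Sliding sums use pairwise-summed window views, keeping the constant-
  track moving average exact to ≤1 ulp.
- Zero-depth markers get frequency NaN (propagated, never silently 0).
- Multiallelic and indel VCF records are dropped, not split: the scan
  is SNP-only. Records missing allele depths for either pool are
  skipped with a logged warning, as are duplicate positions.
- Marker tables are validated on read (negative counts and malformed
  rows are named by line).
- Determinism: every simulation entry point takes a seed or Generator;
  `make_scenario` writes byte-identical outputs for the same seed.

## Problem sizes used in tests

The recovery suite runs 100 replicates at the full default scale
(5 × 2000 markers, pools 87/170, window 200): with ~10 kb marker
spacing a 200-marker window spans ~2 Mb, so the smoothed-p minimum is
expected within a few hundred kb of the causal site — the suite
requires ≤ 1 Mb in ≥ 95 of 100 replicates, and the sub-threshold
interval to contain the true site. Frequency-expectation checks use 100
replicates of a small two-chromosome genome (30 markers each), since
only the causal and unlinked markers matter there. The exhaustive
Fisher validation enumerates all ~2.5 × 10⁵ tables with both pool
depths ≤ 30 against an exact integer-arithmetic oracle.
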