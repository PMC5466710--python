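# Methods

This note documents the models behind `nanosurvey`, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Coordinates, alignments, identity

All internal coordinates are 0-based half-open. SAM (1-based) and GFF3
(1-based closed) are converted at the I/O boundary; PAF and BED pass
through. Minus-strand query coordinates are always reported on the forward
query strand (PAF semantics), and CIGARs are stored in target-forward
orientation, consuming the reverse-complemented query for minus-strand
records (SAM convention).

Identity is indel-inclusive: matching columns divided by *all* alignment
columns (`=`, `X`, `I`, `D`). This is the accounting under which early
nanopore 2D reads show ~17 % error; match-column-only definitions would
understate indel-dominated error. Clipped (unaligned) read tails are
excluded from the denominator.

## The anchor-chain aligner

`align_pair` is a deliberately small seed-and-chain aligner sized for
desk-scale data (features vs. assemblies, reads vs. contigs, contigs vs.
sub-megabase references):

1. exact shared k-mers (default k = 15; k = 11 in noisy-read mode) on both
   strands, with repeat-capped target k-mer occurrences (≤ 16);
2. chaining restricted to the densest diagonal band (width = band +
   2 % of query length). The band restriction is what keeps a chain from
   zigzagging across tandem repeat copies — copies sit on diagonals
   separated by the unit length, so per-copy chains emerge one per
   extraction round;
3. longest-increasing-subsequence chaining inside the band, split wherever
   consecutive anchors imply > 1 kb of gap on either sequence or a
   gap-length difference beyond the 64-column band — the contract is to
   split into multiple records rather than silently absorb a structural
   difference into a low-identity alignment;
4. inter-anchor gaps filled by unit-cost global edit-distance alignment
   (edlib), unanchored ends recovered by a prefix-mode extension of up to
   256 bp accepted only below 50 % edits.

Unit gap costs mirror the gap-open = gap-extend = 1 settings appropriate
for high-error long reads. On ≤ 1 kb sequence pairs where a single chain
covers both sequences end-to-end, the emitted edit distance equals a full
unbanded dynamic program's (tested). Limitations: no affine gaps, no
spliced alignment, and breakpoints that fall inside a tandem repeat
cluster are recovered only up to a repeat-unit shift (an intrinsic
ambiguity, not an implementation artifact).

## Error model and calibration

Each chemistry preset is a generative model with two channels applied to a
sampled reference window:

* **Homopolymer channel.** Every maximal run of one base with length
  ℓ ≥ 2 survives exactly with probability s(class, ℓ), where class pools
  A/T vs. C/G. The survival table is anchored at the printed lengths
  ℓ = 2, 4, 7, linearly interpolated between anchors, and clamped beyond
  ℓ = 7 (runs longer than 7 pool into a "7+" bin in the profiler, matching
  the clamp). An erroneous run changes net length: negative with
  probability ρ (0.66 for R7.3 — deletion-biased; 0.37 for R9 —
  insertion-biased), magnitude Geometric(p_ext = 0.75), deletions floored
  so a run keeps ≥ 1 base. Length changes are realized as `D` columns
  inside the run or same-base `I` columns at its flank, so a profiler
  walking reference runs recovers s and ρ exactly up to binomial noise.
* **Residual channel.** Substitutions and non-homopolymer indels at
  per-base rates on single-base positions only, with inserted bases chosen
  to differ from both neighbours — residual errors never masquerade as
  homopolymer-channel events, which keeps the two channels separately
  identifiable.

The residual rates are not free parameters: for each preset they are
solved by a secant iteration (≤ 8 steps, tolerance 0.05 pp) on a fixed
100 kb calibration genome so that the simulated mean per-read error rate
equals the chemistry's marginal target (17.2 % R7.3 2D, 12.2 % R7.3
2D-pass, 14.8 % R9 2D ≡ 85.2 % identity, 17.2 % R9 1D ≡ 82.8 % identity).
The total residual rate splits 60/20/20 into substitution/deletion/
insertion. The R7.3 1D preset's 30 % target is a representative default
for template-strand reads, not a published figure. Calibration runs once
per preset per process and is cached.

Read lengths are log-normal (median 7.7 kb for R7.3 2D, 8.9 kb for 1D,
6.1 kb for R9; σ = 0.45 for a long right tail), capped at 75 kb, with
uniform start positions and strands, truncated at chromosome ends.

## Profiling

`identity_profile` takes one primary alignment per read (two primaries is
an error; a read with none counts as unaligned) and reports per-class
aligned fractions, mean/median identity, and a 1-percentage-point
histogram. `homopolymer_accuracy` classifies every reference run of
length ≥ 2 fully contained in an alignment span: *correct* iff exactly ℓ
matching columns and no attributable insertion; otherwise by the sign of
(same-base insertions − deletions): net deletion, net insertion, or
substitution-only at zero. Same-base insertions immediately flanking the
run are attributed to it (they lengthen it in the read); different-base
insertions are not. A run overlapping two records *of the same read*
(split chains) counts once, in the higher-identity record; every read
covering a run contributes one observation (per-incidence counting, which
is the convention under which the forge/profiler pair is self-consistent).
Runs truncated by alignment ends are skipped. Recovery statistics are
computed on simulator truth alignments so that aligner bias stays out of
the calibration loop.

## The forge

`build_reference` defaults to three chromosomes of 220/180/150 kb
(desk-scale, full feature inventory): telomeric repeat arrays of ~100 bp
at every chromosome end, one shared 120 bp centromere consensus per
chromosome, five TE families of 5.8 kb planted verbatim at 4/3/2/2/1
copies, an rDNA-like tandem cluster (default 10 × 2 kb — the real
cluster's ~100 tandem copies of a 9.1 kb unit scaled to desk size while
keeping the property that matters: a tandem repeat long enough to fragment
assemblies), CUP1/ENA-like tandem gene arrays at 7 and 4 copies (the
reference copy numbers of those loci), and 12 single-copy genes. Features
are placed uniformly at random with 500 bp margins; placement failure
raises rather than overlaps.

`derive_isolate` applies inversions, tandem copy-number changes, TE
insertions/deletions, then reciprocal translocations, on a piece list that
doubles as an exact isolate-to-reference coordinate map; background SNPs
(default density 0.0062) are applied last and recorded. The piece map
drives truth projection of read intervals (used by the short-read-like
depth simulator, which emits each read's longest reference portion as its
primary alignment — mimicking soft-clipping at copy-number junctions).

`forge_cohort` generates haplotype cohorts from a *shared* pool of
segregating sites: site density snp_density · 3(n−1)/(n+1) with derived
allele counts uniform on 1..n−1, so the expected pairwise diversity equals
`snp_density` (a site with allele count k contributes k(n−k)/C(n,2)
pairwise differences; the uniform-k expectation is (n+1)/(3(n−1)) per
site). Isolates mutated *independently* against the reference would give
cohort π ≈ 2d, not d, which is why the cohort path uses shared
polymorphism rather than chaining `derive_isolate`; the allele-frequency
spectrum is uniform by construction, not neutral-coalescent.

`make_assembly` plants three defect classes with exact truth: chimeric
contigs fusing two chromosomes at a shared TE family copy (no read from
the truth genome spans the junction — the chimera detector's positive
control), fragmentation at the rDNA cluster midpoint, and consensus
homopolymer deletions (each run ≥ 4 loses one base with the configured
probability), emulating the indel load of long-read-only consensus.

## Downstream estimators: choices worth noting

* **Feature retention** follows the survey rule: identity strictly
  > 0.80 ("more than 80 %") over ≥ 0.90 of the feature length, relaxed to
  identity ≥ 0.70 in raw reads; boundary semantics are tested. Partial
  genes are hits covering ≥ 0.50 (the threshold is a documented default —
  the survey never defines "partial"). "Indel-free" means zero I/D columns
  in the retained hit.
* **Nx/Lx** are self-referential (assembly cumulative size), not NG50.
* **Copy number by depth** uses the mean over the region of interest and
  the median over its chromosome; tandem arrays are short and depth-noisy,
  so the mean is the better-behaved numerator while the chromosome median
  is the robust baseline. Ratios round half away from zero.
* **Best-alignment filtering** is greedy by score = identity × aligned
  length with > 50 % overlap trimming and a 10 kb minimum segment — the
  10 kb default deliberately suppresses TE-sized (~5.8 kb) relocations
  from the rearrangement list. On tiling-plus-repeat instances (the real
  use case) the greedy score equals the exhaustive optimum; on adversarial
  random tangles it need not be.
* **Rearrangement calling** reports reciprocal translocations per junction
  and deduplicates them (breakpoint proximity ≤ 2 × 2 kb) into one
  biological event with a junction count. Inversion calls require
  same-chromosome opposite-strand flanks on both sides.
* **Chimera support** counts primary read alignments covering
  junction ± 1 kb in a single record with no deletion gap > 100 bp inside
  the window; zero support marks a chimera.
* **Hotspots** cluster projected insertion sites by single linkage at
  1 kb (the clustering distance is this package's parameter — the survey
  states only the ≥ 7 isolate threshold) and require ≥ 7 distinct
  isolates.
* **Circularization** searches the first 20 % of a contig against the last
  20 % for a ≥ 1 kb, ≥ 0.95-identity prefix-onto-suffix chain anchored
  within 100 bp of both contig ends; equal-score conflicting chains raise
  an ambiguity error rather than guessing. Origin rotation locates the
  reference's first 500 bp on the doubled circle (both strands, ≥ 0.80
  identity).
* **π** is per-pair-normalized then averaged (each pair divided by its own
  callable-site count), which is robust to missing data; a pooled
  definition would weight pairs by coverage.

## Problem sizes

Defaults are chosen so the full test suite runs in about a minute and the
reproduction script in under a minute per preset: recovery statistics use
a 550 kb forged genome with 2 500–5 000 reads per preset (the sparse
length-7 A/T homopolymer bin is the binding constraint — about two runs
per megabase of reads), the SV cohort uses ten isolates on a 240 kb
genome, and copy-number recovery uses 30× coordinate-projected short-read
depth.

## What passing tests show — and what they do not

The synthetic data establish *internal consistency*: the estimators
recover the generative parameters (error rates within 0.5 pp, homopolymer
anchors within 3 pp, error-type partitions within 3 pp, π within 0.0003)
and planted structures (SV recall/precision 1.0 with ≤ 1 kb breakpoint
error on defect-free assemblies with breakpoints in unique sequence;
exact TE counts; copy numbers within ±1 at 30×). They do not establish
performance on real data: the forge's background is i.i.d. uniform
sequence (no GC skew, no k-mer composition bias), errors are independent
across runs (no pore-state autocorrelation or 6-mer signal bias), TE
copies are planted verbatim (no solo LTRs or nested insertions), and the
cohort's allele-frequency spectrum is uniform. Homopolymer survival is
anchored at three printed lengths and linearly interpolated — real
survival curves need not be piecewise linear. Subtelomeric SV calls are
annotated, not suppressed, and should be treated as unreliable, as should
any breakpoint inside a tandem repeat cluster.
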