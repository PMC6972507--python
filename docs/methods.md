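# Methods

## Problem and model

A balanced reciprocal translocation t(A;B) exchanges the terminal segments
of two chromosomes, producing two derivative chromosomes with one novel
adjacency (junction) each; an inversion flips a segment in place, producing
two junctions on one chromosome. A long read crossing a junction aligns as
a chimera: two segments on different loci, adjacent on the read. The
segment boundary on the read localizes the junction, and the unaligned read
bases between the segments measure inserted sequence at the junction.

All user-facing coordinates are 1-based inclusive; internal interval
arithmetic is 0-based half-open with conversion only at I/O boundaries.
Each breakend carries an orientation: `+` when the retained sequence lies
at or left of the breakend on the reference, `-` when at or right of it.
A `+-` junction at A:p1/B:p2 is the VCF 4.2 breakend `N[B:p2[`. The
breakpoint is assigned to the last aligned base of the proximal segment;
this makes the reciprocal-gap arithmetic below well defined (a single
printed position does not itself say which side of the junction it names).

## Split-read evidence

Alignment segments are grouped by read name (primary plus SA-linked
supplementary records; secondary and unmapped records are discarded) and
ordered along the read in sequencer orientation, with read coordinates
recomputed from the CIGAR including hard and soft clips. Segments failing
`min_mapq` (default 20) or `min_segment_len` (default 200 bases) are
dropped; every adjacency among the survivors yields one candidate pair, so
a read with k kept segments contributes k−1 pairs — no whole-read
consistency model is imposed. Pairs overlapping on the read by more than
half the shorter segment are rejected as aligner artifacts; smaller
overlaps (nanopore junction jitter) are tolerated and do not move the
breakend. A MAPQ gate replaces the manual genome-browser review a human
analyst would otherwise perform on ultra-permissive caller output.

Evidence is classified by chromosome and strand: interchromosomal pairs
are translocations and always retained; same-chromosome pairs with a
strand flip are inversions, retained when the span reaches `min_sv_len`
(default 50 bases); same-strand intrachromosomal pairs below that span are
alignment artifacts and rejected.

## Clustering and consensus

Evidence is clustered by single linkage within (chromosome pair,
orientation, class) strata; two evidences link when **both** breakends lie
within `cluster_tol` (default 1 kb — above nanopore junction jitter,
below the distance at which nearby genuine junctions would blur).
Consensus position is the member median, taking the lower-middle member on
even counts (deterministic tie-break); the confidence interval spans the
member extremes; support counts distinct reads; the junction-insertion
estimate is the member median of per-read gaps. Calls are flagged
imprecise — never dropped — when support is below `min_support` (default
3), the interval exceeds `cluster_tol`, or a breakend lies within 5 kb of
a reference N-run of at least 100 bases (the pericentromeric/assembly-gap
case, where alignments cannot pin the position).

## Reciprocal pairing and micro-indel sizing

Two junctions pair when they involve the same chromosome pair with
complementary orientations and their breakends on each chromosome lie
within 1 Mb (configurable). On each chromosome the retained fragment stops
at the `+` breakend and resumes at the partner's `-` breakend; the signed
gap `(resume − 1) − stop` counts bases present in neither derivative
(positive: micro-deletion, reported with its 1-based inclusive interval)
or in both (negative: junction duplication). A perfectly balanced exchange
gives gap 0 on both chromosomes.

## Merging, annotation, junction sequence

Two call sets merge when chromosome pair and orientation agree and both
breakends are within `merge_tol` (default 200 bases); the merged position
is the support-weighted median (lower-middle tie-break, making the
operation commutative), support is the union of read ids, and unmatched
calls are retained tagged with their source. Breakends are annotated with
the names of BED intervals containing them under 0-based half-open
containment. Junction sequence reconstruction concatenates `flank`
reference bases ending at the stop breakend with `flank` bases starting at
the resume breakend, reverse-complementing as orientation requires;
imprecise calls are refused and contig-edge truncation warns.

## CNV windows (no-control mode)

Reads are counted once each in the consecutive, non-overlapping window
containing the primary alignment start (a partition, so window counts sum
to the read count). Windows more than half reference-N are masked. Ratios
are `log2((count + 0.5)/(median + 0.5))` against the sample's own median
unmasked count; the 0.5 pseudo-count keeps sparse windows finite.
Segmentation thresholds each window at ±`cnv_log2_thresh` (default 0.4),
bridges sub-minimum neutral gaps flanked by the same non-neutral state
(Poisson count noise would otherwise fragment genuine events), folds
non-neutral runs shorter than `cnv_min_windows` (default 3) into the
neutral background, and merges the rest. Calls require
`cnv_min_windows × cnv_window` bases. The default window is 10 kb — the
resolution appropriate to ~10× long-read coverage at the method's
original scale — with window size a first-class knob; a genome-wide screen
for megabase-scale events is better served by 100 kb windows, and the
acceptance checks use that size for the 2 Mb-deletion and false-positive
conditions. No GC or mappability correction is applied; with no matched
control there is no principled recipe, and this is a documented
limitation.

## Phasing

Heterozygous SNVs are detected from base pileups of primary alignments
(mapq-gated) in a window around the breakpoint (default ±2 Mb): a site
needs depth ≥ `het_min_depth` (default 5) and a most-common non-reference
base at fraction 0.2–0.8. Indels are excluded: indel alleles in noisy long
reads would need an error model this stage does not have. Reads are then
encoded over the sites as ref/alt/missing and bipartitioned under the MEC
objective — the number of matrix entries to flip so each part is
consistent with one allele per site. Instances with ≤ 12 reads are solved
exactly by enumeration (2^(n−1) bipartitions); larger ones by greedy
seeding from the most informative read, iterative reassignment to
convergence, deterministic restarts (including isolation starts that reach
strongly unbalanced optima), and a short iterated local search — all
seeded, so output is reproducible. The exact solver doubles as the
internal oracle for the heuristic in the test suite. The rearrangement is
assigned to a haplotype when at least two junction-supporting reads appear
in the matrix and ≥ 80% of them fall in one part; the threshold is a
conservative default where no external guidance exists.

## Synthetic data generator

The generator defines the study conditions the tests assert under.
References are uniform-random sequence, optionally stamped with exact
copies of a 300-base Alu-scale repeat unit and with N-runs (centromere
stand-ins). Derivative genomes are block lists over the reference
(interval, strand, or literal inserted sequence), which makes junction
truth, read provenance and read-to-reference mapping exact by
construction. Junction deletions remove bases immediately distal to the
breakpoint on the resuming fragment; insertions add random sequence at the
junction. Haplotype 2 carries Bernoulli-rate SNVs (never in N-runs).

Reads alternate haplotypes to a target total depth, start uniformly per
contig (length-weighted) and draw lognormal lengths — mean 13 kb, shape
σ = 0.6, truncated to [1 kb, 100 kb] — chosen so N50 exceeds the mean
(~15–16 kb vs 13 kb), the pattern real nanopore libraries show. The error
model applies per-base mismatch/insertion/deletion at 0.06/0.04/0.05,
giving BLAST-style identity (gap columns in the denominator)
0.89/1.04 ≈ 0.856, the ≈85% regime of GridION data. Identity is computed
from match/mismatch/indel tallies (NM-consistent), not gap-compressed.

The aligner is emulated: each read emits one record per reference segment
it traverses, with junction-side soft clips, CIGARs reflecting the planted
errors, the longest-aligned record primary and the rest SA-linked
supplementary. Junction boundaries are exact up to edge indel trimming, so
the emulation does not reproduce the junction jitter of a real aligner —
recovery-tolerance results under noise are therefore conservative
statements about error handling, not about aligner breakpoint placement.
Homopolymer-structured error, quality calibration and pore-level effects
are likewise out of scope: passing tests demonstrate the pipeline's
arithmetic and robustness to uniform noise, not performance on real
flowcell data. A layout-only mode emits read coordinates without
sequences for read-count analyses.

Support levels match the real-data observation of roughly ten spanning
reads per breakpoint at ~10× when the rearranged genome is sequenced at
the stated depth; the expected support is
`depth × E[L − 2·min_segment_len]/E[L] ≈ 0.97 × depth`. Diploid
simulation (half the reads per haplotype) is used where heterozygosity is
the object of study — phasing and the heterozygous CNV deletion.

## Problem sizes and numerics

Simulation-backed tests use 100 kb–1 Mb contigs at ~10×, 20 replicates for
the noisy-recovery band, 50 replicates for the CNV null screen, and 200
random ≤10-read matrices for the heuristic-vs-exact MEC comparison; these
sizes make every property statistically meaningful at desk scale.
Deterministic tie-breaks throughout: lower-middle medians, stable sort
orders, seeded generators. Degenerate inputs raise: empty length lists
(N50), all-zero alignment tallies (identity), all-masked windows
(normalization), all-missing matrices (phasing), imprecise calls
(junction sequence).

## Known limitations

- Insertions, deletions and duplications away from junctions are out of
  scope; only translocation/inversion breakends and window-scale CNV.
- No genotyping or multi-sample joint calling; merging assumes both sets
  follow this call model.
- Coverage-rate and depth denominators use non-N reference length; the
  alternative (total length) is not offered.
- Reads spanning more than three junctions are unsupported in the aligner
  emulation.
- CRAM is not supported; SAM/BAM only.
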