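# Methods

## Overview

`svdense` discovers structural variants (SVs ≥ 45 bp by default) from
long-read alignments in six stages: raw signal extraction, depth
estimation, density-based clustering, multi-allele separation, consensus
breakpoint refinement, and depth-adaptive filtering/genotyping, with a
separate local-assembly path for insertions longer than the reads. A
built-in simulator generates ground truth, SV-modified haplotypes,
error-model reads, and *oracle* alignments so that the full caller can be
exercised without an external aligner.

## Raw SV signals

Two evidence channels are scanned per read:

* **Intra-alignment**: CIGAR `I`/`D`/`N` operations of at least
  `min_signal_size` (default 30 bp; final calls are filtered at
  `min_sv_size` = 45 bp, so sub-threshold fragments can merge into
  reportable events). Same-type operations merge when the gap between
  them is at most `max(100 bp, 0.5 × accumulated size)` — noisy reads
  fragment single events, and this chain rule reassembles them. The
  merged signal keeps the first operation's breakpoint.
* **Split reads**: adjacent alignment segments of one read (primary +
  supplementary records, or SA-tag entries when supplementaries are not
  retained), ordered by read coordinate. Classification priority is
  chromosome change (TRA) > orientation change (INV) > gap arithmetic on
  the read gap *g* and reference gap *r*: deletion if `r − g ≥ min`,
  tandem duplication if `r < 0`, `−r ≥ min` and the overlap dominates the
  read gap, insertion if `g − r ≥ min`. Inversion breakpoints come from
  the facing segment ends, which identify both ends of the inverted
  interval regardless of which junction the read crosses or its
  sequencing orientation. Segment pairs where both MAPQ values are 0
  produce no signal.

Alignments with ≥ 200 bp clipped ends (and no sibling segment explaining
the clip) are recorded as clip signals for the large-insertion module.
Secondary alignments are ignored everywhere; split reads are fully
represented by primary + supplementary records, so secondaries only
duplicate evidence.

## Depth and the support threshold

Mean depth = total aligned read bases / total genome length. The minimum
supporting-read count is depth-adaptive:

    N_supp = floor(depth / 10) + 2     (minimum 2)

The floor makes the threshold a conservative integer. N_supp is used
three times: as the density-peak threshold during clustering, as the
per-side clip count for assembly candidates, and as the final support
filter.

## Density clustering

Signals of one type on one chromosome are sorted by position; the signal
density at a position is the count of signals within ± bandwidth/2,
evaluated sparsely at signal positions. Peaks are consumed from highest
summit to lowest; each cluster window extends from the summit until
density drops below 10% of the summit height or the positional gap
exceeds the bandwidth, and consumed signals are removed before the next
peak is sought, making assignment deterministic and one-to-one. The
bandwidth adapts to the local median signal size, clamped to
[100 bp, 1000 bp] (`0.5 × median size`), after a provisional pass at
100 bp — longer events scatter their raw breakpoints more and get wider
windows. Translocation breakpoint pairs use fixed windows instead: 400 bp
when the group's breakpoint standard deviation is ≤ 200 bp, 800 bp
otherwise (the cutoff is the midpoint of the two window radii).

**Multi-allele separation.** For INS/DEL/DUP clusters, Q1 and Q3 of the
member sizes (inclusive linear-interpolation quantiles) decide bimodality.
If Q3 < 2·Q1 the cluster stays single-allele, shedding size outliers
outside [Q1/2, 2·Q3] (the outlier band mirrors the bimodality trigger).
Otherwise the sizes are split by 1-D 2-means. In one dimension the 2-means
optimum is a threshold split of the sorted values, so the implementation
enumerates the n−1 splits and takes the minimum within-cluster sum of
squares — exact and seed-free. Inversions are never split: their size
distribution reflects two anchored junctions, not alternative alleles.

## Breakpoint refinement

Each INS/DEL cluster gets a provisional breakpoint (rounded mean of member
positions/sizes, round-half-up). Supporting reads that fully cover the
breakpoint ± a 500 bp flank contribute windows (reference-oriented);
the longest 8 (descending length, then read id, for determinism) build a
partial order alignment graph, aligned with match +2, mismatch −4 and
affine gaps costing 6 + 2/bp. The consensus is the heaviest
source-to-sink path scored by edge traversal counts — node-support
scoring would let sparsely supported insertion detours outscore the main
bundle, whereas on gap-free equal-length reads edge scoring reduces to a
column-wise majority vote. Two majority-pileup polish rounds (reads
realigned to the consensus with edit-distance alignment; per-column
majority over substitutions, deletions and insertions) remove most
residual error: on 15%-error reads with 8–10 supporting reads the
consensus error is ≈ 0.5–1%.

The consensus is then fit-aligned to the local reference window
(breakpoint ± flank, + event size for deletions, + 200 bp pad) with a
banded-free full affine DP (match +2 / mismatch −4 / gap 6 + 2·L); the
alignment must place ≥ 70% of consensus bases in aligned columns at
≥ 80% identity, otherwise refinement fails. Indels ≥ 30 bp in the
consensus alignment are merged with the same chain rule, left-normalised,
and the event of matching type within 0.5–2× of the provisional size and
within the flank of the provisional position replaces the breakpoint
(`precise=True`). Any failure — fewer than two usable windows, collapsed
consensus, unalignable consensus, no matching event — falls back to the
mean of the raw signals (`precise=False`).

Two scope decisions: clusters whose members are unanimous (identical
position and size in ≥ 3 reads) adopt that coordinate directly — a
consensus cannot move a breakpoint that every read already agrees on —
and INV/TRA clusters keep their mean coordinates, since their
split-segment breakpoints are anchor-defined and refining them would
require orientation-aware alignment for no measurable gain. Events above
10 kbp also fall back (the consensus window would grow quadratically in
the DP).

## Large insertions via local assembly

Insertions longer than the reads never appear as intra-alignment `I`
operations with sufficient support; they surface as stacks of ≥ 200 bp
clips. Clips are chained within 1 kbp windows; windows with ≥ N_supp
reads clipped on each side become assembly candidates (cluster position =
median clip position). The clipped reads (reference-oriented, longest 40)
are assembled by greedy overlap-layout: all-vs-all suffix–prefix overlap
detection with a 1 kbp terminal probe located by banded edit distance at
≥ 65% identity (two 15%-error reads share ≈ 72% identity, so the
field-typical 80% would reject every true overlap), greedy chaining, and
iterative contig-level merging by containment or overlap, which collapses
the parallel chains a greedy path cover leaves behind. No base-level
polish is applied to contigs: insertion sizes derive from anchor
coordinates, where the balanced insertion/deletion error model leaves
length essentially unbiased (< 1% size error observed).

A call is emitted only when exactly one contig remains, its ends anchor
inside the breakpoint ± 50 kbp window (this is the same-chromosome /
not-too-far filter), the reference flanks of the breakpoint bracket a gap
in the contig, and the bracketed insertion is ≥ 1 kbp. Reference-spanning
reads never enter the assembly, so heterozygous events are not
contaminated by the reference allele. An assembly insertion within 1 kbp
and 0.5–2× the size of an existing split/intra insertion call replaces
that call's size (the assembly sees the full sequence).

## Filtering, genotyping, duplication rescue

Candidates below N_supp supporting reads are marked `low_support`; mean
MAPQ below 20 (a conventional uniqueness threshold) marks `low_mapq`.
Multi-allele candidates are filtered per allele; if one allele survives,
a single-allele call is reported instead. Genotype comes from the ratio
of supporting reads to local depth (reads overlapping breakpoint
± 500 bp): ≥ 0.75 → 1/1, else 0/1 (heterozygous support concentrates
near 0.5 and homozygous near 1.0; 0.75 splits the two with a margin on
the hom side), with 1/2 for multi-allele calls whose both alleles pass.

Insertion calls are tested for tandem duplication: each supporting read's
inserted sequence is aligned back to the ± 1 kbp flanking reference in
≤ 500 bp chunks (banded edit distance, ≥ 80% identity per chunk); a read
"aligns back" when ≥ 50% of its inserted bases do, and the call is
re-typed DUP only when strictly more than half of the reads align back.
This bounds rescuable duplications at roughly 2 kbp — longer tandem
copies are detected directly from split-read reference overlaps instead,
which is also how aligners represent them.

Output is VCF 4.2 (1-based positions, SVTYPE/SVLEN/END/SUPPORT and
PRECISE/IMPRECISE INFO keys, negative SVLEN for deletions, BND pairs for
translocations, two ALTs + GT 1/2 for multi-allele records); PASS records
only by default.

## Simulator

The generator works at the paper-protocol scale or any configured one.
Defaults: 10,000 DEL + 10,000 INS + 1,000 DUP + 1,000 INV + 200 TRA
placed uniformly on a human-like chromosome length table, no two events
closer than 2 × max(size, 1 kbp); exact round(2n/3) heterozygote count
per type, heterozygotes phased uniformly; sizes from a mixture of a
geometric-decay background (mean ≈ 300 bp) and Gaussian peaks at
350 ± 30 bp and 6,000 ± 500 bp with weights 0.6/0.3/0.1 — an explicit
stand-in for the Alu/LINE size peaks of human genomes, overridable in
config. Truth indel coordinates are left-normalised, the same convention
the caller reports.

Haplotypes are represented as block maps (mapped reference intervals with
strand, and insertion blocks), which double as exact liftover tables.
Tandem duplications ≤ 2 kbp become insertion blocks (aligners absorb
short extra copies into one alignment); larger ones become overlapping
mapped blocks, i.e. split alignments — the two signatures real aligners
produce. Reciprocal translocations swap block-map tails between
chromosomes; a translocation whose two breakpoints land on the same
derived molecule (possible after earlier swaps) is dropped from the truth
set.

Reads: gamma-distributed lengths (shape 3, configurable mean, minimum
500 bp) drawn until the per-haplotype target depth is reached, uniform
starts, random strand. Error presets apply independent per-base errors —
`pacbio-clr` 15% total (40/30/30 mismatch/ins/del), `nanopore` 12%
(25/35/40), `hifi` 1%, `perfect` 0 — as single-base events, matching the
dominant error mode of the modelled chemistries. Oracle alignments
compose each read's CIGAR from its known placement, the block map, and
the error edits: indels ≤ 10 kbp stay within one record, larger events /
strand flips / chromosome changes split the read into primary +
supplementary records with SA tags, MAPQ 60, and soft clips; mapped
segments under 30 bp are dropped (clipped). Everything is driven by
independent child streams of one seed.

**What the oracle does not emulate:** mapping ambiguity and MAPQ
variation, reference bias, chimeric/junk reads, clustered or
context-dependent errors, and real repeat structure (the synthetic genome
is uniform random, so breakpoints are almost always locally unique).
Passing benchmarks on oracle alignments therefore demonstrates the
correctness of the signal→cluster→refine→filter chain under realistic
error rates, not end-to-end performance on a real genome through a real
aligner.

## Evaluation

A DEL/INS/DUP/INV call is a true positive when type matches, start
coordinates are within 1 kbp, and the call size is within 0.5–2× of
truth; translocations need both breakpoints within 1 kbp. Matching is
one-to-one and greedy by ascending coordinate distance (a multimatch
mode reproduces the alternative convention); both truth and calls are
filtered at ≥ 45 bp symmetrically. Breakpoint shifts are histogrammed
over −100..+100 bp with out-of-range shifts clamped into the end bins;
the exact (shift 0) and |shift| ≤ 1 fractions are reported. Genotype
concordance is reported separately and never affects TP status.

## Benchmark problem sizes

The packaged benchmark protocols are desk-scale versions of the
simulation experiments: discovery on a 5 Mbp, 4-chromosome genome with
400 SVs in 50:50:5:5:1 type proportions at 25× per haplotype and 15 kbp
mean reads (PacBio-like and Nanopore-like presets), and the
ultra-large-insertion study on 2 Mbp with 20 homozygous 20–30 kbp
insertions at 50× total. These sizes keep a full run in minutes on one
core while leaving hundreds of events per metric.

## Known limitations

* No CRAM input; region queries need an indexed BAM.
* k = 2 multi-allele separation only (diploid genomes).
* INV/TRA breakpoints are not consensus-refined (see above).
* The duplication-rescue window bounds rescuable tandem copies at ~2 kbp.
* The assembler is a greedy overlap layouter tuned for a single locus of
  clipped reads, not a general-purpose assembler.
* Nested or complex multi-breakpoint SVs beyond the five classes are out
  of scope.
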