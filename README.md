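# svdense

Structural-variant (SV) discovery from long-read alignments.

Long reads (PacBio CLR/HiFi, Oxford Nanopore) span most structural
variants outright, but their 1–15% error rates scatter the per-read
evidence: a single deletion shows up as slightly different CIGAR
operations in every read, large insertions only as stacks of clipped
alignment ends. `svdense` turns that noisy evidence into a confident VCF
call set. It is aimed at people building or studying SV callers:
everything — including the benchmark data — is generated and scored by
code in this package, so every stage is testable in isolation.

## Method

1. **Raw signals.** Every alignment is scanned for intra-alignment
   indels (CIGAR `I`/`D` ≥ 30 bp, nearby same-type ops merged) and
   split-read segment pairs, classified by chromosome, orientation and
   the read-gap/reference-gap arithmetic into DEL, INS, DUP, INV, TRA.
   Clipped ends ≥ 200 bp are recorded separately.
2. **Depth-adaptive threshold.** The minimum supporting-read count is
   `N_supp = ⌊depth/10⌋ + 2`.
3. **Density clustering.** Signals of one type are clustered around
   density peaks ≥ `N_supp`; each cluster window extends until the
   density falls below 10% of the summit. Translocations use fixed
   400/800 bp windows on both breakpoints. Clusters whose size
   distribution is bimodal (Q3 ≥ 2·Q1) are split into two alleles by
   exact 1-D 2-means.
4. **Breakpoint refinement.** Supporting-read windows (± 500 bp) are
   collapsed into a consensus by partial order alignment plus majority
   polish, the consensus is realigned to the local reference with an
   affine-gap DP, and the indel found there replaces the mean-of-signals
   breakpoint.
5. **Large insertions.** Breakpoints with ≥ `N_supp` clipped reads on
   each side trigger greedy overlap-layout assembly of the clipped
   reads; a single contig whose anchors bracket a ≥ 1 kbp gap yields an
   insertion call even when the event is longer than any read.
6. **Filtering & genotyping.** Support ≥ `N_supp`, mean MAPQ ≥ 20,
   per-allele filtering for multi-allele SVs, genotype from the
   supporting-read : local-depth ratio, and re-typing of insertions as
   tandem duplications when the inserted sequence aligns back to the
   ± 1 kbp flank in most reads.

The built-in simulator implants a configurable SV mix (2:1 het:hom,
size peaks at ~350 bp and ~6 kbp) into a diploid genome, draws
error-model reads, and emits *oracle* alignments computed from the known
read placement — so benchmarks run with no external aligner and no
downloads. The evaluation module scores calls with the standard TP rules
(type match, breakpoints within 1 kbp, size within 0.5–2×).

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small benchmark, call SVs, and score the calls:

```bash
svdense simulate --out bench --genome-length 500000 --chroms 2 \
    --n-del 8 --n-ins 8 --n-dup 2 --n-inv 2 --n-tra 1 \
    --depth 12 --mean-read-length 12000 --preset perfect --seed 5
svdense call --bam bench/oracle.sam --ref bench/reference.fa --out bench/calls.vcf
svdense evaluate --truth bench/truth.tsv --calls bench/calls.vcf
```

The `call` step prints the estimated depth and threshold:

```
depth 23.7x, N_supp 4; 21 PASS calls -> bench/calls.vcf
```

and `evaluate` prints per-type and overall accuracy:

```
type    recall  precision       F1
DEL     100.00  100.00  100.00
INS     100.00  100.00  100.00
DUP     100.00  100.00  100.00
INV     100.00  100.00  100.00
TRA     100.00  100.00  100.00
overall 100.00  100.00  100.00
breakpoints: 100.00% exact, 100.00% within 1 bp
```

On error-free reads every implanted SV ≥ 45 bp is recovered; the
breakpoint lines show how many true-positive calls sit exactly on, or
within 1 bp of, the simulated breakpoint. The same pipeline is available
as a library:

```python
from svdense import SimConfig, simulate, call_svs, match_calls
from svdense.simulator import error_rng

cfg = SimConfig(chrom_lengths={"chr1": 500_000}, counts={"DEL": 10, "INS": 10},
                depth=25, preset="pacbio-clr", seed=1)
sim = simulate(cfg)
calls, profile = call_svs(sim.records(cfg, error_rng(cfg)), sim.genome)
result = match_calls(sim.truth, [c for c in calls if c.filter_status == "PASS"])
print(result.overall.f1, result.exact_fraction)
```

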