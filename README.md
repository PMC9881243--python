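# delcall

Germline deletion calling from paired-end short-read alignments using
discordant read pairs, clipped reads, read-depth features and
unsupervised clustering.

## The problem

Submicroscopic deletions — losses of 50 bp to ~3 Mb of one or both
chromosome copies — are a major class of structural variation in diploid
genomes, and calling them from low-coverage (~5–10×) short-read data is
hard: no single alignment signal is reliable on its own. `delcall` is for
researchers who have a coordinate-sorted BAM of paired-end reads mapped
to a reference and want a deletion callset (VCF/BED) with base-accurate
breakpoints wherever the data allow, plus a simulator and evaluator to
measure how well that works under a known truth.

## The method

Three library statistics are estimated first: the genome-average depth
*Depth<sub>avg</sub>*, and the insert-size mean *Avg<sub>IS</sub>* and
standard deviation *STD<sub>IS</sub>* (outlier-trimmed, so that the
deletion-spanning tail does not contaminate them). Each chromosome is
then processed independently:

1. **Evidence.** Read pairs with insert size
   *Len<sub>IS</sub>* > *Avg<sub>IS</sub>* + 3·*STD<sub>IS</sub>*
   (capped at 3 Mb) are collected as discordant pairs — a fragment
   spanning a deletion is stretched by the deleted length when projected
   onto the reference. Reads soft/hard-clipped ≥ 15 bp at exactly one
   end are collected as border-clipped reads; the clip boundary marks a
   putative breakpoint (tail clips support left breakpoints, head clips
   right breakpoints).
2. **Candidates.** Discordant pairs whose left mates start within one
   read length of each other are grouped into candidate sites
   (singletons dropped), overlapping sites are merged, and sites with no
   clip support are discarded. Initial breakpoints are the innermost
   discordant edges (LBP = largest left-mate end, RBP = smallest
   right-mate start), then refined to the clip position supported by the
   most mate-consistent clipped reads (ties: largest position for LBP,
   smallest for RBP; a single supporting read never moves a breakpoint).
3. **Features.** Candidates whose mean interior depth exceeds
   *Depth<sub>avg</sub>* are discarded. The rest are summarised by the
   fraction LN<sub>i</sub> of interior positions in four depth bands:
   T<sub>0</sub> = 0 (perfect homozygous loss),
   T<sub>1</sub> = (0, ⌈0.25·*Depth<sub>avg</sub>*⌉),
   T<sub>2</sub> = [⌈0.25·*Depth<sub>avg</sub>*⌉, ⌈0.5·*Depth<sub>avg</sub>*⌉]
   (hemizygous loss), T<sub>3</sub> = (⌈0.5·*Depth<sub>avg</sub>*⌉,
   ⌈*Depth<sub>avg</sub>*⌉].
4. **Unsupervised calling.** The LN vectors are embedded by the top two
   principal components and cut into four clusters by Ward/Euclidean
   agglomerative clustering. A cluster is *good* when the sum over
   i = 0..2 of the top-half means THAvg<sub>LN_i</sub> reaches 0.7 (an
   ideal deletion has nearly all its length in T<sub>0</sub>–T<sub>2</sub>).
   With T<sub>high/low</sub> = Avg ± SD of the cluster's principal
   feature, a good cluster discards a member only when both its
   principal feature and the sum of the other two fall below
   T<sub>low</sub>; a bad cluster keeps a member only when either
   exceeds T<sub>high</sub>.

Calls are scored against a truth set with a per-breakpoint tolerance of
15 bp; since every unmatched call is a false positive, precision/recall
equal accuracy/sensitivity and F1 = 2·P·R/(P+R).

## Worked example

Simulate a 1 Mb diploid chromosome with ten planted deletions at the
default 5× coverage, call deletions, and score them:

```sh
delcall simulate --out-dir demo --ref-length 1000000 --n-deletions 10 --seed 17
python -c "from delcall.simulate import to_indexed_bam; to_indexed_bam('demo/sim.sam')"
delcall call --bam demo/sim.bam --out demo/calls.vcf
delcall call --bam demo/sim.bam --out demo/calls.bed --bed
delcall evaluate --calls demo/calls.bed --truth demo/sim.truth.bed
```

which prints

```
INFO delcall.pipeline: library: depth_avg=5.00 avg_is=400.2 std_is=50.0 read_length=101
INFO delcall.pipeline: chr1: 9 candidates -> 7 called (0 depth-filtered, 2 cluster-filtered)
wrote 7 calls to demo/calls.vcf
TP=6 FP=1 FN=4 precision=0.8571 recall=0.6000 F1=0.7059
```

The library line shows the estimated statistics driving every threshold
(5× depth, 400 ± 50 bp inserts, 101 bp reads). Nine candidate sites had
both discordant-pair and clipped-read support; the cluster filter removed
two of them, and six of the seven calls match a planted deletion with
both breakpoints within 15 bp. The VCF records symbolic deletion alleles:

```
chr1	86835	DEL1	N	<DEL>	.	PASS	SVTYPE=DEL;END=94373;SVLEN=-7539;SUPPORT=9
chr1	181197	DEL2	N	<DEL>	.	PASS	SVTYPE=DEL;END=189725;SVLEN=-8529;SUPPORT=8
```

`POS` is the first deleted base (1-based), `END` the last, `SVLEN` the
negated deletion length, and `SUPPORT` the number of discordant pairs in
the candidate site. At 5× some planted deletions are genuinely
uncallable — a hemizygous junction is crossed by only a couple of
usable clipped reads, and missing those leaves the breakpoints beyond
the 15 bp tolerance (see `docs/methods.md` for the evidence-density
arithmetic).

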