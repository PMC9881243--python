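# Methods

`delcall` detects germline submicroscopic deletions (50 bp – 3 Mb) in a
diploid sample from a coordinate-sorted, indexed BAM/SAM of paired-end
reads. This note records the model, the parameters that matter, the
numerical choices made where the design was genuinely open, what the
bundled simulator does and does not emulate, and the method's known
limitations. All internal coordinates are 0-based, half-open; VCF output
converts at the boundary (POS = first deleted base, 1-based).

## Signal model

A deletion leaves three footprints in paired-end alignments:

* **Discordant pairs.** A sequenced fragment that spans the deletion is
  stretched by the deleted length when projected onto the reference, so
  its template length falls in the far upper tail of the insert-size
  distribution. With inserts roughly normal (mean Avg_IS, SD STD_IS),
  pairs with Len_IS > Avg_IS + 3·STD_IS are collected; in a
  deletion-free library only ~0.13% of pairs exceed that threshold.
  Pairs spanning more than 3 Mb (configurable `max_span`) are discarded
  as beyond the submicroscopic range; deletions are intrachromosomal, so
  pairs with mates on different chromosomes are ignored.
* **Border-clipped reads.** A read crossing a breakpoint aligns on one
  side and is soft-clipped on the other, with the clip boundary at the
  breakpoint to the base. Clips shorter than 15 bp (`clip_min`) are too
  ambiguous to trust and are filtered; reads clipped ≥ 15 bp at both
  ends are excluded as side-ambiguous. Hard clips count toward clip
  length.
* **Depth.** Homozygous deletions have (ideally) zero interior depth;
  hemizygous deletions about half the genome average.

Reads that are unmapped, PCR duplicates, secondary/supplementary, or
below mapping quality 20 (`mapq_min`; the conventional q-filter) are
excluded everywhere, including from the depth profiles.

## Library statistics

`Depth_avg` is total aligned bases over total reference length of the
processed chromosomes — zero-depth positions count, and the statistic is
computed once genome-wide, not per chromosome. `Avg_IS`/`STD_IS` come
from usable FR-oriented same-chromosome pairs, counted once from the
leftmost mate. The mean and sample SD are taken after trimming inserts
outside median ± 10·MAD. The trimming is essential, not cosmetic: the
deletion-spanning pairs the caller is looking for sit in the same tail,
and a naive SD over all pairs is inflated several-fold by them, which
would push the 3-sigma discordance threshold past most true deletions.
Multiple read groups are pooled into one global estimate. `read_length`
is the modal query length.

## Candidate detection

Discordant pairs on one chromosome are sorted by left-mate start and
chained while consecutive starts are strictly less than one read length
apart. Groups with a single pair are dropped (one stray tail pair is not
evidence). A site spans the smallest left-mate start (LB) to the largest
right-mate end (RB). Sites whose half-open spans overlap are merged to a
fixed point, recomputing LB/RB from the union of member pairs; merged
sites are kept regardless of how the singleton filter would have treated
their parts (they have ≥ 2 pairs by construction).

Clipped reads are attached to the site whose span, padded by Avg_IS per
flank, contains the clip position — a breakpoint-supporting read can map
just outside LB/RB. A clip inside several padded spans goes to the
nearest unpadded span, ties to the left. Sites with no attached clips
are discarded.

Initial breakpoints are the innermost discordant edges: LBP = largest
left-mate alignment end (reference-consumed length), RBP = smallest
right-mate start. Degenerate sites with LBP ≥ RBP (crossing mates, e.g.
two merged events) are discarded with a warning rather than repaired.

### Breakpoint refinement

Tail clips refine LBP, head clips RBP. A tail clip qualifies when its
clip position is within Avg_IS of the current LBP, lies inside [LB, RB],
and is mate-consistent. Mate roles are positional — "first" is the
leftmost mate of its pair (sign of TLEN), not the read1 flag, which in
Illumina libraries is random with respect to genomic orientation; the
consistency rules below only make physical sense positionally, and using
the flag instead measurably halves the usable clip evidence:

* a **second-mate** (rightmost) tail clip is the 3' end of a concordant
  fragment lying left of the deletion: its insert must be within
  3·STD_IS of Avg_IS and its mate within Avg_IS of LB;
* a **first-mate** (leftmost) tail clip belongs to a fragment spanning
  the deletion: its mate must land within Avg_IS of RB.

Head-clip rules mirror these (second-mate: mate near LB; first-mate:
insert near Avg_IS and mate near RB). Among qualifying clips the
positions with maximal support are taken; if that support is at least 2,
LBP moves to the largest such position (RBP to the smallest). A single
supporting read never moves a breakpoint. If the two refinements cross
(RBP ≤ LBP), both revert to the initial estimates. The proximity
tolerances (3·STD_IS for "insert near Avg_IS", Avg_IS for "mate near a
boundary") reuse the caller's own insert-size scales; nothing else in
the pipeline is sensitive to them at realistic coverage.

## Depth features

Per-base depth over [LBP, RBP) is piled up from usable reads' aligned
blocks (soft-clipped bases contribute nothing). Candidates with mean
interior depth strictly above Depth_avg are discarded. Surviving
candidates are featurized by four coverage bands relative to
d = Depth_avg:

| band | depth range | interpretation |
|------|-------------------------------|----------------|
| T0 | exactly 0 | perfect homozygous deletion |
| T1 | (0, ⌈0.25·d⌉) | homozygous with mapping noise |
| T2 | [⌈0.25·d⌉, ⌈0.5·d⌉] | hemizygous |
| T3 | (⌈0.5·d⌉, ⌈d⌉] | mixed true/false |

Zero depth is assigned to T0 exclusively (T1's nominal closed lower
bound would otherwise claim it, but zero is the perfect homozygous
signal). Positions deeper than ⌈d⌉ belong to no band and only dilute the
normalized features. The feature vector is LN_i = L_i/(RBP − LBP), the
fraction of interior length in each band; per-band mean depths D_i are
computed and reported for inspection but play no role in calling.

## Unsupervised calling

Per chromosome, the n×4 LN matrix is mean-centered (no variance scaling
— the features already share the [0,1] scale) and projected onto its top
two principal components, then cut into exactly four clusters by
bottom-up agglomerative clustering with Euclidean metric and Ward
linkage (scikit-learn's implementation; deterministic given the input).
Four clusters target the four expected populations: clean homozygous,
noisy homozygous, noisy hemizygous, and marginal candidates mixed with
wild-type intervals.

For each cluster and each deletion band i ∈ {0,1,2}, members are sorted
ascending by LN_i (SR_i) and three statistics are computed: the mean
Avg_LN_i, the sample SD STD_LN_i (0 for singleton clusters), and the
top-half mean THAvg_LN_i over the ⌈N/2⌉ largest values. A cluster is
**good** when THAvg_LN_0 + THAvg_LN_1 + THAvg_LN_2 ≥ 0.7, the same
deletion-band mass that defines a plausible true deletion; otherwise
**bad**. The feature with the largest THAvg (ties to the smallest index)
is the cluster's principal feature i\*, and assuming LN_{i\*} roughly
follows the empirical rule (no normality test is performed), T_high/low
= Avg_LN_{i\*} ± STD_LN_{i\*} bracket the cluster bulk. A good cluster
discards a member only when LN_{i\*} < T_low **and** Σ_{j≠i\*} LN_j <
T_low; a bad cluster keeps a member only when LN_{i\*} > T_high **or**
Σ_{j≠i\*} LN_j > T_high. All filter inequalities are strict. Both
thresholds derive from the principal feature yet are also compared
against the sum of the other two features; the rule is implemented as
stated even though that asymmetry is odd on its face.

With fewer than four candidates on a chromosome there is nothing to
cluster; each candidate is then called directly by the same mass rule
Σ_{i=0..2} LN_i ≥ 0.7.

## Simulator

The bundled simulator emulates the data regime the caller is designed
for: a uniform-random A/C/G/T reference, two haplotypes (homozygous
deletions excised from both, hemizygous from one), fragments drawn per
haplotype with normal inserts (defaults 400 ± 50 bp), 101 bp reads, and
coverage defaulting to 5× — the depth of the archetypal low-coverage
human sample this class of caller targets. Alignments are synthesized
directly from the known haplotype-to-reference map rather than via an
external aligner, so output is hermetic and byte-deterministic given the
seed: spanning fragments become discordant pairs with inserts inflated
by the deleted length, junction-crossing reads are soft-clipped exactly
at the breakpoint (the longer segment aligns), and TLEN is the outer
span of the aligned coordinates — which makes a junction-crossing pair
concordant when the deleted part is clipped off, exactly as a real
aligner reports it.

The simulator does **not** model sequencing errors, base-quality
variation, repeats/mapping ambiguity, GC bias, or chimeric fragments.
Passing tests on simulated data therefore demonstrate the pipeline's
logic under clean mapping, not robustness to alignment artifacts in real
genomes; with perfectly mapped reads, candidate precision is near 1 and
the binding constraints are evidence density and the band/threshold
geometry discussed below.

Evaluation matches calls to truth greedily left-to-right, at most one
call per truth record, requiring **both** breakpoints within the
tolerance (15 bp by default, applied per breakpoint — the stricter
reading).

## Numerical choices and degenerate inputs

* Strict inequalities throughout: the discordance threshold, the depth
  filter, the read-length grouping gap, and the cluster filters, with
  the good-cluster label (≥ 0.7) inclusive.
* Agglomerative merge ties are resolved deterministically, so identical
  inputs give byte-identical VCFs; calls are sorted by (chrom, LBP, RBP)
  and the VCF header carries no timestamp.
* Empty chromosomes, zero candidates, or an empty callset produce valid
  empty outputs; an alignment file with no usable pairs is a hard error
  ("cannot estimate insert size").
* Insert-size estimation falls back to the untrimmed sample if MAD
  trimming would remove everything (an all-identical-insert library has
  MAD 0 but also nothing to trim).

## Known limitations

* **Evidence density at low coverage.** A deletion junction at total
  coverage c is crossed by about c reads, of which ~70% carry a ≥ 15 bp
  clip, split between tail (left-breakpoint) and head (right-breakpoint)
  evidence; a hemizygous junction halves all of that. The ≥ 2-support
  rule for moving a breakpoint therefore fires on only ~40–80% of sides
  at 5–8×, and the initial discordant-edge breakpoints are exact only
  when a crossing read of the right type happens to be sampled. With a
  15 bp matching tolerance this caps achievable recall well below 1 at
  low coverage — measured end-to-end recall on clean simulations is
  ~0.55–0.75 at 8×, with precision near 1.
* **Band parity at even coverages.** The hemizygous band top is
  ⌈Depth_avg/2⌉. When Depth_avg sits just below an even integer (e.g.
  7.9–8.0), hemizygous interior depth (~Depth_avg/2) leaves only ~62% of
  interior mass in bands T0–T2, the hemizygous cluster's THAvg sum lands
  just under the 0.7 good threshold, and most of its members are
  discarded; at 5.26× the same arithmetic gives ~0.74 and hemizygous
  clusters are retained. The ceiling discretization makes cluster labels
  oscillate with coverage parity — a genuine sensitivity of the method,
  not of this implementation.
* Two distinct overlapping deletions merged into one site are not
  resolved; the degenerate site is discarded.
* Deletions shorter than ~3·STD_IS cannot inflate the insert past the
  discordance threshold and are invisible to the candidate stage.
* No genotype likelihoods or per-call quality scores are emitted;
  `SUPPORT` (discordant-pair count) is the only confidence proxy.
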