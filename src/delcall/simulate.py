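"""Paired-end read simulation with planted deletions, and call evaluation.

The simulator emulates the low-coverage short-read regime the caller is
designed for: ~5-10x genome coverage, ~101 bp paired-end reads, and a
near-normal insert-size distribution.  A diploid sample is built from two
haplotypes of a random reference; each planted deletion is excised from
both haplotype copies (homozygous) or one (hemizygous).  Fragments are
drawn along each haplotype and their reads are projected back onto the
reference, so that

* a fragment spanning a deletion becomes a discordant pair whose template
  length is inflated by the deleted length,
* a read crossing a breakpoint is soft-clipped exactly at the breakpoint
  (the longer segment aligns, the shorter is clipped), and
* bases interior to a deletion lose the deleted haplotype's coverage.

Alignments are synthesized directly from the known haplotype-to-reference
coordinate map rather than via an external aligner, keeping the output
hermetic and deterministic: the same seed and parameters reproduce the
truth set byte-for-byte and the same multiset of alignment records.

The evaluator implements breakpoint-tolerant matching: a call matches a
truth deletion when both breakpoints agree within the tolerance (15 bp by
default), matching greedily left-to-right with at most one call per truth
record.  Because every non-matched call is a false positive (there are no
true negatives), precision and recall coincide with accuracy and
sensitivity and F1 = 2 * P * R / (P + R).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

#: submicroscopic deletion size range (bp)
MIN_DELETION = 50
MAX_DELETION = 3_000_000

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DeletionSpec:
    """A planted deletion: reference span [start, end) and zygosity."""

    chrom: str
    start: int
    end: int
    zygosity: str  # "homozygous" | "hemizygous"

    def __post_init__(self) -> None:
        length = self.end - self.start
        if not (MIN_DELETION <= length <= MAX_DELETION):
            raise ValueError(
                f"deletion length {length} outside submicroscopic range "
                f"[{MIN_DELETION}, {MAX_DELETION}]"
            )
        if self.zygosity not in ("homozygous", "hemizygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EvalResult:
    """Breakpoint-tolerant matching outcome and the derived rates."""

    true_positive: int
    false_positive: int
    false_negative: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class SimulatedSample:
    """Paths emitted by :func:`simulate_diploid_sample`."""

    fasta: Path
    sam: Path
    bed: Path
    truth: tuple[DeletionSpec, ...]


def _haplotype_segments(
    ref_length: int, deletions: list[DeletionSpec]
) -> list[tuple[int, int, int]]:
    """Piecewise map haplotype -> reference after excising ``deletions``.

    Returns (hap_start, ref_start, length) segments in order.
    """
    segments = []
    hap_pos = 0
    ref_pos = 0
    for d in sorted(deletions, key=lambda d: d.start):
        if d.start < ref_pos:
            raise ValueError("deletions overlap on one haplotype")
        if d.end > ref_length:
            raise ValueError("deletion extends beyond the reference")
        seg_len = d.start - ref_pos
        if seg_len > 0:
            segments.append((hap_pos, ref_pos, seg_len))
            hap_pos += seg_len
        ref_pos = d.end
    if ref_pos < ref_length:
        segments.append((hap_pos, ref_pos, ref_length - ref_pos))
    return segments


def _map_read(
    segments: list[tuple[int, int, int]], start: int, end: int
) -> tuple[int, str, int]:
    """Project haplotype interval [start, end) onto the reference.

    The longest contiguously mapping piece aligns (first wins ties, which
    an aligner's preference for the earlier segment mimics); the remainder
    is soft-clipped.  Returns (ref_pos, cigar, ref_end).
    """
    pieces = []  # (read_offset, ref_start, length)
    for hap_start, ref_start, seg_len in segments:
        lo = max(start, hap_start)
        hi = min(end, hap_start + seg_len)
        if hi > lo:
            pieces.append((lo - start, ref_start + (lo - hap_start), hi - lo))
    if not pieces:
        raise ValueError("read maps to no reference segment")
    best = max(pieces, key=lambda p: p[2])
    offset, ref_pos, length = best
    head = offset
    tail = (end - start) - (offset + length)
    cigar = ""
    if head:
        cigar += f"{head}S"
    cigar += f"{length}M"
    if tail:
        cigar += f"{tail}S"
    return ref_pos, cigar, ref_pos + length


def simulate_diploid_sample(
    ref_length: int,
    deletions: list[DeletionSpec],
    out_dir,
    coverage: float = 5.0,
    read_length: int = 101,
    is_mean: float = 400.0,
    is_std: float = 50.0,
    seed: int = 0,
    chrom: str = "chr1",
    prefix: str = "sim",
) -> SimulatedSample:
    """Write a simulated reference FASTA, sorted SAM and truth BED.

    ``coverage`` is the target genome-wide mean depth over all reference
    positions (deleted regions included); each haplotype receives half the
    fragments.  Homozygous deletions are excised from both haplotypes,
    hemizygous ones from the first only.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    for d in deletions:
        if d.end > ref_length:
            raise ValueError("deletion extends beyond the reference")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    ref_seq = "".join(rng.choice(_BASES, size=ref_length))
    hap_dels = (
        list(deletions),  # haplotype 0 carries every deletion
        [d for d in deletions if d.zygosity == "homozygous"],
    )

    records = []
    frag_id = 0
    min_insert = 2 * read_length
    for hap_index, dels in enumerate(hap_dels):
        segments = _haplotype_segments(ref_length, sorted(dels, key=lambda d: d.start))
        hap_len = sum(s[2] for s in segments)
        hap_seq = "".join(
            ref_seq[ref_start : ref_start + seg_len]
            for _, ref_start, seg_len in segments
        )
        n_frags = int(round(coverage * ref_length / (4 * read_length)))
        inserts = np.rint(rng.normal(is_mean, is_std, size=n_frags)).astype(int)
        inserts = np.clip(inserts, min_insert, hap_len)
        starts = rng.integers(0, hap_len - inserts + 1)
        read1_is_left = rng.random(n_frags) < 0.5
        for ins, s, r1_left in zip(inserts, starts, read1_is_left):
            left_iv = (int(s), int(s) + read_length)
            right_iv = (int(s) + int(ins) - read_length, int(s) + int(ins))
            left_pos, left_cigar, left_end = _map_read(segments, *left_iv)
            right_pos, right_cigar, right_end = _map_read(segments, *right_iv)
            tlen = max(left_end, right_end) - min(left_pos, right_pos)
            name = f"{prefix}_frag{hap_index}_{frag_id}"
            frag_id += 1
            for which, (iv, pos, cigar, is_left) in enumerate(
                (
                    (left_iv, left_pos, left_cigar, True),
                    (right_iv, right_pos, right_cigar, False),
                )
            ):
                flag = 0x1 | 0x2  # paired, proper
                flag |= 0x20 if is_left else 0x10  # mate-reverse / reverse
                is_read1 = (which == 0) == r1_left
                flag |= 0x40 if is_read1 else 0x80
                mate_pos = right_pos if is_left else left_pos
                records.append(
                    (
                        pos,
                        name,
                        flag,
                        cigar,
                        mate_pos,
                        tlen if is_left else -tlen,
                        hap_seq[iv[0] : iv[1]],
                    )
                )

    records.sort(key=lambda r: (r[0], r[1], r[2]))

    fasta_path = out_dir / f"{prefix}.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, ref_length, 60):
            fh.write(ref_seq[i : i + 60] + "\n")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": ref_length}],
    }
    sam_path = out_dir / f"{prefix}.sam"
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for pos, name, flag, cigar, mate_pos, tlen, seq in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.next_reference_id = 0
            a.next_reference_start = mate_pos
            a.template_length = tlen
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            sam.write(a)

    bed_path = out_dir / f"{prefix}.truth.bed"
    truth = tuple(sorted(deletions, key=lambda d: (d.chrom, d.start)))
    with open(bed_path, "w") as fh:
        for d in truth:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.zygosity}\n")

    return SimulatedSample(fasta=fasta_path, sam=sam_path, bed=bed_path, truth=truth)


def to_indexed_bam(sam_path, bam_path=None) -> Path:
    """Sort a SAM into an indexed BAM (convenience for running the caller)."""
    sam_path = Path(sam_path)
    bam_path = Path(bam_path) if bam_path else sam_path.with_suffix(".bam")
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


def read_truth_bed(path) -> list[DeletionSpec]:
    """Load a truth BED (chrom, start, end[, zygosity])."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            zyg = fields[3] if len(fields) > 3 else "homozygous"
            out.append(
                DeletionSpec(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    zygosity=zyg,
                )
            )
    return out


def sample_wildtype_intervals(
    ref_length: int,
    n: int,
    min_len: int,
    max_len: int,
    exclude: list[tuple[int, int]],
    seed: int = 0,
    pad: int = 1000,
) -> list[tuple[int, int]]:
    """Draw ``n`` deletion-free intervals avoiding ``exclude`` spans.

    Used to inject wild-type regions as forced candidates when probing the
    caller's false-positive suppression.
    """
    rng = np.random.default_rng(seed)
    occupied = [(s - pad, e + pad) for s, e in exclude]
    out: list[tuple[int, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("reference too crowded for wild-type intervals")
        length = int(rng.integers(min_len, max_len + 1))
        s = int(rng.integers(0, ref_length - length))
        if all(e0 >= s + length or e1 <= s for e0, e1 in occupied):
            out.append((s, s + length))
            occupied.append((s, s + length))
    return out


def _as_intervals(items) -> list[tuple[str, int, int]]:
    out = []
    for item in items:
        if isinstance(item, tuple):
            out.append((item[0], int(item[1]), int(item[2])))
        elif hasattr(item, "lbp"):
            out.append((item.chrom, item.lbp, item.rbp))
        else:
            out.append((item.chrom, item.start, item.end))
    return out


def evaluate_calls(calls, truth, tolerance: int = 15) -> EvalResult:
    """Match calls to truth deletions within a per-breakpoint tolerance.

    Matching is greedy left-to-right with at most one call per truth
    record; a call is a true positive when both its breakpoints lie
    within ``tolerance`` bp of an unmatched truth deletion's breakpoints.
    """
    call_ivs = sorted(_as_intervals(calls))
    truth_ivs = sorted(_as_intervals(truth))
    matched = [False] * len(truth_ivs)
    tp = 0
    for chrom, start, end in call_ivs:
        for i, (t_chrom, t_start, t_end) in enumerate(truth_ivs):
            if matched[i] or t_chrom != chrom:
                continue
            if abs(start - t_start) <= tolerance and abs(end - t_end) <= tolerance:
                matched[i] = True
                tp += 1
                break
    fp = len(call_ivs) - tp
    fn = len(truth_ivs) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return EvalResult(
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
        precision=precision,
        recall=recall,
        f1=f1,
    )
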