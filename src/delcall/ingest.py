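"""Alignment ingestion: library statistics and breakpoint evidence.

Reads a coordinate-sorted BAM/SAM of paired-end reads and produces

* :class:`LibraryStats` — the genome/library summary (average depth,
  insert-size mean/SD, read length) that drives every downstream
  threshold;
* :class:`DiscordantPair` records — same-chromosome pairs whose insert
  size exceeds ``avg_is + 3 * std_is`` (a fragment spanning a deletion is
  stretched by the deleted length when projected onto the reference);
* :class:`ClippedRead` records — reads soft/hard-clipped by >= 15 bp at
  their head or tail, whose clip boundary marks a putative breakpoint.

All coordinates are 0-based, half-open, as pysam reports them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pysam

#: minimum clip length (bp) for a read to count as border-clipped
MIN_CLIP_LENGTH = 15
#: mapping-quality floor below which a read is considered low quality
DEFAULT_MIN_MAPQ = 20
#: multiples of the insert-size SD defining discordance
DISCORDANT_SIGMA = 3.0
#: submicroscopic ceiling: pairs spanning more than this are discarded
DEFAULT_MAX_SPAN = 3_000_000
#: Picard-style outlier trimming width (median +/- DEVIATIONS * MAD) used
#: when estimating the insert-size mean/SD; without it, the rare
#: deletion-spanning pairs contaminate STD_IS and wreck the 3-sigma rule
MAD_DEVIATIONS = 10.0

CIGAR_SOFT_CLIP = 4
CIGAR_HARD_CLIP = 5


@dataclass(frozen=True)
class LibraryStats:
    """Genome-wide library summary.

    Attributes
    ----------
    depth_avg : float
        Mean read depth (reads per base) over all reference positions of
        the processed chromosomes, zero-depth positions included.
    avg_is : float
        Mean insert size (outer fragment length, bp).
    std_is : float
        Sample standard deviation of the insert size (bp).
    read_length : int
        Modal read length (bp).
    """

    depth_avg: float
    avg_is: float
    std_is: float
    read_length: int

    def __post_init__(self) -> None:
        if self.depth_avg <= 0 or self.avg_is <= 0 or self.read_length <= 0:
            raise ValueError("library statistics must be positive")
        if self.std_is < 0:
            raise ValueError("std_is must be non-negative")

    @property
    def discordant_threshold(self) -> float:
        """Insert size above which a pair is discordant (strict)."""
        return self.avg_is + DISCORDANT_SIGMA * self.std_is


@dataclass(frozen=True)
class DiscordantPair:
    """A same-chromosome pair with an abnormally large insert size."""

    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    insert_size: int


@dataclass(frozen=True)
class ClippedRead:
    """A read clipped >= 15 bp at exactly one end.

    ``clip_side`` is ``"tail"`` when the 3'-reference end of the aligned
    block meets the clip (evidence for a left breakpoint) and ``"head"``
    when the 5'-reference end does (evidence for a right breakpoint).
    ``mate_role`` records whether the clipped read is the first (leftmost,
    upstream) or second (rightmost, downstream) mate of its pair on the
    reference; downstream breakpoint refinement uses it to pick the
    applicable mate-consistency rule.  The role is positional, not the
    read1/read2 flag: a tail-clipped *second* mate is the 3' end of a
    concordant fragment lying left of the deletion (insert near the
    library mean, mate near the left boundary), while a tail-clipped
    *first* mate belongs to a fragment spanning the deletion (mate near
    the right boundary) — relationships that hold regardless of which
    physical read the sequencer labeled first.
    """

    chrom: str
    clip_side: str  # "tail" | "head"
    clip_position: int
    clip_length: int
    mate_role: str  # "first" | "second"
    mate_position: int
    insert_size: int


def is_usable_read(read: pysam.AlignedSegment, min_mapq: int = DEFAULT_MIN_MAPQ) -> bool:
    """Return False for unmapped, duplicate, non-primary or low-MAPQ reads."""
    return not (
        read.is_unmapped
        or read.is_duplicate
        or read.is_secondary
        or read.is_supplementary
        or read.mapping_quality < min_mapq
    )


def _open(source) -> pysam.AlignmentFile:
    if isinstance(source, pysam.AlignmentFile):
        return source
    return pysam.AlignmentFile(str(source))


def _iter_chrom(af: pysam.AlignmentFile, chrom: str) -> Iterator[pysam.AlignedSegment]:
    try:
        yield from af.fetch(chrom)
    except ValueError:
        # no index available (plain SAM): stream and filter
        af.reset()
        for read in af.fetch(until_eof=True):
            if read.reference_name == chrom:
                yield read


def compute_library_stats(
    source,
    chromosomes: Sequence[str] | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> LibraryStats:
    """Estimate :class:`LibraryStats` from an alignment file.

    Insert sizes come from usable, FR-oriented, same-chromosome pairs
    (leftmost mate only, so each pair counts once); the mean/SD are taken
    after trimming inserts outside ``median +/- 10 * MAD``, which keeps the
    estimate robust to the deletion-spanning tail.  Average depth is total
    aligned bases over total reference length of the processed
    chromosomes, so zero-depth positions count.  Multiple libraries/read
    groups are pooled into one global estimate.

    Raises
    ------
    ValueError
        If no usable pair yields an insert size ("cannot estimate insert
        size").
    """
    af = _open(source)
    if chromosomes is None:
        chromosomes = list(af.references)
    chrom_set = set(chromosomes)

    inserts: list[int] = []
    aligned_bases = 0
    length_counts: Counter[int] = Counter()

    def consume(read: pysam.AlignedSegment) -> None:
        nonlocal aligned_bases
        if not is_usable_read(read, min_mapq):
            return
        if read.reference_name not in chrom_set:
            return
        aligned_bases += read.reference_length or 0
        if read.query_length:
            length_counts[read.query_length] += 1
        if (
            read.is_paired
            and not read.mate_is_unmapped
            and read.reference_id == read.next_reference_id
            and read.template_length > 0
            and read.is_forward
            and read.mate_is_reverse
        ):
            inserts.append(read.template_length)

    try:
        for chrom in chromosomes:
            for read in _iter_chrom(af, chrom):
                consume(read)
    except ValueError:
        af.reset()
        for read in af.fetch(until_eof=True):
            consume(read)

    if not inserts:
        raise ValueError("cannot estimate insert size: no usable read pairs")

    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    kept = arr[np.abs(arr - med) <= MAD_DEVIATIONS * mad]
    if kept.size == 0:  # pathological: everything trimmed
        kept = arr
    avg_is = float(np.mean(kept))
    std_is = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0

    ref_length = sum(
        af.get_reference_length(c) for c in chromosomes if c in af.references
    )
    if ref_length == 0:
        raise ValueError("no reference sequence length available")
    depth_avg = aligned_bases / ref_length
    read_length = length_counts.most_common(1)[0][0] if length_counts else 0
    return LibraryStats(
        depth_avg=depth_avg, avg_is=avg_is, std_is=std_is, read_length=read_length
    )


def collect_discordant_pairs(
    source,
    stats: LibraryStats,
    chrom: str,
    max_span: int = DEFAULT_MAX_SPAN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[DiscordantPair]:
    """Collect deletion-supporting discordant pairs on one chromosome.

    A pair qualifies when both mates map to ``chrom`` in FR orientation
    and the template length is strictly greater than
    ``avg_is + 3 * std_is`` but no more than ``max_span`` (insert sizes
    beyond the submicroscopic ceiling cannot come from a callable
    deletion).  Each pair is recorded once, from its leftmost mate.
    """
    af = _open(source)
    threshold = stats.discordant_threshold
    out: list[DiscordantPair] = []
    for read in _iter_chrom(af, chrom):
        if not is_usable_read(read, min_mapq):
            continue
        if not read.is_paired or read.mate_is_unmapped:
            continue
        if read.reference_id != read.next_reference_id:
            continue  # interchromosomal: deletions never span chromosomes
        tlen = read.template_length
        if tlen <= 0:  # rightmost mate or degenerate record
            continue
        if not (read.is_forward and read.mate_is_reverse):
            continue
        if not (threshold < tlen <= max_span):
            continue
        left_start = read.reference_start
        left_end = read.reference_end
        right_start = read.next_reference_start
        right_end = left_start + tlen
        if left_end is None or not (left_start <= left_end < right_start <= right_end):
            continue
        out.append(
            DiscordantPair(
                chrom=chrom,
                left_start=left_start,
                left_end=left_end,
                right_start=right_start,
                right_end=right_end,
                insert_size=tlen,
            )
        )
    return out


def _end_clip_lengths(cigar: list[tuple[int, int]]) -> tuple[int, int]:
    """Total clipped bases (soft + hard) at the head and tail of a CIGAR."""
    head = 0
    for op, length in cigar:
        if op in (CIGAR_SOFT_CLIP, CIGAR_HARD_CLIP):
            head += length
        else:
            break
    tail = 0
    for op, length in reversed(cigar):
        if op in (CIGAR_SOFT_CLIP, CIGAR_HARD_CLIP):
            tail += length
        else:
            break
    return head, tail


def collect_clipped_reads(
    source,
    chrom: str,
    min_clip: int = MIN_CLIP_LENGTH,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[ClippedRead]:
    """Collect border-clipped reads (clip >= ``min_clip`` bp) on one chromosome.

    Reads clipped >= ``min_clip`` on *both* ends are ambiguous about which
    breakpoint they support and are excluded.  Hard clips count toward the
    clip length.
    """
    af = _open(source)
    out: list[ClippedRead] = []
    for read in _iter_chrom(af, chrom):
        if not is_usable_read(read, min_mapq):
            continue
        cigar = read.cigartuples
        if not cigar:
            continue
        head, tail = _end_clip_lengths(cigar)
        head_ok = head >= min_clip
        tail_ok = tail >= min_clip
        if head_ok == tail_ok:  # neither, or both (ambiguous side)
            continue
        if tail_ok:
            side, position, clip_len = "tail", read.reference_end, tail
        else:
            side, position, clip_len = "head", read.reference_start, head
        if read.is_paired and not read.mate_is_unmapped:
            mate_position = read.next_reference_start
            if read.template_length > 0:
                role = "first"
            elif read.template_length < 0:
                role = "second"
            else:
                role = "first" if read.reference_start <= mate_position else "second"
        else:
            mate_position, role = -1, "first"
        out.append(
            ClippedRead(
                chrom=chrom,
                clip_side=side,
                clip_position=position,
                clip_length=clip_len,
                mate_role=role,
                mate_position=mate_position,
                insert_size=abs(read.template_length),
            )
        )
    return out
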