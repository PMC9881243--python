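"""Candidate detection: grouping, merging and breakpoint refinement.

Discordant pairs on one chromosome are sorted by left-mate start and
chained into candidate sites whenever consecutive left mates start less
than one read length apart; singleton sites are dropped.  Overlapping
sites are merged transitively.  Border-clipped reads are then attached to
the site whose (insert-padded) span contains them, and sites without any
clip support are discarded.

Within a site the initial deletion breakpoints are the innermost edges of
the discordant evidence — left breakpoint (LBP) at the rightmost end of a
left mate, right breakpoint (RBP) at the leftmost start of a right mate —
and are subsequently refined to the clip boundaries supported by the most
tail-/head-clipped reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from delcall.ingest import ClippedRead, DiscordantPair, LibraryStats

logger = logging.getLogger(__name__)


@dataclass
class CandidateSite:
    """A group of >= 2 discordant pairs plus attached clipped reads.

    ``lb``/``rb`` span the full evidence: smallest left-mate start to
    largest right-mate end.
    """

    chrom: str
    lb: int
    rb: int
    pairs: list[DiscordantPair]
    tail_clips: list[ClippedRead] = field(default_factory=list)
    head_clips: list[ClippedRead] = field(default_factory=list)


@dataclass(frozen=True)
class DeletionCandidate:
    """A putative deletion: breakpoints plus the site it came from."""

    chrom: str
    lbp: int
    rbp: int
    site: CandidateSite

    @property
    def length(self) -> int:
        return self.rbp - self.lbp


def _site_from_pairs(chrom: str, pairs: list[DiscordantPair]) -> CandidateSite:
    return CandidateSite(
        chrom=chrom,
        lb=min(p.left_start for p in pairs),
        rb=max(p.right_end for p in pairs),
        pairs=list(pairs),
    )


def group_discordant_pairs(
    pairs: list[DiscordantPair], read_length: int
) -> list[CandidateSite]:
    """Chain pairs whose left mates start < ``read_length`` apart.

    Pairs are sorted by left-mate start; a strict start-to-start gap of at
    least ``read_length`` breaks the chain.  Groups supported by a single
    pair are dropped.
    """
    if not pairs:
        return []
    chrom = pairs[0].chrom
    ordered = sorted(pairs, key=lambda p: (p.left_start, p.right_end))
    sites: list[CandidateSite] = []
    group = [ordered[0]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.left_start - prev.left_start < read_length:
            group.append(cur)
        else:
            if len(group) >= 2:
                sites.append(_site_from_pairs(chrom, group))
            group = [cur]
    if len(group) >= 2:
        sites.append(_site_from_pairs(chrom, group))
    return sites


def merge_overlapping_sites(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Merge sites whose [lb, rb) spans overlap, transitively.

    Boundaries of a merged site are recomputed from the union of member
    pairs.  The result is sorted and pairwise non-overlapping.
    """
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: (s.lb, s.rb))
    merged: list[CandidateSite] = [ordered[0]]
    for site in ordered[1:]:
        cur = merged[-1]
        if site.lb < cur.rb:  # half-open overlap
            merged[-1] = _site_from_pairs(cur.chrom, cur.pairs + site.pairs)
        else:
            merged.append(site)
    return merged


def attach_clipped_reads(
    sites: list[CandidateSite],
    clips: list[ClippedRead],
    avg_is: float,
) -> list[CandidateSite]:
    """Assign clips to sites and drop sites without any clip support.

    A clip belongs to the site whose span, padded by ``avg_is`` on each
    flank, contains its clip position (a breakpoint-supporting read can
    map just outside the discordant span).  A clip inside several padded
    spans goes to the nearest unpadded span; exact ties go left.
    """
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: (s.lb, s.rb))
    for clip in clips:
        best = None
        best_dist = None
        for site in ordered:
            if site.lb - avg_is <= clip.clip_position <= site.rb + avg_is:
                if clip.clip_position < site.lb:
                    dist = site.lb - clip.clip_position
                elif clip.clip_position > site.rb:
                    dist = clip.clip_position - site.rb
                else:
                    dist = 0
                if best is None or dist < best_dist:
                    best, best_dist = site, dist
        if best is not None:
            (best.tail_clips if clip.clip_side == "tail" else best.head_clips).append(
                clip
            )
    return [s for s in ordered if s.tail_clips or s.head_clips]


def initial_breakpoints(site: CandidateSite) -> DeletionCandidate | None:
    """Innermost edges of the discordant evidence.

    LBP is the largest left-mate end, RBP the smallest right-mate start.
    Crossing mates (LBP >= RBP) make the site degenerate; it is discarded
    with a warning rather than repaired.
    """
    if len(site.pairs) < 2:
        raise ValueError("site must hold at least two discordant pairs")
    lbp = max(p.left_end for p in site.pairs)
    rbp = min(p.right_start for p in site.pairs)
    if lbp >= rbp:
        logger.warning(
            "discarding degenerate site %s:%d-%d (crossing mates, LBP %d >= RBP %d)",
            site.chrom, site.lb, site.rb, lbp, rbp,
        )
        return None
    return DeletionCandidate(chrom=site.chrom, lbp=lbp, rbp=rbp, site=site)


def _is_close(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol


def _qualifying_tail_clips(
    candidate: DeletionCandidate, site: CandidateSite, stats: LibraryStats
) -> list[ClippedRead]:
    """Tail clips eligible to refine the left breakpoint.

    Eligibility: within ``avg_is`` of the current LBP, inside [lb, rb],
    and mate-consistent.  A second-mate tail clip sits at the end of a
    fragment lying left of the deletion, so its insert should be near
    ``avg_is`` (within 3 SD) and its first mate near the left boundary; a
    first-mate tail clip belongs to a fragment spanning the deletion, so
    its second mate should land near the right boundary.
    """
    out = []
    for clip in site.tail_clips:
        if abs(clip.clip_position - candidate.lbp) >= stats.avg_is:
            continue
        if not (site.lb <= clip.clip_position <= site.rb):
            continue
        if clip.mate_role == "second":
            if not _is_close(clip.insert_size, stats.avg_is, 3 * stats.std_is):
                continue
            if not _is_close(clip.mate_position, site.lb, stats.avg_is):
                continue
        else:
            if not _is_close(clip.mate_position, site.rb, stats.avg_is):
                continue
        out.append(clip)
    return out


def _qualifying_head_clips(
    candidate: DeletionCandidate, site: CandidateSite, stats: LibraryStats
) -> list[ClippedRead]:
    """Head clips eligible to refine the right breakpoint (mirror rules)."""
    out = []
    for clip in site.head_clips:
        if abs(clip.clip_position - candidate.rbp) >= stats.avg_is:
            continue
        if not (site.lb <= clip.clip_position <= site.rb):
            continue
        if clip.mate_role == "second":
            if not _is_close(clip.mate_position, site.lb, stats.avg_is):
                continue
        else:
            if not _is_close(clip.insert_size, stats.avg_is, 3 * stats.std_is):
                continue
            if not _is_close(clip.mate_position, site.rb, stats.avg_is):
                continue
        out.append(clip)
    return out


def _best_positions(clips: list[ClippedRead]) -> tuple[list[int], int]:
    """Clip positions with maximal support, and that support count."""
    if not clips:
        return [], 0
    counts = Counter(c.clip_position for c in clips)
    top = max(counts.values())
    return [pos for pos, n in counts.items() if n == top], top


def refine_left_breakpoint(
    candidate: DeletionCandidate, site: CandidateSite, stats: LibraryStats
) -> int:
    """Refined LBP: largest best-supported qualifying tail-clip position.

    Positions supported by only one tail clip never move the breakpoint.
    """
    positions, support = _best_positions(
        _qualifying_tail_clips(candidate, site, stats)
    )
    if support >= 2:
        return max(positions)
    return candidate.lbp


def refine_right_breakpoint(
    candidate: DeletionCandidate, site: CandidateSite, stats: LibraryStats
) -> int:
    """Refined RBP: smallest best-supported qualifying head-clip position."""
    positions, support = _best_positions(
        _qualifying_head_clips(candidate, site, stats)
    )
    if support >= 2:
        return min(positions)
    return candidate.rbp


def refine_breakpoints(
    candidate: DeletionCandidate, stats: LibraryStats
) -> DeletionCandidate:
    """Apply both refinements; revert to the initial breakpoints if they cross."""
    site = candidate.site
    lbp = refine_left_breakpoint(candidate, site, stats)
    rbp = refine_right_breakpoint(candidate, site, stats)
    if lbp >= rbp:
        return candidate
    return replace(candidate, lbp=lbp, rbp=rbp)
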