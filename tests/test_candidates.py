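"""Grouping, merging, clip attachment and breakpoint refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delcall.candidates import (
    CandidateSite,
    DeletionCandidate,
    attach_clipped_reads,
    group_discordant_pairs,
    initial_breakpoints,
    merge_overlapping_sites,
    refine_breakpoints,
    refine_left_breakpoint,
    refine_right_breakpoint,
)
from delcall.ingest import ClippedRead, DiscordantPair, LibraryStats

STATS = LibraryStats(depth_avg=5.0, avg_is=400.0, std_is=50.0, read_length=101)


def pair(left_start, left_end=None, right_start=None, right_end=None):
    left_end = left_end if left_end is not None else left_start + 101
    right_start = right_start if right_start is not None else left_start + 900
    right_end = right_end if right_end is not None else right_start + 101
    return DiscordantPair(
        chrom="chr1",
        left_start=left_start,
        left_end=left_end,
        right_start=right_start,
        right_end=right_end,
        insert_size=right_end - left_start,
    )


def tail_clip(position, mate_role="second", mate_position=None, insert_size=400):
    return ClippedRead(
        chrom="chr1", clip_side="tail", clip_position=position, clip_length=30,
        mate_role=mate_role,
        mate_position=mate_position if mate_position is not None else position - 300,
        insert_size=insert_size,
    )


def head_clip(position, mate_role="second", mate_position=None, insert_size=400):
    return ClippedRead(
        chrom="chr1", clip_side="head", clip_position=position, clip_length=30,
        mate_role=mate_role,
        mate_position=mate_position if mate_position is not None else position - 1300,
        insert_size=insert_size,
    )


class TestGrouping:
    def test_nearby_left_mates_group_and_singletons_drop(self):
        pairs = [pair(1000), pair(1050), pair(1300)]
        sites = group_discordant_pairs(pairs, read_length=101)
        assert len(sites) == 1
        assert len(sites[0].pairs) == 2
        assert sites[0].lb == 1000

    def test_gap_equal_to_read_length_breaks_the_chain(self):
        assert group_discordant_pairs([pair(1000), pair(1101)], 101) == []

    def test_empty_input(self):
        assert group_discordant_pairs([], 101) == []

    def test_site_boundaries_span_all_member_pairs(self):
        pairs = [pair(1000, right_end=2500), pair(1050, right_end=2300)]
        (site,) = group_discordant_pairs(pairs, 101)
        assert site.lb == 1000
        assert site.rb == 2500

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        pairs = [pair(int(s)) for s in rng.integers(0, 5000, size=40)]
        ref = group_discordant_pairs(pairs, 101)
        for _ in range(5):
            rng.shuffle(pairs)
            again = group_discordant_pairs(pairs, 101)
            assert [(s.lb, s.rb, len(s.pairs)) for s in again] == [
                (s.lb, s.rb, len(s.pairs)) for s in ref
            ]


def brute_force_merge(spans):
    """O(n^2) pairwise interval merging to a fixed point."""
    spans = [list(s) for s in spans]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] < b[1] and b[0] < a[1]:
                    spans[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    spans.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(map(tuple, spans))


class TestMerging:
    def make_site(self, lb, rb):
        return CandidateSite(
            chrom="chr1", lb=lb, rb=rb,
            pairs=[pair(lb, lb + 101, rb - 101, rb), pair(lb, lb + 101, rb - 101, rb)],
        )

    def test_overlapping_sites_merge(self):
        merged = merge_overlapping_sites(
            [self.make_site(100, 500), self.make_site(400, 900)]
        )
        assert [(s.lb, s.rb) for s in merged] == [(100, 900)]

    def test_disjoint_sites_unchanged(self):
        merged = merge_overlapping_sites(
            [self.make_site(100, 300), self.make_site(301, 500)]
        )
        assert [(s.lb, s.rb) for s in merged] == [(100, 300), (301, 500)]

    def test_nested_site_absorbed(self):
        merged = merge_overlapping_sites(
            [self.make_site(100, 900), self.make_site(200, 300)]
        )
        assert [(s.lb, s.rb) for s in merged] == [(100, 900)]

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(50, 800)),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_brute_force_interval_algebra(self, raw):
        sites = [self.make_site(lb, lb + length) for lb, length in raw]
        merged = merge_overlapping_sites(sites)
        spans = [(s.lb, s.rb) for s in merged]
        assert spans == brute_force_merge((s.lb, s.rb) for s in sites)
        # member pairs conserved
        assert sum(len(s.pairs) for s in merged) == 2 * len(raw)
        # output pairwise non-overlapping and sorted
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestAttachClips:
    def make_site(self, lb, rb):
        return CandidateSite(
            chrom="chr1", lb=lb, rb=rb,
            pairs=[pair(lb, lb + 101, rb - 101, rb)] * 2,
        )

    def test_clip_inside_span_attached(self):
        site = self.make_site(1000, 3000)
        out = attach_clipped_reads([site], [tail_clip(1160)], avg_is=400)
        assert len(out) == 1
        assert out[0].tail_clips[0].clip_position == 1160

    def test_site_without_clips_removed(self):
        site = self.make_site(1000, 3000)
        assert attach_clipped_reads([site], [], avg_is=400) == []

    def test_equidistant_clip_goes_to_left_site(self):
        left = self.make_site(1000, 2000)
        right = self.make_site(2400, 3400)
        clip = tail_clip(2200)  # 200 bp from each unpadded span
        out = attach_clipped_reads([left, right], [clip], avg_is=400)
        assert len(out) == 1
        assert out[0].lb == 1000

    def test_clip_in_padded_flank_attached(self):
        site = self.make_site(1000, 3000)
        out = attach_clipped_reads([site], [head_clip(3300)], avg_is=400)
        assert len(out) == 1 and out[0].head_clips


class TestInitialBreakpoints:
    def test_innermost_edges(self):
        site = CandidateSite(
            chrom="chr1", lb=1000, rb=2201,
            pairs=[pair(1000, 1101, 2000, 2101), pair(1050, 1151, 2100, 2201)],
        )
        candidate = initial_breakpoints(site)
        assert (candidate.lbp, candidate.rbp) == (1151, 2000)

    def test_crossing_mates_discard_site(self):
        site = CandidateSite(
            chrom="chr1", lb=1000, rb=2300,
            pairs=[pair(1000, 2050, 2100, 2201), pair(1900, 2050, 2000, 2300)],
        )
        assert initial_breakpoints(site) is None

    def test_single_pair_site_rejected(self):
        site = CandidateSite(chrom="chr1", lb=1000, rb=2101, pairs=[pair(1000)])
        with pytest.raises(ValueError):
            initial_breakpoints(site)


def refinement_site(tail_positions=(), head_positions=(), lb=1000, rb=2600):
    """A two-pair site with given clip positions, all mate-consistent."""
    site = CandidateSite(
        chrom="chr1", lb=lb, rb=rb,
        pairs=[pair(lb, lb + 101, rb - 101, rb), pair(lb + 50, lb + 151, rb - 51, rb + 50)],
    )
    site.tail_clips = [tail_clip(p, mate_position=lb + 10) for p in tail_positions]
    site.head_clips = [head_clip(p, mate_position=lb + 10) for p in head_positions]
    return site


class TestRefinement:
    def candidate(self, site, lbp=1200, rbp=2000):
        return DeletionCandidate(chrom="chr1", lbp=lbp, rbp=rbp, site=site)

    def test_best_supported_position_wins(self):
        site = refinement_site(tail_positions=[1160, 1160, 1160, 1140])
        assert refine_left_breakpoint(self.candidate(site), site, STATS) == 1160

    def test_support_tie_takes_largest_position(self):
        site = refinement_site(tail_positions=[1160, 1160, 1170, 1170])
        assert refine_left_breakpoint(self.candidate(site), site, STATS) == 1170

    def test_singleton_support_never_updates(self):
        site = refinement_site(tail_positions=[1160, 1140, 1180])
        assert refine_left_breakpoint(self.candidate(site), site, STATS) == 1200

    def test_right_breakpoint_best_supported(self):
        site = refinement_site(head_positions=[1990, 1990, 1990, 2010])
        assert refine_right_breakpoint(self.candidate(site), site, STATS) == 1990

    def test_right_tie_takes_smallest_position(self):
        site = refinement_site(head_positions=[1990, 1990, 1970, 1970])
        assert refine_right_breakpoint(self.candidate(site), site, STATS) == 1970

    def test_right_singleton_support_never_updates(self):
        site = refinement_site(head_positions=[1990, 1970])
        assert refine_right_breakpoint(self.candidate(site), site, STATS) == 2000

    def test_far_clips_do_not_qualify(self):
        # clip 500 bp from the breakpoint exceeds the avg_is window
        site = refinement_site(tail_positions=[1700, 1700])
        assert refine_left_breakpoint(self.candidate(site), site, STATS) == 1200

    def test_mate_inconsistent_clips_do_not_qualify(self):
        site = refinement_site()
        site.tail_clips = [
            tail_clip(1160, mate_role="second", insert_size=900,
                      mate_position=1010)
            for _ in range(3)
        ]  # second-mate tail clip must have a near-normal insert
        assert refine_left_breakpoint(self.candidate(site), site, STATS) == 1200

    def test_crossing_refinement_reverts_to_initial(self):
        # each refinement is individually legal but together they cross
        site = refinement_site(
            tail_positions=[2100, 2100], head_positions=[1700, 1700],
        )
        candidate = self.candidate(site, lbp=1800, rbp=2000)
        assert refine_left_breakpoint(candidate, site, STATS) == 2100
        assert refine_right_breakpoint(candidate, site, STATS) == 1700
        refined = refine_breakpoints(candidate, STATS)
        assert (refined.lbp, refined.rbp) == (1800, 2000)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_refinement_stays_within_site_and_ordered(self, data):
        lb, rb = 1000, 2600
        tails = data.draw(
            st.lists(st.integers(lb - 500, rb + 500), max_size=8)
        )
        heads = data.draw(
            st.lists(st.integers(lb - 500, rb + 500), max_size=8)
        )
        site = refinement_site(tail_positions=tails, head_positions=heads)
        refined = refine_breakpoints(self.candidate(site), STATS)
        assert lb <= refined.lbp < refined.rbp <= rb
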