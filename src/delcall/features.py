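"""Depth filtering and coverage-band featurization of candidates.

Each candidate's interior [LBP, RBP) is piled up into a per-base depth
profile.  Candidates whose mean interior depth exceeds the genome average
are discarded outright — a deletion must lose coverage.  The survivors
are summarised by four coverage bands relative to the genome-average
depth d:

====  =============================  =======================================
band  depth range                    interpretation
====  =============================  =======================================
T0    exactly 0                      perfect homozygous deletion
T1    (0, ceil(0.25 d))              homozygous, tolerating mapping noise
T2    [ceil(0.25 d), ceil(0.5 d)]    hemizygous (one allele lost, half depth)
T3    (ceil(0.5 d), ceil(d)]         mixture of true and false candidates
====  =============================  =======================================

Positions deeper than ceil(d) belong to no band.  The feature vector of a
candidate is LN_i = L_i / (RBP - LBP), the fraction of its length falling
in each band (L_i need not be contiguous); the per-band mean depths D_i
are carried along for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pysam

from delcall.ingest import DEFAULT_MIN_MAPQ, LibraryStats, _open, is_usable_read


@dataclass(frozen=True)
class CoverageBands:
    """Band edges derived from the genome-average depth."""

    depth_avg: float
    b1: int
    b2: int
    b3: int

    @classmethod
    def from_depth(cls, depth_avg: float) -> "CoverageBands":
        if depth_avg <= 0:
            raise ValueError("depth_avg must be positive")
        return cls(
            depth_avg=depth_avg,
            b1=math.ceil(depth_avg * 0.25),
            b2=math.ceil(depth_avg * 0.5),
            b3=math.ceil(depth_avg),
        )


@dataclass(frozen=True)
class FeatureVector:
    """Band lengths, band mean depths and normalized lengths (i = 0..3)."""

    L: tuple[int, int, int, int]
    D: tuple[float, float, float, float]
    LN: tuple[float, float, float, float]


def candidate_depth_profile(
    source,
    chrom: str,
    lbp: int,
    rbp: int,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> np.ndarray:
    """Per-base depth over [lbp, rbp) from usable reads (aligned blocks only)."""
    if rbp <= lbp:
        raise ValueError("zero-length candidate region")
    af = _open(source)
    profile = np.zeros(rbp - lbp, dtype=np.int64)
    for read in af.fetch(chrom, lbp, rbp):
        if not is_usable_read(read, min_mapq):
            continue
        for block_start, block_end in read.get_blocks():
            lo = max(block_start, lbp) - lbp
            hi = min(block_end, rbp) - lbp
            if hi > lo:
                profile[lo:hi] += 1
    return profile


def depth_filter(profile: np.ndarray, stats: LibraryStats) -> bool:
    """True (keep) unless the mean interior depth strictly exceeds the average."""
    return float(np.mean(profile)) <= stats.depth_avg


def classify_coverage(depth: int, bands: CoverageBands) -> int | None:
    """Band index for one depth value, or None above the top band.

    Depth 0 is always T0 (the band bounds written as half-open from 0
    would otherwise let T1 claim it, but zero depth is the perfect
    homozygous signal and takes precedence).
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if depth == 0:
        return 0
    if depth < bands.b1:
        return 1
    if depth <= bands.b2:
        return 2
    if depth <= bands.b3:
        return 3
    return None


def extract_features(profile: np.ndarray, bands: CoverageBands) -> FeatureVector:
    """Band lengths/mean depths and length-normalized fractions for one profile."""
    profile = np.asarray(profile)
    n = profile.size
    masks = (
        profile == 0,
        (profile > 0) & (profile < bands.b1),
        (profile >= bands.b1) & (profile <= bands.b2),
        (profile > bands.b2) & (profile <= bands.b3),
    )
    L = tuple(int(m.sum()) for m in masks)
    D = tuple(float(profile[m].mean()) if m.any() else 0.0 for m in masks)
    LN = tuple(length / n for length in L)
    return FeatureVector(L=L, D=D, LN=LN)
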