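"""Per-chromosome pipeline orchestration and standard-format output.

The pipeline runs, for each chromosome: evidence collection (discordant
pairs + clipped reads) -> candidate-site grouping/merging -> breakpoint
refinement -> depth filter + band featurization -> PCA/Ward clustering
with per-cluster statistical filtering.  Library statistics are computed
once, genome-wide, before any chromosome is processed.  A structured
report records per-stage counts so that every initial candidate is
accounted for (called or discarded at a named stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from delcall import candidates as cand
from delcall import clustering, features, ingest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and switches for one pipeline run.

    Defaults follow the method's stated values: 15 bp minimum clip,
    3-sigma insert-size discordance, 3 Mb maximum deletion span, four
    clusters, and the 0.7 deletion-band mass defining a good cluster.
    The mapping-quality floor of 20 is the conventional q-filter.
    """

    clip_min: int = ingest.MIN_CLIP_LENGTH
    discordant_sigma: float = ingest.DISCORDANT_SIGMA
    max_span: int = ingest.DEFAULT_MAX_SPAN
    mapq_min: int = ingest.DEFAULT_MIN_MAPQ
    k_clusters: int = clustering.DEFAULT_K
    good_threshold: float = clustering.GOOD_THRESHOLD
    tolerance: int = 15
    chromosomes: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("clip_min", "discordant_sigma", "max_span", "mapq_min",
                     "k_clusters", "good_threshold", "tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ChromReport:
    """Stage accounting for one chromosome."""

    n_discordant_pairs: int = 0
    n_clipped_reads: int = 0
    n_sites: int = 0
    n_sites_merged: int = 0
    n_sites_with_clips: int = 0
    n_candidates: int = 0
    n_degenerate: int = 0
    n_removed_depth: int = 0
    n_removed_cluster: int = 0
    n_called: int = 0

    def consistent(self) -> bool:
        return self.n_candidates == (
            self.n_called + self.n_removed_depth + self.n_removed_cluster
        )


@dataclass
class CallSet:
    """Final calls plus diagnostics from one run."""

    calls: list[cand.DeletionCandidate]
    stats: ingest.LibraryStats
    report: dict[str, ChromReport] = field(default_factory=dict)


def detect_candidates(
    af: pysam.AlignmentFile,
    stats: ingest.LibraryStats,
    chrom: str,
    config: RunConfig,
    report: ChromReport,
) -> list[cand.DeletionCandidate]:
    """Evidence collection through refined breakpoints for one chromosome."""
    pairs = ingest.collect_discordant_pairs(
        af, stats, chrom, max_span=config.max_span, min_mapq=config.mapq_min
    )
    clips = ingest.collect_clipped_reads(
        af, chrom, min_clip=config.clip_min, min_mapq=config.mapq_min
    )
    report.n_discordant_pairs = len(pairs)
    report.n_clipped_reads = len(clips)
    sites = cand.group_discordant_pairs(pairs, stats.read_length)
    report.n_sites = len(sites)
    sites = cand.merge_overlapping_sites(sites)
    report.n_sites_merged = len(sites)
    sites = cand.attach_clipped_reads(sites, clips, stats.avg_is)
    report.n_sites_with_clips = len(sites)
    out = []
    for site in sites:
        candidate = cand.initial_breakpoints(site)
        if candidate is None:
            report.n_degenerate += 1
            continue
        out.append(cand.refine_breakpoints(candidate, stats))
    report.n_candidates = len(out)
    return out


def call_chromosome(
    af: pysam.AlignmentFile,
    stats: ingest.LibraryStats,
    chrom: str,
    config: RunConfig,
) -> tuple[list[cand.DeletionCandidate], ChromReport]:
    """Full pipeline for one chromosome: candidates -> features -> calls."""
    report = ChromReport()
    detected = detect_candidates(af, stats, chrom, config, report)

    bands = features.CoverageBands.from_depth(stats.depth_avg)
    surviving = []
    ln_rows = []
    for candidate in detected:
        profile = features.candidate_depth_profile(
            af, chrom, candidate.lbp, candidate.rbp, min_mapq=config.mapq_min
        )
        if not features.depth_filter(profile, stats):
            report.n_removed_depth += 1
            continue
        fv = features.extract_features(profile, bands)
        surviving.append(candidate)
        ln_rows.append(fv.LN)

    if not surviving:
        report.n_called = 0
        return [], report

    keep, _ = clustering.call_from_features(
        np.asarray(ln_rows), k=config.k_clusters
    )
    calls = [c for c, k in zip(surviving, keep) if k]
    report.n_removed_cluster = len(surviving) - len(calls)
    report.n_called = len(calls)
    return calls, report


def run_pipeline(bam_path, config: RunConfig | None = None) -> CallSet:
    """Run the caller over a coordinate-sorted, indexed BAM/SAM."""
    config = config or RunConfig()
    af = pysam.AlignmentFile(str(bam_path))
    chroms = config.chromosomes or list(af.references)
    present = [c for c in chroms if c in af.references]
    for missing in set(chroms) - set(present):
        logger.warning("chromosome %s absent from alignment file; skipped", missing)
    stats = ingest.compute_library_stats(af, present, min_mapq=config.mapq_min)
    logger.info(
        "library: depth_avg=%.2f avg_is=%.1f std_is=%.1f read_length=%d",
        stats.depth_avg, stats.avg_is, stats.std_is, stats.read_length,
    )
    all_calls: list[cand.DeletionCandidate] = []
    report: dict[str, ChromReport] = {}
    for chrom in present:
        calls, chrom_report = call_chromosome(af, stats, chrom, config)
        logger.info(
            "%s: %d candidates -> %d called (%d depth-filtered, %d cluster-filtered)",
            chrom, chrom_report.n_candidates, chrom_report.n_called,
            chrom_report.n_removed_depth, chrom_report.n_removed_cluster,
        )
        all_calls.extend(calls)
        report[chrom] = chrom_report
    all_calls.sort(key=lambda c: (c.chrom, c.lbp, c.rbp))
    return CallSet(calls=all_calls, stats=stats, report=report)


_VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    "##source=delcall",
    '##ALT=<ID=DEL,Description="Deletion">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting discordant read pairs">',
)


def write_calls(
    calls,
    path,
    fmt: str = "vcf",
    contigs: dict[str, int] | None = None,
) -> Path:
    """Write calls as VCF 4.2 (symbolic <DEL> alleles) or BED.

    Internal coordinates are 0-based half-open; VCF POS is the 1-based
    first deleted base and END the 1-based last deleted base, so a call
    at [999, 1999) becomes POS=1000, END=1999, SVLEN=-1000.
    """
    path = Path(path)
    ordered = sorted(calls, key=lambda c: (c.chrom, c.lbp, c.rbp))
    if fmt == "bed":
        with open(path, "w") as fh:
            for c in ordered:
                support = len(c.site.pairs) if c.site is not None else 0
                fh.write(f"{c.chrom}\t{c.lbp}\t{c.rbp}\t{support}\n")
        return path
    if fmt != "vcf":
        raise ValueError(f"unknown output format {fmt!r}")
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(ordered):
            pos = c.lbp + 1  # 0-based deletion start -> 1-based first deleted base
            end = c.rbp  # 0-based half-open end -> 1-based last deleted base
            svlen = -(c.rbp - c.lbp)
            support = len(c.site.pairs) if c.site is not None else 0
            info = f"SVTYPE=DEL;END={end};SVLEN={svlen};SUPPORT={support}"
            fh.write(
                f"{c.chrom}\t{pos}\tDEL{i + 1}\tN\t<DEL>\t.\tPASS\t{info}\n"
            )
    return path
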