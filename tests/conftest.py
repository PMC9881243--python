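"""Shared fixtures: hand-built alignment files and a simulated sample."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from delcall.cli import simulate_random_deletions
from delcall.simulate import simulate_diploid_sample, to_indexed_bam

# SAM flag shorthand for an FR proper pair
FLAG_LEFT = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate-reverse, read1
FLAG_RIGHT = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, read2


def make_bam(
    path: Path,
    records: list[dict],
    ref_length: int = 100_000,
    chrom: str = "chr1",
) -> Path:
    """Write an indexed BAM from minimal record dicts.

    Each record needs ``pos`` and ``cigar``; ``flag``, ``mapq``, ``pnext``
    and ``tlen`` default to a mapped, high-quality leftmost mate.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": ref_length}]}
    sam_path = Path(path).with_suffix(".sam")
    ordered = sorted(enumerate(records), key=lambda ir: ir[1]["pos"])
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for i, rec in ordered:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.get("name", f"r{i}")
            a.flag = rec.get("flag", FLAG_LEFT)
            a.reference_id = 0
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec["cigar"]
            a.next_reference_id = 0 if rec.get("pnext", -1) >= 0 else -1
            a.next_reference_start = rec.get("pnext", -1)
            a.template_length = rec.get("tlen", 0)
            qlen = a.infer_query_length() or 0
            if qlen:
                a.query_sequence = "A" * qlen
                a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            sam.write(a)
    bam_path = Path(path)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


def proper_pair(pos: int, tlen: int, read_length: int = 101) -> list[dict]:
    """Two records forming an FR pair with outer span ``tlen``."""
    mate_pos = pos + tlen - read_length
    return [
        {"pos": pos, "cigar": f"{read_length}M", "flag": FLAG_LEFT,
         "pnext": mate_pos, "tlen": tlen},
        {"pos": mate_pos, "cigar": f"{read_length}M", "flag": FLAG_RIGHT,
         "pnext": pos, "tlen": -tlen},
    ]


@pytest.fixture(scope="session")
def sim_sample(tmp_path_factory):
    """A small simulated diploid sample with eight planted deletions."""
    out = tmp_path_factory.mktemp("sim")
    deletions = simulate_random_deletions(
        800_000, 8, 500, 8_000, seed=11, margin=1500
    )
    sample = simulate_diploid_sample(
        800_000, deletions, out, coverage=6.0, seed=11
    )
    bam = to_indexed_bam(sample.sam)
    return sample, bam
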