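"""Per-transcript RPKM from alignments or count tables, plus summary
statistics, fold-vs-mean and the sequencing-depth estimate.

RPKM = 1e9 * C / (N_total * L) where C is the mapped-read count for the
transcript, L its length in bp and N_total the total mapped reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import pysam


@dataclass(frozen=True)
class RpkmRecord:
    transcript_id: str
    count: int
    length: int
    n_total: int
    rpkm: float


@dataclass(frozen=True)
class DepthEstimate:
    total_read_bases: float
    genome_size: float
    transcriptome_fraction: float
    depth: float


def rpkm_value(count: int, length: int, n_total: int) -> float:
    if length <= 0:
        raise ValueError("transcript length must be positive")
    if n_total <= 0:
        raise ValueError("N_total must be positive")
    return 1e9 * count / (n_total * length)


def rpkm_from_counts(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    n_total: Optional[int] = None,
) -> List[RpkmRecord]:
    """RPKM records for every transcript in ``lengths``.

    Zero-count transcripts are retained with RPKM 0 so downstream
    category aggregation denominators are stable.  ``n_total`` defaults
    to the sum of the counts (every read mapped primarily and uniquely).
    """
    for tid in counts:
        if tid not in lengths:
            raise KeyError(f"no length for counted transcript {tid!r}")
    if n_total is None:
        n_total = sum(counts.values())
    if n_total <= 0:
        raise ValueError("N_total must be positive")
    records = []
    for tid in lengths:
        c = counts.get(tid, 0)
        records.append(
            RpkmRecord(tid, c, lengths[tid], n_total, rpkm_value(c, lengths[tid], n_total))
        )
    return records


def counts_from_sam(sam_path, lengths: Mapping[str, int]) -> Dict[str, int]:
    """Primary mapped-read counts per transcript from a SAM file.

    Unmapped (0x4), secondary (0x100) and supplementary (0x800) records
    are excluded.  Every reference in the SAM header must be present in
    ``lengths``.
    """
    counts: Dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in lengths:
                raise KeyError(
                    f"transcript {ref!r} in SAM header absent from FASTA/lengths"
                )
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            ref = read.reference_name
            if ref not in lengths:
                raise KeyError(
                    f"transcript {ref!r} in SAM absent from FASTA/lengths"
                )
            counts[ref] = counts.get(ref, 0) + 1
    return counts


def rpkm_from_sam(
    sam_path, lengths: Mapping[str, int], n_total: Optional[int] = None
) -> List[RpkmRecord]:
    """RPKM from SAM alignments; equals rpkm_from_counts on the induced
    count table."""
    counts = counts_from_sam(sam_path, lengths)
    return rpkm_from_counts(counts, lengths, n_total=n_total)


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimal places."""
    return math.floor(x * 100.0) / 100.0


def summarize_rpkm(records: Iterable[RpkmRecord]) -> Dict[str, float]:
    """Sum, mean (also truncated to 2 dp), max and nonzero dynamic range."""
    rpkms = [r.rpkm for r in records]
    if not rpkms:
        raise ValueError("no RPKM records to summarize")
    total = sum(rpkms)
    nonzero = [v for v in rpkms if v > 0]
    return {
        "n": len(rpkms),
        "rpkm_sum": total,
        "rpkm_mean": total / len(rpkms),
        "rpkm_mean_2dp": truncate2(total / len(rpkms)),
        "rpkm_max": max(rpkms),
        "dynamic_range": (max(nonzero) / min(nonzero)) if nonzero else 0.0,
    }


def fold_vs_mean(rpkm: float, mean_rpkm: float) -> int:
    """Integer fold change relative to the mean, floored."""
    if mean_rpkm <= 0:
        raise ValueError("mean RPKM must be positive")
    return math.floor(rpkm / mean_rpkm)


def estimate_depth(
    total_read_bases: float, genome_size: float, fraction: float
) -> DepthEstimate:
    """Sequencing depth = total read bases / (genome size * transcriptome
    fraction)."""
    if total_read_bases <= 0 or genome_size <= 0:
        raise ValueError("total_read_bases and genome_size must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("transcriptome fraction must be in (0, 1]")
    return DepthEstimate(
        total_read_bases,
        genome_size,
        fraction,
        total_read_bases / (genome_size * fraction),
    )
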