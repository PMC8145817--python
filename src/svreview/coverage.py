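"""Per-base, MAPQ-stratified depth and the depth fold-change (DHFFC) metric.

The coverage track backs two consumers: the gray background of review
images (dark = reads at or above the MAPQ threshold, light = below) and
deletion filtering via the fold change between a called region's mean
depth and its flanks' — a value well below 1 supports a copy loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence import AlignedRead

#: flank width (bp) on each side of an SV interval used for the fold-change
#: denominator; truncated at sequence ends.
DEFAULT_FLANK = 1000

#: windows longer than this are binned for display (mean pooling) down to
#: at most MAX_BINS bins; per-base resolution is kept below it.
PER_BASE_LIMIT = 100_000
MAX_BINS = 10_000


@dataclass
class CoverageTrack:
    chrom: str
    start: int
    end: int
    depth_high: np.ndarray
    depth_low: np.ndarray
    mapq_threshold: int

    def __post_init__(self) -> None:
        n = self.end - self.start
        assert len(self.depth_high) == len(self.depth_low) == n

    @property
    def total(self) -> np.ndarray:
        return self.depth_high + self.depth_low

    def mean_total(self) -> float:
        return float(self.total.mean()) if len(self.total) else 0.0

    def binned(self, max_bins: int = MAX_BINS) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(bin start positions, high, low) mean-pooled to <= max_bins bins."""
        n = self.end - self.start
        if n <= max(max_bins, 0) or n <= PER_BASE_LIMIT:
            pos = np.arange(self.start, self.end)
            return pos, self.depth_high.astype(float), self.depth_low.astype(float)
        width = int(np.ceil(n / max_bins))
        nbins = int(np.ceil(n / width))
        pad = nbins * width - n
        hi = np.pad(self.depth_high.astype(float), (0, pad), constant_values=np.nan)
        lo = np.pad(self.depth_low.astype(float), (0, pad), constant_values=np.nan)
        hi = np.nanmean(hi.reshape(nbins, width), axis=1)
        lo = np.nanmean(lo.reshape(nbins, width), axis=1)
        pos = self.start + np.arange(nbins) * width
        return pos, hi, lo


@dataclass(frozen=True)
class FoldChange:
    """Region mean depth divided by flank mean depth; ``value`` is None when
    the flanks carry no coverage (uncallable), never infinity."""

    value: float | None

    @property
    def uncallable(self) -> bool:
        return self.value is None


def compute_coverage(
    reads: list[AlignedRead], chrom: str, start: int, end: int, mapq_threshold: int = 10
) -> CoverageTrack:
    """Pile up aligned reference bases of every segment into two MAPQ strata.

    Deletion/skip CIGAR gaps and clipped bases do not contribute (segments
    carry their reference-consuming blocks).  Each aligned base increments
    exactly one stratum, decided by its segment's MAPQ.
    """
    if end <= start:
        raise ValueError(f"empty window {chrom}:{start}-{end}")
    n = end - start
    high = np.zeros(n, dtype=np.int64)
    low = np.zeros(n, dtype=np.int64)
    for read in reads:
        for seg in read.segments:
            if seg.chrom != chrom:
                continue
            target = high if seg.mapq >= mapq_threshold else low
            for bstart, bend in seg.aligned_blocks():
                lo = max(bstart, start) - start
                hi = min(bend, end) - start
                if lo < hi:
                    target[lo:hi] += 1
    return CoverageTrack(chrom, start, end, high, low, mapq_threshold)


def depth_fold_change(track_region: CoverageTrack, track_flanks: CoverageTrack | list[CoverageTrack]) -> FoldChange:
    """Mean total depth inside the SV interval over mean total depth of the
    flanks.  Zero flank depth yields an uncallable marker."""
    flanks = track_flanks if isinstance(track_flanks, list) else [track_flanks]
    flank_bases = np.concatenate([t.total for t in flanks]) if flanks else np.array([])
    if len(flank_bases) == 0 or flank_bases.mean() == 0:
        return FoldChange(value=None)
    return FoldChange(value=track_region.mean_total() / float(flank_bases.mean()))


def fold_change_for_interval(
    bam_path: str,
    chrom: str,
    start: int,
    end: int,
    flank: int = DEFAULT_FLANK,
    mapq_threshold: int = 10,
    reference: str | None = None,
) -> FoldChange:
    """Convenience DHFFC-style metric straight from an alignment file.

    ``[start, end)`` is 0-based half-open; flanks are ``flank`` bp on each
    side, truncated at the sequence ends.
    """
    import pysam

    from .evidence import InsertStats, load_alignments

    kwargs = {"reference_filename": reference} if reference else {}
    with pysam.AlignmentFile(bam_path, **kwargs) as afile:
        seq_len = afile.get_reference_length(chrom)
    lo = max(0, start - flank)
    hi = min(seq_len, end + flank)
    # one load spanning region + flanks; categories are irrelevant to depth,
    # so skip insert-stats estimation with an infinite limit
    reads = load_alignments(
        bam_path, chrom, lo, hi, min_mapq=0,
        insert_stats=InsertStats(0.0, 0.0, float("inf")),
        reference=reference,
    )
    region = compute_coverage(reads, chrom, start, end, mapq_threshold)
    flanks = []
    if lo < start:
        flanks.append(compute_coverage(reads, chrom, lo, start, mapq_threshold))
    if end < hi:
        flanks.append(compute_coverage(reads, chrom, end, hi, mapq_threshold))
    return depth_fold_change(region, flanks)
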