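"""Alignment evidence extraction and classification.

Loads reads overlapping a plot window from an indexed BAM/CRAM and assigns
each read exactly one :class:`EvidenceCategory`: concordant, support for a
deletion / duplication / inversion / translocation, or low-confidence
(mapping quality below the user threshold).  Two signal sources are used:

* **pair configuration** — orientation, order, chromosome and template
  length of a read pair relative to the library's concordant expectation;
* **split configuration** — reference placement of the query-adjacent
  segments of a single read (primary + supplementary alignments).

Low-MAPQ reads are retained, not dropped: they feed the low-quality
coverage stratum and are rendered de-emphasized.
"""

from __future__ import annotations

import logging
import os
import re
import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pysam

log = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

#: minimum reference gap (bp) between split segments before the gap is
#: treated as deletion evidence rather than an indel-scale artifact.
#: SVs are conventionally defined as >= 50 bp; half of that is used as a
#: conservative floor.
MIN_SPLIT_DEL_GAP = 25

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class Kind(str, Enum):
    CONCORDANT = "CONCORDANT"
    DEL_SUPPORT = "DEL_SUPPORT"
    DUP_SUPPORT = "DUP_SUPPORT"
    INV_SUPPORT = "INV_SUPPORT"
    TRA_SUPPORT = "TRA_SUPPORT"
    LOW_CONFIDENCE = "LOW_CONFIDENCE"


class Source(str, Enum):
    PAIR = "PAIR"
    SPLIT = "SPLIT"
    LONG_READ = "LONG_READ"


@dataclass(frozen=True)
class EvidenceCategory:
    kind: Kind
    source: Source

    @property
    def is_sv_support(self) -> bool:
        return self.kind not in (Kind.CONCORDANT, Kind.LOW_CONFIDENCE)


@dataclass
class AlignmentSegment:
    """One aligned segment: 0-based half-open reference span plus the
    span of the read (query) it accounts for, in original read orientation."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    query_start: int = 0
    query_end: int = 0
    #: reference-consuming aligned blocks (gaps from D/N CIGAR ops excluded);
    #: defaults to the full [start, end) span
    blocks: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")

    def aligned_blocks(self) -> list[tuple[int, int]]:
        return self.blocks if self.blocks is not None else [(self.start, self.end)]


@dataclass
class AlignedRead:
    name: str
    segments: list[AlignmentSegment]
    is_paired: bool = False
    mate: AlignmentSegment | None = None
    is_first_in_template: bool = True
    template_length: int = 0
    haplotype: int | None = None
    molecule: str | None = None
    category: EvidenceCategory = field(
        default_factory=lambda: EvidenceCategory(Kind.CONCORDANT, Source.PAIR)
    )

    @property
    def start(self) -> int:
        return min(s.start for s in self.segments)

    @property
    def end(self) -> int:
        return max(s.end for s in self.segments)


@dataclass(frozen=True)
class InsertStats:
    """Template-length distribution of concordantly oriented pairs.

    ``concordance_limit = mean + z * sd``; pairs beyond it are treated as
    insert-size discordant (deletion pattern)."""

    mean: float
    sd: float
    concordance_limit: float


def estimate_insert_stats(template_lengths: Sequence[float], z: float = 3.0) -> InsertStats:
    """Estimate InsertStats from observed FR-pair template lengths.

    Uses the sample standard deviation (n-1 denominator).  Raises
    ``ValueError`` when fewer than two observations are available, in which
    case the caller should supply an explicit concordance limit.
    """
    lengths = [abs(t) for t in template_lengths]
    if len(lengths) < 2:
        raise ValueError(
            "need >= 2 concordant pairs to estimate insert stats; "
            "supply an explicit concordance_limit instead"
        )
    mean = statistics.fmean(lengths)
    sd = statistics.stdev(lengths)
    return InsertStats(mean=mean, sd=sd, concordance_limit=mean + z * sd)


def classify_pair(
    read_strand: str,
    mate_strand: str,
    read_is_leftmost: bool,
    same_chrom: bool,
    template_length: float,
    stats: InsertStats,
) -> EvidenceCategory:
    """Classify a read pair from its orientation/order/insert configuration.

    Rules (leftmost mate = smaller reference start):

    * different chromosomes -> translocation support
    * same strand -> inversion support
    * reverse-then-forward order -> duplication support (tandem junction)
    * forward-then-reverse with template length beyond the concordance
      limit -> deletion support; within the limit -> concordant
    """
    if not same_chrom:
        return EvidenceCategory(Kind.TRA_SUPPORT, Source.PAIR)
    if read_strand == mate_strand:
        return EvidenceCategory(Kind.INV_SUPPORT, Source.PAIR)
    left_strand = read_strand if read_is_leftmost else mate_strand
    if left_strand == REVERSE:  # RF: reverse leftmost, forward rightmost
        return EvidenceCategory(Kind.DUP_SUPPORT, Source.PAIR)
    if abs(template_length) > stats.concordance_limit:
        return EvidenceCategory(Kind.DEL_SUPPORT, Source.PAIR)
    return EvidenceCategory(Kind.CONCORDANT, Source.PAIR)


def classify_split(
    seg_a: AlignmentSegment, seg_b: AlignmentSegment, min_del_gap: int = MIN_SPLIT_DEL_GAP
) -> EvidenceCategory:
    """Classify two query-adjacent segments of one split read.

    ``seg_a`` must precede ``seg_b`` in query coordinates.  A reference gap
    (in the direction of travel) signals a deletion; overlap or reversed
    reference order signals a duplication; a strand switch an inversion;
    a chromosome switch a translocation.
    """
    if (
        seg_a.chrom == seg_b.chrom
        and seg_a.start == seg_b.start
        and seg_a.end == seg_b.end
        and seg_a.strand == seg_b.strand
    ):
        raise ValueError("identical split segments (malformed supplementary record)")
    if seg_a.chrom != seg_b.chrom:
        return EvidenceCategory(Kind.TRA_SUPPORT, Source.SPLIT)
    if seg_a.strand != seg_b.strand:
        return EvidenceCategory(Kind.INV_SUPPORT, Source.SPLIT)
    # On the reverse strand, increasing query position walks the reference
    # right-to-left: swap roles so "gap ahead" means the same thing.
    first, second = (seg_a, seg_b) if seg_a.strand == FORWARD else (seg_b, seg_a)
    gap = second.start - first.end
    if gap >= min_del_gap:
        return EvidenceCategory(Kind.DEL_SUPPORT, Source.SPLIT)
    if gap >= 0:
        return EvidenceCategory(Kind.CONCORDANT, Source.SPLIT)
    return EvidenceCategory(Kind.DUP_SUPPORT, Source.SPLIT)


def _cigar_spans(cigar: str) -> tuple[int, int, int, int]:
    """Return (read_len, leading_clip, trailing_clip, ref_len) for a CIGAR."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{c}" for n, c in ops) != cigar:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    read_len = sum(int(n) for n, c in ops if c in "MIS=XH")
    ref_len = sum(int(n) for n, c in ops if c in "MDN=X")
    leading = int(ops[0][0]) if ops[0][1] in "SH" else 0
    trailing = int(ops[-1][0]) if ops[-1][1] in "SH" else 0
    return read_len, leading, trailing, ref_len


def _query_span(read_len: int, leading_clip: int, trailing_clip: int, strand: str) -> tuple[int, int]:
    # Query coordinates are reported in the original read's orientation:
    # for a reverse-strand alignment the leading (reference-left) clip is
    # the *tail* of the read.
    if strand == FORWARD:
        return leading_clip, read_len - trailing_clip
    return trailing_clip, read_len - leading_clip


def extract_splits(rec: pysam.AlignedSegment) -> list[AlignmentSegment]:
    """Build the ordered segment list for one primary alignment.

    Returns the primary segment plus one segment per SA-tag entry, each with
    its query span reconstructed clip-aware from its CIGAR and normalized to
    the original read orientation, sorted by query_start.  Unparseable SA
    entries are skipped with a warning.
    """
    strand = REVERSE if rec.is_reverse else FORWARD
    read_len = rec.infer_read_length() or (rec.query_length or 0)
    cig = rec.cigartuples or []
    leading = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    trailing = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    qs, qe = _query_span(read_len, leading, trailing, strand)
    primary = AlignmentSegment(
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand=strand,
        mapq=rec.mapping_quality,
        query_start=qs,
        query_end=qe,
        blocks=rec.get_blocks() or None,
    )
    segments = [primary]
    sa = rec.get_tag("SA") if rec.has_tag("SA") else ""
    for entry in filter(None, sa.split(";")):
        try:
            chrom, pos, sa_strand, cigar, mapq = entry.split(",")[:5]
            sa_read_len, lead, trail, ref_len = _cigar_spans(cigar)
            if sa_read_len != read_len and read_len:
                raise ValueError("SA read length disagrees with primary")
            sqs, sqe = _query_span(sa_read_len, lead, trail, sa_strand)
            start = int(pos) - 1
            segments.append(
                AlignmentSegment(
                    chrom=chrom,
                    start=start,
                    end=start + ref_len,
                    strand=sa_strand,
                    mapq=int(mapq),
                    query_start=sqs,
                    query_end=sqe,
                )
            )
        except (ValueError, IndexError) as exc:
            log.warning("skipping unparseable SA entry %r: %s", entry, exc)
    segments.sort(key=lambda s: s.query_start)
    return segments


_SPLIT_PRIORITY = [Kind.TRA_SUPPORT, Kind.INV_SUPPORT, Kind.DEL_SUPPORT, Kind.DUP_SUPPORT]


def categorize_read(read: AlignedRead, stats: InsertStats | None) -> EvidenceCategory:
    """Assign the single category of one read from its split and pair signals.

    Split evidence wins over pair evidence; among multiple split junctions the
    most specific kind wins (translocation > inversion > deletion > duplication).
    """
    source = Source.PAIR if read.is_paired else Source.LONG_READ
    if len(read.segments) > 1:
        kinds = set()
        for a, b in zip(read.segments, read.segments[1:]):
            try:
                kinds.add(classify_split(a, b).kind)
            except ValueError:
                continue
        for kind in _SPLIT_PRIORITY:
            if kind in kinds:
                return EvidenceCategory(kind, Source.SPLIT)
    if read.is_paired and read.mate is not None:
        seg = read.segments[0]
        return classify_pair(
            read_strand=seg.strand,
            mate_strand=read.mate.strand,
            read_is_leftmost=(
                seg.start < read.mate.start
                or (seg.start == read.mate.start and read.is_first_in_template)
            ),
            same_chrom=seg.chrom == read.mate.chrom,
            template_length=read.template_length,
            stats=stats if stats is not None else InsertStats(0.0, 0.0, float("inf")),
        )
    return EvidenceCategory(Kind.CONCORDANT, source)


def _open_alignment(path: str, reference: str | None = None) -> pysam.AlignmentFile:
    mode_kwargs = {"reference_filename": reference} if reference else {}
    afile = pysam.AlignmentFile(path, **mode_kwargs)
    if not afile.has_index():
        expected = path + (".crai" if path.endswith(".cram") else ".bai")
        raise FileNotFoundError(
            f"alignment file {path} has no index; expected {expected} "
            f"(create one with `samtools index`)"
        )
    return afile


def load_alignments(
    source: str | pysam.AlignmentFile,
    chrom: str,
    start: int,
    end: int,
    min_mapq: int = 10,
    insert_stats: InsertStats | None = None,
    insert_z: float = 3.0,
    reference: str | None = None,
) -> list[AlignedRead]:
    """Load and classify every primary alignment overlapping ``[start, end)``.

    Reads below ``min_mapq`` are retained and flagged LOW_CONFIDENCE (they
    still contribute to the low-MAPQ coverage stratum).  Secondary,
    supplementary and duplicate records are excluded; supplementary
    alignments enter only via their primary's SA tag.

    When ``insert_stats`` is omitted it is estimated from up to 1000 FR
    pairs in the window and its flanks (falling back to an infinite limit
    when too few pairs exist).
    """
    afile = source if isinstance(source, pysam.AlignmentFile) else _open_alignment(source, reference)
    if chrom not in afile.references:
        raise ValueError(
            f"unknown sequence {chrom!r}; available: {', '.join(afile.references)}"
        )
    if insert_stats is None:
        insert_stats = _estimate_window_insert_stats(afile, chrom, start, end, z=insert_z)

    reads: list[AlignedRead] = []
    for rec in afile.fetch(chrom, max(0, start), end):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        segments = extract_splits(rec)
        mate = None
        if rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_name is not None:
            mstart = rec.next_reference_start
            mlen = rec.infer_read_length() or rec.query_length or 1
            mate = AlignmentSegment(
                chrom=rec.next_reference_name,
                start=mstart,
                end=mstart + mlen,
                strand=REVERSE if rec.mate_is_reverse else FORWARD,
                mapq=rec.mapping_quality,
            )
        read = AlignedRead(
            name=rec.query_name,
            segments=segments,
            is_paired=rec.is_paired,
            mate=mate,
            is_first_in_template=rec.is_read1 or not rec.is_paired,
            template_length=rec.template_length,
            haplotype=rec.get_tag("HP") if rec.has_tag("HP") else None,
            molecule=str(rec.get_tag("MI")) if rec.has_tag("MI") else None,
        )
        if rec.mapping_quality < min_mapq:
            read.category = EvidenceCategory(
                Kind.LOW_CONFIDENCE, Source.PAIR if rec.is_paired else Source.LONG_READ
            )
        else:
            read.category = categorize_read(read, insert_stats)
        reads.append(read)
    return reads


def _estimate_window_insert_stats(
    afile: pysam.AlignmentFile,
    chrom: str,
    start: int,
    end: int,
    z: float = 3.0,
    max_pairs: int = 1000,
    flank: int = 5000,
) -> InsertStats:
    """Sample FR-oriented pair template lengths from the window plus flanks."""
    lengths: list[float] = []
    lo = max(0, start - flank)
    hi = min(afile.get_reference_length(chrom), end + flank)
    for rec in afile.fetch(chrom, lo, hi):
        if (
            rec.is_paired
            and not rec.is_secondary
            and not rec.is_supplementary
            and not rec.is_duplicate
            and not rec.mate_is_unmapped
            and rec.reference_id == rec.next_reference_id
            and rec.is_reverse != rec.mate_is_reverse
            and rec.template_length > 0
            and not rec.is_reverse  # leftmost forward mate of an FR pair
        ):
            lengths.append(rec.template_length)
            if len(lengths) >= max_pairs:
                break
    # SV-scale template lengths (deletion-spanning pairs) would inflate the
    # estimate; drop gross outliers before computing mean/sd
    if lengths:
        med = statistics.median(lengths)
        lengths = [l for l in lengths if l <= 3 * med]
    try:
        return estimate_insert_stats(lengths, z=z)
    except ValueError:
        return InsertStats(mean=0.0, sd=0.0, concordance_limit=float("inf"))


def partition_by_haplotype(reads: Iterable[AlignedRead]) -> dict[int | None, list[AlignedRead]]:
    """Group reads by HP tag, ascending, with an ``None`` (untagged) group last.

    Returns an insertion-ordered dict whose groups partition the input; the
    untagged group is present only when untagged reads exist."""
    tagged: dict[int, list[AlignedRead]] = {}
    untagged: list[AlignedRead] = []
    for read in reads:
        if read.haplotype is None:
            untagged.append(read)
        else:
            tagged.setdefault(read.haplotype, []).append(read)
    groups: dict[int | None, list[AlignedRead]] = {
        hp: tagged[hp] for hp in sorted(tagged)
    }
    if untagged:
        groups[None] = untagged
    return groups
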