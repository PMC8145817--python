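"""Shared test fixtures: in-memory read builders and tiny crafted BAMs.

All alignment fixtures are generated at test time — nothing binary is
checked in.
"""

from __future__ import annotations

import re

import pysam
import pytest

from svreview.evidence import AlignedRead, AlignmentSegment, EvidenceCategory, Kind, Source
from svreview.fixtures import LibraryProfile, SVSpec, simulate_region


def make_segment(chrom="chr1", start=1000, end=1100, strand="+", mapq=60,
                 query_start=0, query_end=100, blocks=None) -> AlignmentSegment:
    return AlignmentSegment(chrom, start, end, strand, mapq, query_start, query_end, blocks)


def make_read(name="r", chrom="chr1", start=1000, end=1100, mapq=60, strand="+",
              haplotype=None, kind=Kind.CONCORDANT, source=Source.PAIR,
              blocks=None) -> AlignedRead:
    seg = make_segment(chrom, start, end, strand, mapq, blocks=blocks)
    read = AlignedRead(name=name, segments=[seg], haplotype=haplotype)
    read.category = EvidenceCategory(kind, source)
    return read


def bam_header(ref_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": c, "LN": n} for c, n in ref_lengths.items()]}
    )


def make_bam_record(header, name, chrom, start, cigar, mapq=60, reverse=False,
                    paired=False, mate_chrom=None, mate_start=None, mate_reverse=False,
                    tlen=0, first=True, sa=None, hp=None, seq_char="A"):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    flag = 0
    if paired:
        flag |= 0x1
        flag |= 0x40 if first else 0x80
        if mate_reverse:
            flag |= 0x20
    if reverse:
        flag |= 0x10
    rec.flag = flag
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = start
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    read_len = sum(int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
                   if op in "MIS=X")
    rec.query_sequence = seq_char * read_len
    if paired and mate_chrom is not None:
        rec.next_reference_id = header.get_tid(mate_chrom)
        rec.next_reference_start = mate_start
        rec.template_length = tlen
    if sa:
        rec.set_tag("SA", sa)
    if hp is not None:
        rec.set_tag("HP", hp)
    return rec


def write_bam(path, records, ref_lengths):
    header = bam_header(ref_lengths)
    records = sorted(records, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def het_del_sim(tmp_path_factory):
    """One standard heterozygous 2-kb deletion at 30x, reused across tests."""
    out = tmp_path_factory.mktemp("het_del")
    return simulate_region(
        12000, [SVSpec("DEL", "chr1", 5000, 7000, "HET")],
        LibraryProfile(depth=30), seed=42, out_dir=str(out),
    )


@pytest.fixture(scope="session")
def hom_del_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("hom_del")
    return simulate_region(
        12000, [SVSpec("DEL", "chr1", 5000, 7000, "HOM_ALT")],
        LibraryProfile(depth=30), seed=43, out_dir=str(out),
    )
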