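"""Evidence classification: pairs, splits, SA parsing, haplotype grouping."""

import collections

import pysam
import pytest
from hypothesis import given, settings, strategies as st

from svreview.evidence import (
    AlignmentSegment,
    InsertStats,
    Kind,
    Source,
    classify_pair,
    classify_split,
    estimate_insert_stats,
    extract_splits,
    load_alignments,
    partition_by_haplotype,
)

from conftest import bam_header, make_bam_record, make_read, make_segment, write_bam


class TestInsertStats:
    def test_zero_variance(self):
        stats = estimate_insert_stats([300, 300, 300, 300], z=3)
        assert (stats.mean, stats.sd, stats.concordance_limit) == (300, 0, 300)

    def test_sample_sd_uses_n_minus_1(self):
        stats = estimate_insert_stats([200, 400], z=1)
        assert stats.mean == 300
        assert stats.sd == pytest.approx(141.4214, abs=1e-3)
        assert stats.concordance_limit == pytest.approx(441.4214, abs=1e-3)

    def test_single_pair_is_an_error(self):
        with pytest.raises(ValueError, match="concordance_limit"):
            estimate_insert_stats([300])


def oracle_pair(read_strand, mate_strand, read_is_leftmost, same_chrom, tlen, limit):
    """Independent truth table for pair classification."""
    if not same_chrom:
        return Kind.TRA_SUPPORT
    if read_strand == mate_strand:
        return Kind.INV_SUPPORT
    left = read_strand if read_is_leftmost else mate_strand
    if left == "-":
        return Kind.DUP_SUPPORT
    return Kind.DEL_SUPPORT if abs(tlen) > limit else Kind.CONCORDANT


class TestClassifyPair:
    STATS = InsertStats(mean=400.0, sd=50.0, concordance_limit=500.0)

    @pytest.mark.parametrize("rs", "+-")
    @pytest.mark.parametrize("ms", "+-")
    @pytest.mark.parametrize("leftmost", [True, False])
    @pytest.mark.parametrize("same_chrom", [True, False])
    @pytest.mark.parametrize("tlen", [350, 2000])
    def test_truth_table(self, rs, ms, leftmost, same_chrom, tlen):
        got = classify_pair(rs, ms, leftmost, same_chrom, tlen, self.STATS)
        assert got.kind == oracle_pair(rs, ms, leftmost, same_chrom, tlen, 500.0)
        assert got.source == Source.PAIR

    def test_nominal_pair_is_concordant(self):
        assert classify_pair("+", "-", True, True, 350, self.STATS).kind == Kind.CONCORDANT

    def test_rf_order_supports_duplication(self):
        # reverse strand leftmost, forward rightmost: tandem-junction pattern
        assert classify_pair("-", "+", True, True, 2000, self.STATS).kind == Kind.DUP_SUPPORT

    def test_same_strand_supports_inversion(self):
        assert classify_pair("+", "+", True, True, 3000, self.STATS).kind == Kind.INV_SUPPORT

    def test_interchromosomal_supports_translocation(self):
        assert classify_pair("+", "-", True, False, 0, self.STATS).kind == Kind.TRA_SUPPORT


class TestClassifySplit:
    def test_reference_gap_supports_deletion(self):
        a = make_segment(start=1000, end=1100, query_start=0, query_end=100)
        b = make_segment(start=5000, end=5100, query_start=100, query_end=200)
        assert classify_split(a, b).kind == Kind.DEL_SUPPORT

    def test_reversed_reference_order_supports_duplication(self):
        a = make_segment(start=1000, end=1100, query_start=0, query_end=100)
        b = make_segment(start=900, end=1000, query_start=100, query_end=200)
        assert classify_split(a, b).kind == Kind.DUP_SUPPORT

    def test_strand_switch_supports_inversion(self):
        a = make_segment(start=1000, end=1100)
        b = make_segment(start=5000, end=5100, strand="-", query_start=100, query_end=200)
        assert classify_split(a, b).kind == Kind.INV_SUPPORT

    def test_chromosome_switch_supports_translocation(self):
        a = make_segment(chrom="chr1")
        b = make_segment(chrom="chr5", query_start=100, query_end=200)
        assert classify_split(a, b).kind == Kind.TRA_SUPPORT

    def test_small_gap_stays_concordant(self):
        a = make_segment(start=1000, end=1100)
        b = make_segment(start=1110, end=1200, query_start=100, query_end=200)
        assert classify_split(a, b).kind == Kind.CONCORDANT

    def test_reverse_strand_pair_is_normalized(self):
        # both segments reverse: increasing query walks the reference leftward,
        # so a gap *before* seg_a is still a deletion signature
        a = make_segment(start=5000, end=5100, strand="-", query_start=0, query_end=100)
        b = make_segment(start=1000, end=1100, strand="-", query_start=100, query_end=200)
        assert classify_split(a, b).kind == Kind.DEL_SUPPORT

    def test_identical_segments_raise(self):
        a = make_segment()
        b = make_segment()
        with pytest.raises(ValueError, match="identical"):
            classify_split(a, b)


class TestExtractSplits:
    def _primary(self, cigar, start=1000, reverse=False, sa=None):
        header = bam_header({"chr1": 100000})
        return make_bam_record(header, "r1", "chr1", start, cigar, reverse=reverse, sa=sa)

    def test_no_sa_tag_single_segment(self):
        segs = extract_splits(self._primary("100M"))
        assert len(segs) == 1
        assert (segs[0].query_start, segs[0].query_end) == (0, 100)

    def test_forward_split_query_spans(self):
        rec = self._primary("50M50S", sa="chr1,5001,+,50S50M,60,0;")
        segs = extract_splits(rec)
        assert [(s.query_start, s.query_end) for s in segs] == [(0, 50), (50, 100)]
        assert (segs[1].start, segs[1].end) == (5000, 5050)

    def test_reverse_strand_sa_reads_cigar_backwards(self):
        # on the reverse strand the reference-left clip is the read tail
        rec = self._primary("50M50S", sa="chr1,5001,-,50S50M,60,0;")
        segs = extract_splits(rec)
        # forward primary leading half; the reverse SA's leading 50S is the
        # read *tail*, so its 50M also covers query [0, 50)
        assert sorted((s.query_start, s.query_end) for s in segs) == [(0, 50), (0, 50)]

    def test_unparseable_sa_entry_skipped(self, caplog):
        rec = self._primary("50M50S", sa="chr1,notanumber,+,50S50M,60,0;")
        with caplog.at_level("WARNING"):
            segs = extract_splits(rec)
        assert len(segs) == 1
        assert "skipping unparseable SA" in caplog.text


class TestLoadAlignments:
    def test_empty_region(self, het_del_sim):
        assert load_alignments(het_del_sim.bam, "chr1", 0, 10) == []

    def test_all_reads_counted_once(self, tmp_path):
        header = bam_header({"chr1": 100000})
        records = [
            make_bam_record(header, f"r{i}", "chr1", 2000 + i * 10, "100M")
            for i in range(10)
        ]
        path = write_bam(tmp_path / "ten.bam", records, {"chr1": 100000})
        reads = load_alignments(path, "chr1", 1500, 4000, min_mapq=10)
        assert len(reads) == 10
        assert all(r.category.kind != Kind.LOW_CONFIDENCE for r in reads)

    def test_low_mapq_flagged_not_dropped(self, tmp_path):
        header = bam_header({"chr1": 100000})
        records = [make_bam_record(header, "lowq", "chr1", 2000, "100M", mapq=5)]
        path = write_bam(tmp_path / "low.bam", records, {"chr1": 100000})
        reads = load_alignments(path, "chr1", 1900, 2200, min_mapq=10)
        assert len(reads) == 1
        assert reads[0].category.kind == Kind.LOW_CONFIDENCE

    def test_missing_index_names_expected_file(self, tmp_path, het_del_sim):
        import shutil

        dst = tmp_path / "noindex.bam"
        shutil.copy(het_del_sim.bam, dst)
        with pytest.raises(FileNotFoundError, match="noindex.bam.bai"):
            load_alignments(str(dst), "chr1", 0, 100)

    def test_unknown_sequence_lists_available(self, het_del_sim):
        with pytest.raises(ValueError, match="chr1"):
            load_alignments(het_del_sim.bam, "chrMissing", 0, 100)

    def test_every_read_has_exactly_one_category(self, het_del_sim):
        reads = load_alignments(het_del_sim.bam, "chr1", 3000, 9000)
        counts = collections.Counter(r.category.kind for r in reads)
        assert sum(counts.values()) == len(reads)

    def test_fixture_recall_on_het_deletion(self, het_del_sim):
        """Breakpoint-straddling long-insert pairs are DEL support; pairs fully
        inside the unaffected flank stay concordant."""
        reads = load_alignments(het_del_sim.bam, "chr1", 3000, 9000)
        flank_only = [
            r for r in reads
            if r.mate is not None and r.start >= 1000 and max(r.end, r.mate.end) <= 4800
        ]
        assert flank_only, "expected flank pairs in the fixture"
        assert all(r.category.kind == Kind.CONCORDANT for r in flank_only)
        straddling = [r for r in reads if r.category.kind == Kind.DEL_SUPPORT]
        assert len(straddling) > 10


class TestPartitionByHaplotype:
    def test_all_untagged(self):
        reads = [make_read(name=f"r{i}") for i in range(3)]
        groups = partition_by_haplotype(reads)
        assert list(groups) == [None]
        assert groups[None] == reads

    def test_tagged_groups_ascending_then_untagged(self):
        reads = [
            make_read(name="a", haplotype=2),
            make_read(name="b", haplotype=1),
            make_read(name="c"),
        ]
        groups = partition_by_haplotype(reads)
        assert list(groups) == [1, 2, None]

    def test_empty_input(self):
        assert partition_by_haplotype([]) == {}

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.one_of(st.none(), st.integers(min_value=1, max_value=3)), max_size=30))
    def test_groups_partition_input(self, haplotypes):
        reads = [make_read(name=f"r{i}", haplotype=hp) for i, hp in enumerate(haplotypes)]
        groups = partition_by_haplotype(reads)
        flattened = [r for group in groups.values() for r in group]
        assert sorted(r.name for r in flattened) == sorted(r.name for r in reads)
        keys = [k for k in groups if k is not None]
        assert keys == sorted(keys)
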