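"""Synthetic reference / alignment / truth-VCF generation with known SVs.

Every other module is tested against these fixtures: a random reference is
drawn, alternate haplotypes are built as block rearrangements of it
(deletion, tandem duplication, inversion, reciprocal translocation), and
reads are sampled from the haplotypes.  Alignment records — CIGARs, split
(SA) supplementary records, pairing flags and template lengths — are then
computed *analytically* from the block structure, with no external
aligner, so every record's truth is known bit-for-bit.

Reads are error-free by default (optional substitution noise changes base
calls only, never alignment records).  This emulates the alignment
signatures of SVs at chosen genotypes and allele balances; it does not
emulate sequencing error profiles, GC bias or mappability artifacts.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pysam

GENOTYPES = ("HOM_REF", "HET", "HOM_ALT")

#: shortest haplotype piece that receives its own alignment segment; shorter
#: pieces stay soft-clipped, as a real aligner would leave them
MIN_ANCHOR = 20

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class LibraryProfile:
    """Sequencing library the generator emulates.

    Defaults follow a typical short-read germline library: 150-bp paired
    ends, 400 +/- 50 bp inserts, 30x depth, error-free."""

    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    depth: float = 30.0
    long_reads: bool = False
    long_read_mean: float = 8000.0
    long_read_sd: float = 2000.0
    mapq: int = 60
    error_rate: float = 0.0
    tag_haplotypes: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not self.long_reads and self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed twice the read length")


@dataclass
class SVSpec:
    """One planted SV on the alternate haplotype.

    Coordinates are 0-based half-open on the reference.  ``allele_balance``
    overrides the genotype-implied fraction of fragments drawn from the
    alternate haplotype (0.5 for HET, 1.0 for HOM_ALT)."""

    svtype: str  # DEL | DUP | INV | TRA
    chrom: str
    start: int
    end: int
    genotype: str = "HET"
    allele_balance: float | None = None
    chrom2: str | None = None  # TRA partner breakpoint
    pos2: int | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.svtype != "TRA" and self.end - self.start < 50:
            raise ValueError("SV length must be >= 50 bp")

    @property
    def alt_fraction(self) -> float:
        if self.allele_balance is not None:
            return self.allele_balance
        return {"HOM_REF": 0.0, "HET": 0.5, "HOM_ALT": 1.0}[self.genotype]


@dataclass(frozen=True)
class _Block:
    """A haplotype block: a contiguous reference span copied (strand +) or
    reverse-complemented (strand -) into the alternate haplotype."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedRegion:
    fasta: str
    bam: str
    vcf: str
    reference: dict[str, str]
    svs: list[SVSpec]


def build_alt_blocks(ref_lengths: dict[str, int], svs: list[SVSpec]) -> dict[str, list[_Block]]:
    """Alternate-haplotype block lists, one per reference sequence."""
    intra: dict[str, list[SVSpec]] = {}
    tras: list[SVSpec] = []
    for sv in svs:
        if sv.svtype == "TRA":
            tras.append(sv)
        else:
            intra.setdefault(sv.chrom, []).append(sv)
    blocks: dict[str, list[_Block]] = {}
    for chrom, length in ref_lengths.items():
        events = sorted(intra.get(chrom, []), key=lambda s: s.start)
        out: list[_Block] = []
        cursor = 0
        for sv in events:
            if sv.start < cursor:
                raise ValueError(f"overlapping SVs on {chrom} haplotype")
            if sv.end > length:
                raise ValueError(f"SV {sv.svtype} {chrom}:{sv.start}-{sv.end} exceeds reference")
            if sv.start > cursor:
                out.append(_Block(chrom, cursor, sv.start))
            if sv.svtype == "DEL":
                pass
            elif sv.svtype == "DUP":  # tandem: two copies
                out.append(_Block(chrom, sv.start, sv.end))
                out.append(_Block(chrom, sv.start, sv.end))
            elif sv.svtype == "INV":
                out.append(_Block(chrom, sv.start, sv.end, "-"))
            else:
                raise ValueError(f"unsupported svtype {sv.svtype}")
            cursor = sv.end
        if cursor < length:
            out.append(_Block(chrom, cursor, length))
        blocks[chrom] = out
    for sv in tras:
        if sv.chrom2 is None or sv.pos2 is None:
            raise ValueError("TRA requires chrom2/pos2")
        a, b = sv.chrom, sv.chrom2
        if intra.get(a) or intra.get(b):
            raise ValueError("TRA chromosomes must carry no other SVs")
        la, lb = ref_lengths[a], ref_lengths[b]
        # reciprocal exchange of the two tails
        blocks[a] = [_Block(a, 0, sv.start), _Block(b, sv.pos2, lb)]
        blocks[b] = [_Block(b, 0, sv.pos2), _Block(a, sv.start, la)]
        blocks[a] = [bl for bl in blocks[a] if len(bl) > 0]
        blocks[b] = [bl for bl in blocks[b] if len(bl) > 0]
    return blocks


def _hap_sequence(blocks: list[_Block], ref: dict[str, str]) -> str:
    parts = []
    for b in blocks:
        piece = ref[b.chrom][b.start:b.end]
        parts.append(piece if b.strand == "+" else revcomp(piece))
    return "".join(parts)


def _map_interval(blocks: list[_Block], a: int, b: int) -> list[tuple[str, int, int, str, int]]:
    """Map haplotype interval [a, b) onto the reference.

    Returns pieces ``(chrom, ref_start, ref_end, strand, hap_offset)`` in
    haplotype order, where hap_offset is the piece's offset from ``a``.
    """
    pieces = []
    h0 = 0
    for blk in blocks:
        h1 = h0 + len(blk)
        lo, hi = max(a, h0), min(b, h1)
        if lo < hi:
            if blk.strand == "+":
                rs = blk.start + (lo - h0)
                re_ = blk.start + (hi - h0)
            else:
                rs = blk.end - (hi - h0)
                re_ = blk.end - (lo - h0)
            pieces.append((blk.chrom, rs, re_, blk.strand, lo - a))
        h0 = h1
    return pieces


@dataclass
class _Seg:
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # alignment strand in reference terms
    q_start: int  # in original read orientation
    q_end: int

    def cigar(self, read_len: int) -> str:
        m = self.q_end - self.q_start
        if self.strand == "+":
            lead, trail = self.q_start, read_len - self.q_end
        else:
            lead, trail = read_len - self.q_end, self.q_start
        parts = []
        if lead:
            parts.append(f"{lead}S")
        parts.append(f"{m}M")
        if trail:
            parts.append(f"{trail}S")
        return "".join(parts)


def _align_read(blocks: list[_Block], h_start: int, h_end: int, is_revcomp: bool) -> list[_Seg]:
    """Analytic alignment of the haplotype interval giving read segments in
    original read orientation, sorted by query start."""
    length = h_end - h_start
    segs: list[_Seg] = []
    for chrom, rs, re_, blk_strand, off in _map_interval(blocks, h_start, h_end):
        plen = re_ - rs
        if is_revcomp:
            q_start = length - (off + plen)
            strand = "-" if blk_strand == "+" else "+"
        else:
            q_start = off
            strand = blk_strand
        segs.append(_Seg(chrom, rs, re_, strand, q_start, q_start + plen))
    segs.sort(key=lambda s: s.q_start)
    keep = [s for s in segs if (s.q_end - s.q_start) >= MIN_ANCHOR]
    if not keep:
        keep = [max(segs, key=lambda s: s.q_end - s.q_start)]
    return keep


def _sa_entry(seg: _Seg, read_len: int, mapq: int) -> str:
    return f"{seg.chrom},{seg.ref_start + 1},{seg.strand},{seg.cigar(read_len)},{mapq},0;"


def _make_records(
    header: pysam.AlignmentHeader,
    name: str,
    segs_pair: list[list[_Seg]],
    seqs: list[str],
    mapq: int,
    paired: bool,
    haplotype: int | None,
) -> list[pysam.AlignedSegment]:
    """SAM records for one fragment: primaries plus supplementaries, with SA
    tags, mate fields and signed template length filled in."""
    records: list[pysam.AlignedSegment] = []
    primaries = [max(segs, key=lambda s: s.q_end - s.q_start) for segs in segs_pair]
    # template length from the primary segments when both mates share a chrom
    tlen = 0
    if paired and len(primaries) == 2 and primaries[0].chrom == primaries[1].chrom:
        left = min(p.ref_start for p in primaries)
        right = max(p.ref_end for p in primaries)
        tlen = right - left
    for mate_idx, (segs, seq) in enumerate(zip(segs_pair, seqs)):
        read_len = len(seq)
        primary = primaries[mate_idx]
        other_primary = primaries[1 - mate_idx] if paired and len(primaries) == 2 else None
        for seg in segs:
            rec = pysam.AlignedSegment(header)
            rec.query_name = name
            is_primary = seg is primary
            flag = 0
            if paired:
                flag |= 0x1 | 0x2
                flag |= 0x40 if mate_idx == 0 else 0x80
                if other_primary is not None:
                    if other_primary.strand == "-":
                        flag |= 0x20
            if seg.strand == "-":
                flag |= 0x10
            if not is_primary:
                flag |= 0x800
            rec.flag = flag
            rec.reference_id = header.get_tid(seg.chrom)
            rec.reference_start = seg.ref_start
            rec.mapping_quality = mapq
            rec.cigarstring = seg.cigar(read_len)
            rec.query_sequence = seq if seg.strand == "+" else revcomp(seq)
            if paired and other_primary is not None:
                rec.next_reference_id = header.get_tid(other_primary.chrom)
                rec.next_reference_start = other_primary.ref_start
                if tlen and primary.chrom == other_primary.chrom:
                    sign = 1 if primary.ref_start <= other_primary.ref_start else -1
                    if primary.ref_start == other_primary.ref_start:
                        sign = 1 if mate_idx == 0 else -1
                    rec.template_length = sign * tlen
            others = [s for s in segs if s is not seg]
            if others:
                rec.set_tag("SA", "".join(_sa_entry(s, read_len, mapq) for s in others))
            if haplotype is not None:
                rec.set_tag("HP", haplotype)
            records.append(rec)
    return records


def simulate_region(
    reference_length: int | dict[str, int],
    svs: list[SVSpec],
    profile: LibraryProfile,
    seed: int,
    out_dir: str,
    prefix: str = "sim",
    sample: str = "sample1",
) -> SimulatedRegion:
    """Generate reference FASTA, coordinate-sorted indexed BAM and truth VCF.

    Fragments are drawn per chromosome from the reference and alternate
    haplotypes according to each SV's genotype / allele balance (the
    alternate fraction of the chromosome is the maximum alt_fraction of its
    SVs; reference-only chromosomes contribute reference fragments only).
    """
    rng = np.random.default_rng(seed)
    ref_lengths = (
        {"chr1": reference_length} if isinstance(reference_length, int) else dict(reference_length)
    )
    os.makedirs(out_dir, exist_ok=True)
    ref = {
        chrom: "".join(rng.choice(list("ACGT"), size=length))
        for chrom, length in ref_lengths.items()
    }
    # diploid haplotypes: hap A carries the hom-alt SVs only, hap B every
    # carrier SV (het + hom-alt); hom-ref "calls" land on neither, so
    # per-SV genotypes stay independent on a shared chromosome
    hap_a_blocks = build_alt_blocks(ref_lengths, [s for s in svs if s.genotype == "HOM_ALT"])
    hap_b_blocks = build_alt_blocks(ref_lengths, [s for s in svs if s.genotype != "HOM_REF"])
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in ref_lengths.items()],
        }
    )

    # probability of drawing a fragment from hap B: the explicit allele
    # balance when one is given on the chromosome (meaningful for single-SV
    # HET chromosomes, e.g. mixture experiments), else an unbiased 0.5
    hap_b_fraction = {}
    for chrom in ref_lengths:
        balances = [
            sv.allele_balance
            for sv in svs
            if sv.allele_balance is not None and chrom in (sv.chrom, sv.chrom2)
        ]
        hap_b_fraction[chrom] = max(balances) if balances else 0.5

    records: list[pysam.AlignedSegment] = []
    frag_id = 0
    for chrom, length in ref_lengths.items():
        hap_choices = {0: hap_a_blocks[chrom], 1: hap_b_blocks[chrom]}
        hap_seqs = {h: _hap_sequence(b, ref) for h, b in hap_choices.items()}
        p_alt = hap_b_fraction[chrom]
        rl = profile.read_length
        if profile.long_reads:
            n_frags = int(round(profile.depth * length / profile.long_read_mean))
        else:
            n_frags = int(round(profile.depth * length / (2 * rl)))
        for _ in range(n_frags):
            hap = 1 if rng.random() < p_alt else 0
            blocks, hap_seq = hap_choices[hap], hap_seqs[hap]
            hap_len = len(hap_seq)
            if profile.long_reads:
                flen = int(rng.normal(profile.long_read_mean, profile.long_read_sd))
                flen = max(500, min(flen, hap_len))
            else:
                # insert draws are truncated at +/- 2.5 sd: the stated world
                # defines an error-free concordant library, so no fragment may
                # exceed the z=3 concordance limit by statistical accident
                flen = int(rng.normal(profile.insert_mean, profile.insert_sd))
                lo_f = int(profile.insert_mean - 2.5 * profile.insert_sd)
                hi_f = int(profile.insert_mean + 2.5 * profile.insert_sd)
                flen = max(lo_f, min(flen, hi_f))
                flen = max(2 * rl + 1, min(flen, hap_len))
            pos = int(rng.integers(0, hap_len - flen + 1))
            name = f"{prefix}_frag{frag_id}"
            frag_id += 1
            hp_tag = (hap + 1) if profile.tag_haplotypes else None
            if profile.long_reads:
                segs = _align_read(blocks, pos, pos + flen, is_revcomp=False)
                seq = _maybe_noise(hap_seq[pos : pos + flen], profile.error_rate, rng)
                records.extend(
                    _make_records(header, name, [segs], [seq], profile.mapq, False, hp_tag)
                )
            else:
                s1 = _align_read(blocks, pos, pos + rl, is_revcomp=False)
                s2 = _align_read(blocks, pos + flen - rl, pos + flen, is_revcomp=True)
                seq1 = _maybe_noise(hap_seq[pos : pos + rl], profile.error_rate, rng)
                seq2 = revcomp(_maybe_noise(hap_seq[pos + flen - rl : pos + flen], profile.error_rate, rng))
                records.extend(
                    _make_records(header, name, [s1, s2], [seq1, seq2], profile.mapq, True, hp_tag)
                )

    fasta_path = os.path.join(out_dir, f"{prefix}.fa")
    with open(fasta_path, "w") as fh:
        for chrom, seq in ref.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    try:
        pysam.faidx(fasta_path)
    except pysam.SamtoolsError:
        pass

    bam_path = os.path.join(out_dir, f"{prefix}.bam")
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(bam_path)

    vcf_path = os.path.join(out_dir, f"{prefix}.vcf")
    write_truth_vcf(vcf_path, ref_lengths, svs, sample=sample)
    return SimulatedRegion(fasta_path, bam_path, vcf_path, ref, svs)


def _maybe_noise(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < error_rate
    if hits.any():
        chars[hits] = rng.choice(list("ACGT"), size=int(hits.sum()))
    return "".join(chars)


_GT_CODE = {"HOM_REF": (0, 0), "HET": (0, 1), "HOM_ALT": (1, 1)}


def write_truth_vcf(
    path: str, ref_lengths: dict[str, int], svs: list[SVSpec], sample: str = "sample1"
) -> None:
    header = pysam.VariantHeader()
    for chrom, length in ref_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SVLEN", 1, "Integer", "Signed length of the variant")
    header.info.add("CHR2", 1, "String", "Partner chromosome for translocations")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for i, sv in enumerate(sorted(svs, key=lambda s: (s.chrom, s.start))):
            # VCF anchors symbolic SVs on the padding base before the event:
            # POS = last unaffected base, END = last affected base.  END
            # carries the partner-breakpoint position for translocations.
            stop = sv.pos2 if sv.svtype == "TRA" else sv.end
            rec = vcf.new_record(
                contig=sv.chrom,
                start=max(0, sv.start - 1),  # pysam 0-based; writes POS = start
                stop=stop,
                alleles=("N", f"<{sv.svtype}>"),
                id=f"sv{i}",
            )
            rec.info["SVTYPE"] = sv.svtype
            if sv.svtype == "TRA":
                rec.info["CHR2"] = sv.chrom2
            else:
                svlen = sv.end - sv.start
                rec.info["SVLEN"] = -svlen if sv.svtype == "DEL" else svlen
            rec.samples[sample]["GT"] = _GT_CODE[sv.genotype]
            rec.samples[sample].phased = False
            rec.stop = stop
            vcf.write(rec)


def mix_alignments(file_a: str, file_b: str, fraction_a: float, seed: int, out_path: str) -> str:
    """Merge two alignment files, keeping each fragment of ``file_a`` with
    probability ``fraction_a`` and of ``file_b`` with ``1 - fraction_a``.

    Retention is decided per fragment name (a hash of seed and name), so
    mates and supplementaries of one fragment are kept or dropped together.
    Output is coordinate-sorted and indexed.
    """
    if not 0.0 <= fraction_a <= 1.0:
        raise ValueError("fraction_a must be within [0, 1]")

    def keep(name: str, salt: str, p: float) -> bool:
        u = zlib.crc32(f"{seed}:{salt}:{name}".encode()) / 2**32
        return u < p

    with pysam.AlignmentFile(file_a) as fa, pysam.AlignmentFile(file_b) as fb:
        if list(fa.references) != list(fb.references):
            raise ValueError("alignment files use different reference naming")
        header = fa.header
        records = [r for r in fa if keep(r.query_name, "a", fraction_a)]
        records += [r for r in fb if keep(r.query_name, "b", 1.0 - fraction_a)]
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(out_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(out_path)
    return out_path


def simulate_deletion_cohort(
    n_per_class: int,
    profile: LibraryProfile,
    seed: int,
    out_dir: str,
    chrom_cycle: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 9)),
    region_length: int = 4000,
    del_span: tuple[int, int] = (1500, 2500),
) -> list[tuple[SimulatedRegion, str, str]]:
    """Independent single-deletion fixtures for classifier training.

    Each example is its own mini-reference carrying one candidate deletion
    at genotype HOM_REF (no variant present), HET or HOM_ALT.  Chromosome
    names cycle through ``chrom_cycle`` so a held-out-chromosome
    validation split (chr1-chr3) applies naturally.

    Returns (region, genotype label, chromosome) triples.
    """
    out = []
    rng = np.random.default_rng(seed)
    for i in range(3 * n_per_class):
        gt = GENOTYPES[i % 3]
        chrom = chrom_cycle[i % len(chrom_cycle)]
        sv = SVSpec("DEL", chrom, del_span[0], del_span[1], gt)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sim = simulate_region(
            {chrom: region_length}, [sv], profile, seed=sub_seed,
            out_dir=out_dir, prefix=f"cohort{i}",
        )
        out.append((sim, gt, chrom))
    return out


def filter_low_coverage_regions(
    regions: list[tuple[str, int, int]],
    bam_path: str,
    min_depth: float = 10.0,
    min_mapq: int = 10,
    reference: str | None = None,
) -> list[tuple[str, int, int]]:
    """Retain regions whose mean depth of MAPQ >= ``min_mapq`` reads is at
    least ``min_depth`` (boundary inclusive: exactly 10.0x is retained)."""
    from .coverage import compute_coverage
    from .evidence import InsertStats, load_alignments

    kept = []
    for chrom, start, end in regions:
        reads = load_alignments(
            bam_path, chrom, start, end, min_mapq=0,
            insert_stats=InsertStats(0.0, 0.0, float("inf")), reference=reference,
        )
        track = compute_coverage(reads, chrom, start, end, mapq_threshold=min_mapq)
        if float(track.depth_high.mean()) >= min_depth:
            kept.append((chrom, start, end))
    return kept
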