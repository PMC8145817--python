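"""SV call records parsed from VCF.

Coordinates follow VCF convention (1-based ``pos``, ``end`` inclusive of
the SV interval); conversion to the 0-based half-open coordinates used
internally happens where alignments are fetched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import pysam


@dataclass
class SVRecord:
    chrom: str
    start: int  # 1-based VCF POS
    end: int
    svtype: str | None = None
    chrom2: str | None = None
    ci_pos: tuple[int, int] = (0, 0)
    ci_end: tuple[int, int] = (0, 0)
    genotypes: dict[str, tuple[int | None, ...]] = field(default_factory=dict)
    info: dict[str, Any] = field(default_factory=dict)
    record_id: str | None = None

    @property
    def svlen(self) -> int | None:
        if "SVLEN" in self.info:
            v = self.info["SVLEN"]
            if isinstance(v, (tuple, list)):
                v = v[0]
            if v is not None:
                return abs(int(v))
        if self.chrom2 not in (None, self.chrom):
            return None
        return max(0, self.end - self.start)

    @property
    def is_interchromosomal(self) -> bool:
        return self.chrom2 is not None and self.chrom2 != self.chrom

    def gt_class(self, sample: str) -> str:
        """hom_ref / het / hom_alt / missing for one sample's GT."""
        gt = self.genotypes.get(sample)
        if gt is None or any(a is None for a in gt) or len(gt) == 0:
            return "missing"
        alts = sum(1 for a in gt if a not in (0, None))
        if alts == 0:
            return "hom_ref"
        if alts == len(gt):
            return "hom_alt"
        return "het"

    def label(self) -> str:
        t = self.svtype or "REGION"
        if self.is_interchromosomal:
            return f"{t} {self.chrom}:{self.start} <-> {self.chrom2}:{self.end}"
        return f"{t} {self.chrom}:{self.start}-{self.end}"


def _scalar(value: Any) -> Any:
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def from_variant_record(rec: pysam.VariantRecord) -> SVRecord:
    info = dict(rec.info)
    svtype = info.get("SVTYPE")
    alt = rec.alts[0] if rec.alts else None
    if svtype is None and alt and alt.startswith("<") and alt.endswith(">"):
        svtype = alt.strip("<>")
    chrom2 = info.get("CHR2")
    if chrom2 is None and alt and ("[" in alt or "]" in alt):
        # breakend notation: N[chr2:pos[ etc.
        sep = "[" if "[" in alt else "]"
        locus = alt.split(sep)[1]
        if ":" in locus:
            chrom2 = locus.split(":")[0]
        if svtype is None:
            svtype = "BND"
    ci_pos = tuple(info.get("CIPOS", (0, 0)))
    ci_end = tuple(info.get("CIEND", (0, 0)))
    gts = {}
    for name, call in rec.samples.items():
        gts[name] = tuple(call.get("GT") or ())
    return SVRecord(
        chrom=rec.chrom,
        start=rec.pos,
        end=rec.stop,
        svtype=svtype,
        chrom2=chrom2,
        ci_pos=(int(ci_pos[0]), int(ci_pos[-1])),
        ci_end=(int(ci_end[0]), int(ci_end[-1])),
        genotypes=gts,
        info={k: _scalar(v) if k in ("SVLEN", "END", "SVTYPE", "CHR2", "MATEID") else v for k, v in info.items()},
        record_id=rec.id,
    )


def iter_vcf(path: str) -> Iterator[SVRecord]:
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            yield from_variant_record(rec)
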