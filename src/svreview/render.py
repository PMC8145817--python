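"""Static review-image layout and drawing.

One image summarizes the alignment evidence for one SV call: the call bar
with confidence-interval whiskers on top, then one track per sample
(split into haplotype sub-tracks when HP tags are present) showing the
MAPQ-stratified coverage background and color-coded read glyphs, then
optional annotation (BED) and gene-model (GFF3) tracks.  For long SVs two
zoom panels centered on the breakpoints replace the single window.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.path import Path as MplPath
import matplotlib.patches as mpatches

from .coverage import CoverageTrack, compute_coverage
from .evidence import AlignedRead, Kind, load_alignments, partition_by_haplotype
from .variants import SVRecord

#: SVs longer than this auto-enable breakpoint zoom panels
AUTO_ZOOM_THRESHOLD = 5000
AUTO_ZOOM_WINDOW = 1000

DEFAULT_COLORS = {
    Kind.CONCORDANT: "#333333",
    Kind.DEL_SUPPORT: "#e6550d",  # red-orange, distinct from duplication red
    Kind.DUP_SUPPORT: "#d7191c",
    Kind.INV_SUPPORT: "#2c7fb8",
    Kind.TRA_SUPPORT: "#4575b4",
    Kind.LOW_CONFIDENCE: "#999999",
}


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicWindow") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class PlotStyle:
    """Figure geometry and palette.

    The axes region occupies the figure between the margin fractions; the
    ML preprocessing crop is derived from these same numbers, so the crop
    is exact by construction rather than inferred from pixels."""

    fig_width: float = 8.0
    fig_height: float = 5.0
    dpi: int = 150
    margin_left: float = 0.08
    margin_right: float = 0.99
    margin_bottom: float = 0.09
    margin_top: float = 0.94
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    coverage_high_color: str = "#9a9a9a"  # dark gray: MAPQ >= threshold stratum
    coverage_low_color: str = "#dddddd"  # light gray: below-threshold stratum
    gene_color: str = "#1f77b4"
    annotation_color: str = "#7a0177"
    output_format: str = "png"
    max_rows: int = 300

    def pixel_size(self) -> tuple[int, int]:
        return int(round(self.fig_width * self.dpi)), int(round(self.fig_height * self.dpi))

    def crop_box(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) pixel box of the axes region (origin top-left)."""
        w, h = self.pixel_size()
        return (
            int(round(self.margin_left * w)),
            int(round((1 - self.margin_top) * h)),
            int(round(self.margin_right * w)),
            int(round((1 - self.margin_bottom) * h)),
        )


@dataclass
class TrackSpec:
    label: str
    #: haplotype -> list of (read, row); row 0 is drawn topmost
    layouts: dict[int | None, list[tuple[AlignedRead, int]]]
    #: haplotype -> window index -> CoverageTrack
    coverage: dict[int | None, list[CoverageTrack]]
    n_rows: dict[int | None, int]


@dataclass
class PlotSpec:
    windows: list[GenomicWindow]
    sv: SVRecord | None
    tracks: list[TrackSpec]
    annotations: list[tuple[str, list[tuple[str, int, int, str]]]] = field(default_factory=list)
    gene_models: list["Transcript"] = field(default_factory=list)
    style: PlotStyle = field(default_factory=PlotStyle)
    seed: int = 0


@dataclass
class Transcript:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]


def plan_windows(
    sv: SVRecord, zoom: int | None = None, pad_fraction: float = 0.5
) -> list[GenomicWindow]:
    """Resolve the plot window(s) for one SV.

    Without zoom, a single window pads the SV interval by ``pad_fraction``
    of its length on each side.  With zoom, two ``zoom``-bp windows are
    centered on the breakpoints; if they overlap or abut they are merged
    into their union.  Interchromosomal calls get one window per
    breakpoint chromosome.
    """
    if zoom is not None and zoom <= 0:
        raise ValueError("zoom must be > 0")
    if sv.is_interchromosomal:
        w = zoom or AUTO_ZOOM_WINDOW
        return [
            GenomicWindow(sv.chrom, max(0, sv.start - w // 2), sv.start + w // 2),
            GenomicWindow(sv.chrom2, max(0, sv.end - w // 2), sv.end + w // 2),
        ]
    length = sv.end - sv.start
    if zoom is None:
        pad = int(round(length * pad_fraction)) or 1
        return [GenomicWindow(sv.chrom, max(0, sv.start - pad), sv.end + pad)]
    half = zoom // 2
    w1 = GenomicWindow(sv.chrom, max(0, sv.start - half), sv.start + half)
    w2 = GenomicWindow(sv.chrom, max(0, sv.end - half), sv.end + half)
    if w1.end >= w2.start:  # overlap or abut -> union
        return [GenomicWindow(sv.chrom, w1.start, w2.end)]
    return [w1, w2]


def auto_zoom(sv: SVRecord) -> int | None:
    """Default zoom rule: 1000-bp breakpoint panels for SVs > 5000 bp."""
    length = sv.svlen
    if not sv.is_interchromosomal and length is not None and length > AUTO_ZOOM_THRESHOLD:
        return AUTO_ZOOM_WINDOW
    return None


def layout_reads(
    reads: list[AlignedRead],
    windows: list[GenomicWindow],
    max_rows: int = 300,
    seed: int = 0,
) -> list[tuple[AlignedRead, int]]:
    """Greedy interval scheduling of reads into vertical rows.

    SV-supporting (discordant/split) reads occupy the topmost rows and are
    never dropped; concordant reads fill rows below and are deterministically
    subsampled when the row budget is exceeded.
    """
    def visible(read: AlignedRead) -> bool:
        return any(
            seg.chrom == w.chrom and seg.start < w.end and seg.end > w.start
            for w in windows
            for seg in read.segments + ([read.mate] if read.mate else [])
        )

    def span(read: AlignedRead) -> tuple[int, int]:
        points = [p for seg in read.segments for p in (seg.start, seg.end)]
        if read.mate is not None and read.mate.chrom == read.segments[0].chrom:
            points += [read.mate.start, read.mate.end]
        return min(points), max(points)

    supporting = sorted(
        (r for r in reads if r.category.is_sv_support and visible(r)), key=lambda r: span(r)[0]
    )
    plain = sorted(
        (r for r in reads if not r.category.is_sv_support and visible(r)), key=lambda r: span(r)[0]
    )

    def greedy(rows_taken: list[int], items: list[AlignedRead], base: int) -> list[tuple[AlignedRead, int]]:
        # rows_taken[i] = rightmost occupied coordinate in row base+i
        out = []
        for read in items:
            lo, hi = span(read)
            for i, edge in enumerate(rows_taken):
                if lo > edge:
                    rows_taken[i] = hi
                    out.append((read, base + i))
                    break
            else:
                rows_taken.append(hi)
                out.append((read, base + len(rows_taken) - 1))
        return out

    sup_rows: list[int] = []
    placed = greedy(sup_rows, supporting, base=0)
    budget = max(max_rows - len(sup_rows), 1)
    plain_rows_probe: list[int] = []
    probe = greedy(plain_rows_probe, plain, base=0)
    if len(plain_rows_probe) > budget:
        rng = random.Random(seed)
        keep_fraction = budget / len(plain_rows_probe)
        plain = [r for r in plain if rng.random() < keep_fraction]
        probe = greedy([], plain, base=0)
    placed += [(r, len(sup_rows) + row) for r, row in probe]
    return placed


def read_bed(path: str, windows: list[GenomicWindow]) -> list[tuple[str, int, int, str]]:
    """Intervals (chrom, start0, end, name) from a BED file overlapping any
    window; uses the tabix index when present, otherwise scans the text."""
    import pysam

    out = []
    if os.path.exists(path + ".tbi"):
        with pysam.TabixFile(path) as tbx:
            for w in windows:
                if w.chrom not in tbx.contigs:
                    continue
                for line in tbx.fetch(w.chrom, w.start, w.end):
                    out.append(_parse_bed_line(line))
    else:
        opener = open
        if path.endswith(".gz"):
            import gzip

            opener = gzip.open
        with opener(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                iv = _parse_bed_line(line)
                if any(iv[0] == w.chrom and iv[1] < w.end and iv[2] > w.start for w in windows):
                    out.append(iv)
    return out


def _parse_bed_line(line: str) -> tuple[str, int, int, str]:
    parts = line.rstrip("\n").split("\t")
    name = parts[3] if len(parts) > 3 else ""
    return parts[0], int(parts[1]), int(parts[2]), name


def read_gff3(path: str, windows: list[GenomicWindow]) -> list[Transcript]:
    """Transcripts with exon spans from a (possibly gzipped) GFF3 file.

    GFF3 is 1-based inclusive; converted here to 0-based half-open."""
    import gzip

    opener = gzip.open if path.endswith(".gz") else open
    transcripts: dict[str, Transcript] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("mRNA", "transcript"):
                tid = fields.get("ID", f"{chrom}:{start}")
                name = fields.get("Name", tid)
                transcripts[tid] = Transcript(
                    name, chrom, int(start) - 1, int(end), strand, []
                )
            elif ftype == "exon":
                parent = fields.get("Parent", "")
                exons.setdefault(parent, []).append((int(start) - 1, int(end)))
    for tid, tr in transcripts.items():
        tr.exons = sorted(exons.get(tid, []))
    out = [
        tr
        for tr in transcripts.values()
        if any(tr.chrom == w.chrom and tr.start < w.end and tr.end > w.start for w in windows)
    ]
    return sorted(out, key=lambda t: (t.chrom, t.start))


def build_plot_spec(
    sv: SVRecord | None,
    bam_paths: dict[str, str],
    windows: list[GenomicWindow] | None = None,
    zoom: int | None = None,
    min_mapq: int = 10,
    annotation_paths: dict[str, str] | None = None,
    gff3_path: str | None = None,
    style: PlotStyle | None = None,
    seed: int = 0,
    reference: str | None = None,
) -> PlotSpec:
    """Assemble the full resolved layout for one review image."""
    style = style or PlotStyle()
    if windows is None:
        if sv is None:
            raise ValueError("either an SV record or explicit windows are required")
        windows = plan_windows(sv, zoom=zoom if zoom is not None else auto_zoom(sv))
    tracks = []
    for label, bam in bam_paths.items():
        all_reads: dict[int | None, list[AlignedRead]] = {}
        for w in windows:
            try:
                reads = load_alignments(bam, w.chrom, w.start, w.end, min_mapq=min_mapq, reference=reference)
            except ValueError:
                reads = []
            for hp, group in partition_by_haplotype(reads).items():
                all_reads.setdefault(hp, []).extend(group)
        if not all_reads:
            all_reads = {None: []}
        layouts, cov, nrows = {}, {}, {}
        for hp, group in all_reads.items():
            # de-duplicate reads loaded from several windows
            seen: dict[tuple, AlignedRead] = {}
            for r in group:
                seen.setdefault((r.name, r.is_first_in_template), r)
            group = list(seen.values())
            layouts[hp] = layout_reads(group, windows, max_rows=style.max_rows, seed=seed)
            cov[hp] = [
                compute_coverage(
                    [r for r in group], w.chrom, w.start, w.end, mapq_threshold=min_mapq
                )
                for w in windows
            ]
            nrows[hp] = max((row for _, row in layouts[hp]), default=0) + 1
        tracks.append(TrackSpec(label, layouts, cov, nrows))
    annotations = []
    for name, path in (annotation_paths or {}).items():
        annotations.append((name, read_bed(path, windows)))
    genes = read_gff3(gff3_path, windows) if gff3_path else []
    return PlotSpec(windows=windows, sv=sv, tracks=tracks, annotations=annotations,
                    gene_models=genes, style=style, seed=seed)


def _arc_path(x0: float, x1: float, y: float, height: float) -> MplPath:
    mid = (x0 + x1) / 2
    return MplPath(
        [(x0, y), (mid, y + height), (x1, y)],
        [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
    )


def render_image(spec: PlotSpec, out_path: str) -> str:
    """Draw the review image and write it (format chosen by extension).

    SVG output is byte-stable for identical specs and seeds.
    """
    style = spec.style
    out_dir = os.path.dirname(os.path.abspath(out_path))
    if not os.path.isdir(out_dir):
        raise FileNotFoundError(f"output directory {out_dir} does not exist")
    with matplotlib.rc_context({"svg.hashsalt": str(spec.seed)}):
        fig = _draw(spec)
        try:
            fig.savefig(out_path, dpi=style.dpi, metadata=_stable_metadata(out_path))
        finally:
            plt.close(fig)
    return out_path


def _stable_metadata(out_path: str) -> dict | None:
    if out_path.endswith(".svg"):
        return {"Date": None}
    if out_path.endswith(".png"):
        return {"Software": "svreview"}
    return None


def _draw(spec: PlotSpec) -> plt.Figure:
    style = spec.style
    ncols = len(spec.windows)
    # one row for the SV bar, one per (sample, haplotype) sub-track,
    # one per annotation set, one for genes
    subtracks = [
        (ti, hp) for ti, tr in enumerate(spec.tracks) for hp in tr.layouts
    ]
    n_ann = len(spec.annotations)
    n_gene = 1 if spec.gene_models else 0
    heights = [0.045] + [1.0] * max(len(subtracks), 1) + [0.1] * n_ann + [0.16] * n_gene
    nrows = len(heights)
    fig = plt.figure(figsize=(style.fig_width, style.fig_height))
    gs = fig.add_gridspec(
        nrows=nrows, ncols=ncols, height_ratios=heights, hspace=0.35, wspace=0.08,
        left=style.margin_left, right=style.margin_right,
        bottom=style.margin_bottom, top=style.margin_top,
    )

    for ci, w in enumerate(spec.windows):
        ax = fig.add_subplot(gs[0, ci])
        _draw_sv_bar(ax, spec, w)
    for si, (ti, hp) in enumerate(subtracks):
        track = spec.tracks[ti]
        for ci, w in enumerate(spec.windows):
            ax = fig.add_subplot(gs[1 + si, ci])
            _draw_read_track(ax, spec, track, hp, ci, w, label_col=ci == 0)
            if si == len(subtracks) - 1 and n_ann == 0 and n_gene == 0:
                _x_axis(ax, w)
            else:
                ax.set_xticks([])
    row = 1 + max(len(subtracks), 1)
    for ai, (name, intervals) in enumerate(spec.annotations):
        for ci, w in enumerate(spec.windows):
            ax = fig.add_subplot(gs[row + ai, ci])
            _draw_annotations(ax, style, name if ci == 0 else "", intervals, w)
            if ai == n_ann - 1 and n_gene == 0:
                _x_axis(ax, w)
            else:
                ax.set_xticks([])
    if n_gene:
        for ci, w in enumerate(spec.windows):
            ax = fig.add_subplot(gs[nrows - 1, ci])
            _draw_genes(ax, style, spec.gene_models, w)
            _x_axis(ax, w)
    if spec.sv is not None:
        fig.suptitle(spec.sv.label(), fontsize=9)
    return fig


def _x_axis(ax, w: GenomicWindow) -> None:
    ax.set_xlim(w.start, w.end)
    ticks = np.linspace(w.start, w.end, 4)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{int(t):,}" for t in ticks], fontsize=6)
    ax.set_xlabel(w.chrom, fontsize=7)


def _draw_sv_bar(ax, spec: PlotSpec, w: GenomicWindow) -> None:
    ax.set_xlim(w.start, w.end)
    ax.set_ylim(0, 1)
    ax.axis("off")
    sv = spec.sv
    if sv is None:
        return
    lo = sv.start if not sv.is_interchromosomal or w.chrom == sv.chrom else sv.end
    hi = sv.end if not sv.is_interchromosomal else lo
    if sv.is_interchromosomal:
        ax.plot([lo], [0.5], marker="v", color="#222222", markersize=5)
    else:
        x0, x1 = max(lo, w.start), min(hi, w.end)
        if x0 < x1:
            ax.plot([x0, x1], [0.5, 0.5], lw=4, color="#222222", solid_capstyle="butt")
        for bp, ci in ((sv.start, sv.ci_pos), (sv.end, sv.ci_end)):
            if ci != (0, 0) and w.start <= bp <= w.end:
                ax.plot([bp + ci[0], bp + ci[1]], [0.5, 0.5], lw=1, color="#222222")


def _draw_read_track(ax, spec: PlotSpec, track: TrackSpec, hp: int | None, ci: int,
                     w: GenomicWindow, label_col: bool) -> None:
    style = spec.style
    layout = track.layouts[hp]
    n_rows = max(track.n_rows[hp], 1)
    ax.set_xlim(w.start, w.end)
    ax.set_ylim(-0.5, n_rows + 0.5)
    ax.invert_yaxis()  # row 0 (SV support) on top
    ax.set_yticks([])
    if label_col:
        label = track.label if hp is None else f"{track.label} HP{hp}"
        ax.set_ylabel(label, fontsize=7)

    cov = track.coverage[hp][ci]
    pos, hi, lo = cov.binned()
    if hi.max(initial=0) + lo.max(initial=0) > 0:
        cax = ax.twinx()
        cax.set_xlim(w.start, w.end)
        cax.fill_between(pos, 0, hi, step="post", color=style.coverage_high_color, lw=0, zorder=0)
        cax.fill_between(pos, hi, hi + lo, step="post", color=style.coverage_low_color, lw=0, zorder=0)
        cax.set_ylim(0, max(1.0, float((hi + lo).max()) * 1.05))
        cax.tick_params(axis="y", labelsize=5)
        cax.set_zorder(ax.get_zorder() - 1)
        ax.patch.set_visible(False)

    for read, row in layout:
        color = style.colors.get(read.category.kind, "#333333")
        alpha = 0.45 if read.category.kind == Kind.LOW_CONFIDENCE else 0.9
        segs = [s for s in read.segments if s.chrom == w.chrom]
        for seg in segs:
            x0, x1 = max(seg.start, w.start), min(seg.end, w.end)
            if x0 < x1:
                ax.plot([x0, x1], [row, row], lw=1.6, color=color, alpha=alpha,
                        solid_capstyle="butt", zorder=2)
        # split-segment arcs
        ordered = sorted(segs, key=lambda s: s.query_start)
        for a, b in zip(ordered, ordered[1:]):
            xa, xb = a.end, b.start
            if min(xa, xb) < w.end and max(xa, xb) > w.start:
                patch = mpatches.PathPatch(
                    _arc_path(xa, xb, row, -0.8), fill=False, lw=0.7, color=color, alpha=alpha, zorder=1
                )
                ax.add_patch(patch)
        # pair connector to the mate
        if read.mate is not None and read.mate.chrom == w.chrom and segs:
            left = min(s.end for s in segs)
            if read.mate.start >= left:
                x0, x1 = max(left, w.start), min(read.mate.start, w.end)
                if x0 < x1:
                    ax.plot([x0, x1], [row, row], lw=0.5, color=color, alpha=alpha * 0.7, zorder=1)


def _draw_annotations(ax, style: PlotStyle, name: str, intervals, w: GenomicWindow) -> None:
    ax.set_xlim(w.start, w.end)
    ax.set_ylim(0, 1)
    ax.set_yticks([])
    if name:
        ax.set_ylabel(name, fontsize=6, rotation=0, ha="right", va="center")
    for chrom, start, end, _label in intervals:
        if chrom != w.chrom:
            continue
        x0, x1 = max(start, w.start), min(end, w.end)
        if x0 < x1:
            ax.axvspan(x0, x1, 0.25, 0.75, color=style.annotation_color, alpha=0.7, lw=0)


def _draw_genes(ax, style: PlotStyle, transcripts: list[Transcript], w: GenomicWindow) -> None:
    ax.set_xlim(w.start, w.end)
    n = max(len(transcripts), 1)
    ax.set_ylim(0, n)
    ax.set_yticks([])
    for i, tr in enumerate(t for t in transcripts if t.chrom == w.chrom):
        y = i + 0.5
        x0, x1 = max(tr.start, w.start), min(tr.end, w.end)
        if x0 >= x1:
            continue
        # intron backbone: thin line; exons: thick boxes
        ax.plot([x0, x1], [y, y], lw=0.8, color=style.gene_color, zorder=1)
        for es, ee in tr.exons:
            ex0, ex1 = max(es, w.start), min(ee, w.end)
            if ex0 < ex1:
                ax.plot([ex0, ex1], [y, y], lw=5, color=style.gene_color,
                        solid_capstyle="butt", zorder=2)
        # transcription-direction arrow at the right edge
        direction = 1 if tr.strand == "+" else -1
        ax.annotate(
            "", xy=(x1 + 0.015 * len(w) * direction, y), xytext=(x1, y),
            arrowprops=dict(arrowstyle="-|>", color=style.gene_color, lw=0.8),
            annotation_clip=False,
        )
        ax.text(x0, y + 0.28, tr.name, fontsize=5, color=style.gene_color)
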