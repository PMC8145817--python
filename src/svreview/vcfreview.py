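"""Filter a multi-sample SV VCF and emit a static HTML review gallery.

For every record passing the (optional) filter expression one review image
is rendered; the equivalent shell command is appended to ``commands.sh``
for reproducibility, and ``index.html`` presents a sortable, searchable
table whose rows load the corresponding image.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from string import Template

import pysam

from .filter_lang import FilterExpression, Pedigree, evaluate_filter, parse_filter
from .render import PlotStyle, auto_zoom, build_plot_spec, render_image
from .variants import SVRecord, from_variant_record

log = logging.getLogger(__name__)

__all__ = [
    "parse_filter",
    "evaluate_filter",
    "FilterExpression",
    "Pedigree",
    "ReviewSite",
    "build_review_site",
]


@dataclass
class ReviewSite:
    index_path: str
    commands_path: str
    image_paths: list[str]
    rows: list[dict] = field(default_factory=list)


def _dedupe_mates(records: list[SVRecord]) -> list[SVRecord]:
    """Keep one record per breakend pair (mate identified via MATEID)."""
    seen_ids: set[str] = set()
    out = []
    for rec in records:
        mate = rec.info.get("MATEID")
        if isinstance(mate, (tuple, list)):
            mate = mate[0] if mate else None
        if mate is not None and mate in seen_ids:
            continue
        if rec.record_id:
            seen_ids.add(rec.record_id)
        out.append(rec)
    return out


def _image_name(rec: SVRecord, idx: int) -> str:
    t = rec.svtype or "SV"
    return f"{idx:04d}_{t}_{rec.chrom}_{rec.start}_{rec.end}.png"


def _plot_command(rec: SVRecord, bams: dict[str, str], image: str, min_mapq: int,
                  zoom: int | None) -> str:
    parts = [
        "svreview plot",
        f"-c {rec.chrom}",
        f"-s {rec.start}",
        f"-e {rec.end}",
    ]
    if rec.svtype:
        parts.append(f"-t {rec.svtype}")
    for path in bams.values():
        parts.append(f"-b {path}")
    parts.append(f"--min_mqual {min_mapq}")
    if zoom:
        parts.append(f"--zoom {zoom}")
    parts.append(f"-o {image}")
    return " ".join(parts)


def build_review_site(
    vcf_path: str,
    alignments: dict[str, str],
    expr: FilterExpression | str | None = None,
    pedigree: Pedigree | str | None = None,
    out_dir: str = "review",
    max_variants: int | None = None,
    min_mapq: int = 10,
    style: PlotStyle | None = None,
    seed: int = 0,
    reference: str | None = None,
) -> ReviewSite:
    """Render images and an index page for every record passing ``expr``.

    ``alignments`` maps VCF sample names to BAM/CRAM paths; samples with no
    alignment file are warned about and their tracks omitted.  Paired
    breakend records are plotted once (deduplicated by MATEID).
    """
    if os.path.exists(out_dir) and not os.path.isdir(out_dir):
        raise NotADirectoryError(f"{out_dir} exists and is not a directory")
    os.makedirs(out_dir, exist_ok=True)
    if isinstance(expr, str):
        expr = parse_filter(expr)
    if isinstance(pedigree, str):
        pedigree = Pedigree.read(pedigree)

    with pysam.VariantFile(vcf_path) as vcf:
        vcf_samples = list(vcf.header.samples)
        records = [from_variant_record(r) for r in vcf]
    for sample in vcf_samples:
        if sample not in alignments:
            log.warning("sample %s has no alignment file; its track is omitted", sample)
    usable_bams = {s: p for s, p in alignments.items() if s in vcf_samples or not vcf_samples}
    if not usable_bams:
        usable_bams = dict(alignments)

    records = _dedupe_mates(records)
    passing = [r for r in records if expr is None or evaluate_filter(expr, r, pedigree)]
    if max_variants is not None:
        passing = passing[:max_variants]

    image_paths: list[str] = []
    rows: list[dict] = []
    commands: list[str] = []
    for idx, rec in enumerate(passing):
        image = _image_name(rec, idx)
        zoom = auto_zoom(rec)
        spec = build_plot_spec(
            rec, usable_bams, zoom=zoom, min_mapq=min_mapq, style=style, seed=seed,
            reference=reference,
        )
        out_path = os.path.join(out_dir, image)
        render_image(spec, out_path)
        image_paths.append(out_path)
        commands.append(_plot_command(rec, usable_bams, image, min_mapq, zoom))
        rows.append(
            {
                "image": image,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "svtype": rec.svtype or "",
                "svlen": rec.svlen if rec.svlen is not None else "",
                "genotypes": {s: "/".join("." if a is None else str(a) for a in g) or "./."
                              for s, g in rec.genotypes.items()},
                "info": {k: str(v) for k, v in list(rec.info.items())[:8]},
            }
        )

    commands_path = os.path.join(out_dir, "commands.sh")
    with open(commands_path, "w") as fh:
        fh.write("#!/bin/sh\n# one review-image command per passing variant\n")
        fh.write("\n".join(commands) + ("\n" if commands else ""))

    index_path = os.path.join(out_dir, "index.html")
    with open(index_path, "w") as fh:
        fh.write(_render_index(rows))
    return ReviewSite(index_path, commands_path, image_paths, rows)


_INDEX_TEMPLATE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>SV review gallery</title>
<style>
body { font-family: sans-serif; margin: 1em; }
table { border-collapse: collapse; width: 100%; }
th, td { border: 1px solid #ccc; padding: 4px 8px; font-size: 13px; }
th { cursor: pointer; background: #f0f0f0; }
tr.variant { cursor: pointer; }
tr.variant:hover { background: #eef; }
tr.selected { background: #dde; }
#viewer { margin-top: 1em; }
#viewer img { max-width: 100%; border: 1px solid #aaa; }
</style>
</head>
<body>
<h1>SV review gallery</h1>
<p>$count variants. Click a column header to sort, a row to view its image.</p>
<input id="search" type="text" placeholder="filter table..." size="40">
<table id="variants">
<thead><tr>
<th data-k="chrom">chrom</th><th data-k="start">start</th><th data-k="end">end</th>
<th data-k="svtype">type</th><th data-k="svlen">length</th>
<th>genotypes</th><th>info</th>
</tr></thead>
<tbody></tbody>
</table>
<div id="viewer"></div>
<script>
var rows = $rows_json;
var tbody = document.querySelector('#variants tbody');
function fmt(o){ return Object.entries(o).map(function(e){return e[0]+'='+e[1];}).join(' '); }
function draw(data){
  tbody.innerHTML = '';
  data.forEach(function(r){
    var tr = document.createElement('tr');
    tr.className = 'variant';
    tr.innerHTML = '<td>'+r.chrom+'</td><td>'+r.start+'</td><td>'+r.end+'</td>'+
      '<td>'+r.svtype+'</td><td>'+r.svlen+'</td><td>'+fmt(r.genotypes)+'</td>'+
      '<td>'+fmt(r.info)+'</td>';
    tr.onclick = function(){
      document.querySelectorAll('tr.selected').forEach(function(x){x.classList.remove('selected');});
      tr.classList.add('selected');
      document.getElementById('viewer').innerHTML =
        '<a href="'+r.image+'"><img src="'+r.image+'"></a>';
    };
    tbody.appendChild(tr);
  });
}
document.getElementById('search').oninput = function(){
  var q = this.value.toLowerCase();
  draw(rows.filter(function(r){ return JSON.stringify(r).toLowerCase().indexOf(q) >= 0; }));
};
var asc = {};
document.querySelectorAll('th[data-k]').forEach(function(th){
  th.onclick = function(){
    var k = th.dataset.k;
    asc[k] = !asc[k];
    rows.sort(function(a,b){
      var va=a[k], vb=b[k];
      if (typeof va === 'number' && typeof vb === 'number') return asc[k] ? va-vb : vb-va;
      return asc[k] ? String(va).localeCompare(String(vb)) : String(vb).localeCompare(String(va));
    });
    draw(rows);
  };
});
draw(rows);
</script>
</body>
</html>
"""
)


def _render_index(rows: list[dict]) -> str:
    # inside a <script> block only the closing-tag sequence needs escaping
    return _INDEX_TEMPLATE.substitute(
        count=len(rows), rows_json=json.dumps(rows).replace("</", "<\\/")
    )
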