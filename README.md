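# svreview

Structural variants (SVs) — deletions, duplications, inversions and
translocations larger than 50 bp — are still called with high
false-positive rates by short-read pipelines, and visual inspection of the
alignments around each call remains the most reliable way to separate real
events from artifacts. `svreview` is a toolkit for exactly that curation
loop, aimed at researchers and clinical analysts triaging SV call sets:

* **Review images.** One static image per SV call: the call bar with
  confidence-interval whiskers, one alignment track per sample (split into
  haplotype sub-tracks when HP tags are present), a coverage background
  stratified by mapping quality (dark gray ≥ threshold, light gray below),
  color-coded read glyphs with split/discordant evidence elevated to the
  top rows, plus optional BED annotation and GFF3 gene tracks. Long SVs
  automatically switch to two zoom panels centered on the breakpoints.
* **Evidence classification.** Each read pair is classified from its
  orientation/order/insert configuration (different chromosomes →
  translocation; same strand → inversion; reverse-before-forward →
  duplication; stretched template → deletion), and each split read from
  the reference geometry of its query-adjacent segments (gap → deletion,
  overlap or reversed order → duplication, strand switch → inversion,
  chromosome switch → translocation).
* **VCF galleries.** `svreview vcf` filters a multi-sample SV VCF with a
  small expression language (`SVTYPE == 'DEL' && SVLEN > 500`,
  `het(offspring) && hom_ref(mother) && hom_ref(father)`, …) and emits a
  static HTML gallery: a sortable/searchable table where each row loads
  the corresponding review image, alongside a `commands.sh` that
  reproduces every image.
* **Automated deletion curation.** A small residual CNN (pure numpy,
  ~120k parameters) re-genotypes putative deletions from their review
  images into hom-ref / het / hom-alt. Training regions are sampled with
  principled rules built on the depth fold change
  `DHFFC = mean depth(call) / mean depth(flanks)`: positive candidates
  with DHFFC > 0.7 are rejected (no depth drop → dubious call), and
  negative candidates from caller exclude-regions with DHFFC ≤ 0.7 are
  rejected (possible real deletion). The optimizer is SGD with momentum
  under cosine annealing with warm restarts (initial rate 0.2, first
  restart period 2 epochs, doubling after each restart; with 50 epochs the
  restarts fall at epochs 2, 6, 14 and 30), keeping the checkpoint with
  the best validation loss on held-out chromosomes. Predictions are
  written back into the VCF as a 3-float FORMAT field plus a pass/reject
  call (reject when hom-ref is the most probable class).
* **Known-truth fixtures.** `svreview fixtures` builds synthetic
  references, coordinate-sorted indexed BAMs and truth VCFs in which every
  CIGAR, SA tag, flag and template length is computed analytically from
  the planted haplotype structure — no aligner, bit-reproducible, so every
  other component is testable offline.

## Worked example

```sh
# a 40-kb synthetic sample with a 2-kb heterozygous deletion
svreview fixtures --out-dir demo --length 12000 --sv DEL:5000-7000:HET --seed 3
# -> {"fasta": "demo/sim.fa", "bam": "demo/sim.bam", "vcf": "demo/sim.vcf"}

svreview plot -c chr1 -s 4000 -e 8000 -t DEL -b demo/sim.bam -o demo/del.png
# -> demo/del.png

svreview vcf --vcf demo/sim.vcf --out-dir demo/site \
    --sample-bams sample1=demo/sim.bam --filter "SVTYPE == 'DEL'"
# -> 1 variants -> demo/site/index.html
```

`demo/del.png` shows the deletion-support pairs (long templates bridging
the breakpoints) elevated in orange above the concordant reads, and the
coverage background dropping to roughly half depth inside the call —
the visual signature of a one-copy loss. The gallery's `index.html`
lists the single passing deletion and loads that image on click.

Programmatic use mirrors the CLI: `svreview.evidence.load_alignments`
returns classified reads, `svreview.coverage.fold_change_for_interval`
computes the DHFFC-style metric, `svreview.render.build_plot_spec` /
`render_image` draw, and `svreview.mlfilter` holds the training and
prediction pipeline. See `docs/methods.md` for the models, defaults and
their rationale.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch at the given seed:
it generates a synthetic cohort, classifies its alignment evidence,
computes fold changes, renders a review image and a filtered gallery,
samples training regions under the fold-change rules, trains a short
CNN, predicts on a held-out deletion and annotates its VCF, then writes
the results JSON to `--out`.
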