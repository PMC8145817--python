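# Methods

This note documents the models and procedures implemented in `svreview`,
the defaults chosen where the design was genuinely open, and what the
synthetic fixtures do and do not establish.

## Alignment evidence model

A read is *concordant* when it aligns as a single contiguous segment and,
if paired, its mate sits on the same chromosome in forward–reverse
orientation within the library's expected template length. Departures
carry SV-type information:

**Pair configuration** (applies when both mates are mapped):

| observation | call |
|---|---|
| mates on different chromosomes | translocation support |
| both mates on the same strand | inversion support |
| reverse-strand mate leftmost (RF order) | duplication support (tandem junction) |
| FR order, template length > concordance limit | deletion support |
| FR order within the limit | concordant |

**Split configuration** (query-adjacent segments of one read, from the
primary alignment plus its SA-tag entries, query spans reconstructed
clip-aware and strand-normalized): a chromosome switch is translocation
support, a strand switch inversion support; on one strand, a reference
gap of at least 25 bp in the direction of travel is deletion support and
a reference overlap or order reversal is duplication support. When both
segments are on the reverse strand the roles are swapped first, since
increasing query position then walks the reference right-to-left. The
25-bp floor avoids promoting indel-scale gaps to SV evidence: SVs are
conventionally defined as ≥ 50 bp, and half that is used as a
conservative margin.

Split evidence takes precedence over pair evidence for a read's single
category; among several split junctions the most specific wins
(translocation > inversion > deletion > duplication).

**Concordance limit.** The insert-size threshold is `mean + z·sd` with
z = 3, estimated per plotted window from up to 1000 FR pairs in the
window and its ±5 kb flanks, using the sample standard deviation.
Template lengths above 3× the median are dropped before estimating, so
deletion-spanning pairs cannot inflate the limit. Too few pairs fall
back to an infinite limit (no insert-size discordance is called) unless
the caller supplies explicit statistics.

**Retention of low-quality reads.** Reads below the MAPQ threshold
(default 10) are kept, categorized LOW_CONFIDENCE, drawn at reduced
opacity, and counted in the light-gray coverage stratum — dropping them
would hide mapping-ambiguity signal that a reviewer needs. Secondary and
duplicate records are excluded outright; supplementary records enter
only through their primary's SA tag to avoid double counting. All
non-concordant reads are elevated; no minimum cluster size is required
before a read is highlighted.

## Coverage and depth fold change

Coverage is a per-base pileup of reference-consuming aligned blocks
(CIGAR D/N gaps and clips do not count), split into two strata at the
MAPQ threshold. Windows up to 100 kb stay at base-pair resolution;
larger windows are mean-pooled to at most 10,000 bins for display.

The deletion filter metric is the depth fold change
`region mean total depth / flank mean total depth` with flanks of
1000 bp on each side, truncated at sequence ends (configurable). The
mean uses both MAPQ strata, since the metric describes copy number, not
mappability. Zero flank coverage yields an explicit *uncallable* marker,
never infinity. Expected values: ≈ 1 for two copies, ≈ 0.5 for a
heterozygous deletion, ≈ 0 for a homozygous one; 0.7 is the working
boundary used by the training-data rules below.

## Review images

Window planning: without zoom, the SV interval is padded by half its
length on each side. With zoom (explicitly set, or automatically 1000 bp
for SVs longer than 5000 bp), two zoom-length windows are centered on
the breakpoints and merged into their union when they overlap or abut.
Interchromosomal calls get one window per breakpoint chromosome.

Read layout is greedy interval scheduling into rows; SV-supporting reads
occupy the topmost rows and are never dropped, while concordant reads
are deterministically subsampled (seeded) when the row budget (default
300) is exceeded. Colors: concordant near-black, deletion support
red-orange, duplication red, inversion and translocation blues,
low-confidence gray at reduced opacity; the palette is configurable.
Pair mates are joined by a thin connector, split segments by an arc.
Figure geometry defaults to 8 × 5 inches at 150 dpi; margins are part of
the style so that downstream cropping is exact by construction. SVG
output is byte-stable for a fixed spec and seed.

## VCF filtering language

A deliberately small grammar (comparisons, `&&`/`||`/`!`, parentheses,
`INFO.key` access, `SVTYPE`/`SVLEN`/`CHROM`/`POS`/`END`, genotype
predicates `het/hom_ref/hom_alt/missing` over sample names or pedigree
roles, and `exists(INFO.key)`). `SVLEN` is the magnitude of the SV
length. Missing-value rule: a comparison with a missing operand is
false, and that falseness is sticky through negation — presence is
asserted only via `exists()`. This keeps evaluation total and
predictable without tri-valued logic. Pedigree roles resolve against a
6-column PED file: *offspring* is the first affected individual with
both parents listed; *mother*/*father* are its parents. Paired breakend
records are deduplicated by MATEID so each event is plotted once.
Gene models are read from GFF3 with a minimal transcript/exon reader —
enough to draw intron/exon glyphs and strand arrows without building an
annotation database.

## Deletion re-classification model

**Training regions.** Positive candidates are het / hom-alt deletion
calls from a trusted call set; any with depth fold change above 0.7 is
rejected as showing no copy loss. Negative (hom-ref) candidates combine
calls re-discovered inside caller exclude-regions — enriched for exactly
the false positives a filter must learn — and hom-ref background loci;
any negative with fold change at or below 0.7 is rejected as possibly
hiding a real deletion. The 0.7 boundary is shared by both rules.
Sampling to per-class targets is uniform without replacement and seeded;
an overdrawn target takes all candidates with a warning.

**Images.** Classifier inputs are review images rendered with a compact
style (4 × 2.5 in at 60 dpi), cropped to the axes region using the
style's own margins (no pixel heuristics), block-mean downscaled 8× in
each dimension (floor division, trailing partial blocks discarded) and
normalized to [0, 1]. Deletions longer than 5000 bp use the two 1000-bp
breakpoint zoom panels, mirroring the interactive default.

**Architecture.** A residual CNN written directly in numpy (no
deep-learning framework is available in the target environment): three
stages of stride-2 3×3 convolution + batch norm + ReLU followed by one
identity-skip residual block each (widths 16/32/64), global average
pooling and a 3-way softmax head — about 120k parameters, minutes to
train on a CPU at desk scale. Convolution is im2col + matmul; batch
norm uses the standard backward formulas with running statistics for
inference.

**Optimization.** SGD with momentum 0.9 (momentum is our choice; the
schedule is not tied to it) under cosine annealing with warm restarts:
rate decaying from 0.2 to 0 over each cycle, first cycle 2 epochs,
cycle length doubling at each restart, 50 epochs by default (restarts at
epochs 2, 6, 14, 30). Gradients are clipped to global norm 5 — a
numerical safeguard for the large post-restart rate in float32 without
fused kernels. Batch size defaults to 32. Validation is held out by
chromosome (chr1–chr3 by default) and the checkpoint with the best
validation loss is returned. Desk-scale runs in the tests train 14
epochs (the first three full cycles); the schedule itself is verified
against its closed form separately.

**Output.** For each putative deletion: render → preprocess → forward
pass → probability triplet (hom-ref, het, hom-alt) summing to 1. The
annotated VCF declares `DGP` (3 floats) and `DGC` (pass/reject) FORMAT
fields; a record is rejected when hom-ref is the most probable class,
and records that failed to render get missing values while the pipeline
continues.

## Synthetic fixtures

The generator draws a random reference, builds two haplotypes per
chromosome as block rearrangements (hap A carries hom-alt SVs, hap B all
carrier SVs, so genotypes of co-located calls stay independent), and
samples fragments uniformly: paired ends with normal insert lengths, or
long reads. Alignment records — CIGARs with soft clips, SA tags for
split segments (pieces shorter than 20 bp stay clipped, as an aligner
would leave them), flags, mate fields and signed template lengths — are
derived analytically from the block mapping. Defaults describe a
typical germline short-read library: 150-bp reads, 400 ± 50 bp inserts,
30× depth, error-free; long-read profiles default to 8 ± 2 kb reads at
the same depth accounting.

Insert lengths are truncated at ±2.5 sd: the generator's stated world is
an error-free concordant library, and an unbounded tail would contradict
that by producing statistically "discordant" pairs in negative controls
(the estimated z = 3 limit on the truncated sample sits near 2.86 sd,
safely above the 2.5-sd maximum draw). Optional substitution noise
changes base calls only, never alignment records.

The allele-balance mixing operation retains each fragment of one file
with probability *f* and of the other with 1 − *f*, deciding per
fragment name (hash of seed and name) so mates travel together, and
writes a sorted, indexed merge. Low-coverage region filtering keeps a
region when the mean depth of MAPQ ≥ 10 reads is at least 10×
(inclusive boundary).

What a green test establishes: that the classifiers, pileups, window
planner, filter language, sampling rules, schedule and CNN behave
exactly as specified on data whose truth is known bit-for-bit. What it
does not establish: performance under sequencing error, GC or
mappability bias, breakpoint imprecision, or real caller false-positive
modes — the fixtures deliberately model none of these, and published
large-cohort benchmark numbers are out of scope here.

## Numerical and degenerate-case choices

* Coordinates are 0-based half-open internally; VCF (1-based, anchored
  on the padding base before a symbolic SV) and BED (0-based) convert at
  the parser boundaries.
* "Leftmost" mate of a pair is the smaller start coordinate; ties break
  toward the first-in-template read.
* Insert statistics require ≥ 2 pairs; fewer is an error instructing the
  caller to pass an explicit limit.
* Empty coverage windows are an error; empty read sets still render
  (coverage-only tracks); an empty region list predicts to an empty list.
* Identical split segments raise (malformed supplementary record);
  unparseable SA entries are skipped with a warning.
* Zoom must be positive; fold change with uncovered flanks is
  uncallable, never infinite; mixing fractions outside [0, 1] are
  rejected.

## Known limitations

* Pair classification uses orientation/order/insert only; no assembly or
  realignment, and no minimum-support clustering before evidence is
  highlighted.
* The expression language is intentionally minimal (no arithmetic, no
  per-sample FORMAT access beyond GT classes).
* The CNN supports the three deletion genotype classes only; other SV
  types are rendered but not re-classified.
* Explicit allele balance applies per chromosome, so it is meaningful
  for single-SV chromosomes (the mixture-experiment setting), not for
  several het SVs sharing one chromosome.
* Translocations are simulated as reciprocal exchanges on otherwise
  SV-free chromosomes.
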