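"""Training-region sampling with principled positive/negative rules.

True positives are het / hom-alt deletion calls from a trusted call set,
minus any whose depth fold change exceeds 0.7 (a region whose depth does
not drop is likely a false positive).  True negatives combine two
provenances: calls re-discovered inside caller "exclude regions" (enriched
for the false positives a filter model must learn) and hom-ref background
loci, minus any with fold change at or below 0.7 (which might hide a real
deletion).  Sampling to the requested per-class counts is uniform without
replacement and seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..coverage import FoldChange
from ..variants import SVRecord, iter_vcf

log = logging.getLogger(__name__)

LABELS = ("HOM_REF", "HET_DEL", "HOM_DEL")

#: fold-change boundary shared by both rules: TPs above it are rejected,
#: TNs at or below it are rejected
FOLD_CHANGE_CUTOFF = 0.7


@dataclass(frozen=True)
class TrainingRegion:
    chrom: str
    start: int  # 1-based, inclusive interval per VCF convention
    end: int
    label: str  # HOM_REF | HET_DEL | HOM_DEL
    provenance: str  # callset_tp | exclude_region_fp | hom_ref_background
    fold_change: float | None

    def __post_init__(self) -> None:
        if self.label in ("HET_DEL", "HOM_DEL") and self.provenance != "callset_tp":
            raise ValueError("deletion labels must come from the trusted call set")
        if self.label == "HOM_REF" and self.provenance == "callset_tp":
            raise ValueError("HOM_REF labels cannot carry callset_tp provenance")


def _load_bed_intervals(bed_path: str) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    for ivs in out.values():
        ivs.sort()
    return out


def _intersects(intervals: dict[str, list[tuple[int, int]]], rec: SVRecord) -> bool:
    # rec.start is 1-based; BED is 0-based half-open
    lo, hi = rec.start - 1, rec.end
    return any(s < hi and lo < e for s, e in intervals.get(rec.chrom, ()))


def _fc_value(fold_changes, rec: SVRecord) -> float | None:
    if callable(fold_changes):
        fc = fold_changes(rec.chrom, rec.start, rec.end)
    else:
        fc = fold_changes.get((rec.chrom, rec.start, rec.end))
    if isinstance(fc, FoldChange):
        return fc.value
    return fc


def _records(source) -> list[SVRecord]:
    if isinstance(source, str):
        return list(iter_vcf(source))
    return list(source)


def sample_training_regions(
    callset,
    exclude_regions: str | dict[str, list[tuple[int, int]]],
    recalled_set,
    fold_changes: Callable[[str, int, int], FoldChange | float | None] | dict,
    counts: dict[str, int],
    seed: int,
    sample: str | None = None,
) -> list[TrainingRegion]:
    """Build a labeled region list from the TP/TN rules above.

    ``callset`` / ``recalled_set`` are VCF paths or iterables of
    :class:`~svreview.variants.SVRecord`; ``fold_changes`` maps a region to
    its depth fold change (callable or dict keyed by (chrom, start, end)).
    ``counts`` gives per-label targets, e.g. ``{"HET_DEL": 300, ...}``;
    when a target exceeds the candidates available, all are taken with a
    warning.  Regions with an uncallable fold change are rejected outright.
    """
    intervals = (
        _load_bed_intervals(exclude_regions)
        if isinstance(exclude_regions, str)
        else exclude_regions
    )
    candidates: dict[str, list[TrainingRegion]] = {label: [] for label in LABELS}

    for rec in _records(callset):
        if rec.svtype not in (None, "DEL"):
            continue
        s = sample or (next(iter(rec.genotypes)) if rec.genotypes else None)
        gt = rec.gt_class(s) if s else "missing"
        fc = _fc_value(fold_changes, rec)
        if gt in ("het", "hom_alt"):
            if fc is None or fc > FOLD_CHANGE_CUTOFF:
                continue  # does not look like a real copy loss
            label = "HET_DEL" if gt == "het" else "HOM_DEL"
            candidates[label].append(
                TrainingRegion(rec.chrom, rec.start, rec.end, label, "callset_tp", fc)
            )
        elif gt == "hom_ref":
            if fc is None or fc <= FOLD_CHANGE_CUTOFF:
                continue  # might hide a real deletion
            candidates["HOM_REF"].append(
                TrainingRegion(rec.chrom, rec.start, rec.end, "HOM_REF", "hom_ref_background", fc)
            )

    for rec in _records(recalled_set):
        if rec.svtype not in (None, "DEL"):
            continue
        if not _intersects(intervals, rec):
            continue
        fc = _fc_value(fold_changes, rec)
        if fc is None or fc <= FOLD_CHANGE_CUTOFF:
            continue  # might be a real deletion, not a usable negative
        candidates["HOM_REF"].append(
            TrainingRegion(rec.chrom, rec.start, rec.end, "HOM_REF", "exclude_region_fp", fc)
        )

    rng = np.random.default_rng(seed)
    out: list[TrainingRegion] = []
    for label in LABELS:
        target = counts.get(label, 0)
        pool = sorted(candidates[label], key=lambda r: (r.chrom, r.start, r.end, r.provenance))
        if target >= len(pool):
            if target > len(pool):
                log.warning(
                    "requested %d %s regions but only %d candidates; taking all",
                    target, label, len(pool),
                )
            out.extend(pool)
        else:
            idx = rng.choice(len(pool), size=target, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out
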