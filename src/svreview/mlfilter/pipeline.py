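"""Training harness, prediction and VCF annotation for the deletion model.

The classifier maps a preprocessed review image to probabilities of the
three deletion genotype classes (hom-ref, het, hom-alt).  Validation is
held out by chromosome (chr1-chr3 by default) so the model is never
scored on loci it trained near; the checkpoint with the best validation
loss is kept.  Predictions are written back into the VCF as a
FORMAT field of three floats plus a pass/reject call (reject when the
most likely class is hom-ref, i.e. the call looks like a false positive).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pysam

from ..render import PlotStyle, build_plot_spec, render_image
from ..variants import SVRecord
from .nn import SGD, ResNetClassifier, cross_entropy
from .preprocess import preprocess_image
from .schedule import TrainingSchedule

log = logging.getLogger(__name__)

CLASS_NAMES = ("HOM_REF", "HET_DEL", "HOM_DEL")
DEFAULT_VALIDATION_CHROMS = ("chr1", "chr2", "chr3", "1", "2", "3")

#: mirror of the image-generation rule: breakpoint zoom panels of 1000 bp
#: for deletions longer than 5000 bp
ZOOM_BP = 1000
ZOOM_THRESHOLD = 5000

PROB_FORMAT = "DGP"  # deletion genotype probabilities (hom-ref, het, hom-alt)
CALL_FORMAT = "DGC"  # pass/reject call derived from the argmax


def ml_plot_style() -> PlotStyle:
    """Compact render style for classifier images.

    Smaller and plainer than the interactive default: the CNN needs the
    coverage silhouette and read glyphs, not labels; small rasters keep
    desk-scale training in CPU minutes."""
    return PlotStyle(fig_width=4.0, fig_height=2.5, dpi=60, max_rows=120)


@dataclass
class TrainingLogEntry:
    epoch: int
    lr_start: float
    train_loss: float
    val_loss: float
    val_acc: float


@dataclass
class TrainedModel:
    model: ResNetClassifier
    schedule: TrainingSchedule
    style: PlotStyle
    min_mapq: int = 10
    log: list[TrainingLogEntry] = field(default_factory=list)
    step_lrs: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(images)

    def save(self, path: str) -> None:
        """Single-file .npz: weights plus embedded render/preprocess config."""
        cfg = {
            "input_shape": list(self.model.input_shape),
            "widths": list(self.model.widths),
            "n_classes": self.model.n_classes,
            "min_mapq": self.min_mapq,
            "style": {
                k: getattr(self.style, k)
                for k in (
                    "fig_width", "fig_height", "dpi", "margin_left", "margin_right",
                    "margin_bottom", "margin_top", "max_rows",
                )
            },
            "schedule": {
                k: getattr(self.schedule, k)
                for k in (
                    "initial_lr", "min_lr", "initial_restart_period",
                    "period_multiplier", "total_epochs", "batch_size", "momentum",
                )
            },
        }
        state = self.model.get_state()
        np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        model = ResNetClassifier(
            tuple(cfg["input_shape"]), n_classes=cfg["n_classes"], widths=tuple(cfg["widths"])
        )
        model.set_state({k: data[k] for k in data.files if k != "__config__"})
        style = PlotStyle(**cfg["style"])
        schedule = TrainingSchedule(**cfg["schedule"])
        return cls(model=model, schedule=schedule, style=style, min_mapq=cfg["min_mapq"])


def train_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    chroms: list[str],
    schedule: TrainingSchedule | None = None,
    validation_chroms: tuple[str, ...] = DEFAULT_VALIDATION_CHROMS,
    widths: tuple[int, ...] = (16, 32, 64),
    style: PlotStyle | None = None,
    min_mapq: int = 10,
    seed: int = 0,
) -> TrainedModel:
    """Train the residual classifier under the warm-restart schedule.

    ``images`` is (N, H, W, C) in [0, 1]; ``labels`` indexes CLASS_NAMES;
    ``chroms`` gives each region's chromosome for the held-out-chromosome
    validation split.  The returned model is the checkpoint minimizing
    validation loss.  Raises when a class is absent from the training
    partition.
    """
    schedule = schedule or TrainingSchedule()
    style = style or ml_plot_style()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    chroms = np.asarray(chroms)
    val_mask = np.isin(chroms, validation_chroms)
    if not val_mask.any() or val_mask.all():
        raise ValueError("validation split by chromosome produced an empty partition")
    x_train, y_train = images[~val_mask], labels[~val_mask]
    x_val, y_val = images[val_mask], labels[val_mask]
    present = set(np.unique(y_train))
    for ci, name in enumerate(CLASS_NAMES[: int(labels.max()) + 1]):
        if ci not in present:
            raise ValueError(f"class {name} absent from the training partition")

    model = ResNetClassifier(images.shape[1:], n_classes=len(CLASS_NAMES), widths=widths, seed=seed)
    opt = SGD(model, momentum=schedule.momentum)
    rng = np.random.default_rng(seed)
    n = len(x_train)
    bs = schedule.batch_size
    n_batches = max(1, (n + bs - 1) // bs)

    trained = TrainedModel(model=model, schedule=schedule, style=style, min_mapq=min_mapq)
    best_loss = np.inf
    best_state = model.get_state()
    for epoch in range(schedule.total_epochs):
        perm = rng.permutation(n)
        losses = []
        for bi in range(n_batches):
            idx = perm[bi * bs : (bi + 1) * bs]
            if len(idx) == 0:
                continue
            lr = schedule.lr_at(epoch + bi / n_batches)
            trained.step_lrs.append(lr)
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        val_logits = model.forward(x_val, train=False)
        val_loss, _ = cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        trained.log.append(
            TrainingLogEntry(epoch, schedule.lr_at(epoch), float(np.mean(losses)), val_loss, val_acc)
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            trained.best_epoch = epoch
    model.set_state(best_state)
    return trained


def render_region_image(
    rec: SVRecord,
    bam_paths: dict[str, str],
    style: PlotStyle,
    out_path: str,
    min_mapq: int = 10,
    seed: int = 0,
    reference: str | None = None,
) -> str:
    zoom = ZOOM_BP if (rec.svlen or 0) > ZOOM_THRESHOLD else None
    spec = build_plot_spec(
        rec, bam_paths, zoom=zoom, min_mapq=min_mapq, style=style, seed=seed, reference=reference
    )
    return render_image(spec, out_path)


def images_for_regions(
    records: list[SVRecord],
    bam_paths: dict[str, str],
    style: PlotStyle,
    min_mapq: int = 10,
    seed: int = 0,
    reference: str | None = None,
    workdir: str | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Render + preprocess each region; returns (tensor stack, indices of
    regions that failed to render and were marked uncallable)."""
    tensors = []
    failed: list[int] = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for i, rec in enumerate(records):
            out = os.path.join(tmp, f"region{i}.png")
            try:
                render_region_image(rec, bam_paths, style, out, min_mapq, seed, reference)
                tensors.append(preprocess_image(out, style.crop_box()))
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("region %s uncallable: %s", rec.label(), exc)
                failed.append(i)
                tensors.append(None)
    shapes = {t.shape for t in tensors if t is not None}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent image shapes {shapes}")
    shape = shapes.pop() if shapes else (1, 1, 3)
    stack = np.stack([t if t is not None else np.zeros(shape) for t in tensors]) if tensors else np.zeros((0, *shape))
    return stack.astype(np.float32), failed


def predict_genotypes(
    trained: TrainedModel,
    records: list[SVRecord],
    bam_paths: dict[str, str],
    seed: int = 0,
    reference: str | None = None,
) -> list[tuple[float, float, float] | None]:
    """Per-region probability triplets (hom-ref, het, hom-alt); None marks a
    region that could not be rendered."""
    if not records:
        return []
    images, failed = images_for_regions(
        records, bam_paths, trained.style, trained.min_mapq, seed, reference
    )
    probs = trained.predict_proba(images)
    out: list[tuple[float, float, float] | None] = []
    for i in range(len(records)):
        if i in failed:
            out.append(None)
        else:
            out.append(tuple(float(p) for p in probs[i]))
    return out


def annotate_vcf(
    vcf_in: str,
    predictions: dict[tuple[str, int, int], tuple[float, float, float] | None],
    vcf_out: str,
    sample: str | None = None,
) -> str:
    """Write genotype probabilities and the pass/reject call into FORMAT.

    ``predictions`` is keyed by (chrom, pos, end) in VCF coordinates.
    Records without a prediction get missing values.  A record is rejected
    when hom-ref is the most probable class.
    """
    with pysam.VariantFile(vcf_in) as vin:
        header = vin.header.copy()
        if PROB_FORMAT not in header.formats:
            header.formats.add(
                PROB_FORMAT, 3, "Float",
                "Deletion genotype probabilities (hom-ref, het, hom-alt)",
            )
        if CALL_FORMAT not in header.formats:
            header.formats.add(
                CALL_FORMAT, 1, "String",
                "Deletion re-classification call (pass/reject; reject when hom-ref is most probable)",
            )
        samples = list(header.samples)
        target = sample or (samples[0] if samples else None)
        with pysam.VariantFile(vcf_out, "w", header=header) as vout:
            for rec in vin:
                out_rec = rec.copy()
                out_rec.translate(header)
                key = (rec.chrom, rec.pos, rec.stop)
                probs = predictions.get(key)
                if probs is not None and target is not None:
                    out_rec.samples[target][PROB_FORMAT] = tuple(round(p, 6) for p in probs)
                    call = "reject" if int(np.argmax(probs)) == 0 else "pass"
                    out_rec.samples[target][CALL_FORMAT] = call
                vout.write(out_rec)
    return vcf_out
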