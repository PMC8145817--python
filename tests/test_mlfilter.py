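"""ML pipeline units: SGDR schedule, sampling rules, preprocessing, training."""

import math

import numpy as np
import pysam
import pytest

from svreview.mlfilter import (
    TrainingRegion,
    TrainingSchedule,
    annotate_vcf,
    preprocess_image,
    sample_training_regions,
    train_classifier,
)
from svreview.mlfilter.nn import ResNetClassifier, SGD, cross_entropy, softmax
from svreview.mlfilter.preprocess import block_mean
from svreview.variants import SVRecord


class TestSchedule:
    SCHED = TrainingSchedule()  # lr 0.2, period 2 doubling, 50 epochs

    def test_restarts_at_documented_epochs(self):
        assert self.SCHED.restart_epochs() == [2, 6, 14, 30]

    def test_lr_resets_to_initial_at_each_restart(self):
        for epoch in [0] + self.SCHED.restart_epochs():
            assert self.SCHED.lr_at(epoch) == pytest.approx(0.2)

    def test_closed_form_cosine_everywhere(self):
        starts = [0, 2, 6, 14, 30]
        periods = [2, 4, 8, 16, 32]
        for epoch in np.arange(0, 50, 0.125):
            ci = max(i for i, s in enumerate(starts) if epoch >= s)
            t = epoch - starts[ci]
            expected = 0.1 * (1 + math.cos(math.pi * t / periods[ci]))
            assert self.SCHED.lr_at(float(epoch)) == pytest.approx(expected, abs=1e-12)

    def test_lr_vanishes_at_cycle_end(self):
        assert self.SCHED.lr_at(5.999) == pytest.approx(0.0, abs=1e-5)


def _rec(chrom, start, end, gt):
    return SVRecord(chrom, start, end, "DEL", genotypes={"s": gt},
                    info={"SVLEN": -(end - start)})


class TestRegionSampling:
    EXCLUDE = {"chr1": [(10_000, 20_000)]}

    def fold_changes(self):
        return {
            ("chr1", 1000, 2000): 0.45,   # genuine het
            ("chr1", 3000, 4000): 0.80,   # het call without a depth drop
            ("chr1", 5000, 6000): 0.05,   # genuine hom
            ("chr1", 7000, 8000): 0.95,   # hom-ref background
            ("chr1", 11_000, 12_000): 0.50,  # excluded-region call, real drop
            ("chr1", 13_000, 14_000): 0.95,  # excluded-region call, flat depth
            ("chr1", 25_000, 26_000): 0.95,  # recalled but outside excludes
        }

    def callset(self):
        return [
            _rec("chr1", 1000, 2000, (0, 1)),
            _rec("chr1", 3000, 4000, (0, 1)),
            _rec("chr1", 5000, 6000, (1, 1)),
            _rec("chr1", 7000, 8000, (0, 0)),
        ]

    def recalled(self):
        return [
            _rec("chr1", 11_000, 12_000, (0, 1)),
            _rec("chr1", 13_000, 14_000, (0, 1)),
            _rec("chr1", 25_000, 26_000, (0, 1)),
        ]

    def sample(self, counts, seed=0):
        return sample_training_regions(
            self.callset(), self.EXCLUDE, self.recalled(), self.fold_changes(),
            counts, seed=seed, sample="s",
        )

    def test_tp_with_high_fold_change_rejected(self):
        regions = self.sample({"HET_DEL": 10})
        starts = [r.start for r in regions if r.label == "HET_DEL"]
        assert starts == [1000]  # the 0.8-fold-change het is gone

    def test_tn_with_low_fold_change_rejected(self):
        regions = self.sample({"HOM_REF": 10})
        starts = sorted(r.start for r in regions if r.label == "HOM_REF")
        assert 11_000 not in starts  # looks like a real deletion

    def test_exclude_region_negative_kept_with_provenance(self):
        regions = self.sample({"HOM_REF": 10})
        by_start = {r.start: r for r in regions}
        assert by_start[13_000].provenance == "exclude_region_fp"
        assert by_start[7000].provenance == "hom_ref_background"
        assert 25_000 not in by_start  # outside the exclude intervals

    def test_hom_del_candidates(self):
        regions = self.sample({"HOM_DEL": 10})
        assert [r.start for r in regions] == [5000]

    def test_seeded_sampling_reproducible(self):
        a = self.sample({"HOM_REF": 1, "HET_DEL": 1}, seed=3)
        b = self.sample({"HOM_REF": 1, "HET_DEL": 1}, seed=3)
        assert a == b

    def test_overdrawn_target_takes_all_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            regions = self.sample({"HET_DEL": 99})
        assert len([r for r in regions if r.label == "HET_DEL"]) == 1
        assert "taking all" in caplog.text

    def test_label_provenance_invariant(self):
        with pytest.raises(ValueError, match="call set"):
            TrainingRegion("chr1", 1, 2, "HET_DEL", "hom_ref_background", 0.5)


class TestPreprocess:
    def test_eightfold_dimension_arithmetic(self):
        img = np.ones((750, 1200, 3))
        tensor = preprocess_image(img, crop_box=(100, 60, 1124, 700))  # 1024 x 640 crop
        assert tensor.shape == (80, 128, 3)

    def test_uniform_white_stays_one(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        tensor = preprocess_image(img)
        assert np.allclose(tensor, 1.0)

    def test_half_black_half_white_block_means(self):
        img = np.zeros((16, 16, 3))
        img[:, 8:] = 1.0
        tensor = block_mean(img, 8)
        assert tensor.shape == (2, 2, 3)
        assert np.allclose(tensor[:, 0], 0.0)
        assert np.allclose(tensor[:, 1], 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_block_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((40, 56, 3))
        tensor = block_mean(img, 8)
        for bi in range(5):
            for bj in range(7):
                block = img[bi * 8 : (bi + 1) * 8, bj * 8 : (bj + 1) * 8]
                assert np.allclose(tensor[bi, bj], block.mean(axis=(0, 1)))

    def test_image_smaller_than_crop_rejected(self):
        with pytest.raises(ValueError, match="crop box"):
            preprocess_image(np.ones((50, 50, 3)), crop_box=(0, 0, 100, 100))


class TestNetwork:
    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = softmax(rng.standard_normal((8, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_analytic_gradient_matches_numeric(self):
        rng = np.random.default_rng(1)
        model = ResNetClassifier((8, 8, 3), widths=(4,), seed=0)
        x = rng.standard_normal((3, 8, 8, 3)).astype(np.float32)
        y = np.array([0, 1, 2])
        logits = model.forward(x, train=True)
        _, dlogits = cross_entropy(logits, y)
        model.backward(dlogits)
        params, grads = model.parameters(), model.gradients()
        for pi in (0, len(params) // 2, len(params) - 2):
            flat = params[pi].reshape(-1)
            idx = int(rng.integers(0, flat.size))
            eps, orig = 1e-3, flat[idx]
            flat[idx] = orig + eps
            lp = cross_entropy(model.forward(x, train=True), y)[0]
            flat[idx] = orig - eps
            lm = cross_entropy(model.forward(x, train=True), y)[0]
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = float(grads[pi].reshape(-1)[idx])
            assert numeric == pytest.approx(analytic, abs=2e-2)

    def test_sgd_descends_on_separable_data(self):
        rng = np.random.default_rng(2)
        x = np.zeros((60, 8, 8, 3), dtype=np.float32)
        y = np.repeat([0, 1, 2], 20)
        for i, label in enumerate(y):
            x[i, :, :, label] = 1.0
            x[i] += rng.standard_normal((8, 8, 3)).astype(np.float32) * 0.2
        model = ResNetClassifier((8, 8, 3), widths=(8,), seed=3)
        opt = SGD(model)
        for _ in range(30):
            logits = model.forward(x, train=True)
            loss, d = cross_entropy(logits, y)
            model.backward(d)
            opt.step(0.05)
        assert (model.predict_proba(x).argmax(axis=1) == y).mean() >= 0.95


def synthetic_class_images(n_per_class, rng, shape=(16, 24, 3)):
    """Arrays that mimic the three coverage silhouettes: full depth, half
    depth, near-zero depth in the middle third."""
    h, w, c = shape
    xs, ys, chroms = [], [], []
    mid = slice(w // 3, 2 * w // 3)
    for label, level in ((0, 1.0), (1, 0.5), (2, 0.05)):
        for i in range(n_per_class):
            img = np.ones(shape, dtype=np.float32)
            img[:, mid] = level
            img += rng.standard_normal(shape).astype(np.float32) * 0.1
            xs.append(img)
            ys.append(label)
            chroms.append(f"chr{(len(xs) % 6) + 1}")
    return np.stack(xs), np.array(ys), chroms


class TestTraining:
    def test_missing_class_in_training_partition_is_named(self):
        rng = np.random.default_rng(0)
        x, y, chroms = synthetic_class_images(6, rng)
        # push every HOM_DEL example into the validation chromosomes
        chroms = ["chr1" if label == 2 else "chr5" for label in y]
        with pytest.raises(ValueError, match="HOM_DEL"):
            train_classifier(x, y, chroms, TrainingSchedule(total_epochs=2))

    def test_learns_separable_classes_quickly(self):
        rng = np.random.default_rng(4)
        x, y, chroms = synthetic_class_images(30, rng)
        trained = train_classifier(
            x, y, chroms, TrainingSchedule(total_epochs=10, batch_size=16),
            widths=(8, 16), seed=0,
        )
        assert trained.log[trained.best_epoch].val_acc >= 0.9

    def test_step_lrs_follow_schedule(self):
        rng = np.random.default_rng(5)
        x, y, chroms = synthetic_class_images(8, rng)
        sched = TrainingSchedule(total_epochs=4, batch_size=16)
        trained = train_classifier(x, y, chroms, sched, widths=(4,), seed=0)
        n_batches = max(1, (int((~np.isin(chroms, ("chr1", "chr2", "chr3"))).sum()) + 15) // 16)
        expected = [
            sched.lr_at(e + b / n_batches)
            for e in range(4) for b in range(n_batches)
        ]
        assert trained.step_lrs == pytest.approx(expected)


class TestAnnotateVcf:
    @pytest.fixture()
    def small_vcf(self, tmp_path):
        from svreview.fixtures import SVSpec, write_truth_vcf

        path = str(tmp_path / "calls.vcf")
        write_truth_vcf(
            path, {"chr1": 50_000},
            [
                SVSpec("DEL", "chr1", 10_000, 12_000, "HET"),
                SVSpec("DEL", "chr1", 20_000, 22_000, "HOM_ALT"),
                SVSpec("DEL", "chr1", 30_000, 32_000, "HET"),
            ],
            sample="s1",
        )
        return path

    def test_probabilities_and_calls_written(self, small_vcf, tmp_path):
        out = str(tmp_path / "annotated.vcf")
        predictions = {
            ("chr1", 10_000, 12_000): (0.9, 0.05, 0.05),   # looks hom-ref: reject
            ("chr1", 20_000, 22_000): (0.1, 0.8, 0.1),     # het: keep
        }
        annotate_vcf(small_vcf, predictions, out, sample="s1")
        with pysam.VariantFile(out) as vcf:
            assert "DGP" in vcf.header.formats
            assert vcf.header.formats["DGP"].number == 3
            recs = list(vcf)
        assert recs[0].samples["s1"]["DGC"] == "reject"
        assert recs[1].samples["s1"]["DGC"] == "pass"
        probs = recs[1].samples["s1"]["DGP"]
        assert sum(probs) == pytest.approx(1.0, abs=1e-5)
        # record without a prediction carries missing values
        assert recs[2].samples["s1"].get("DGC") is None

    def test_record_count_conserved(self, small_vcf, tmp_path):
        out = str(tmp_path / "annotated.vcf")
        annotate_vcf(small_vcf, {}, out)
        with pysam.VariantFile(small_vcf) as a, pysam.VariantFile(out) as b:
            assert len(list(a)) == len(list(b))
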