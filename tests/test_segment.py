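from __future__ import annotations

import numpy as np
import pytest

from histoquant.errors import DegenerateHistogramError, ModelStateError
from histoquant.images import BinaryMask, CalibratedImage, ROIBox
from histoquant.segment import (
    THRESHOLD_METHODS,
    PixelClassifier,
    auto_threshold,
    threshold_from_histogram,
    threshold_per_roi,
    train_pixel_classifier,
)

from oracles import THRESHOLD_SCANS, li_fixed_point


def bimodal_image(rng, lo=20, hi=200, frac_hi=0.3, shape=(64, 64), sd=5.0):
    pixels = rng.normal(lo, sd, shape)
    sel = rng.random(shape) < frac_hi
    pixels[sel] = rng.normal(hi, sd, sel.sum())
    return CalibratedImage(np.clip(pixels, 0, None), 1.0)


class TestAutoThreshold:
    def test_otsu_two_spikes_matches_scan(self):
        values = np.concatenate([np.full(900, 10.0), np.full(100, 200.0)])
        img = CalibratedImage(values.reshape(20, 50), 1.0)
        result, mask = auto_threshold(img, "otsu")
        assert result.bin_index == THRESHOLD_SCANS["otsu"](result.histogram)
        assert mask.pixels.sum() == 100

    def test_mean_spikes(self):
        values = np.concatenate([np.zeros(50), np.full(50, 100.0)])
        result, mask = auto_threshold(CalibratedImage(values.reshape(10, 10), 1.0), "mean")
        assert result.threshold == pytest.approx(50.0)
        assert mask.pixels.sum() == 50

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            auto_threshold(CalibratedImage(np.full((10, 10), 7.0), 1.0), "otsu")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            auto_threshold(CalibratedImage(np.arange(100.0).reshape(10, 10), 1.0), "magic")

    def test_threshold_within_range(self, rng):
        img = bimodal_image(rng)
        for method in THRESHOLD_METHODS:
            result, _ = auto_threshold(img, method)
            assert img.pixels.min() <= result.threshold <= img.pixels.max()

    def test_restriction_changes_histogram(self, rng):
        img = bimodal_image(rng)
        restrict = BinaryMask(img.pixels > 100, 1.0)
        result, _ = auto_threshold(img, "otsu", restrict=restrict)
        full, _ = auto_threshold(img, "otsu")
        assert result.threshold != full.threshold

    @pytest.mark.parametrize("method", THRESHOLD_METHODS)
    def test_oracle_agreement_random_histograms(self, method, rng):
        for _ in range(20):
            h = rng.integers(0, 1000, 256)
            if np.count_nonzero(h) < 2:
                continue
            assert threshold_from_histogram(h, method) == THRESHOLD_SCANS[method](h)

    def test_li_scan_consistent_with_fixed_point(self, rng):
        # smooth bimodal histograms: the Li iteration lands on the scan's bin
        for _ in range(20):
            h = rng.poisson(5, 256)
            c1 = int(rng.integers(30, 90))
            c2 = int(rng.integers(140, 220))
            h[c1 - 15 : c1 + 15] += rng.poisson(800, 30)
            h[c2 - 15 : c2 + 15] += rng.poisson(400, 30)
            scan = threshold_from_histogram(h, "li")
            assert abs(scan - li_fixed_point(h)) <= 1.5

    def test_mask_monotone_in_threshold(self, rng):
        img = bimodal_image(rng)
        result, mask = auto_threshold(img, "otsu")
        one_bin = result.bin_edges[1] - result.bin_edges[0]
        higher = img.pixels > (result.threshold + one_bin)
        assert not (higher & ~mask.pixels).any()


class TestThresholdPerRoi:
    def test_independent_thresholds(self, rng):
        pixels = np.zeros((40, 80))
        pixels[:, :40] = rng.normal(30, 3, (40, 40))
        pixels[:, 40:] = rng.normal(180, 3, (40, 40))
        pixels[::7, :] = 250.0  # bright rows so each crop is bimodal
        img = CalibratedImage(pixels, 1.0)
        rois = [ROIBox((0, 0), (40, 40)), ROIBox((0, 40), (40, 40))]
        out = threshold_per_roi(img, rois, "otsu")
        assert len(out) == 2
        assert out[0].result.threshold != out[1].result.threshold

    def test_constant_roi_flagged(self):
        pixels = np.zeros((20, 40))
        pixels[:, 20:] = np.arange(20 * 20).reshape(20, 20)
        img = CalibratedImage(pixels, 1.0)
        out = threshold_per_roi(img, [ROIBox((0, 0), (20, 20)), ROIBox((0, 20), (20, 20))])
        assert out[0].degenerate and out[0].result is None
        assert not out[0].mask.pixels.any()
        assert not out[1].degenerate

    def test_stationary_image_rois_match_whole(self, rng):
        # identical ROI statistics: per-ROI thresholds sit in the same
        # inter-mode valley, so the classifications agree almost everywhere
        img = bimodal_image(rng, shape=(128, 128))
        whole, whole_mask = auto_threshold(img, "otsu")
        rois = [ROIBox((0, 0), (64, 64)), ROIBox((64, 64), (64, 64))]
        for item in threshold_per_roi(img, rois, "otsu"):
            crop = whole_mask.pixels[item.roi.slices()]
            agreement = (item.mask.pixels == crop).mean()
            assert agreement > 0.999
            assert abs(item.result.threshold - whole.threshold) < 10.0

    def test_roi_outside_rejected(self, rng):
        img = bimodal_image(rng)
        with pytest.raises(ValueError):
            threshold_per_roi(img, [ROIBox((60, 60), (10, 10))])


@pytest.fixture(scope="module")
def separable_training():
    rng = np.random.default_rng(7)
    images, labels = [], []
    for _ in range(2):
        pixels = rng.normal(20, 5, (48, 48))
        blob = np.zeros((48, 48), bool)
        blob[10:30, 10:30] = True
        pixels[blob] = rng.normal(200, 5, blob.sum())
        lab = np.zeros((48, 48), np.uint8)
        lab[12:28, 12:28] = 1
        lab[:8, :] = 2
        images.append(CalibratedImage(np.clip(pixels, 0, None), 1.0))
        labels.append(lab)
    return images, labels


class TestPixelClassifier:
    def test_separable_accuracy(self, separable_training):
        images, labels = separable_training
        model = train_pixel_classifier(images, labels, n_trees=30, seed=0)
        mask = model.predict(images[0])
        lab = labels[0]
        labeled = lab != 0
        agree = (mask.pixels[labeled] == (lab[labeled] == 1)).mean()
        assert agree >= 0.95

    def test_constant_images_classified(self, separable_training):
        images, labels = separable_training
        model = train_pixel_classifier(images, labels, n_trees=30, seed=0)
        hi = CalibratedImage(np.full((24, 24), 200.0), 1.0)
        lo = CalibratedImage(np.full((24, 24), 20.0), 1.0)
        assert model.predict(hi).pixels.all()
        assert not model.predict(lo).pixels.any()

    def test_single_class_rejected(self, separable_training):
        images, labels = separable_training
        only_pos = [np.where(l == 1, 1, 0).astype(np.uint8) for l in labels]
        with pytest.raises(ValueError):
            train_pixel_classifier(images, only_pos)

    def test_untrained_predict_rejected(self):
        with pytest.raises(ModelStateError):
            PixelClassifier().predict(CalibratedImage(np.zeros((8, 8)), 1.0))

    def test_deterministic_given_seed(self, separable_training):
        images, labels = separable_training
        m1 = train_pixel_classifier(images, labels, n_trees=20, seed=3)
        m2 = train_pixel_classifier(images, labels, n_trees=20, seed=3)
        p1 = m1.predict(images[1]).pixels
        p2 = m2.predict(images[1]).pixels
        np.testing.assert_array_equal(p1, p2)

    def test_save_load_round_trip(self, separable_training, tmp_path):
        images, labels = separable_training
        model = train_pixel_classifier(images, labels, n_trees=20, seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = PixelClassifier.load(path)
        np.testing.assert_array_equal(
            model.predict(images[0]).pixels, loaded.predict(images[0]).pixels
        )
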