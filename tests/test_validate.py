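from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import MultiPolygon, Polygon

from histoquant.errors import SamplingError
from histoquant.images import BinaryMask, CalibratedImage, PointSet, RegionOutline
from histoquant.quantify import intersection_over_union
from histoquant.validate import (
    apply_inclusion_rules,
    detection_dice,
    match_points,
    observer_report,
    pixel_metrics,
    sample_validation_rois,
)

from oracles import max_matching_cardinality


def mask_of(array, scale=1.0):
    return BinaryMask(np.asarray(array, dtype=bool), scale)


class TestPixelMetrics:
    def test_identical_masks(self, rng):
        m = mask_of(rng.random((20, 20)) > 0.5)
        metrics = pixel_metrics(m, m)
        assert metrics.sensitivity == 1.0
        assert metrics.specificity == 1.0
        assert metrics.dice == 1.0

    def test_half_hits_half_false_positives(self):
        ref = np.zeros((4, 4), bool)
        ref[0, :4] = True  # 4 positives
        comp = np.zeros((4, 4), bool)
        comp[0, :2] = True  # hits 2
        comp[1, :2] = True  # 2 false positives
        metrics = pixel_metrics(mask_of(ref), mask_of(comp))
        assert metrics.dice == pytest.approx(0.5)
        assert metrics.confusion.tp == 2
        assert metrics.confusion.fp == 2
        assert metrics.confusion.fn == 2

    def test_all_negative_comparator(self):
        ref = np.zeros((5, 5), bool)
        ref[2, 2] = True
        metrics = pixel_metrics(mask_of(ref), mask_of(np.zeros((5, 5))))
        assert metrics.sensitivity == 0.0
        assert metrics.dice == 0.0

    def test_undefined_flags_not_zero(self):
        empty = mask_of(np.zeros((5, 5)))
        metrics = pixel_metrics(empty, empty)
        assert metrics.sensitivity is None  # 0/0 sensitivity
        assert metrics.dice is None  # 0/0 dice
        assert metrics.specificity == 1.0
        full = mask_of(np.ones((5, 5)))
        assert pixel_metrics(full, full).specificity is None

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_metrics(mask_of(np.zeros((4, 4))), mask_of(np.zeros((5, 5))))

    def test_confusion_totals(self, rng):
        a = mask_of(rng.random((16, 16)) > 0.4)
        b = mask_of(rng.random((16, 16)) > 0.6)
        c = pixel_metrics(a, b).confusion
        assert c.total == 256

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_dice_iou_identity(self, seed):
        r = np.random.default_rng(seed)
        a = mask_of(r.random((12, 12)) > 0.5)
        b = mask_of(r.random((12, 12)) > 0.5)
        dice = pixel_metrics(a, b).dice
        iou = intersection_over_union(a, b)
        if iou is None:
            assert dice is None
        else:
            assert dice == pytest.approx(2 * iou / (1 + iou))


class TestMatchPoints:
    def test_simple_pair(self):
        m = match_points(PointSet([[0, 0]]), PointSet([[0, 3]]), 5.0)
        assert len(m.pairs) == 1
        assert m.pairs[0][2] == pytest.approx(3.0)

    def test_beyond_radius(self):
        m = match_points(PointSet([[0, 0]]), PointSet([[0, 6]]), 5.0)
        assert not m.pairs
        assert m.unmatched_reference == [0]
        assert m.unmatched_comparator == [0]

    def test_globally_nearest_first(self):
        # comparator point is closer to ref 0 (d=2) than ref 1 (d=3)
        m = match_points(PointSet([[0, 0], [0, 5]]), PointSet([[0, 2]]), 5.0)
        assert m.pairs == [(0, 0, pytest.approx(2.0))]
        assert m.unmatched_reference == [1]

    def test_each_point_used_once(self, rng):
        ref = PointSet(rng.uniform(0, 30, (15, 2)))
        comp = PointSet(rng.uniform(0, 30, (15, 2)))
        m = match_points(ref, comp, 5.0)
        ref_idx = [p[0] for p in m.pairs]
        comp_idx = [p[1] for p in m.pairs]
        assert len(set(ref_idx)) == len(ref_idx)
        assert len(set(comp_idx)) == len(comp_idx)
        assert all(p[2] <= 5.0 for p in m.pairs)

    def test_cardinality_matches_exhaustive_optimum(self, rng):
        # instances mirror validation-ROI geometry: <= 12 annotations spread
        # over a 100x100 um crop, matched at the 5 um rule
        for _ in range(40):
            nr, nc = rng.integers(0, 13, 2)
            ref = rng.uniform(0, 100, (nr, 2))
            comp = rng.uniform(0, 100, (nc, 2))
            m = match_points(PointSet(ref), PointSet(comp), 5.0)
            assert len(m.pairs) == max_matching_cardinality(ref, comp, 5.0)

    def test_order_invariance(self, rng):
        pts = rng.uniform(0, 10, (8, 2))
        comp = rng.uniform(0, 10, (8, 2))
        m1 = match_points(PointSet(pts), PointSet(comp), 5.0)
        perm = rng.permutation(8)
        m2 = match_points(PointSet(pts[perm]), PointSet(comp), 5.0)
        pairs1 = {(tuple(pts[i]), j) for i, j, _ in m1.pairs}
        pairs2 = {(tuple(pts[perm][i]), j) for i, j, _ in m2.pairs}
        assert pairs1 == pairs2


class TestDetectionDice:
    def test_two_thirds(self):
        m = match_points(PointSet([[0, 0], [10, 10]]), PointSet([[0, 1]]), 5.0)
        assert detection_dice(m) == pytest.approx(2 / 3)

    def test_perfect(self):
        pts = PointSet([[0, 0], [5, 5]])
        assert detection_dice(match_points(pts, pts, 5.0)) == 1.0

    def test_zero_pairs(self):
        m = match_points(PointSet([[0, 0]]), PointSet([[100, 100]]), 5.0)
        assert detection_dice(m) == 0.0

    def test_both_empty_flagged(self):
        m = match_points(PointSet(np.empty((0, 2))), PointSet(np.empty((0, 2))), 5.0)
        assert detection_dice(m) is None

    def test_symmetry(self, rng):
        a = PointSet(rng.uniform(0, 20, (10, 2)))
        b = PointSet(rng.uniform(0, 20, (7, 2)))
        assert detection_dice(match_points(a, b, 5.0)) == pytest.approx(
            detection_dice(match_points(b, a, 5.0))
        )


class TestRoiSampling:
    def _sections(self, n, side_px=200, scale=1.0):
        outline = RegionOutline(
            MultiPolygon([Polygon([(20, 20), (180, 20), (180, 180), (20, 180)])])
        )
        return [
            (
                CalibratedImage(
                    np.zeros((side_px, side_px)), scale, source_id=f"sec{i}"
                ),
                outline,
            )
            for i in range(n)
        ]

    def test_deterministic(self):
        sections = self._sections(4)
        a = sample_validation_rois(sections, (40, 40), seed=5)
        b = sample_validation_rois(sections, (40, 40), seed=5)
        assert [s.roi for s in a] == [s.roi for s in b]

    def test_one_roi_per_section(self):
        samples = sample_validation_rois(self._sections(10), (40, 40), seed=1)
        assert len(samples) == 10
        assert {s.section_id for s in samples} == {f"sec{i}" for i in range(10)}

    def test_centers_inside_region(self):
        for s in sample_validation_rois(self._sections(6), (40, 40), seed=2):
            (r0, c0), (h, w) = s.roi.origin_px, s.roi.size_px
            cy, cx = r0 + h / 2, c0 + w / 2
            assert 20 < cx < 180 and 20 < cy < 180

    def test_region_too_small(self):
        sections = self._sections(1, side_px=30)
        with pytest.raises(SamplingError):
            sample_validation_rois(sections, (40, 40), seed=0)


class TestInclusionRules:
    def test_membrane_low_fraction_excluded(self):
        m = mask_of(np.zeros((10, 10)))
        m.pixels[0, :5] = True  # fraction 0.05
        included, reason = apply_inclusion_rules(m, "membrane")
        assert not included and "below" in reason

    def test_membrane_bounds_inclusive(self):
        m = mask_of(np.zeros((10, 10)))
        m.pixels[:1, :] = True  # exactly 0.1
        assert apply_inclusion_rules(m, "membrane")[0]
        m9 = mask_of(np.ones((10, 10)))
        m9.pixels[:1, :] = False  # exactly 0.9
        assert apply_inclusion_rules(m9, "membrane")[0]

    def test_membrane_mid_included(self):
        m = mask_of(np.zeros((10, 10)))
        m.pixels[:5, :] = True
        assert apply_inclusion_rules(m, "membrane") == (True, None)

    def test_nuclear_counts(self):
        four = PointSet(np.zeros((4, 2)))
        five = PointSet(np.zeros((5, 2)))
        assert not apply_inclusion_rules(four, "nuclear")[0]
        assert apply_inclusion_rules(five, "nuclear")[0]

    def test_mismatched_payload(self):
        with pytest.raises(ValueError):
            apply_inclusion_rules(PointSet(np.zeros((3, 2))), "membrane")


class TestObserverReport:
    def test_identical_comparator(self, rng):
        refs = [mask_of(rng.random((12, 12)) > 0.5) for _ in range(3)]
        table = observer_report(refs, {"self": refs}, "membrane")
        roi_rows = table[table.row_kind == "roi"]
        assert (roi_rows.dice == 1.0).all()
        summary = table[table.row_kind == "summary"].iloc[0]
        assert summary.dice_median == 1.0
        assert summary.dice_iqr == 0.0

    def test_two_comparators_two_summaries(self, rng):
        refs = [mask_of(rng.random((12, 12)) > 0.5) for _ in range(3)]
        comps = {
            "a": refs,
            "b": [mask_of(rng.random((12, 12)) > 0.5) for _ in range(3)],
        }
        table = observer_report(refs, comps, "membrane")
        assert (table.row_kind == "summary").sum() == 2

    def test_median_of_three(self):
        # three point-set ROIs engineered to give dice 0.5, 0.7 (approx), 1.0
        ref0 = PointSet([[0, 0], [10, 0], [20, 0], [30, 0]])
        comp0 = PointSet([[0, 1], [10, 1], [100, 0], [110, 0]])  # dice 0.5
        ref1 = PointSet([[0, 0], [10, 0]])
        comp1 = PointSet([[0, 1], [10, 1]])  # dice 1.0
        ref2 = PointSet([[0, 0], [10, 0], [20, 0]])
        comp2 = PointSet([[0, 1], [50, 0]])  # 1 match of 3+2 -> 0.4
        table = observer_report(
            [ref0, ref1, ref2], {"alg": [comp0, comp1, comp2]}, "nuclear"
        )
        summary = table[table.row_kind == "summary"].iloc[0]
        assert summary.dice_median == pytest.approx(0.5)

    def test_length_mismatch_rejected(self, rng):
        refs = [mask_of(rng.random((8, 8)) > 0.5) for _ in range(3)]
        with pytest.raises(ValueError):
            observer_report(refs, {"a": refs[:2]}, "membrane")
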