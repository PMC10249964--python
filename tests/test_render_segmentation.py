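"""Renderer ground truth and colour-rule segmentation, including the
image -> masks -> traits round trip."""

import numpy as np
import pytest

from ricepheno import (
    GrowthGroundTruth,
    PlantImage,
    SegmentationConfig,
    SegmentationResult,
    evaluate_segmentation,
    external_mask_result,
    render_plant_image,
    segment_panicle,
    segment_plant,
)
from ricepheno.synthetic import PlantState


def state(day=120, height=1000.0, tpa=50_000.0, ypar=0.2, ptpa=0.0, pypar=0.0, headed=False):
    return PlantState(day=day, height_mm=height, tpa_mm2=tpa, ypar=ypar,
                      panicle_tpa_mm2=ptpa, panicle_ypar=pypar, headed=headed)


class TestRenderer:
    def test_mask_area_matches_planted_tpa_exactly(self):
        img, truth = render_plant_image(state(tpa=10_000.0, height=400.0), scale=1.0,
                                        canvas=(500, 300), seed=0)
        assert int(truth.plant_mask.sum()) == 10_000

    def test_height_extent_matches_planted_height(self):
        img, truth = render_plant_image(state(height=900.0), scale=2.0, seed=0)
        rows = np.nonzero(truth.plant_mask.any(axis=1))[0]
        assert rows[-1] - rows[0] + 1 == round(900.0 / 2.0)

    @pytest.mark.parametrize("ypar", [0.0, 0.25, 1.0])
    def test_yellow_fraction_quantization(self, ypar):
        img, truth = render_plant_image(state(ypar=ypar), seed=1)
        n = truth.plant_mask.sum()
        frac = truth.yellow_mask.sum() / n
        assert abs(frac - ypar) <= 1.0 / n
        if ypar == 0.0:
            assert truth.yellow_mask.sum() == 0
        if ypar == 1.0:
            assert truth.green_mask.sum() == 0

    def test_panicle_drawn_iff_headed(self):
        _, pre = render_plant_image(state(headed=False, ptpa=5_000.0), seed=0)
        assert pre.panicle_mask is None
        _, post = render_plant_image(state(ypar=0.3, headed=True, ptpa=5_000.0), seed=0)
        assert post.panicle_mask is not None
        npix = int(post.panicle_mask.sum())
        target = round(5_000.0 / 4.0)
        hp = int(np.ptp(np.nonzero(post.panicle_mask.any(axis=1))[0])) + 1
        wp = int(np.ptp(np.nonzero(post.panicle_mask.any(axis=0))[0])) + 1
        assert abs(npix - target) <= hp + wp  # the renderer's stated tolerance

    def test_truth_masks_satisfy_partition_invariant(self):
        _, truth = render_plant_image(state(ypar=0.4, headed=True, ptpa=6_000.0), seed=2)
        truth.validate()  # raises on violation

    def test_errors_on_bad_geometry(self):
        with pytest.raises(ValueError, match="scale"):
            render_plant_image(state(), scale=-1.0)
        with pytest.raises(ValueError, match="canvas"):
            render_plant_image(state(height=2_000.0), scale=1.0, canvas=(100, 100))


class TestSegmentPlant:
    def test_recovers_renderer_truth(self, segmented_mid_season):
        img, truth, seg = segmented_mid_season
        m = evaluate_segmentation(seg.plant_mask, truth.plant_mask)
        assert m.iou >= 0.99

    def test_yellow_fraction_recovery(self, segmented_mid_season):
        img, truth, seg = segmented_mid_season
        true_frac = truth.yellow_mask.sum() / truth.plant_mask.sum()
        got_frac = seg.yellow_mask.sum() / seg.plant_mask.sum()
        assert got_frac == pytest.approx(true_frac, abs=0.02)

    def test_deterministic(self, rendered_mid_season):
        img, _ = rendered_mid_season
        a = segment_plant(img)
        b = segment_plant(img)
        assert np.array_equal(a.plant_mask, b.plant_mask)
        assert np.array_equal(a.yellow_mask, b.yellow_mask)

    def test_empty_image_gives_empty_mask(self):
        grey = np.full((50, 50, 3), 210, dtype=np.uint8)
        seg = segment_plant(PlantImage(grey))
        assert not seg.plant_mask.any()

    def test_partition_invariant_on_random_images(self, rng):
        for _ in range(5):
            rgb = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
            seg = segment_plant(PlantImage(rgb))
            seg.validate()

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            PlantImage(np.zeros((10, 10), dtype=np.uint8))


class TestSegmentPanicle:
    def test_pre_heading_gives_empty_mask(self):
        img, truth = render_plant_image(state(day=60, ypar=0.02, headed=False), seed=0)
        seg = segment_plant(img)
        pan = segment_panicle(img, seg)
        assert not pan.any()

    def test_post_heading_panicle_recovered(self, segmented_mid_season):
        img, truth, seg = segmented_mid_season
        pan = segment_panicle(img, seg)
        m = evaluate_segmentation(pan, truth.panicle_mask)
        assert m.iou >= 0.8

    def test_panicle_subset_of_plant(self, segmented_mid_season):
        img, truth, seg = segmented_mid_season
        pan = segment_panicle(img, seg)
        assert not np.any(pan & ~seg.plant_mask)

    def test_external_mask_passthrough(self):
        plant = np.zeros((20, 20), dtype=bool)
        plant[5:15, 5:15] = True
        pan = np.zeros_like(plant)
        pan[5:8, 5:15] = True
        res = external_mask_result(plant, panicle_mask=pan)
        assert res.source == "external"
        assert np.array_equal(res.panicle_mask, pan)
        assert np.array_equal(res.plant_mask, plant)

    def test_shape_mismatch_rejected(self, rendered_mid_season):
        img, _ = rendered_mid_season
        bad = SegmentationResult(np.ones((5, 5), bool), np.ones((5, 5), bool),
                                 np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="mismatch"):
            segment_panicle(img, bad)


class TestEvaluateSegmentation:
    def test_identity(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        res = evaluate_segmentation(m, m)
        assert (res.iou, res.precision, res.recall, res.f_measure) == (1, 1, 1, 1)

    def test_disjoint(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        res = evaluate_segmentation(a, b)
        assert (res.iou, res.precision, res.recall, res.f_measure) == (0, 0, 0, 0)

    def test_hand_counted_block_overlap(self):
        # pred: 2x2 block fully inside a 2x4 truth block
        truth = np.zeros((6, 8), bool)
        truth[2:4, 2:6] = True
        pred = np.zeros_like(truth)
        pred[2:4, 2:4] = True
        res = evaluate_segmentation(pred, truth)
        assert res.iou == pytest.approx(0.5)
        assert res.precision == pytest.approx(1.0)
        assert res.recall == pytest.approx(0.5)
        assert res.f_measure == pytest.approx(2.0 / 3.0)

    def test_symmetry_of_iou(self, rng):
        a = rng.random((15, 15)) > 0.5
        b = rng.random((15, 15)) > 0.5
        b[0, 0] = a[0, 0] = True
        assert evaluate_segmentation(a, b).iou == evaluate_segmentation(b, a).iou

    def test_f_measure_identity_and_bounds(self, rng):
        for _ in range(10):
            a = rng.random((12, 12)) > 0.4
            b = rng.random((12, 12)) > 0.4
            if not b.any():
                continue
            m = evaluate_segmentation(a, b)
            if m.precision + m.recall > 0:
                assert m.f_measure == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )
            assert m.iou <= min(m.precision, m.recall) + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError, match="shape"):
            evaluate_segmentation(np.ones((3, 3), bool), np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            evaluate_segmentation(np.ones((3, 3), bool), np.zeros((3, 3), bool))
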