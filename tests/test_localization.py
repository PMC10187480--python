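import numpy as np
import pytest

from mvshake.errors import DataError
from mvshake.io_formats import ROI
from mvshake.localization import (
    LOW_CONFIDENCE,
    crop_square,
    iou,
    load_localizer,
    mean_iou,
    nms,
    predict_roi,
    predict_rois,
    save_localizer,
    train_localizer,
)


def pixel_grid_iou(a, b):
    """Brute-force oracle: count membership of every pixel in a superset grid."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    x1 = max(ax + aw, bx + bw)
    y1 = max(ay + ah, by + bh)
    inter = union = 0
    for x in range(min(ax, bx), x1):
        for y in range(min(ay, by), y1):
            in_a = ax <= x < ax + aw and ay <= y < ay + ah
            in_b = bx <= x < bx + bw and by <= y < by + bh
            inter += in_a and in_b
            union += in_a or in_b
    return inter / union if union else 0.0


class TestIoU:
    def test_self_iou_is_one(self):
        assert iou(ROI(3, 4, 10, 12), ROI(3, 4, 10, 12)) == 1.0

    def test_disjoint_boxes_are_zero(self):
        assert iou(ROI(0, 0, 5, 5), ROI(10, 10, 5, 5)) == 0.0

    def test_half_overlap_example(self):
        assert iou(ROI(0, 0, 10, 10), ROI(5, 0, 10, 10)) == pytest.approx(50 / 150)

    def test_matches_pixel_grid_oracle_on_random_boxes(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a = (int(rng.integers(0, 15)), int(rng.integers(0, 15)),
                 int(rng.integers(1, 12)), int(rng.integers(1, 12)))
            b = (int(rng.integers(0, 15)), int(rng.integers(0, 15)),
                 int(rng.integers(1, 12)), int(rng.integers(1, 12)))
            assert iou(np.array(a), np.array(b)) == pytest.approx(
                pixel_grid_iou(a, b), abs=1e-12
            )

    def test_symmetry(self):
        a, b = ROI(0, 0, 8, 6), ROI(4, 2, 7, 9)
        assert iou(a, b) == iou(b, a)


class TestNMS:
    def test_overlapping_candidates_keep_best_score(self):
        boxes = np.array([[0, 0, 10, 10], [1, 0, 10, 10]])
        assert iou(boxes[0], boxes[1]) > 0.8
        keep = nms(boxes, np.array([0.8, 0.6]), iou_threshold=0.5)
        assert keep == [0]

    def test_distant_candidates_all_survive(self):
        boxes = np.array([[0, 0, 5, 5], [20, 20, 5, 5], [40, 0, 5, 5]])
        keep = nms(boxes, np.array([0.5, 0.9, 0.7]))
        assert sorted(keep) == [0, 1, 2]
        assert keep[0] == 1  # best first


class TestCropSquare:
    def test_zero_margin_crop_is_exact_patch(self):
        frame = np.arange(50 * 50, dtype=np.uint8).reshape(50, 50)
        out = crop_square(frame, ROI(10, 10, 20, 20), margin_frac=0.0, out_px=20)
        np.testing.assert_array_equal(out, frame[10:30, 10:30])

    def test_margin_side_arithmetic(self):
        # side = ceil(max(10, 30) * 1.1) = 33
        frame = np.zeros((100, 100), dtype=np.uint8)
        out = crop_square(frame, ROI(40, 40, 10, 30), margin_frac=0.1, out_px=33)
        assert out.shape == (33, 33)

    def test_border_roi_still_square_via_edge_padding(self):
        frame = np.full((40, 40), 7, dtype=np.uint8)
        frame[0, 0] = 200
        out = crop_square(frame, ROI(0, 0, 10, 10), margin_frac=0.5, out_px=15)
        assert out.shape == (15, 15)

    @pytest.mark.parametrize("roi", [ROI(0, 0, 5, 9), ROI(30, 35, 9, 3),
                                     ROI(12, 2, 31, 14)])
    def test_output_always_requested_size(self, roi):
        frame = np.random.default_rng(0).integers(0, 255, (40, 40)).astype(np.uint8)
        assert crop_square(frame, roi, out_px=24).shape == (24, 24)


@pytest.fixture(scope="module")
def trained(rendered_session):
    sess = rendered_session
    idx = np.arange(0, sess.n_frames, 9)
    frames = np.concatenate([sess.views[0][idx], sess.views[1][idx]])
    boxes = np.concatenate([sess.rois[0][idx], sess.rois[1][idx]])
    return train_localizer(frames, boxes, seed=0)


class TestLocalizer:
    def test_heldout_iou_beats_benchmark_floor(self, rendered_session, trained):
        sess = rendered_session
        hold = np.arange(4, sess.n_frames, 31)
        pred, _ = predict_rois(trained, sess.views[2][hold])
        assert mean_iou(pred, sess.rois[2][hold]) >= 0.9

    def test_training_is_deterministic(self, rendered_session, trained):
        sess = rendered_session
        idx = np.arange(0, sess.n_frames, 9)
        frames = np.concatenate([sess.views[0][idx], sess.views[1][idx]])
        boxes = np.concatenate([sess.rois[0][idx], sess.rois[1][idx]])
        again = train_localizer(frames, boxes, seed=0)
        np.testing.assert_array_equal(again.template, trained.template)
        np.testing.assert_array_equal(again.calibration, trained.calibration)

    def test_empty_annotations_rejected(self):
        with pytest.raises(DataError):
            train_localizer(np.empty((0, 32, 32), dtype=np.uint8),
                            np.empty((0, 4)))

    def test_blank_frame_flagged_low_confidence(self, trained):
        blank = np.full((64, 64), 30, dtype=np.uint8)
        roi, conf = predict_roi(trained, blank)
        assert conf < LOW_CONFIDENCE
        assert roi.w >= 1 and roi.h >= 1  # still emits a box

    def test_single_frame_prediction_quality(self, rendered_session, trained):
        sess = rendered_session
        roi, conf = predict_roi(trained, sess.views[0][500])
        assert iou(roi, sess.rois[0][500]) >= 0.8
        assert conf > LOW_CONFIDENCE

    def test_save_load_round_trip(self, trained, tmp_path):
        save_localizer(trained, tmp_path / "loc.npz")
        back = load_localizer(tmp_path / "loc.npz")
        np.testing.assert_array_equal(back.template, trained.template)
        assert back.threshold == trained.threshold
        blank = np.full((64, 64), 30, dtype=np.uint8)
        assert predict_roi(back, blank)[0] == predict_roi(trained, blank)[0]
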