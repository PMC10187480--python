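"""Per-frame single-animal localization (the pipeline's first network stage).

The localizer finds the one animal in each frame and emits exactly one ROI
plus a confidence. It is a trained matched-filter detector: a mean template
learned from annotated boxes is cross-correlated with the frame, candidate
peaks become candidate boxes via a learned intensity threshold and a
mask-extent rule, duplicates are removed by non-maximum suppression (IoU >
0.5 keeps only the best-scoring box), and a linear calibration learned from
the annotations corrects systematic box biases. Prediction is deterministic
given the trained model.

Also home to the box utilities the rest of the pipeline uses: ``iou`` on
inclusive integer-pixel boxes, ``nms`` de-duplication, and ``crop_square``
(square, margin-padded, edge-replicated crops used by the classifier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize

from .errors import DataError
from .io_formats import ROI

LOW_CONFIDENCE = 0.3  # boxes below this are flagged, never dropped


# ---------------------------------------------------------------------------
# box utilities
# ---------------------------------------------------------------------------

def iou(a: ROI | np.ndarray, b: ROI | np.ndarray) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes with pixel areas."""
    ax, ay, aw, ah = _unpack(a)
    bx, by, bw, bh = _unpack(b)
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _unpack(box) -> tuple[int, int, int, int]:
    if isinstance(box, ROI):
        return box.x, box.y, box.w, box.h
    x, y, w, h = (int(v) for v in np.asarray(box))
    return x, y, w, h


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.5) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = list(np.argsort(scores)[::-1])
    keep: list[int] = []
    while order:
        i = order.pop(0)
        keep.append(i)
        order = [j for j in order if iou(boxes[i], boxes[j]) <= iou_threshold]
    return keep


def crop_square(
    frame: np.ndarray, roi: ROI, margin_frac: float = 0.1, out_px: int = 64
) -> np.ndarray:
    """Square crop around an ROI, padded with edge replication, resized.

    The side is ``ceil(max(w, h) * (1 + margin_frac))``, centered on the ROI
    center; parts outside the frame are filled by edge replication so the
    output is always ``out_px`` x ``out_px``. The crop is taken from the
    frame at its native resolution before resizing.
    """
    x, y, w, h = roi.x, roi.y, roi.w, roi.h
    side = int(math.ceil(max(w, h) * (1.0 + margin_frac) - 1e-9))
    cx = x + w / 2.0
    cy = y + h / 2.0
    left = int(round(cx - side / 2.0))
    top = int(round(cy - side / 2.0))
    H, W = frame.shape[:2]
    x0, x1 = max(0, left), min(W, left + side)
    y0, y1 = max(0, top), min(H, top + side)
    patch = frame[y0:y1, x0:x1]
    pad = ((y0 - top, (top + side) - y1), (x0 - left, (left + side) - x1))
    if any(p > 0 for pair in pad for p in pair):
        patch = np.pad(patch, pad, mode="edge")
    if side == out_px:
        return patch.copy()
    out = _sk_resize(patch.astype(np.float32), (out_px, out_px), order=1,
                     anti_aliasing=False, preserve_range=True)
    if np.issubdtype(frame.dtype, np.integer):
        return np.clip(out + 0.5, 0, 255).astype(frame.dtype)
    return out.astype(frame.dtype)


# ---------------------------------------------------------------------------
# the localizer
# ---------------------------------------------------------------------------

@dataclass
class LocalizerModel:
    """Trained matched-filter localizer parameters."""

    template: np.ndarray          # mean-centered appearance template
    threshold: float              # foreground intensity threshold (0-1 scale)
    calibration: np.ndarray       # (4, 2) per-coordinate linear correction
    peak_scale: float             # typical correlation peak, for confidence
    input_px: int                 # frame side length seen in training
    version: str = "matched-filter-1"

    def __post_init__(self):
        self.template = np.asarray(self.template, dtype=np.float32)
        self.calibration = np.asarray(self.calibration, dtype=np.float64)


def train_localizer(
    frames: np.ndarray | list[np.ndarray],
    boxes: np.ndarray,
    config: dict | None = None,
    seed: int = 0,
) -> LocalizerModel:
    """Train the localizer from annotated frames.

    ``frames`` is ``(n, H, W)`` uint8; ``boxes`` is ``(n, 4)`` as
    (x, y, w, h). Training learns the mean appearance template, an Otsu
    foreground threshold, and a per-coordinate linear calibration fitted by
    least squares on the training frames' raw predictions. Deterministic
    given the inputs (``seed`` is accepted for interface symmetry).
    """
    del seed  # training is fully deterministic
    frames = np.asarray(frames)
    boxes = np.asarray(boxes, dtype=np.int64)
    if len(frames) == 0:
        raise DataError("train_localizer needs at least one annotated frame")
    if len(frames) != len(boxes):
        raise DataError("frames and boxes must align")
    config = config or {}
    tpl_px = int(config.get("template_px", 0))
    if tpl_px <= 0:
        side = int(np.median(np.maximum(boxes[:, 2], boxes[:, 3])))
        tpl_px = side + (side + 1) % 2  # odd

    scale = 255.0 if np.issubdtype(frames.dtype, np.integer) else 1.0
    crops = []
    for frame, (x, y, w, h) in zip(frames, boxes):
        roi = ROI(int(x), int(y), max(int(w), 1), max(int(h), 1))
        crops.append(crop_square(frame, roi, margin_frac=0.0, out_px=tpl_px)
                     .astype(np.float32) / scale)
    template = np.mean(crops, axis=0)
    template -= template.mean()

    sample = frames[:: max(1, len(frames) // 64)].astype(np.float32) / scale
    threshold = float(threshold_otsu(sample.ravel()))

    model = LocalizerModel(
        template=template,
        threshold=threshold,
        calibration=np.tile([1.0, 0.0], (4, 1)),
        peak_scale=1.0,
        input_px=frames.shape[-1],
    )
    raw, peaks = _predict_raw(model, frames)
    model.peak_scale = float(np.median(peaks)) or 1.0
    # least-squares per-coordinate correction: true ~ a * raw + b
    calib = np.empty((4, 2))
    for k in range(4):
        A = np.stack([raw[:, k], np.ones(len(raw))], axis=1)
        calib[k] = np.linalg.lstsq(A, boxes[:, k].astype(float), rcond=None)[0]
    model.calibration = calib
    return model


def _candidate_boxes(
    model: LocalizerModel, frame01: np.ndarray, corr: np.ndarray, max_candidates: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation peaks -> candidate (box, score) pairs via mask extents."""
    tpl = model.template
    local_max = corr == maximum_filter(corr, size=tpl.shape[0])
    ys, xs = np.nonzero(local_max)
    vals = corr[ys, xs]
    order = np.argsort(vals)[::-1][:max_candidates]
    H, W = frame01.shape
    R = int(tpl.shape[0] * 1.2) + 2
    boxes, scores = [], []
    for idx in order:
        py, pxx, val = int(ys[idx]), int(xs[idx]), float(vals[idx])
        y0, y1 = max(0, py - R), min(H, py + R + 1)
        x0, x1 = max(0, pxx - R), min(W, pxx + R + 1)
        mask = frame01[y0:y1, x0:x1] > model.threshold
        # ignore isolated noise pixels: a row/column must hold >= 2 pixels
        cols = np.nonzero(mask.sum(axis=0) >= 2)[0]
        rows = np.nonzero(mask.sum(axis=1) >= 2)[0]
        if cols.size == 0 or rows.size == 0:
            side = tpl.shape[0]
            boxes.append([pxx - side // 2, py - side // 2, side, side])
            scores.append(0.0)
            continue
        bx, by = x0 + cols[0], y0 + rows[0]
        bw, bh = cols[-1] - cols[0] + 1, rows[-1] - rows[0] + 1
        boxes.append([bx, by, bw, bh])
        scores.append(val)
    return np.asarray(boxes, dtype=float), np.asarray(scores, dtype=float)


def _predict_raw(
    model: LocalizerModel, frames: np.ndarray, chunk: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Uncalibrated boxes and peak scores for a stack of frames."""
    frames = np.asarray(frames)
    scale = 255.0 if np.issubdtype(frames.dtype, np.integer) else 1.0
    tpl = model.template[::-1, ::-1]
    out_boxes = np.empty((len(frames), 4), dtype=float)
    out_peaks = np.empty(len(frames), dtype=float)
    for c0 in range(0, len(frames), chunk):
        block = frames[c0 : c0 + chunk].astype(np.float32) / scale
        block_c = block - block.mean(axis=(1, 2), keepdims=True)
        corr = fftconvolve(block_c, tpl[None], mode="same", axes=(1, 2))
        for i, (frame01, cmap) in enumerate(zip(block, corr)):
            boxes, scores = _candidate_boxes(model, frame01, cmap)
            keep = nms(boxes, scores, iou_threshold=0.5)
            best = keep[0]
            out_boxes[c0 + i] = boxes[best]
            out_peaks[c0 + i] = scores[best]
    return out_boxes, out_peaks


def _calibrate(model: LocalizerModel, raw: np.ndarray, frame_hw: tuple[int, int]) -> np.ndarray:
    cal = model.calibration
    out = raw * cal[:, 0] + cal[:, 1]
    out = np.rint(out).astype(np.int64)
    H, W = frame_hw
    out[:, 2] = np.clip(out[:, 2], 1, W)
    out[:, 3] = np.clip(out[:, 3], 1, H)
    out[:, 0] = np.clip(out[:, 0], 0, W - out[:, 2])
    out[:, 1] = np.clip(out[:, 1], 0, H - out[:, 3])
    return out


def predict_rois(
    model: LocalizerModel, frames: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict one box per frame.

    Returns ``(boxes, confidences)`` where boxes is ``(n, 4)`` int64 and
    confidences are correlation peaks normalized by the training-time
    typical peak, clipped to [0, 1]. Every frame gets a box; frames whose
    confidence falls below :data:`LOW_CONFIDENCE` should be treated as
    low-trust but are never dropped (downstream stages need a score for
    every frame).
    """
    frames = np.asarray(frames)
    raw, peaks = _predict_raw(model, frames)
    boxes = _calibrate(model, raw, frames.shape[-2:])
    conf = np.clip(peaks / model.peak_scale, 0.0, 1.0)
    return boxes, conf


def predict_roi(model: LocalizerModel, frame: np.ndarray) -> tuple[ROI, float]:
    """Single-frame convenience wrapper around :func:`predict_rois`."""
    boxes, conf = predict_rois(model, frame[None])
    x, y, w, h = (int(v) for v in boxes[0])
    return ROI(x, y, w, h), float(conf[0])


def mean_iou(boxes_a: np.ndarray, boxes_b: np.ndarray) -> float:
    """Mean IoU over paired box arrays."""
    return float(np.mean([iou(a, b) for a, b in zip(boxes_a, boxes_b)]))


def save_localizer(model: LocalizerModel, path) -> None:
    np.savez(
        path,
        template=model.template,
        threshold=model.threshold,
        calibration=model.calibration,
        peak_scale=model.peak_scale,
        input_px=model.input_px,
        version=np.array(model.version),
    )


def load_localizer(path) -> LocalizerModel:
    data = np.load(path, allow_pickle=False)
    return LocalizerModel(
        template=data["template"],
        threshold=float(data["threshold"]),
        calibration=data["calibration"],
        peak_scale=float(data["peak_scale"]),
        input_px=int(data["input_px"]),
        version=str(data["version"]),
    )
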