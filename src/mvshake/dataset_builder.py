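"""Balanced crop-classification dataset construction.

Every WDS-labeled frame is cropped in every view (labels annotate *time*,
not views, so a view where the shake happened to be invisible still yields
a WDS-labeled crop — realistic label noise that is deliberately kept), and
an equal number of NWDS frames is sampled uniformly without replacement.
Crops use the predicted ROIs, treated as ground truth, including their
occasional inaccuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io_formats import NWDS, WDS, MultiViewSession, ROI
from .localization import crop_square


@dataclass
class CropDataset:
    """A balanced set of (square crop, label) pairs with provenance."""

    images: np.ndarray      # (n, out_px, out_px) uint8
    labels: np.ndarray      # (n,) int8, WDS=1 / NWDS=0
    provenance: pd.DataFrame  # columns: session_id, view, frame_index
    split: str = "train"
    balance_tol: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n_wds = int((self.labels == WDS).sum())
        n_nwds = int((self.labels == NWDS).sum())
        if abs(n_wds - n_nwds) > self.balance_tol:
            raise ValidationError(
                f"{self.split} split unbalanced: {n_wds} WDS vs {n_nwds} NWDS "
                f"(tolerance {self.balance_tol})"
            )
        dup = self.provenance.duplicated(["session_id", "view", "frame_index"])
        if dup.any():
            raise ValidationError("duplicate (session, view, frame) in dataset")

    def __len__(self) -> int:
        return len(self.labels)


def build_classification_dataset(
    sessions: list[MultiViewSession],
    rois: dict[str, list[np.ndarray]],
    seed: int = 0,
    balance_tol: int = 0,
    margin_frac: float = 0.1,
    out_px: int = 64,
    val_fraction: float = 0.025,
) -> tuple[CropDataset, CropDataset]:
    """Build (train, val) balanced crop datasets from sessions + ROIs.

    ``rois`` maps session_id to one (T, 4) box array per view. All WDS
    frames from every view are included; NWDS frames are sampled per
    session to balance. The validation split holds out the last session
    when >= 2 sessions are given, otherwise it is a stratified random
    ``val_fraction`` of the crops.
    """
    if sum(int((s.labels == WDS).sum()) for s in sessions) == 0:
        raise DataError("no WDS frames in the provided sessions")
    rng = np.random.default_rng(seed)
    per_session: list[tuple[np.ndarray, np.ndarray, pd.DataFrame]] = []
    for sess in sessions:
        boxes = rois[sess.session_id]
        images, labels, prov = _session_crops(
            sess, boxes, rng, margin_frac, out_px
        )
        per_session.append((images, labels, prov))

    if len(sessions) >= 2:
        tr = per_session[:-1]
        va = per_session[-1:]
        train = _concat(tr, "train", balance_tol)
        val = _concat(va, "val", balance_tol)
    else:
        images, labels, prov = per_session[0]
        train_idx, val_idx = _stratified_split(labels, val_fraction, rng)
        train = CropDataset(images[train_idx], labels[train_idx],
                            prov.iloc[train_idx].reset_index(drop=True),
                            "train", balance_tol)
        val = CropDataset(images[val_idx], labels[val_idx],
                          prov.iloc[val_idx].reset_index(drop=True),
                          "val", balance_tol)
    return train, val


def _session_crops(sess, boxes, rng, margin_frac, out_px):
    wds_frames = np.nonzero(sess.labels == WDS)[0]
    nwds_frames = np.nonzero(sess.labels == NWDS)[0]
    n_views = sess.n_views
    n_wds = len(wds_frames) * n_views
    # sample NWDS (frame, view) pairs uniformly without replacement
    pool = np.array(
        [(t, v) for t in nwds_frames for v in range(n_views)], dtype=np.int64
    )
    take = rng.choice(len(pool), size=min(n_wds, len(pool)), replace=False)
    chosen = pool[np.sort(take)]

    images, labels, rows = [], [], []
    for t in wds_frames:
        for v in range(n_views):
            images.append(_crop(sess, boxes, v, t, margin_frac, out_px))
            labels.append(WDS)
            rows.append((sess.session_id, sess.view_names[v], int(t)))
    for t, v in chosen:
        images.append(_crop(sess, boxes, v, t, margin_frac, out_px))
        labels.append(NWDS)
        rows.append((sess.session_id, sess.view_names[v], int(t)))
    prov = pd.DataFrame(rows, columns=["session_id", "view", "frame_index"])
    if not images:  # a session may hold no events at all
        return (np.empty((0, out_px, out_px), dtype=np.uint8),
                np.empty(0, dtype=np.int8), prov)
    return np.stack(images), np.asarray(labels, dtype=np.int8), prov


def _crop(sess, boxes, v, t, margin_frac, out_px):
    x, y, w, h = (int(c) for c in boxes[v][t])
    return crop_square(sess.views[v][t], ROI(x, y, max(w, 1), max(h, 1)),
                       margin_frac=margin_frac, out_px=out_px)


def _concat(parts, split, balance_tol):
    images = np.concatenate([p[0] for p in parts])
    labels = np.concatenate([p[1] for p in parts])
    prov = pd.concat([p[2] for p in parts], ignore_index=True)
    return CropDataset(images, labels, prov, split, balance_tol)


def _stratified_split(labels, val_fraction, rng):
    val_idx = []
    for cls in (WDS, NWDS):
        idx = np.nonzero(labels == cls)[0]
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.append(rng.choice(idx, size=n_val, replace=False))
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    return train_idx, val_idx


def write_crop_dataset(dataset: CropDataset, out_dir: str | Path) -> Path:
    """Write crops as ``{split}/{WDS,NWDS}/*.png`` plus a manifest CSV."""
    out_dir = Path(out_dir)
    names = {WDS: "WDS", NWDS: "NWDS"}
    rows = []
    for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        cls_dir = out_dir / dataset.split / names[int(lab)]
        cls_dir.mkdir(parents=True, exist_ok=True)
        fname = f"crop_{i:06d}.png"
        iio.imwrite(cls_dir / fname, img)
        rows.append(
            {**dataset.provenance.iloc[i].to_dict(),
             "label": names[int(lab)], "file": f"{dataset.split}/{names[int(lab)]}/{fname}"}
        )
    manifest = out_dir / f"manifest_{dataset.split}.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return out_dir
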