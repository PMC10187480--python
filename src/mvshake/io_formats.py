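"""Domain types and on-disk formats for multi-view behavior sessions.

A session lives in a directory::

    session/
        session.yaml      # session_id, fps, view names
        <view_name>/      # one directory of PNG frames per view
            frame_00000.png ...
        labels.csv        # frame_index,label   (label in {WDS, NWDS})
        events.json       # [{"start_frame": int, "end_frame": int}, ...]
        rois.csv          # optional: view_id,frame_index,x,y,w,h

Frames are grayscale uint8 arrays. Event intervals use inclusive frame
endpoints; a frame is labeled WDS exactly when it lies inside an event.
Pixel coordinates are 0-based with the origin at the top-left corner, and
box width/height are pixel extents (a box covers columns ``x .. x+w-1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import SynchronizationError, ValidationError

WDS = 1
NWDS = 0
_LABEL_NAMES = {WDS: "WDS", NWDS: "NWDS"}
_LABEL_CODES = {"WDS": WDS, "NWDS": NWDS}


@dataclass(frozen=True)
class EventList:
    """Sorted, non-overlapping behavior intervals with inclusive endpoints."""

    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        ivs = tuple((int(s), int(e)) for s, e in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_end = None
        for s, e in ivs:
            if s < 0 or e < s:
                raise ValidationError(f"invalid interval ({s}, {e})")
            if prev_end is not None and s <= prev_end + 1:
                raise ValidationError(
                    f"intervals must be sorted with a gap >= 1 frame; "
                    f"interval starting at {s} follows one ending at {prev_end}"
                )
            prev_end = e

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @property
    def n_frames_covered(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned box locating the animal: top-left (x, y), extents (w, h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValidationError(f"ROI extents must be >= 1, got w={self.w} h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=np.int64)


@dataclass
class MultiViewSession:
    """Synchronized multi-view frame streams plus ground-truth annotations.

    ``views`` holds one ``(T, H, W)`` uint8 array per camera, all with the
    same frame count T. ``labels`` is the per-frame WDS indicator implied by
    ``events``. ``rois`` optionally stores one ``(T, 4)`` integer box array
    per view (ground-truth or predicted animal locations). ``meta`` carries
    generator-side ground truth (e.g. per-event visibility flags) and is not
    part of the on-disk contract.
    """

    session_id: str
    fps: float
    views: list[np.ndarray]
    view_names: list[str]
    labels: np.ndarray
    events: EventList
    rois: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if not self.views:
            raise ValidationError("session needs at least one view")
        lengths = {len(v) for v in self.views}
        if len(lengths) != 1:
            raise SynchronizationError(
                f"views have mismatched frame counts: "
                f"{[len(v) for v in self.views]}"
            )
        T = lengths.pop()
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != T:
            raise SynchronizationError(
                f"labels length {len(self.labels)} != frame count {T}"
            )
        expected = labels_from_events(self.events, T)
        bad = np.nonzero(self.labels != expected)[0]
        if bad.size:
            raise ValidationError(
                f"labels inconsistent with events; first offending frame: {bad[0]}"
            )

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_frames(self) -> int:
        return len(self.views[0])


def labels_from_events(events: EventList, T: int) -> np.ndarray:
    """Indicator vector of length T: 1 on frames inside an event, else 0."""
    labels = np.zeros(T, dtype=np.int8)
    for s, e in events:
        if e > T - 1:
            raise ValidationError(f"interval ({s}, {e}) exceeds last frame {T - 1}")
        labels[s : e + 1] = WDS
    return labels


# ---------------------------------------------------------------------------
# session directory I/O
# ---------------------------------------------------------------------------

def write_session(session: MultiViewSession, path: str | Path, overwrite: bool = False) -> Path:
    """Write a session directory (PNG frame streams + annotations)."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise ValidationError(f"refusing to overwrite non-empty directory {path}")
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "fps": float(session.fps),
        "views": list(session.view_names),
    }
    (path / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for name, frames in zip(session.view_names, session.views):
        vdir = path / name
        vdir.mkdir(exist_ok=True)
        for t, frame in enumerate(frames):
            iio.imwrite(vdir / f"frame_{t:05d}.png", np.asarray(frame, dtype=np.uint8))
    write_events(session.events, path / "events.json")
    write_labels(session.labels, path / "labels.csv")
    if session.rois is not None:
        write_rois({n: r for n, r in zip(session.view_names, session.rois)}, path / "rois.csv")
    return path


def read_session(path: str | Path) -> MultiViewSession:
    """Read a session directory written by :func:`write_session`.

    ``labels.csv`` is optional; labels are regenerated from ``events.json``
    when absent. Raises :class:`SynchronizationError` on mismatched stream
    lengths and :class:`ValidationError` on label/event inconsistency.
    """
    path = Path(path)
    meta = yaml.safe_load((path / "session.yaml").read_text())
    view_names = list(meta["views"])
    views = [_read_frame_stream(path / name) for name in view_names]
    events = read_events(path / "events.json")
    lengths = {len(v) for v in views}
    if len(lengths) != 1:
        raise SynchronizationError(
            f"views have mismatched frame counts: {[len(v) for v in views]}"
        )
    T = lengths.pop()
    labels_path = path / "labels.csv"
    labels = read_labels(labels_path) if labels_path.exists() else labels_from_events(events, T)
    rois_path = path / "rois.csv"
    rois = None
    if rois_path.exists():
        roi_map = read_rois(rois_path)
        rois = [roi_map[name] for name in view_names]
    return MultiViewSession(
        session_id=str(meta["session_id"]),
        fps=float(meta["fps"]),
        views=views,
        view_names=view_names,
        labels=labels,
        events=events,
        rois=rois,
    )


def _read_frame_stream(path: Path) -> np.ndarray:
    """Read one view: a directory of PNG frames, or a single video file."""
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise ValidationError(f"no frames found in {path}")
        return np.stack([iio.imread(f) for f in files])
    for ext in (".mp4", ".avi", ".mov"):
        f = path.with_suffix(ext)
        if f.exists():
            return np.stack(list(iio.imiter(f)))
    raise ValidationError(f"no frame source found for view {path.name}")


# ---------------------------------------------------------------------------
# annotation files
# ---------------------------------------------------------------------------

def write_events(events: EventList, path: str | Path) -> None:
    payload = [{"start_frame": s, "end_frame": e} for s, e in events]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path: str | Path) -> EventList:
    payload = json.loads(Path(path).read_text())
    return EventList(tuple((d["start_frame"], d["end_frame"]) for d in payload))


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(labels)),
            "label": [_LABEL_NAMES[int(v)] for v in labels],
        }
    )
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    try:
        codes = df["label"].map(_LABEL_CODES)
    except KeyError as exc:
        raise ValidationError(f"labels file {path} lacks a 'label' column") from exc
    if codes.isna().any():
        bad = df.loc[codes.isna(), "label"].iloc[0]
        raise ValidationError(f"unknown label {bad!r} in {path}")
    labels = np.full(int(df["frame_index"].max()) + 1, NWDS, dtype=np.int8)
    labels[df["frame_index"].to_numpy()] = codes.to_numpy(dtype=np.int8)
    return labels


def write_rois(rois: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-view per-frame boxes as ``view_id,frame_index,x,y,w,h``."""
    rows = []
    for view_id, arr in rois.items():
        arr = np.asarray(arr, dtype=np.int64)
        df = pd.DataFrame(arr, columns=["x", "y", "w", "h"])
        df.insert(0, "frame_index", np.arange(len(arr)))
        df.insert(0, "view_id", view_id)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_rois(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    out: dict[str, np.ndarray] = {}
    for view_id, grp in df.groupby("view_id", sort=False):
        grp = grp.sort_values("frame_index")
        out[str(view_id)] = grp[["x", "y", "w", "h"]].to_numpy(dtype=np.int64)
    return out


def rois_to_coco(
    rois: dict[str, np.ndarray], frame_hw: tuple[int, int]
) -> dict:
    """Export boxes as a COCO-style dict with a single ``animal`` category."""
    h, w = frame_hw
    images, annotations = [], []
    ann_id = 1
    img_id = 1
    for view_id, arr in rois.items():
        for t, (bx, by, bw, bh) in enumerate(np.asarray(arr, dtype=np.int64)):
            images.append(
                {"id": img_id, "file_name": f"{view_id}/frame_{t:05d}.png",
                 "width": int(w), "height": int(h)}
            )
            annotations.append(
                {"id": ann_id, "image_id": img_id, "category_id": 1,
                 "bbox": [int(bx), int(by), int(bw), int(bh)],
                 "area": int(bw * bh), "iscrowd": 0}
            )
            ann_id += 1
            img_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "animal"}],
    }


# ---------------------------------------------------------------------------
# prediction files
# ---------------------------------------------------------------------------

def write_predictions(
    scores: np.ndarray, path: str | Path, view_ids: list[str] | None = None
) -> None:
    """Write per-frame scores as CSV.

    ``scores`` is ``(T,)`` for a fused series or ``(V, T)`` for per-view
    series (then ``view_ids`` names the rows). Scores must be finite and in
    [0, 1]; values round-trip through :func:`read_predictions` at 6 decimal
    places.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores contain NaN or infinite values")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValidationError("scores must lie in [0, 1]")
    if scores.ndim == 1:
        df = pd.DataFrame({"frame_index": np.arange(len(scores)), "score": scores})
    elif scores.ndim == 2:
        if view_ids is None or len(view_ids) != len(scores):
            raise ValidationError("per-view scores need one view_id per row")
        parts = [
            pd.DataFrame(
                {"frame_index": np.arange(scores.shape[1]), "score": row, "view_id": vid}
            )
            for vid, row in zip(view_ids, scores)
        ]
        df = pd.concat(parts, ignore_index=True)
    else:
        raise ValidationError("scores must be 1-D (fused) or 2-D (per view)")
    df.to_csv(path, index=False, float_format="%.6f")


def read_predictions(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a prediction CSV; returns (scores, view_ids or None)."""
    df = pd.read_csv(path)
    if "view_id" in df.columns:
        view_ids = [str(v) for v in df["view_id"].drop_duplicates()]
        series = []
        for vid in view_ids:
            grp = df[df["view_id"].astype(str) == vid].sort_values("frame_index")
            series.append(grp["score"].to_numpy())
        return np.stack(series), view_ids
    df = df.sort_values("frame_index")
    return df["score"].to_numpy(), None
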