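"""Binary WDS/NWDS crop classifier (the pipeline's second network stage).

A small seeded convolutional network maps a square animal crop to softmax
class scores (p_wds, p_nwds). Applied per frame and per view it produces
the per-view score series that the fusion stage consumes. The backbone is
deliberately compact — the conformance contract is the validation-accuracy
floor on the benchmark, not a particular architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .dataset_builder import CropDataset
from .errors import DataError, ValidationError
from .io_formats import WDS, MultiViewSession, ROI
from .localization import crop_square


@dataclass(frozen=True)
class ClassifierConfig:
    input_px: int = 32          # crops are mean-pooled/strided down to this
    conv_channels: tuple[int, int] = (8, 16)
    dense_units: int = 32
    dropout_rate: float = 0.2
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    augment_flips: bool = True
    margin_frac: float = 0.1    # crop margin used at scoring time
    out_px: int = 64            # crop resolution before downsampling


@dataclass
class ClassifierModel:
    net: nn.Sequential
    config: ClassifierConfig
    val_accuracy: float | None = None
    history: dict = field(default_factory=dict)


@dataclass
class ClassifierEnsemble:
    """Average of several crop classifiers sharing one preprocessing config.

    Averaging decorrelates individual models' overconfident mistakes on
    ambiguous crops (their background score bumps land on different
    frames), while crops every member agrees on — actual shakes — keep
    scores near 1. Used at inference time on top of fold-trained members.
    """

    members: list[ClassifierModel]
    val_accuracy: float | None = None

    def __post_init__(self):
        if not self.members:
            raise DataError("ensemble needs at least one member")

    @property
    def config(self) -> ClassifierConfig:
        return self.members[0].config


def _build_net(cfg: ClassifierConfig, rng: np.random.Generator) -> nn.Sequential:
    c1, c2 = cfg.conv_channels
    s = cfg.input_px
    h1 = (s - 5) // 2 + 1
    h2 = (h1 - 3) // 2 + 1
    return nn.Sequential([
        nn.Conv2D(1, c1, (5, 5), stride=2, rng=rng),
        nn.ReLU(),
        nn.Conv2D(c1, c2, (3, 3), stride=2, rng=rng),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(h2 * h2 * c2, cfg.dense_units, rng=rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout_rate),
        nn.Dense(cfg.dense_units, 2, rng=rng),
    ])


def _preprocess(images: np.ndarray, cfg: ClassifierConfig) -> np.ndarray:
    """uint8 crops -> float32 (n, input_px, input_px, 1) in [-0.5, 0.5]."""
    x = np.asarray(images, dtype=np.float32) / 255.0 - 0.5
    step = max(1, x.shape[1] // cfg.input_px)
    x = x[:, :: step, :: step][:, : cfg.input_px, : cfg.input_px]
    return x[..., None]


def train_classifier(
    train: CropDataset,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    val: CropDataset | None = None,
) -> ClassifierModel:
    """Train the crop classifier; seeded and deterministic.

    Raises :class:`DataError` if the training set contains a single class.
    Reports validation accuracy on ``val`` when given.
    """
    cfg = config or ClassifierConfig()
    if len(np.unique(train.labels)) < 2:
        raise DataError("training dataset contains a single class")
    rng = np.random.default_rng(seed)
    net = _build_net(cfg, rng)
    x = _preprocess(train.images, cfg)
    y = train.labels.astype(np.int64)
    if cfg.augment_flips:
        x = np.concatenate([x, x[:, ::-1], x[:, :, ::-1], x[:, ::-1, ::-1]])
        y = np.tile(y, 4)
    kwargs = {}
    if val is not None:
        kwargs = {"x_val": _preprocess(val.images, cfg),
                  "y_val": val.labels.astype(np.int64)}
    history = net.fit(
        x, y, epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr, rng=rng,
        **kwargs,
    )
    val_acc = history["val_accuracy"][-1] if val is not None else None
    return ClassifierModel(net=net, config=cfg, val_accuracy=val_acc,
                           history=history)


def predict_scores(
    model: ClassifierModel | ClassifierEnsemble, crops: np.ndarray
) -> np.ndarray:
    """Softmax (p_nwds, p_wds) rows for a stack of uint8 crops."""
    if isinstance(model, ClassifierEnsemble):
        x = _preprocess(crops, model.config)
        probs = [m.net.predict_proba(x) for m in model.members]
        return np.mean(probs, axis=0)
    x = _preprocess(crops, model.config)
    return model.net.predict_proba(x)


def score_session(
    model: ClassifierModel | ClassifierEnsemble,
    session: MultiViewSession,
    rois: list[np.ndarray],
    batch_size: int = 512,
) -> np.ndarray:
    """Per-view per-frame p_wds series, shape (n_views, T).

    Every (view, frame) needs an ROI; a missing (non-finite or degenerate)
    box raises :class:`ValidationError` naming the frame.
    """
    cfg = model.config
    T = session.n_frames
    out = np.empty((session.n_views, T), dtype=np.float64)
    for v in range(session.n_views):
        boxes = np.asarray(rois[v])
        if len(boxes) != T:
            raise ValidationError(
                f"view {session.view_names[v]}: {len(boxes)} ROIs for {T} frames"
            )
        crops = np.empty((T, cfg.out_px, cfg.out_px), dtype=np.uint8)
        for t in range(T):
            x, y, w, h = (int(c) for c in boxes[t])
            if w < 1 or h < 1:
                raise ValidationError(
                    f"missing/degenerate ROI at view {session.view_names[v]} "
                    f"frame {t}"
                )
            crops[t] = crop_square(session.views[v][t], ROI(x, y, w, h),
                                   margin_frac=cfg.margin_frac, out_px=cfg.out_px)
        probs = predict_scores(model, crops)
        out[v] = probs[:, WDS]
    return out


def save_classifier(model: ClassifierModel, path) -> None:
    import dataclasses
    import json

    state = model.net.state_dict()
    meta = {"config": dataclasses.asdict(model.config),
            "val_accuracy": model.val_accuracy}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **state)


def load_classifier(path) -> ClassifierModel:
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg_dict = meta["config"]
    cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
    cfg = ClassifierConfig(**cfg_dict)
    net = _build_net(cfg, np.random.default_rng(0))
    net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return ClassifierModel(net=net, config=cfg, val_accuracy=meta["val_accuracy"])


def per_view_correlation(
    series: np.ndarray, labels: np.ndarray, view_names: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix between per-view scores and ground truth.

    Rows/columns are the views plus a final ``truth`` entry. Zero-variance
    series yield NaN entries (flagged as undefined rather than erroring).
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if series.shape[1] != len(labels):
        raise ValidationError("score series and labels have different lengths")
    names = list(view_names or [f"view_{i}" for i in range(len(series))]) + ["truth"]
    data = np.vstack([series, labels[None]])
    n = len(data)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            si, sj = data[i], data[j]
            if si.std() == 0 or sj.std() == 0:
                mat[i, j] = 1.0 if i == j else np.nan
                continue
            mat[i, j] = float(np.corrcoef(si, sj)[0, 1])
    return pd.DataFrame(mat, index=names, columns=names)
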