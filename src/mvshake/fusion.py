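"""Multi-view temporal score fusion (the pipeline's third network stage).

For every timestamp t a *score map* is assembled: the per-view classifier
scores over the window t-n .. t+n (31 frames at the default n=15), one row
per view. A small convolutional network classifies the map — 2-D
convolution with 30 filters and a (3, 5) kernel spanning (views, time),
flatten, a 20-unit ReLU dense layer, batch normalization, dropout, and a
2-unit softmax head. The fused score series is then cleaned with one median
and one minimum filter before thresholding into binary per-frame
predictions.

The network is retrained per camera configuration; applying a model to a
different view count raises :class:`ConfigurationError`. For fewer than
three views the map is zero-padded along the view axis so the same
architecture applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import median_filter as _nd_median
from scipy.ndimage import minimum_filter1d as _nd_minimum

from . import nn
from .errors import ConfigurationError, DataError, ParameterError, SynchronizationError

MIN_VIEW_ROWS = 3  # maps are zero-padded to this many rows


@dataclass(frozen=True)
class FusionConfig:
    """Fusion network and post-filter settings.

    ``n`` is the window half-width (frames); ``median_width`` must be odd.
    ``channels`` = 1 feeds p_wds only (p_nwds is redundant under softmax);
    2 feeds both class scores.
    """

    n: int = 15
    conv_filters: int = 30
    conv_kernel: tuple[int, int] = (3, 5)
    dense_units: int = 20
    dropout_rate: float = 0.3
    median_width: int = 5
    min_width: int = 5
    threshold: float = 0.5
    channels: int = 1
    epochs: int = 60
    batch_size: int = 64
    lr: float = 2e-3
    neg_ratio: float | None = None  # negatives per positive; None = keep all
    augment: bool = True            # score-map augmentation of event windows

    def __post_init__(self):
        if self.median_width % 2 == 0:
            raise ParameterError("median_width must be odd")
        if self.min_width < 1:
            raise ParameterError("min_width must be >= 1")
        if self.channels not in (1, 2):
            raise ParameterError("channels must be 1 or 2")


@dataclass
class FusionModel:
    net: nn.Sequential
    config: FusionConfig
    n_views: int
    history: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# score-map assembly
# ---------------------------------------------------------------------------

def assemble_score_maps(series: np.ndarray, n: int = 15, channels: int = 1) -> np.ndarray:
    """Build one (n_views, 2n+1, channels) score map per frame.

    ``series`` is (n_views, T) of p_wds values in [0, 1]. Boundary frames
    are handled by edge replication of the first/last score. Returns an
    array of shape (T, n_views, 2n+1, channels).
    """
    series = np.atleast_2d(np.asarray(series, dtype=np.float32))
    if series.ndim != 2:
        raise SynchronizationError("series must be (n_views, T)")
    v, t_len = series.shape
    if t_len < 1:
        raise SynchronizationError("empty score series")
    padded = np.pad(series, ((0, 0), (n, n)), mode="edge")
    win = sliding_window_view(padded, 2 * n + 1, axis=1)  # (V, T, 2n+1)
    maps = np.transpose(win, (1, 0, 2))[..., None]        # (T, V, 2n+1, 1)
    if channels == 2:
        maps = np.concatenate([maps, 1.0 - maps], axis=-1)
    return np.ascontiguousarray(maps, dtype=np.float32)


def _pad_views(maps: np.ndarray) -> np.ndarray:
    v = maps.shape[1]
    if v >= MIN_VIEW_ROWS:
        return maps
    pad = np.zeros(
        (maps.shape[0], MIN_VIEW_ROWS - v, *maps.shape[2:]), dtype=maps.dtype
    )
    return np.concatenate([maps, pad], axis=1)


def build_fusion_network(
    n_views: int, cfg: FusionConfig, rng: np.random.Generator
) -> nn.Sequential:
    """The score-map classifier: Conv2D(30, (3,5)) -> dense 20 -> softmax 2."""
    rows = max(MIN_VIEW_ROWS, n_views)
    kh, kw = cfg.conv_kernel
    ho = rows - kh + 1
    wo = (2 * cfg.n + 1) - kw + 1
    if ho < 1 or wo < 1:
        raise ParameterError("conv kernel does not fit the score map")
    return nn.Sequential([
        nn.Conv2D(cfg.channels, cfg.conv_filters, (kh, kw), rng=rng),
        nn.Flatten(),
        nn.Dense(ho * wo * cfg.conv_filters, cfg.dense_units, rng=rng),
        nn.ReLU(),
        nn.BatchNorm(cfg.dense_units),
        nn.Dropout(cfg.dropout_rate),
        nn.Dense(cfg.dense_units, 2, rng=rng),
    ])


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_fusion(
    series: np.ndarray,
    labels: np.ndarray,
    cfg: FusionConfig | None = None,
    seed: int = 0,
) -> FusionModel:
    """Train the fusion network from per-view score series + frame labels.

    WDS center frames are rare (~0.4%), so classes are re-balanced with
    sample weights. By default every frame of the series is kept as a
    training example — the network must see the classifier's full
    background score distribution, including its false-positive bumps, to
    learn to reject them; setting ``neg_ratio`` subsamples negatives to
    all frames within 2n of a positive plus ``neg_ratio`` x positives
    random ones. Seeded and deterministic.
    """
    cfg = cfg or FusionConfig()
    series = np.atleast_2d(np.asarray(series, dtype=np.float32))
    labels = np.asarray(labels, dtype=np.int64)
    if series.shape[1] != len(labels):
        raise SynchronizationError("labels must align with score series")
    if len(np.unique(labels)) < 2:
        raise DataError("fusion training needs both classes present")
    rng = np.random.default_rng(seed)
    maps = _pad_views(assemble_score_maps(series, cfg.n, cfg.channels))

    if cfg.neg_ratio is None:
        idx = np.arange(len(labels))
    else:
        pos = np.nonzero(labels == 1)[0]
        near = np.zeros(len(labels), dtype=bool)
        for p in pos:
            near[max(0, p - 2 * cfg.n) : p + 2 * cfg.n + 1] = True
        near[pos] = False
        neg_pool = np.nonzero((labels == 0) & ~near)[0]
        hard_neg = np.nonzero(near)[0]
        n_random = max(0, int(cfg.neg_ratio * len(pos)))
        rand_neg = rng.choice(neg_pool, size=min(n_random, len(neg_pool)),
                              replace=False)
        idx = np.sort(np.concatenate([pos, hard_neg, rand_neg]))

    x, y = maps[idx], labels[idx]
    natural = np.ones(len(y), dtype=bool)
    if cfg.augment:
        ax, ay = _augment_event_windows(maps, labels, series.shape[0], cfg, rng)
        if len(ax):
            x = np.concatenate([x, ax])
            y = np.concatenate([y, ay])
            natural = np.concatenate([natural, np.zeros(len(ay), dtype=bool)])

    # class-balanced weights; augmented samples share their class mass with
    # the natural ones so neither can dominate the boundary
    weights = np.empty(len(y))
    groups = []
    masses = {0: (0.4, 0.1), 1: (0.3, 0.2)}
    for cls in (0, 1):
        nat = natural & (y == cls)
        aug = ~natural & (y == cls)
        if aug.any() and nat.any():
            m_nat, m_aug = masses[cls]
            groups += [(nat, m_nat), (aug, m_aug)]
        else:
            groups += [(nat | aug, 0.5)]
    for mask, mass in groups:
        weights[mask] = mass / max(1, mask.sum())
    weights *= len(y)

    net = build_fusion_network(series.shape[0], cfg, rng)
    e1 = max(1, int(cfg.epochs * 2 / 3))
    rest = cfg.epochs - e1
    history = net.fit(
        x, y, epochs=e1, batch_size=cfg.batch_size, lr=cfg.lr, rng=rng,
        sample_weight=weights,
    )
    # hard-example mining: after the first phase, negatives that still
    # score high are upweighted (keeps rare background score bumps from
    # surviving fusion), and so are positives that still score low while
    # their window visibly carries signal (a near-1 plateau at the
    # center) — without the signal check, shakes invisible in every used
    # view would be upweighted and would fight the noise rejection. Two
    # rounds, the second at reduced learning rate: classic bootstrapping.
    weights = weights.copy()
    has_signal = x[:, :, cfg.n - 3 : cfg.n + 4].max(axis=(1, 2, 3)) > 0.9
    for epochs, lr in [(rest - rest // 2, cfg.lr), (rest // 2, cfg.lr / 2)]:
        if epochs <= 0:
            continue
        p = net.predict_proba(x)[:, 1]
        hard_neg = (y == 0) & (p > 0.25)
        hard_pos = (y == 1) & (p < 0.75) & has_signal
        for hard in (hard_neg, hard_pos):
            if hard.any():
                weights[hard] *= 8.0
        extra = net.fit(
            x, y, epochs=epochs, batch_size=cfg.batch_size, lr=lr, rng=rng,
            sample_weight=weights,
        )
        history = {k: history[k] + extra[k] for k in history}
    return FusionModel(net=net, config=cfg, n_views=series.shape[0],
                       history=history)


def _augment_event_windows(
    maps: np.ndarray,
    labels: np.ndarray,
    n_views: int,
    cfg: FusionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Score-map augmentation of event neighborhoods.

    A handful of training events cannot cover the patterns the fusion
    network must recognize, so windows within n frames of an event are
    replicated in three label-preserving ways:

    - *view permutations*: any camera may carry the shake signal, so the
      data-carrying rows are shuffled (up to 5 non-identity orders);
    - *single-view isolation*: for each row that actually carries signal
      near the window center, a copy keeps that row and silences the other
      data rows — teaching that a plateau confined to one view is still an
      event (real single-visible-view events are too rare to learn from);
    - *short plateaus*: for positive windows, plateau cells outside the
      center +-1 columns are lowered to background level, emulating
      events near the minimum duration, which are underrepresented.
    """
    import itertools

    pos = np.nonzero(labels == 1)[0]
    if len(pos) == 0:
        return np.empty((0, *maps.shape[1:]), maps.dtype), np.empty(0, np.int64)
    around = np.zeros(len(labels), dtype=bool)
    for p in pos:
        around[max(0, p - cfg.n) : p + cfg.n + 1] = True
    sel = np.nonzero(around)[0]
    base, base_y = maps[sel], labels[sel]
    center = cfg.n
    background = 0.02
    extra_x, extra_y = [], []

    if n_views > 1:
        perms = [p for p in itertools.permutations(range(n_views))
                 if p != tuple(range(n_views))]
        if len(perms) > 5:
            perms = [perms[i] for i in
                     rng.choice(len(perms), size=5, replace=False)]
        for perm in perms:
            order = list(perm) + list(range(n_views, maps.shape[1]))
            extra_x.append(base[:, order])
            extra_y.append(base_y)

        # signal near the center, per window and data row
        core = base[:, :n_views, center - 2 : center + 3].max(axis=(2, 3))
        for r in range(n_views):
            keep = np.nonzero((base_y == 0) | (core[:, r] > 0.5))[0]
            if not len(keep):
                continue
            iso = base[keep].copy()
            for other in range(n_views):
                if other != r:
                    iso[:, other] = background
            extra_x.append(iso)
            extra_y.append(base_y[keep])

    pos_sel = np.nonzero(base_y == 1)[0]
    if len(pos_sel):
        # events near the minimum duration may start or end at the center
        # frame, so both asymmetric 2-frame cores are generated too
        for keep in ((-1, 0, 1), (-1, 0), (0, 1)):
            short = base[pos_sel].copy()
            plateau = short > 0.5
            for off in keep:
                plateau[:, :, center + off] = False
            short[plateau] = background
            extra_x.append(short)
            extra_y.append(base_y[pos_sel])

    bx, by = _inject_bump_negatives(maps, labels, n_views, cfg, rng)
    if len(bx):
        extra_x.append(bx)
        extra_y.append(by)

    x = np.concatenate(extra_x)
    y = np.concatenate(extra_y)
    _paste_context_bumps(x, y, n_views, cfg, rng)
    return x, y


def _paste_context_bumps(
    x: np.ndarray,
    y: np.ndarray,
    n_views: int,
    cfg: FusionConfig,
    rng: np.random.Generator,
) -> None:
    """Add off-center mid-amplitude bumps to augmented positive windows.

    Real events often sit next to background score bumps (the agent faced
    away from a camera just before freezing into the shake), and a network
    taught that bumps mean noise must not let a bump in the *context*
    columns veto a genuine centered plateau. Bumps are pasted at least
    three frames away from the center, in place, labels untouched.
    """
    center = cfg.n
    pos = np.nonzero(y == 1)[0]
    take = pos[rng.random(len(pos)) < 0.5]
    W = x.shape[2]
    for i in take:
        for _ in range(int(rng.integers(1, 3))):
            L = int(rng.integers(1, 7))
            side = rng.choice([-1, 1])
            if side < 0:
                hi = center - 3
                lo = max(0, hi - L)
            else:
                lo = center + 4
                hi = min(W, lo + L)
            if hi <= lo:
                continue
            amp = rng.uniform(0.4, 0.75)
            profile = np.clip(amp + rng.normal(0, 0.05, hi - lo), 0.25, 0.82)
            rows = (range(n_views) if rng.random() < 0.7 else
                    np.atleast_1d(rng.integers(0, n_views)))
            for r in rows:
                cells = x[i, r, lo:hi, 0]
                x[i, r, lo:hi, 0] = np.maximum(cells, profile)
                if x.shape[-1] == 2:
                    x[i, r, lo:hi, 1] = 1.0 - x[i, r, lo:hi, 0]


def _inject_bump_negatives(
    maps: np.ndarray,
    labels: np.ndarray,
    n_views: int,
    cfg: FusionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic negative windows carrying mid-amplitude score bumps.

    The crop classifier's residual errors are mid-confidence (~0.5-0.9)
    bumps on background frames, often simultaneous across views (the
    views share what they see). How many such bumps land in the fusion
    training series varies a lot between runs, so rejection of this noise
    class is taught explicitly: background windows are copied with a
    short-to-long mid-amplitude plateau pasted across the center frame
    and kept labeled negative. Real shakes score near 1.0 in the views
    that see them, so amplitude (plus duration) separates the classes.
    """
    center = cfg.n
    near = np.zeros(len(labels), dtype=bool)
    for p in np.nonzero(labels == 1)[0]:
        near[max(0, p - 4) : p + 5] = True
    pool = np.nonzero((labels == 0) & ~near)[0]
    n_bumps = min(len(pool), max(200, len(labels) // 40))
    if n_bumps == 0:
        return (np.empty((0, *maps.shape[1:]), maps.dtype),
                np.empty(0, np.int64))
    centers = rng.choice(pool, size=n_bumps, replace=False)
    out = maps[centers].copy()
    lengths = rng.choice([1, 2, 3, 4, 6, 9, 14, 22], size=n_bumps,
                         p=[0.18, 0.2, 0.16, 0.12, 0.1, 0.09, 0.08, 0.07])
    for i in range(n_bumps):
        L = int(lengths[i])
        start = center - int(rng.integers(0, L))
        lo = max(0, start)
        hi = min(out.shape[2], start + L)
        amp = rng.uniform(0.4, 0.75)
        profile = np.clip(
            amp + rng.normal(0.0, 0.05, hi - lo), 0.25, 0.82
        ).astype(out.dtype)
        if rng.random() < 0.7:  # views usually agree on what they saw
            rows = list(range(n_views))
        else:
            rows = rng.choice(n_views, size=int(rng.integers(1, n_views + 1)),
                              replace=False)
        for r in np.atleast_1d(rows):
            cells = out[i, r, lo:hi, 0]
            out[i, r, lo:hi, 0] = np.maximum(cells, profile)
            if out.shape[-1] == 2:
                out[i, r, lo:hi, 1] = 1.0 - out[i, r, lo:hi, 0]
    return out, np.zeros(n_bumps, dtype=np.int64)


def fuse_session(model: FusionModel, series: np.ndarray) -> np.ndarray:
    """Fused per-frame p_wds series for one session; deterministic.

    Raises :class:`ConfigurationError` when the view count differs from the
    one the model was trained for (the network is retrained per camera
    configuration).
    """
    series = np.atleast_2d(np.asarray(series, dtype=np.float32))
    if series.shape[0] != model.n_views:
        raise ConfigurationError(
            f"model trained for {model.n_views} views, got {series.shape[0]}"
        )
    cfg = model.config
    maps = _pad_views(assemble_score_maps(series, cfg.n, cfg.channels))
    probs = model.net.predict_proba(maps)
    return probs[:, 1]


# ---------------------------------------------------------------------------
# post-filters
# ---------------------------------------------------------------------------

def median_filter(series: np.ndarray, width: int) -> np.ndarray:
    """Sliding median with edge-replicated borders; width must be odd."""
    if width % 2 == 0 or width < 1:
        raise ParameterError(f"median width must be odd and >= 1, got {width}")
    series = np.asarray(series, dtype=float)
    if width == 1:
        return series.copy()
    return _nd_median(series, size=width, mode="nearest")


def min_filter(series: np.ndarray, width: int) -> np.ndarray:
    """Sliding minimum with edge-replicated borders.

    The window is centered; even widths take the extra sample on the left
    (width 2 looks at frames t-1 and t), so on binarized input a positive
    run of length L survives as a run of length max(0, L - width + 1).
    """
    if width < 1:
        raise ParameterError(f"min width must be >= 1, got {width}")
    series = np.asarray(series, dtype=float)
    if width == 1:
        return series.copy()
    return _nd_minimum(series, size=width, mode="nearest")


def postprocess(series: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Median filter, then minimum filter, then threshold -> binary labels."""
    filtered = min_filter(median_filter(series, cfg.median_width), cfg.min_width)
    return (filtered > cfg.threshold).astype(np.int8)


def save_fusion(model: FusionModel, path) -> None:
    import dataclasses
    import json

    meta = {"config": dataclasses.asdict(model.config), "n_views": model.n_views}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.net.state_dict())


def load_fusion(path) -> FusionModel:
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg_dict = meta["config"]
    cfg_dict["conv_kernel"] = tuple(cfg_dict["conv_kernel"])
    cfg = FusionConfig(**cfg_dict)
    net = build_fusion_network(meta["n_views"], cfg, np.random.default_rng(0))
    net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return FusionModel(net=net, config=cfg, n_views=meta["n_views"])
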