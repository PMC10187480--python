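"""Diverse frame subsampling for manual ROI annotation.

Recordings contain far more frames than anyone can annotate, so a diverse
subsample is chosen by embedding every candidate frame with a fixed generic
convolutional feature extractor, reducing to 100 principal components, and
clustering with K-means; the frame nearest each centroid is selected.

The embedder is pluggable. The default is a fixed bank of seeded random
convolution filters with ReLU and coarse spatial average pooling — a
training-free generic feature extractor whose output dimension is
configurable (1280 matches the classic pretrained-backbone choice). A plain
downsampled-pixel embedder is also provided and is what the test suite
uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DataError, ParameterError


@dataclass(frozen=True)
class EmbedderConfig:
    """Configuration for :func:`embed_frames`.

    ``kind``: ``"randconv"`` (random convolutional features) or ``"pixel"``
    (downsampled pixels). ``dim`` controls the output dimension; for
    randconv it is ``n_filters * pool_grid**2``.
    """

    kind: str = "randconv"
    dim: int = 256
    pool_grid: int = 4
    kernel_px: int = 7
    filter_seed: int = 20230515  # fixed: the extractor is generic, not fitted


def embed_frames(
    frames: np.ndarray | list[np.ndarray], config: EmbedderConfig | None = None
) -> np.ndarray:
    """Embed frames as an (n, d) feature matrix; deterministic."""
    config = config or EmbedderConfig()
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise DataError("embed_frames needs at least one frame")
    x = frames.astype(np.float32)
    if np.issubdtype(frames.dtype, np.integer):
        x /= 255.0
    if config.kind == "pixel":
        side = max(1, int(np.sqrt(config.dim)))
        step_r = max(1, x.shape[1] // side)
        step_c = max(1, x.shape[2] // side)
        pooled = x[:, : step_r * side, : step_c * side]
        pooled = pooled.reshape(len(x), side, step_r, side, step_c).mean(axis=(2, 4))
        return pooled.reshape(len(x), -1)
    if config.kind != "randconv":
        raise ParameterError(f"unknown embedder kind {config.kind!r}")
    g = config.pool_grid
    n_filters = max(1, config.dim // (g * g))
    rng = np.random.default_rng(config.filter_seed)
    k = config.kernel_px
    filters = rng.standard_normal((n_filters, k, k)).astype(np.float32)
    filters -= filters.mean(axis=(1, 2), keepdims=True)
    feats = np.empty((len(x), n_filters, g, g), dtype=np.float32)
    H, W = x.shape[1:]
    gy = np.linspace(0, H, g + 1).astype(int)
    gx = np.linspace(0, W, g + 1).astype(int)
    for f_idx in range(n_filters):
        resp = fftconvolve(x, filters[f_idx][None], mode="same", axes=(1, 2))
        np.maximum(resp, 0.0, out=resp)
        for i in range(g):
            for j in range(g):
                feats[:, f_idx, i, j] = resp[
                    :, gy[i] : gy[i + 1], gx[j] : gx[j + 1]
                ].mean(axis=(1, 2))
    return feats.reshape(len(x), -1)


def select_annotation_frames(
    features: np.ndarray,
    k: int,
    n_components: int = 100,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Select k diverse frame indices by PCA + seeded K-means.

    Features are reduced to ``min(n_components, n - 1, d)`` principal
    components, clustered into k groups (k-means++ init, ``n_init``
    restarts), and the member nearest each centroid (Euclidean, in PCA
    space) is selected. Returns sorted unique indices.
    """
    features = np.asarray(features, dtype=np.float64)
    n, d = features.shape
    if not 1 <= k <= n:
        raise ParameterError(f"need 1 <= k <= n frames, got k={k}, n={n}")
    if k == n:
        return np.arange(n)
    n_comp = max(1, min(n_components, n - 1, d))
    reduced = PCA(n_components=n_comp, random_state=seed).fit_transform(features)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    assign = km.fit_predict(reduced)
    selected = []
    for c in range(k):
        members = np.nonzero(assign == c)[0]
        if members.size == 0:
            continue
        dists = np.linalg.norm(reduced[members] - km.cluster_centers_[c], axis=1)
        selected.append(members[int(np.argmin(dists))])
    return np.unique(selected)
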