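"""Event-level and per-frame evaluation of shake predictions.

Binary per-frame predictions are converted to events (maximal runs of 1),
matched one-to-one against ground-truth events by temporal-order greedy
matching with a >= 1 frame overlap criterion, and summarized as per-event
precision/recall. Per-frame discrimination is summarized with ROC curves on
the raw (fused but unfiltered) scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import UndefinedMetricError
from .io_formats import EventList


def events_from_labels(series: np.ndarray) -> EventList:
    """Maximal runs of 1 as inclusive intervals."""
    series = np.asarray(series).astype(bool).astype(np.int8)
    diff = np.diff(np.concatenate(([0], series, [0])))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    return EventList(tuple(zip(starts.tolist(), ends.tolist())))


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]  # (predicted index, truth index)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def match_events(
    predicted: EventList, truth: EventList, min_overlap: int = 1
) -> MatchResult:
    """Greedy one-to-one matching of predicted to truth events.

    Predictions are visited in temporal order; each matches the earliest
    still-unmatched truth event it overlaps by >= ``min_overlap`` frames.
    Multiple predictions over one truth event yield one TP and the rest FP
    (fragmentation is penalized).
    """
    matched_truth: set[int] = set()
    pairs = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            if j in matched_truth:
                continue
            if _overlap(p, t) >= min_overlap:
                matched_truth.add(j)
                pairs.append((i, j))
                break
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(predicted) - tp, fn=len(truth) - tp, pairs=tuple(pairs)
    )


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """(precision, recall); undefined denominators come back as None."""
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return precision, recall


def roc_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-frame ROC over all thresholds: (thresholds, tpr, fpr, auc)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC is undefined for single-class labels")
    fpr, tpr, thresholds = _skm.roc_curve(labels, np.asarray(scores, dtype=float))
    auc = float(_skm.auc(fpr, tpr))
    return thresholds, tpr, fpr, auc


def evaluate_configurations(
    truth: EventList,
    labels: np.ndarray,
    configurations: dict[str, dict],
) -> pd.DataFrame:
    """Tidy metric table across camera configurations.

    ``configurations`` maps a name (e.g. ``"3_views"``) to a dict with keys
    ``prediction`` (binary per-frame array) and optionally ``scores`` (raw
    fused series, for per-frame AUC). Configurations with missing entries
    are skipped with a warning.
    """
    rows = []
    for name, entry in configurations.items():
        if entry is None or "prediction" not in entry:
            warnings.warn(f"configuration {name!r} has no prediction; skipped")
            continue
        pred_events = events_from_labels(entry["prediction"])
        m = match_events(pred_events, truth)
        precision, recall = precision_recall(m.tp, m.fp, m.fn)
        auc = np.nan
        if entry.get("scores") is not None:
            try:
                auc = roc_curve(entry["scores"], labels)[3]
            except UndefinedMetricError:
                auc = np.nan
        rows.append(
            {"configuration": name, "tp": m.tp, "fp": m.fp, "fn": m.fn,
             "precision": precision, "recall": recall, "frame_auc": auc}
        )
    return pd.DataFrame(rows)


def plot_roc(configurations: dict[str, dict], labels: np.ndarray, path=None):
    """ROC overlay across configurations; writes a PNG when ``path`` given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, entry in configurations.items():
        if entry.get("scores") is None:
            continue
        _, tpr, fpr, auc = roc_curve(entry["scores"], labels)
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
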