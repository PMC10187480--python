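"""End-to-end synthetic benchmark: generate, localize, classify, fuse, score.

This module wires the full detection pipeline together on the synthetic
benchmark so that one seeded call reproduces the study's whole experiment
at desk scale:

1. generate two training sessions and one validation session;
2. pick localizer training frames by embedding + PCA + K-means selection,
   annotate them with the generator's ground-truth boxes, train the
   matched-filter localizer, and measure held-out IoU;
3. predict ROIs everywhere, build the balanced crop dataset from the
   training sessions (session-held-out validation split), train fold
   classifiers for out-of-fold scoring and refit the deployed classifier
   on all crops;
4. train one fusion network per camera configuration (1, 2 and 3 views)
   on the training sessions' out-of-fold score series;
5. evaluate event-level precision/recall on the validation session, and
   pool recall per configuration over additional freshly generated
   validation sessions so the view-count comparison rests on ~100 events.

Everything flows from one seed through named SeedSequence children.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation_selection import EmbedderConfig, embed_frames, select_annotation_frames
from .classifier import (
    ClassifierConfig,
    ClassifierEnsemble,
    ClassifierModel,
    score_session,
    train_classifier,
)
from .dataset_builder import build_classification_dataset
from .errors import UndefinedMetricError
from .evaluation import events_from_labels, match_events, precision_recall, roc_curve
from .fusion import FusionConfig, FusionModel, fuse_session, postprocess, train_fusion
from .io_formats import MultiViewSession
from .localization import LocalizerModel, mean_iou, predict_rois, train_localizer
from .synthetic import benchmark_params, generate_benchmark, _generate_with


#: Post-filter widths for the 15 fps fast profile: the default 5/5 pair
#: suppresses events shorter than ~0.17 s at 30 fps; at 15 fps the same
#: cutoff is ~2.5 frames, giving median 3 / min 2.
FAST_FUSION = FusionConfig(median_width=3, min_width=2)


@dataclass(frozen=True)
class BenchmarkConfig:
    profile: str = "fast"
    n_annotation_frames: int = 500
    n_holdout_frames: int = 72
    annotation_stride: int = 8     # frame subsampling before embedding
    n_eval_sessions: int = 20      # extra validation sessions for the
                                   # view-count recall comparison (~140
                                   # events; each session holds only ~7)
    view_configs: tuple[tuple[int, ...], ...] = ((0,), (0, 1), (0, 1, 2))
    fusion: FusionConfig = FAST_FUSION
    classifier: ClassifierConfig = ClassifierConfig()
    embedder: EmbedderConfig = EmbedderConfig()


@dataclass
class BenchmarkResult:
    """All quantities the benchmark computes, by pipeline stage."""

    precision: float | None          # 3-view, validation session, per event
    recall: float | None
    classifier_val_accuracy: float
    localizer_holdout_iou: float
    recall_by_views: dict[int, float]     # pooled over eval sessions
    precision_by_views: dict[int, float | None]
    auc_by_views: dict[int, float]        # per-frame, validation session
    table: pd.DataFrame                   # per-configuration metrics
    n_val_events: int
    n_eval_events: int
    n_crops_train: int
    n_crops_val: int
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def train_pipeline_models(
    trains: list[MultiViewSession],
    cfg: BenchmarkConfig,
    seed: int,
) -> tuple[LocalizerModel, ClassifierModel, dict[int, FusionModel], dict]:
    """Train localizer, classifier and per-configuration fusion models."""
    s_select, s_loc, s_crops, s_clf, s_fuse = _child_seeds(seed, 5)

    # -- localizer: diverse annotated frames via embedding + PCA + K-means
    pool_frames, pool_boxes = [], []
    for sess in trains:
        for v in range(sess.n_views):
            idx = np.arange(0, sess.n_frames, cfg.annotation_stride)
            pool_frames.append(sess.views[v][idx])
            pool_boxes.append(sess.rois[v][idx])
    pool_frames = np.concatenate(pool_frames)
    pool_boxes = np.concatenate(pool_boxes)
    feats = embed_frames(pool_frames, cfg.embedder)
    chosen = select_annotation_frames(
        feats, k=min(cfg.n_annotation_frames, len(pool_frames)), seed=s_select
    )
    localizer = train_localizer(pool_frames[chosen], pool_boxes[chosen], seed=s_loc)

    # -- predicted ROIs on the training sessions feed everything downstream
    rois_pred = {s.session_id: predict_session_rois(localizer, s) for s in trains}

    # -- balanced crop dataset (validation split = held-out session)
    crops_train, crops_val = build_classification_dataset(
        trains, rois_pred, seed=s_crops,
        margin_frac=cfg.classifier.margin_frac, out_px=cfg.classifier.out_px,
    )

    # -- classifiers, stacking-style. Two fold classifiers (one per
    # session) produce out-of-fold score series: a classifier partly
    # memorizes its own training crops, so in-sample scores would make
    # shakes that were invisible in a view look detectable there and would
    # hide the mid-confidence background bumps the fusion stage must learn
    # to reject. The deployed scorer is an ensemble of the fold models and
    # a refit on all crops: averaging decorrelates each member's
    # overconfident background mistakes, so inference-time bump amplitudes
    # sit at or below those of the single-model out-of-fold training
    # series — fusion is biased toward rejecting noise, the safe
    # direction. Validation accuracy is the pooled two-fold figure.
    s_clf2, s_clf_full = _child_seeds(s_clf, 2)
    clf_a = train_classifier(crops_train, cfg.classifier, seed=s_clf,
                             val=crops_val)
    clf_b = train_classifier(crops_val, cfg.classifier, seed=s_clf2,
                             val=crops_train)
    n_a, n_b = len(crops_train), len(crops_val)
    val_accuracy = (clf_a.val_accuracy * n_b + clf_b.val_accuracy * n_a) \
        / (n_a + n_b)
    all_crops = _merge_crops(crops_train, crops_val)
    clf_full = train_classifier(all_crops, cfg.classifier, seed=s_clf_full)
    clf = ClassifierEnsemble([clf_a, clf_b, clf_full],
                             val_accuracy=val_accuracy)

    # out-of-fold series over both training sessions feed fusion training
    held_out_id = trains[-1].session_id
    series_parts, label_parts = [], []
    for sess in trains:
        scorer = clf_a if sess.session_id == held_out_id else clf_b
        series_parts.append(score_session(scorer, sess,
                                          rois_pred[sess.session_id]))
        label_parts.append(sess.labels)
    full_series = np.concatenate(series_parts, axis=1)
    labels = np.concatenate(label_parts)

    # -- one fusion model per camera configuration
    fusers: dict[int, FusionModel] = {}
    fusion_seeds = _child_seeds(s_fuse, len(cfg.view_configs))
    for views, fs in zip(cfg.view_configs, fusion_seeds):
        fusers[len(views)] = train_fusion(
            full_series[list(views)], labels, cfg.fusion, seed=fs
        )
    info = {
        "rois_pred": rois_pred,
        "crops_train": crops_train,
        "crops_val": crops_val,
        "classifier_val_accuracy": val_accuracy,
        "n_annotation_frames": len(chosen),
    }
    return localizer, clf, fusers, info


def _merge_crops(a, b):
    import pandas as pd

    from .dataset_builder import CropDataset

    return CropDataset(
        np.concatenate([a.images, b.images]),
        np.concatenate([a.labels, b.labels]),
        pd.concat([a.provenance, b.provenance], ignore_index=True),
        split="all",
        balance_tol=a.balance_tol + b.balance_tol,
    )


def predict_session_rois(
    localizer: LocalizerModel, sess: MultiViewSession
) -> list[np.ndarray]:
    out = []
    for v in range(sess.n_views):
        boxes, _ = predict_rois(localizer, sess.views[v])
        out.append(boxes)
    return out


def evaluate_session(
    sess: MultiViewSession,
    localizer: LocalizerModel,
    clf: ClassifierModel,
    fusers: dict[int, FusionModel],
    cfg: BenchmarkConfig,
    return_series: bool = False,
):
    """Per-configuration event metrics + per-frame AUC for one session.

    With ``return_series`` also returns the raw per-view score series and
    the fused series per configuration (for diagnostics).
    """
    rois = predict_session_rois(localizer, sess)
    series = score_session(clf, sess, rois)
    rows = []
    fused_by_k = {}
    for views in cfg.view_configs:
        k = len(views)
        fused = fuse_session(fusers[k], series[list(views)])
        fused_by_k[k] = fused
        pred = postprocess(fused, cfg.fusion)
        m = match_events(events_from_labels(pred), sess.events)
        prec, rec = precision_recall(m.tp, m.fp, m.fn)
        try:
            auc = roc_curve(fused, sess.labels)[3]
        except UndefinedMetricError:
            auc = np.nan
        rows.append({
            "configuration": f"{k}_view" + ("s" if k > 1 else ""),
            "n_views": k, "tp": m.tp, "fp": m.fp, "fn": m.fn,
            "precision": prec, "recall": rec, "frame_auc": auc,
        })
    table = pd.DataFrame(rows)
    if return_series:
        return table, series, fused_by_k
    return table


def run_benchmark(seed: int = 0, cfg: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Run the full benchmark from one seed; see the module docstring."""
    cfg = cfg or BenchmarkConfig()
    s_gen, s_train, s_holdout, s_eval = _child_seeds(seed, 4)

    trains, val = generate_benchmark(cfg.profile, seed=s_gen)
    localizer, clf, fusers, info = train_pipeline_models(trains, cfg, s_train)

    # -- localizer held-out IoU on frames the training pool never saw
    rng = np.random.default_rng(s_holdout)
    hold_idx = rng.choice(val.n_frames, size=cfg.n_holdout_frames, replace=False)
    hold_view = rng.integers(0, val.n_views, size=cfg.n_holdout_frames)
    hold_frames = np.stack([val.views[v][t] for v, t in zip(hold_view, hold_idx)])
    hold_truth = np.stack([val.rois[v][t] for v, t in zip(hold_view, hold_idx)])
    hold_pred, _ = predict_rois(localizer, hold_frames)
    holdout_iou = mean_iou(hold_pred, hold_truth)

    # -- validation-session metrics per configuration
    table, val_series, val_fused = evaluate_session(
        val, localizer, clf, fusers, cfg, return_series=True
    )
    row3 = table[table.n_views == max(len(v) for v in cfg.view_configs)].iloc[0]

    # -- pooled recall per configuration over extra validation sessions
    _, val_sp, rp = benchmark_params(cfg.profile)
    counts = {len(v): {"tp": 0, "fn": 0, "fp": 0} for v in cfg.view_configs}
    for c in counts:
        counts[c]["tp"] += int(table[table.n_views == c].tp.iloc[0])
        counts[c]["fn"] += int(table[table.n_views == c].fn.iloc[0])
        counts[c]["fp"] += int(table[table.n_views == c].fp.iloc[0])
    n_eval_events = len(val.events)
    eval_seeds = _child_seeds(s_eval, max(0, cfg.n_eval_sessions - 1))
    for i, es in enumerate(eval_seeds):
        sess = _generate_with(val_sp, rp, es, f"eval_{i}")
        sub = evaluate_session(sess, localizer, clf, fusers, cfg)
        n_eval_events += len(sess.events)
        for c in counts:
            r = sub[sub.n_views == c].iloc[0]
            counts[c]["tp"] += int(r.tp)
            counts[c]["fn"] += int(r.fn)
            counts[c]["fp"] += int(r.fp)
    recall_by_views = {
        c: v["tp"] / max(1, v["tp"] + v["fn"]) for c, v in counts.items()
    }
    precision_by_views = {
        c: (v["tp"] / (v["tp"] + v["fp"]) if v["tp"] + v["fp"] else None)
        for c, v in counts.items()
    }

    return BenchmarkResult(
        precision=None if pd.isna(row3.precision) else float(row3.precision),
        recall=None if pd.isna(row3.recall) else float(row3.recall),
        classifier_val_accuracy=float(info["classifier_val_accuracy"]),
        localizer_holdout_iou=float(holdout_iou),
        recall_by_views=recall_by_views,
        precision_by_views=precision_by_views,
        auc_by_views={int(r.n_views): float(r.frame_auc) for _, r in table.iterrows()},
        table=table,
        n_val_events=len(val.events),
        n_eval_events=n_eval_events,
        n_crops_train=len(info["crops_train"]),
        n_crops_val=len(info["crops_val"]),
        seed=seed,
        extras={
            "counts": counts,
            "n_annotation_frames": info["n_annotation_frames"],
            "val_events": val.events,
            "val_labels": val.labels,
            "val_series": val_series,
            "val_fused": val_fused,
        },
    )
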