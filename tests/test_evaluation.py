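import itertools
import warnings

import numpy as np
import pytest

from mvshake.errors import UndefinedMetricError
from mvshake.evaluation import (
    evaluate_configurations,
    events_from_labels,
    match_events,
    precision_recall,
    roc_curve,
)
from mvshake.io_formats import EventList, labels_from_events

from conftest import random_event_list


class TestEventsFromLabels:
    def test_maximal_runs(self):
        ev = events_from_labels([0, 1, 1, 0, 1, 0])
        assert ev.intervals == ((1, 2), (4, 4))

    def test_all_zeros(self):
        assert events_from_labels(np.zeros(8)).intervals == ()

    def test_all_ones(self):
        assert events_from_labels(np.ones(5)).intervals == ((0, 4),)


def max_matching_oracle(pred, truth):
    """Exhaustive bipartite-overlap oracle: maximum one-to-one matching."""
    overlaps = {
        (i, j)
        for i, p in enumerate(pred)
        for j, t in enumerate(truth)
        if min(p[1], t[1]) >= max(p[0], t[0])
    }
    best = 0
    n = min(len(pred), len(truth))
    for k in range(n, 0, -1):
        for pi in itertools.permutations(range(len(truth)), k):
            for ci in itertools.combinations(range(len(pred)), k):
                if all((i, j) in overlaps for i, j in zip(ci, pi)):
                    return k
    return best


class TestMatching:
    def test_overlapping_pair_is_tp(self):
        m = match_events(EventList(((12, 18),)), EventList(((10, 20),)))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_disjoint_pair_is_fp_and_fn(self):
        m = match_events(EventList(((30, 35),)), EventList(((10, 20),)))
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_fragmented_prediction_penalized(self):
        m = match_events(EventList(((10, 12), (14, 20))), EventList(((10, 20),)))
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_counts_partition_both_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            T = int(rng.integers(10, 60))
            pred = random_event_list(rng, T)
            truth = random_event_list(rng, T)
            m = match_events(pred, truth)
            assert m.tp + m.fp == len(pred)
            assert m.tp + m.fn == len(truth)

    def test_greedy_matches_exhaustive_oracle(self):
        # on sorted non-overlapping interval lists the greedy temporal-order
        # matching attains the maximum bipartite matching
        rng = np.random.default_rng(1)
        for _ in range(300):
            T = int(rng.integers(8, 40))
            pred = random_event_list(rng, T)
            truth = random_event_list(rng, T)
            m = match_events(pred, truth)
            assert m.tp == max_matching_oracle(pred.intervals, truth.intervals)


class TestPrecisionRecall:
    def test_direct_arithmetic(self):
        assert precision_recall(2, 1, 3) == (pytest.approx(2 / 3),
                                             pytest.approx(0.4))

    def test_perfect_detection(self):
        assert precision_recall(5, 0, 0) == (1.0, 1.0)

    def test_undefined_denominators_flagged(self):
        precision, recall = precision_recall(0, 0, 3)
        assert precision is None and recall == 0.0
        precision, recall = precision_recall(0, 2, 0)
        assert precision == 0.0 and recall is None


def threshold_enumeration_roc(scores, labels):
    """Oracle: sweep every distinct score as threshold, trapezoid AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for thr in np.unique(scores):
        pred = scores >= thr
        tpr = (pred & (labels == 1)).sum() / max(1, (labels == 1).sum())
        fpr = (pred & (labels == 0)).sum() / max(1, (labels == 0).sum())
        pts.add((float(fpr), float(tpr)))
    pts = sorted(pts)
    return float(np.trapezoid([p[1] for p in pts], [p[0] for p in pts]))


class TestRoc:
    def test_perfect_separation_auc_one(self):
        labels = np.array([0, 0, 1, 1])
        _, _, _, auc = roc_curve(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert abs(roc_curve(scores, labels)[3] - 0.5) <= 0.02

    def test_matches_threshold_enumeration_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert roc_curve(scores, labels)[3] == pytest.approx(
            threshold_enumeration_roc(scores, labels)
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_curve(scores, labels)[3] == pytest.approx(
                threshold_enumeration_roc(scores, labels)
            )

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_curve(np.array([0.2, 0.6]), np.array([1, 1]))

    def test_curve_monotone_and_auc_bounded(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        _, tpr, fpr, auc = roc_curve(scores, labels)
        assert (np.diff(tpr) >= 0).all()
        assert (np.diff(fpr) >= 0).all()
        assert 0.0 <= auc <= 1.0


class TestEvaluateConfigurations:
    def test_three_configurations_three_rows(self):
        T = 50
        truth = EventList(((10, 14), (30, 33)))
        labels = labels_from_events(truth, T)
        pred = labels.copy()
        configs = {f"{k}_views": {"prediction": pred,
                                  "scores": pred.astype(float)}
                   for k in (1, 2, 3)}
        table = evaluate_configurations(truth, labels, configs)
        assert len(table) == 3
        assert set(table.columns) >= {"precision", "recall", "frame_auc"}

    def test_identical_predictions_identical_rows(self):
        truth = EventList(((5, 8),))
        labels = labels_from_events(truth, 30)
        entry = {"prediction": labels.copy(), "scores": labels.astype(float)}
        table = evaluate_configurations(truth, labels,
                                        {"a": dict(entry), "b": dict(entry)})
        a = table[table.configuration == "a"].drop(columns="configuration")
        b = table[table.configuration == "b"].drop(columns="configuration")
        assert a.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_missing_configuration_skipped_with_warning(self):
        truth = EventList(((5, 8),))
        labels = labels_from_events(truth, 30)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = evaluate_configurations(
                truth, labels,
                {"ok": {"prediction": labels.copy()}, "missing": {}},
            )
        assert len(table) == 1
        assert any("missing" in str(w.message) for w in caught)
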