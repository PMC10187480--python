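import numpy as np
import pytest
from scipy.stats import truncnorm

from mvshake.errors import ResolutionError, SchedulingError, ValidationError
from mvshake.io_formats import EventList, read_session
from mvshake.synthetic import (
    RenderParams,
    ScheduleParams,
    benchmark_params,
    default_views,
    make_benchmark,
    render_session,
    sample_durations,
    sample_event_schedule,
)


class TestSchedule:
    def test_fixed_event_count_is_exact(self):
        ev = sample_event_schedule(ScheduleParams(n_events=49), seed=0)
        assert len(ev) == 49

    def test_zero_events_gives_empty_list(self):
        assert len(sample_event_schedule(ScheduleParams(n_events=0), seed=0)) == 0

    def test_duration_moments_match_truncated_normal(self):
        # Monte-Carlo check of the sampler against its target moments; the
        # tolerance covers the truncation shift (+0.005 s) plus standard error
        p = ScheduleParams()
        d = sample_durations(1000, p, np.random.default_rng(123))
        assert abs(d.mean() - 0.33) <= 0.01
        assert abs(d.std(ddof=1) - 0.11) <= 0.01
        assert d.min() >= p.duration_min_s
        # and against scipy's analytic truncated-normal mean
        a = (p.duration_min_s - p.duration_mean_s) / p.duration_sd_s
        exact_mean = truncnorm.mean(a, np.inf, loc=0.33, scale=0.11)
        assert abs(d.mean() - exact_mean) < 3 * 0.11 / np.sqrt(1000)

    def test_schedules_respect_min_gap_and_bounds(self):
        p = ScheduleParams(session_seconds=120, fps=30, n_events=12)
        for seed in range(20):
            ev = sample_event_schedule(p, seed)
            assert len(ev) == 12
            gap_frames = int(p.min_gap_s * p.fps)
            prev_end = None
            for s, e in ev:
                assert 0 <= s <= e <= 120 * 30 - 1
                if prev_end is not None:
                    assert s - prev_end - 1 >= gap_frames - 2  # rounding slack
                prev_end = e

    def test_overfull_schedule_raises(self):
        with pytest.raises(SchedulingError):
            sample_event_schedule(
                ScheduleParams(session_seconds=5, n_events=30), seed=0
            )

    def test_mean_wds_fraction_near_paper_rate(self):
        # 200 one-hour schedules at the default Poisson rate: the mean
        # WDS-frame fraction should sit within 10% of 0.38%
        fracs = []
        for seed in range(200):
            ev = sample_event_schedule(ScheduleParams(), seed)
            fracs.append(ev.n_frames_covered / (3600 * 30))
        mean_frac = float(np.mean(fracs))
        assert 0.9 * 0.0038 <= mean_frac <= 1.1 * 0.0038

    def test_deterministic_given_seed(self):
        p = ScheduleParams(n_events=10)
        assert (sample_event_schedule(p, 5).intervals
                == sample_event_schedule(p, 5).intervals)


class TestRendering:
    def test_empty_schedule_renders_all_nwds(self):
        rp = RenderParams(frame_px=48, n_views=2, session_seconds=10, fps=30)
        sess = render_session(EventList(), rp, seed=0)
        assert sess.n_frames == 300
        assert all(len(v) == 300 for v in sess.views)
        assert sess.labels.sum() == 0

    def test_same_seed_renders_bit_identical_frames(self):
        rp = RenderParams(frame_px=48, n_views=2, session_seconds=4, fps=15)
        ev = EventList(((10, 14),))
        a = render_session(ev, rp, seed=9)
        b = render_session(ev, rp, seed=9)
        for va, vb in zip(a.views, b.views):
            np.testing.assert_array_equal(va, vb)

    def test_resolution_floor_enforced(self):
        with pytest.raises(ResolutionError):
            render_session(EventList(), RenderParams(frame_px=31), seed=0)

    def test_schedule_must_fit_session(self):
        rp = RenderParams(frame_px=48, session_seconds=1, fps=10)
        with pytest.raises(ValidationError):
            render_session(EventList(((5, 20),)), rp, seed=0)

    def test_rois_track_agent_within_bounds(self):
        rp = RenderParams(frame_px=48, n_views=1, session_seconds=6, fps=15)
        sess = render_session(EventList(((20, 24),)), rp, seed=3)
        boxes = sess.rois[0]
        assert (boxes[:, 2] >= 1).all() and (boxes[:, 3] >= 1).all()
        assert (boxes[:, 0] >= 0).all()
        assert (boxes[:, 0] + boxes[:, 2] <= 48).all()
        assert (boxes[:, 1] + boxes[:, 3] <= 48).all()

    def test_multi_view_recovers_events_single_view_misses(self):
        # over many events, the union of three views renders strictly more
        # events visibly than the first side view alone
        sp = ScheduleParams(session_seconds=240, fps=15, n_events=30,
                            min_gap_s=1.0)
        rp = RenderParams(frame_px=48, n_views=3, session_seconds=240, fps=15)
        gates = []
        for seed in range(4):
            ev = sample_event_schedule(sp, seed)
            sess = render_session(ev, rp, seed=seed)
            gates.append(sess.meta["event_visibility"])
        g = np.concatenate(gates)
        assert len(g) == 120
        frac_view0 = g[:, 0].mean()
        frac_union = g.any(axis=1).mean()
        assert frac_union > frac_view0
        assert g.any(axis=1).all()  # every event visible somewhere
        # per-view misses exist but the union miss rate is strictly smaller
        assert (1 - g[:, 0].mean()) > 0
        assert (1 - g.any(axis=1).mean()) < (1 - g[:, 0].mean())

    def test_visibility_probability_follows_orientation(self):
        side = default_views(3)[0]
        away = np.radians(side.azimuth_deg + 180)
        assert side.prob(away) == side.vis_blind
        assert side.prob(away + np.pi) == side.vis_facing
        top = default_views(3)[2]
        assert top.prob(0.0) == top.prob(2.0) == top.vis_facing


class TestBenchmarkProfiles:
    def test_fast_profile_preserves_wds_fraction(self):
        train_sp, val_sp, rp = benchmark_params("fast")
        assert rp.fps == 15 and rp.frame_px == 64
        for sp in [*train_sp, val_sp]:
            for seed in range(5):
                ev = sample_event_schedule(sp, seed)
                frac = ev.n_frames_covered / (600 * 15)
                assert 0.002 <= frac <= 0.006

    def test_full_profile_validation_hour_has_49_events(self):
        _, val_sp, _ = benchmark_params("full")
        assert val_sp.n_events == 49
        assert len(sample_event_schedule(val_sp, 0)) == 49

    def test_full_profile_training_counts_mirror_study(self):
        train_sp, _, _ = benchmark_params("full")
        assert [sp.n_events for sp in train_sp] == [149, 220]

    def test_tiny_benchmark_round_trips_through_session_reader(self, tmp_path):
        out = make_benchmark(tmp_path / "bench", profile="tiny", seed=0)
        for name in ("train_0", "train_1", "val"):
            sess = read_session(out / name)
            assert sess.n_views == 3
            assert sess.n_frames == 300
            assert len(sess.events) == 2
            assert sess.rois is not None

    def test_benchmark_refuses_overwrite(self, tmp_path):
        out = tmp_path / "bench"
        out.mkdir()
        (out / "marker.txt").write_text("x")
        with pytest.raises(ValidationError):
            make_benchmark(out, profile="tiny", seed=0)
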