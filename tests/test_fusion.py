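import numpy as np
import pytest

from mvshake.errors import ConfigurationError, DataError, ParameterError
from mvshake.fusion import (
    FusionConfig,
    assemble_score_maps,
    build_fusion_network,
    fuse_session,
    load_fusion,
    median_filter,
    min_filter,
    postprocess,
    save_fusion,
    train_fusion,
)


# -- brute-force window oracles ---------------------------------------------

def window_median_oracle(x, width):
    half = width // 2
    out = np.empty_like(np.asarray(x, dtype=float))
    for t in range(len(x)):
        idx = [min(max(t + k, 0), len(x) - 1) for k in range(-half, half + 1)]
        out[t] = np.median([x[i] for i in idx])
    return out


def window_min_oracle(x, width):
    # centered window; even widths take the extra sample on the left
    lo, hi = -(width // 2), width - width // 2 - 1
    out = np.empty_like(np.asarray(x, dtype=float))
    for t in range(len(x)):
        idx = [min(max(t + k, 0), len(x) - 1) for k in range(lo, hi + 1)]
        out[t] = min(x[i] for i in idx)
    return out


class TestScoreMaps:
    def test_default_window_shape_is_31_frames(self):
        series = np.random.default_rng(0).random((3, 100))
        maps = assemble_score_maps(series, n=15)
        assert maps.shape == (100, 3, 31, 1)

    def test_constant_series_fill_every_cell(self):
        maps = assemble_score_maps(np.full((2, 40), 0.7), n=15)
        np.testing.assert_allclose(maps, 0.7)

    def test_boundary_edge_replication(self):
        series = np.array([[0.1, 0.2, 0.3, 0.4, 0.5]])
        maps = assemble_score_maps(series, n=2)
        np.testing.assert_allclose(maps[0, 0, :, 0], [0.1, 0.1, 0.1, 0.2, 0.3])
        np.testing.assert_allclose(maps[4, 0, :, 0], [0.3, 0.4, 0.5, 0.5, 0.5])

    def test_values_stay_in_unit_interval_everywhere(self):
        series = np.random.default_rng(1).random((4, 60))
        maps = assemble_score_maps(series, n=15, channels=2)
        assert maps.shape == (60, 4, 31, 2)
        assert maps.min() >= 0.0 and maps.max() <= 1.0


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self):
        # conv: (1*3*5 + 1) * 30 = 480 ; flatten 1*27*30 = 810
        # dense: 810*20 + 20 = 16220 ; batchnorm: 2*20 = 40
        # head: 20*2 + 2 = 42  -> total 16782
        cfg = FusionConfig()
        net = build_fusion_network(3, cfg, np.random.default_rng(0))
        conv = (1 * 3 * 5 + 1) * 30
        dense = (1 * 27 * 30) * 20 + 20
        bn = 2 * 20
        head = 20 * 2 + 2
        assert net.n_params == conv + dense + bn + head == 16782

    def test_four_view_variant_grows_conv_output(self):
        net = build_fusion_network(4, FusionConfig(), np.random.default_rng(0))
        dense = (2 * 27 * 30) * 20 + 20
        assert net.n_params == 480 + dense + 40 + 42

    def test_kernel_must_fit_window(self):
        with pytest.raises(ParameterError):
            build_fusion_network(3, FusionConfig(n=1), np.random.default_rng(0))


def make_separable_series(rng, t_len=400, n_views=3):
    """Score series where the center frame alone separates the classes."""
    labels = np.zeros(t_len, dtype=np.int64)
    pos = rng.choice(np.arange(20, t_len - 20), size=t_len // 10, replace=False)
    labels[pos] = 1
    series = rng.random((n_views, t_len)) * 0.25
    series[:, labels == 1] = 0.85 + rng.random((n_views, (labels == 1).sum())) * 0.1
    return series, labels


class TestTraining:
    def test_separable_fixture_reaches_high_accuracy(self):
        rng = np.random.default_rng(0)
        series, labels = make_separable_series(rng)
        cfg = FusionConfig(epochs=25)
        model = train_fusion(series, labels, cfg, seed=0)
        fused = fuse_session(model, series)
        acc = ((fused > 0.5).astype(int) == labels).mean()
        assert acc >= 0.99

    def test_same_seed_reproduces_training_curve(self):
        rng = np.random.default_rng(1)
        series, labels = make_separable_series(rng, t_len=200)
        cfg = FusionConfig(epochs=5)
        a = train_fusion(series, labels, cfg, seed=4)
        b = train_fusion(series, labels, cfg, seed=4)
        assert a.history["loss"] == b.history["loss"]

    def test_single_class_labels_rejected(self):
        series = np.random.default_rng(0).random((3, 100))
        with pytest.raises(DataError):
            train_fusion(series, np.zeros(100), FusionConfig(epochs=1), seed=0)

    def test_view_count_mismatch_raises_configuration_error(self):
        rng = np.random.default_rng(2)
        series, labels = make_separable_series(rng, t_len=150, n_views=2)
        model = train_fusion(series, labels, FusionConfig(epochs=2), seed=0)
        three_view = np.random.default_rng(3).random((3, 50))
        with pytest.raises(ConfigurationError):
            fuse_session(model, three_view)

    def test_t_frames_in_t_scores_out(self):
        rng = np.random.default_rng(3)
        series, labels = make_separable_series(rng, t_len=150)
        model = train_fusion(series, labels, FusionConfig(epochs=2), seed=0)
        fused = fuse_session(model, rng.random((3, 77)))
        assert fused.shape == (77,)
        assert (fused >= 0).all() and (fused <= 1).all()

    def test_four_view_training_and_inference(self):
        # exercises the >5-permutation sampling path of the augmentation
        rng = np.random.default_rng(5)
        series, labels = make_separable_series(rng, t_len=250, n_views=4)
        model = train_fusion(series, labels, FusionConfig(epochs=10), seed=0)
        fused = fuse_session(model, series)
        acc = ((fused > 0.5).astype(int) == labels).mean()
        assert acc >= 0.95

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        series, labels = make_separable_series(rng, t_len=150)
        model = train_fusion(series, labels, FusionConfig(epochs=2), seed=0)
        save_fusion(model, tmp_path / "f.npz")
        back = load_fusion(tmp_path / "f.npz")
        np.testing.assert_array_equal(fuse_session(back, series),
                                      fuse_session(model, series))


class TestFilters:
    def test_median_removes_isolated_spike(self):
        out = median_filter(np.array([0, 1, 0, 0, 0], dtype=float), 3)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_median_idempotent_on_constant(self):
        np.testing.assert_array_equal(median_filter(np.full(9, 0.4), 5),
                                      np.full(9, 0.4))

    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).random(12)
        np.testing.assert_array_equal(median_filter(x, 1), x)
        np.testing.assert_array_equal(min_filter(x, 1), x)

    def test_even_median_width_rejected(self):
        with pytest.raises(ParameterError):
            median_filter(np.zeros(5), 4)

    def test_min_filter_width_two_enumerated_example(self):
        out = min_filter(np.array([0, 1, 1, 0], dtype=float), 2)
        np.testing.assert_array_equal(out, [0, 0, 1, 0])

    def test_min_filter_all_ones_unchanged(self):
        np.testing.assert_array_equal(min_filter(np.ones(7), 3), np.ones(7))

    def test_filters_match_window_oracles_on_random_series(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            x = rng.random(int(rng.integers(1, 40)))
            w_med = int(rng.choice([1, 3, 5, 7]))
            w_min = int(rng.integers(1, 7))
            np.testing.assert_allclose(
                median_filter(x, w_med), window_median_oracle(x, w_med)
            )
            np.testing.assert_allclose(
                min_filter(x, w_min), window_min_oracle(x, w_min)
            )

    def test_min_filter_shrinks_short_runs_on_binary_input(self):
        x = np.array([0, 1, 1, 1, 0, 0, 1, 0, 1, 1], dtype=float)
        out = min_filter(x, 3)
        # runs shorter than the width vanish; a length-3 run survives as 1;
        # the trailing run keeps its last frame through edge replication
        np.testing.assert_array_equal(out, [0, 0, 1, 0, 0, 0, 0, 0, 0, 1])


class TestPostprocess:
    CFG = FusionConfig(median_width=5, min_width=5)

    def test_all_zero_scores_stay_nwds(self):
        assert postprocess(np.zeros(50), self.CFG).sum() == 0

    def test_single_frame_spike_suppressed(self):
        x = np.zeros(41)
        x[20] = 1.0
        assert postprocess(x, self.CFG).sum() == 0

    def test_long_plateau_survives(self):
        x = np.zeros(60)
        x[20:32] = 0.95  # 12-frame plateau
        out = postprocess(x, self.CFG)
        assert out.sum() > 0
        assert out[24:28].all()

    def test_min_filter_never_adds_positive_frames(self):
        rng = np.random.default_rng(6)
        cfg = FusionConfig(median_width=1, min_width=4)
        for _ in range(50):
            x = rng.random(40)
            before = set(np.nonzero(x > cfg.threshold)[0])
            after = set(np.nonzero(postprocess(x, cfg))[0])
            assert after <= before
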