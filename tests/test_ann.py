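import numpy as np
import pytest

from petdenoise.ann import (
    AnnModel,
    PatchPairSet,
    ScalingRecord,
    TrainConfig,
    ann_forward,
    apply_row_scaling,
    denoise_frame,
    denoise_series,
    extract_patch_pairs,
    fit_row_scaling,
    invert_row_scaling,
    select_training_patches,
    train_ann,
    train_from_frame_pair,
)
from petdenoise.core import DynamicImage, FrameSchedule

from _oracles import ann_forward_loops, denoise_frame_loops


def random_model(rng, n_inp=64, n_hid=128, n_out=8):
    sc = ScalingRecord(
        input_min=-np.abs(rng.normal(1, 0.1, n_inp)),
        input_max=np.abs(rng.normal(1, 0.1, n_inp)),
        label_min=-np.abs(rng.normal(0.5, 0.05, n_out)),
        label_max=np.abs(rng.normal(0.5, 0.05, n_out)),
        global_max=1.0,
    )
    return AnnModel(
        w1=rng.normal(0, 0.1, (n_hid, n_inp)),
        b1=rng.normal(0, 0.1, n_hid),
        w2=rng.normal(0, 0.1, (n_out, n_hid)),
        b2=rng.normal(0, 0.1, n_out),
        scaling=sc,
    )


class TestExtractPatchPairs:
    def test_pair_count_is_number_of_valid_origins(self):
        rng = np.random.default_rng(0)
        f = rng.random((7, 6, 5))
        pairs = extract_patch_pairs(f, f)
        assert pairs.count == (7 - 3) * (6 - 3) * (5 - 3)

    def test_constant_image_gives_all_zero_inputs(self):
        f = np.full((5, 5, 5), 3.7)
        pairs = extract_patch_pairs(f, f)
        assert np.allclose(pairs.inputs, 0)

    def test_single_patch_label_against_hand_indexed_voxels(self):
        """On a 4×4×4 raster volume, verify both label-baseline conventions."""
        u = np.arange(64, dtype=float).reshape(4, 4, 4)
        f = np.zeros((4, 4, 4))
        # central 2×2×2 voxels of the raster cube, C order
        central = np.array(
            [u[1, 1, 1], u[1, 1, 2], u[1, 2, 1], u[1, 2, 2],
             u[2, 1, 1], u[2, 1, 2], u[2, 2, 1], u[2, 2, 2]]
        )
        pairs = extract_patch_pairs(f, u, label_mean="patch")
        assert pairs.count == 1
        assert np.allclose(pairs.labels[0], central - u.mean())
        pairs_c = extract_patch_pairs(f, u, label_mean="central")
        assert np.allclose(pairs_c.labels[0], central - central.mean())

    def test_inputs_are_mean_removed(self):
        rng = np.random.default_rng(1)
        pairs = extract_patch_pairs(rng.random((6, 6, 6)), rng.random((6, 6, 6)))
        assert np.allclose(pairs.inputs.sum(axis=1), 0, atol=1e-10)

    def test_central_mode_labels_are_mean_removed(self):
        rng = np.random.default_rng(2)
        pairs = extract_patch_pairs(
            rng.random((6, 6, 6)), rng.random((6, 6, 6)), label_mean="central"
        )
        assert np.allclose(pairs.labels.sum(axis=1), 0, atol=1e-10)

    def test_shape_mismatch_and_small_volumes_rejected(self):
        with pytest.raises(ValueError):
            extract_patch_pairs(np.zeros((5, 5, 5)), np.zeros((5, 5, 4)))
        with pytest.raises(ValueError):
            extract_patch_pairs(np.zeros((3, 5, 5)), np.zeros((3, 5, 5)))


class TestSelectTrainingPatches:
    def make_pairs(self, variances):
        k = len(variances)
        labels = np.zeros((k, 8))
        for i, v in enumerate(variances):
            labels[i, 0] = np.sqrt(v * 8 / 2)  # var of [a,-a,0..] pattern
            labels[i, 1] = -labels[i, 0]
        return PatchPairSet(np.zeros((k, 64)), labels, np.zeros((k, 3), dtype=int))

    def test_all_pairs_selected_when_count_equals_k(self):
        pairs = self.make_pairs([0.0, 1.0, 2.0])
        cfg = TrainConfig(k_pairs=3, high_variance_count=2, iterations=1)
        sel = select_training_patches(pairs, cfg)
        assert sorted(sel.labels[:, 0].tolist()) == sorted(pairs.labels[:, 0].tolist())

    def test_highest_variance_pairs_kept(self):
        pairs = self.make_pairs([0.0, 1.0, 2.0, 3.0])
        cfg = TrainConfig(k_pairs=2, high_variance_count=2, iterations=1)
        sel = select_training_patches(pairs, cfg)
        got = sorted(np.round(sel.labels.var(axis=1), 6).tolist())
        assert got == [2.0, 3.0]

    def test_same_seed_reproduces_selection(self):
        rng = np.random.default_rng(3)
        pairs = PatchPairSet(
            rng.random((50, 64)), rng.random((50, 8)), np.zeros((50, 3), dtype=int)
        )
        cfg = TrainConfig(k_pairs=20, high_variance_count=10, iterations=1, seed=9)
        a = select_training_patches(pairs, cfg)
        b = select_training_patches(pairs, cfg)
        assert np.array_equal(a.inputs, b.inputs)

    def test_insufficient_pairs_rejected_with_guidance(self):
        pairs = self.make_pairs([1.0, 2.0])
        cfg = TrainConfig(k_pairs=5, high_variance_count=2, iterations=1)
        with pytest.raises(ValueError, match="shrink k_pairs"):
            select_training_patches(pairs, cfg)


class TestRowScaling:
    def test_extrema_map_to_unit_interval_ends(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 64))
        y = rng.normal(size=(100, 8))
        rec, xs, ys = fit_row_scaling(x, y)
        assert np.allclose(xs.min(axis=0), -1)
        assert np.allclose(xs.max(axis=0), 1)
        assert np.allclose(ys.min(axis=0), -1)
        assert np.allclose(ys.max(axis=0), 1)

    def test_scaling_is_an_exact_bijection(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 10))
        lo, hi = x.min(axis=0), x.max(axis=0)
        back = invert_row_scaling(apply_row_scaling(x, lo, hi), lo, hi)
        assert np.allclose(back, x, atol=1e-12)

    def test_degenerate_rows_scale_to_zero_and_back_to_constant(self):
        x = np.full((20, 3), 2.5)
        lo, hi = x.min(axis=0), x.max(axis=0)
        scaled = apply_row_scaling(x, lo, hi)
        assert np.all(scaled == 0)
        assert np.all(invert_row_scaling(scaled, lo, hi) == 2.5)


class TestAnnForward:
    def test_zero_weights_give_zero_output(self):
        m = AnnModel(
            w1=np.zeros((128, 64)), b1=np.zeros(128),
            w2=np.zeros((8, 128)), b2=np.zeros(8),
            scaling=ScalingRecord(np.zeros(64), np.ones(64), np.zeros(8), np.ones(8), 1.0),
        )
        assert np.allclose(ann_forward(m, np.ones(64)), 0)

    def test_pure_offset_network_outputs_its_bias(self):
        c = np.arange(8, dtype=float)
        m = AnnModel(
            w1=np.zeros((128, 64)), b1=np.zeros(128),
            w2=np.zeros((8, 128)), b2=c,
            scaling=ScalingRecord(np.zeros(64), np.ones(64), np.zeros(8), np.ones(8), 1.0),
        )
        rng = np.random.default_rng(6)
        assert np.allclose(ann_forward(m, rng.normal(size=(5, 64))), c)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(7)
        m = random_model(rng, n_hid=16)
        for _ in range(10):
            x = rng.normal(size=64)
            assert np.allclose(ann_forward(m, x), ann_forward_loops(m.w1, m.b1, m.w2, m.b2, x), atol=1e-10)

    def test_wrong_input_length_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            ann_forward(random_model(rng), np.ones(32))


class TestTraining:
    def test_identity_task_trains_to_small_loss(self):
        """Mapping clean patches to their own central crop reaches <1% of label variance."""
        rng = np.random.default_rng(9)
        from scipy import ndimage

        vol = ndimage.gaussian_filter(rng.random((20, 20, 20)), 1.5)
        pairs = extract_patch_pairs(vol / vol.max(), vol / vol.max())
        cfg = TrainConfig(k_pairs=3000, high_variance_count=1500, iterations=20_000, seed=1)
        sel = select_training_patches(pairs, cfg)
        rec, xs, ys = fit_row_scaling(sel.inputs, sel.labels, 1.0)
        model = train_ann(xs, ys, cfg, rec)
        label_var = ys.var(axis=0).sum()
        assert model.loss_trace[-500:].mean() < 0.01 * label_var

    def test_loss_decreases_from_start_to_end(self):
        rng = np.random.default_rng(10)
        xs = rng.normal(size=(2000, 64))
        ys = xs[:, :8] * 0.5
        cfg = TrainConfig(k_pairs=2000, high_variance_count=1000, iterations=3000, seed=2)
        model = train_ann(xs, ys, cfg, ScalingRecord(
            -np.ones(64), np.ones(64), -np.ones(8), np.ones(8), 1.0))
        w = 500
        assert model.loss_trace[-w:].mean() < model.loss_trace[:w].mean()

    def test_same_seed_gives_identical_weights(self):
        rng = np.random.default_rng(11)
        xs = rng.normal(size=(500, 64))
        ys = rng.normal(size=(500, 8))
        cfg = TrainConfig(k_pairs=500, high_variance_count=250, iterations=200, seed=3)
        sc = ScalingRecord(-np.ones(64), np.ones(64), -np.ones(8), np.ones(8), 1.0)
        a = train_ann(xs, ys, cfg, sc)
        b = train_ann(xs, ys, cfg, sc)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        assert np.array_equal(a.loss_trace, b.loss_trace)


class TestDenoiseFrame:
    def test_zero_passes_returns_input(self):
        rng = np.random.default_rng(12)
        z = rng.random((6, 6, 6))
        m = random_model(rng)
        assert np.array_equal(denoise_frame(m, z, passes=0), z)

    def test_negative_passes_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            denoise_frame(random_model(rng), np.ones((6, 6, 6)), passes=-1)

    def test_all_zero_frame_unchanged(self):
        rng = np.random.default_rng(14)
        z = np.zeros((6, 6, 6))
        assert np.array_equal(denoise_frame(random_model(rng), z, 1), z)

    def test_matches_bruteforce_patch_loop_oracle(self):
        rng = np.random.default_rng(15)
        m = random_model(rng, n_hid=16)
        z = rng.random((8, 8, 8))
        fast = denoise_frame(m, z, passes=1)
        slow = denoise_frame_loops(m, z)
        assert np.allclose(fast, slow, rtol=1e-8, atol=1e-10)

    def test_identity_trained_model_nearly_preserves_training_image(self):
        rng = np.random.default_rng(16)
        from scipy import ndimage

        vol = ndimage.gaussian_filter(rng.random((20, 20, 20)), 1.5)
        cfg = TrainConfig(k_pairs=3000, high_variance_count=1500, iterations=6000, seed=4)
        model = train_from_frame_pair(vol, vol, cfg)
        out = denoise_frame(model, vol, passes=1)
        rel_rms = np.sqrt(np.mean((out - vol) ** 2)) / np.sqrt(np.mean(vol**2))
        assert rel_rms < 0.02


class TestDenoiseSeries:
    def test_zero_passes_leaves_series_unchanged(self):
        rng = np.random.default_rng(17)
        dyn = DynamicImage(rng.random((6, 6, 6, 3)), FrameSchedule.from_durations([1, 1, 1]))
        out = denoise_series(random_model(rng), dyn, passes=0)
        assert np.array_equal(out.frames, dyn.frames)

    def test_equals_framewise_denoise_frame(self):
        rng = np.random.default_rng(18)
        m = random_model(rng, n_hid=16)
        dyn = DynamicImage(rng.random((6, 6, 6, 3)), FrameSchedule.from_durations([1, 1, 1]))
        out = denoise_series(m, dyn, passes=2)
        for i in range(3):
            assert np.allclose(out.frames[..., i], denoise_frame(m, dyn.frames[..., i], 2))


class TestSerialization:
    def test_json_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(19)
        m = random_model(rng)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = AnnModel.from_json(path)
        assert np.array_equal(back.w1, m.w1)
        assert np.array_equal(back.b1, m.b1)
        assert np.array_equal(back.w2, m.w2)
        assert np.array_equal(back.b2, m.b2)
        assert np.array_equal(back.scaling.input_min, m.scaling.input_min)
        assert back.scaling.global_max == m.scaling.global_max
        rng2 = np.random.default_rng(20)
        x = rng2.normal(size=(4, 64))
        assert np.array_equal(ann_forward(back, x), ann_forward(m, x))
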