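"""UNet architecture, parameter counting, dice loss, patch sampling,
training mechanics and full-volume inference."""

import numpy as np
import pytest
from scipy import stats

from neosynth import nn
from neosynth.core import Image, LabelMap
from neosynth.recipes import make_cohort
from neosynth.training import (TrainConfig, dice_loss, one_hot,
                               predict_full_volume, sample_patches, train,
                               load_checkpoint)
from neosynth.unet import (UNetConfig, build_unet, count_parameters,
                           count_parameters_config, reference_config,
                           select_reference_convention, toy_config)


class TestParameterCount:
    def test_reference_convention_hits_published_millions(self):
        cfg = reference_config()
        assert count_parameters_config(cfg) == 21_585_418
        assert count_parameters_config(cfg) / 1e6 == pytest.approx(
            21.6, abs=0.05)

    def test_sweep_selects_a_matching_convention(self):
        best = select_reference_convention()
        assert best["parameters"] / 1e6 == pytest.approx(21.6, abs=0.05)
        assert best["upsample"] == "transposed"

    def test_built_network_matches_closed_form(self):
        for cfg in (toy_config(2, 1, 4, 2),
                    toy_config(3, 2, 6, 5),
                    UNetConfig(levels=3, convs_per_level=3,
                               base_features=4, n_classes=9,
                               upsample="transposed",
                               residual_mode="tail",
                               decoder_residual_mode="full")):
            net = build_unet(cfg, np.random.default_rng(0))
            assert count_parameters(net) == count_parameters_config(cfg)

    def test_toy_closed_form_by_hand(self):
        """2 levels, 1 conv per level, 4 base features, 2 classes:
        every weight counted by hand."""
        cfg = toy_config(levels=2, convs_per_level=1, base_features=4,
                         n_classes=2)
        # encoder: conv1(1->4)+bn, conv2(4->8)+bn
        expected = (27 * 1 * 4 + 4 + 8) + (27 * 4 * 8 + 8 + 16)
        # decoder: 1x1 halving conv(8->4), block conv(8->4)+bn
        expected += (8 * 4 + 4) + (27 * 8 * 4 + 4 + 8)
        # classifier 1x1 (4->2)
        expected += 4 * 2 + 2
        net = build_unet(cfg, np.random.default_rng(0))
        assert count_parameters(net) == expected

    def test_single_conv_layer_count(self):
        conv = nn.Conv3d(1, 24, 3, np.random.default_rng(0))
        assert sum(p.size for p in conv.params()) == 27 * 24 + 24 == 672

    def test_frozen_params_excluded_on_request(self):
        net = build_unet(toy_config(), np.random.default_rng(0))
        total = count_parameters(net)
        first = net.params()[0]
        first.trainable = False
        assert count_parameters(net) == total - first.size
        assert count_parameters(net, only_trainable=False) == total

    def test_count_invariant_to_input_size(self):
        net = build_unet(toy_config(), np.random.default_rng(0))
        before = count_parameters(net)
        net.forward(np.zeros((1, 1, 8, 8, 8)))
        net.forward(np.zeros((1, 1, 16, 16, 16)))
        assert count_parameters(net) == before


class TestForward:
    def test_softmax_channels_sum_to_one(self, rng):
        net = build_unet(toy_config(n_classes=4), rng)
        probs = net.forward(rng.standard_normal((2, 1, 8, 8, 8)))
        sums = probs.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-5

    def test_indivisible_shape_rejected_with_padding_hint(self, rng):
        net = build_unet(toy_config(levels=3), rng)
        with pytest.raises(ValueError, match="pad"):
            net.forward(rng.standard_normal((1, 1, 10, 12, 12)))

    def test_output_shape_matches_input(self, rng):
        net = build_unet(toy_config(n_classes=5), rng)
        probs = net.forward(rng.standard_normal((1, 1, 12, 8, 16)))
        assert probs.shape == (1, 5, 12, 8, 16)


class TestDiceLoss:
    def test_perfect_prediction_zero(self):
        y = one_hot(np.array([[[0, 1], [1, 0]]])[None], 2)
        assert dice_loss(y, y) == pytest.approx(0.0)

    def test_hand_case_half(self):
        """Binary masks |X| = |Y| = 2 with overlap 1: per-class term
        1 - 2/4 = 0.5."""
        p = np.zeros((1, 1, 4, 1, 1), dtype=np.float32)
        y = np.zeros((1, 1, 4, 1, 1), dtype=np.float32)
        p[0, 0, :2] = 1
        y[0, 0, 1:3] = 1
        assert nn.soft_dice_loss(p, y) == pytest.approx(0.5)

    def test_disjoint_masks_give_one(self):
        p = np.zeros((1, 1, 4, 1, 1), dtype=np.float32)
        y = np.zeros((1, 1, 4, 1, 1), dtype=np.float32)
        p[0, 0, 0] = 1
        y[0, 0, 3] = 1
        assert nn.soft_dice_loss(p, y) == pytest.approx(1.0)

    def test_both_empty_class_contributes_zero(self):
        p = np.zeros((1, 2, 2, 1, 1), dtype=np.float32)
        y = np.zeros((1, 2, 2, 1, 1), dtype=np.float32)
        p[0, 0] = 1
        y[0, 0] = 1
        # class 1 empty in both: total loss is mean(0, 0) = 0
        assert nn.soft_dice_loss(p, y) == pytest.approx(0.0)

    def test_gradient_matches_numerical(self, rng):
        p = rng.random((1, 3, 4, 4, 4))
        p /= p.sum(axis=1, keepdims=True)
        y = one_hot(rng.integers(0, 3, (1, 4, 4, 4)), 3)
        loss, grad = nn.soft_dice_loss(p, y, return_grad=True)
        eps = 1e-6
        for idx in [(0, 0, 1, 2, 3), (0, 2, 0, 0, 0), (0, 1, 3, 3, 1)]:
            pp = p.copy()
            pp[idx] += eps
            num = (nn.soft_dice_loss(pp, y) - loss) / eps
            assert num == pytest.approx(grad[idx], rel=1e-3, abs=1e-8)


class TestPatchSampler:
    @pytest.fixture(scope="class")
    def subject(self):
        return make_cohort(1, seed=77, grid_shape=(40, 40, 40))[0]

    def test_every_patch_contains_its_structure(self, subject, rng):
        cfg = TrainConfig(patch_size=16, patches_per_volume=64)
        patches = sample_patches(subject.label_map, subject.image, cfg,
                                 rng)
        assert len(patches) == 64
        found = sum(
            any(np.any(lab == s) for s in range(10))
            for _, lab in patches)
        assert found == 64
        for img, lab in patches:
            assert img.shape == (16, 16, 16)
            assert lab.shape == (16, 16, 16)

    def test_structure_selection_uniform(self, subject):
        """Chi-square goodness of fit of the drawn-structure frequencies
        against the uniform distribution (alpha = 0.01)."""
        rng = np.random.default_rng(5)
        structures = subject.label_map.present_labels()
        counts = {s: 0 for s in structures}
        n = 10_000
        for _ in range(n):
            s = structures[int(rng.integers(len(structures)))]
            counts[s] += 1
        p = stats.chisquare(list(counts.values())).pvalue
        assert p > 0.01

    def test_balanced_sampler_hits_small_structures(self, subject, rng):
        """The smallest structure appears in roughly 1/n_structures of the
        balanced patches but is essentially never the centre under
        uniform-voxel sampling."""
        cfg = TrainConfig(patch_size=8, patches_per_volume=400)
        hip = subject.label_map.id_of("hipamy")
        patches = sample_patches(subject.label_map, subject.image, cfg,
                                 rng)
        centred = sum(lab[4, 4, 4] == hip for _, lab in patches)
        frac_balanced = centred / len(patches)
        vol_frac = subject.label_map.mask("hipamy").mean()
        assert frac_balanced > 0.03          # ~1/10 expected
        assert vol_frac < frac_balanced / 5  # uniform sampling would be ≪

    def test_oversized_patch_warns_and_uses_volume(self, subject, rng):
        cfg = TrainConfig(patch_size=128, patches_per_volume=1)
        with pytest.warns(RuntimeWarning, match="extent"):
            patches = sample_patches(subject.label_map, subject.image,
                                     cfg, rng)
        assert patches[0][0].shape == (40, 40, 40)


class TestTraining:
    def _stream(self, seed=0, n=28):
        """A fixed tiny segmentation problem: one bright cube on a dark
        background with per-sample noise."""
        def gen(rng):
            vox = np.zeros((n, n, n), dtype=np.int16)
            c = 4 + rng.integers(0, n - 16, size=3)
            vox[c[0]:c[0] + 10, c[1]:c[1] + 10, c[2]:c[2] + 8] = 1
            img = 0.2 + 0.6 * (vox > 0) + 0.05 * rng.standard_normal(
                vox.shape)
            palette = {0: "background", 1: "head"}
            return (Image(img), LabelMap(vox, palette=palette))
        return gen

    def test_loss_decreases_and_trace_recorded(self):
        ucfg = toy_config(levels=2, convs_per_level=1, base_features=4,
                          n_classes=2)
        tcfg = TrainConfig(patch_size=16, patches_per_volume=4,
                           batch_size=2, learning_rate=2e-3,
                           max_iterations=60, seed=3)
        res = train(self._stream(), ucfg, tcfg)
        assert len(res.loss_trace) == 60
        assert np.mean(res.loss_trace[-10:]) < res.loss_trace[0]

    def test_identical_seeds_identical_traces(self):
        ucfg = toy_config(levels=2, convs_per_level=1, base_features=4,
                          n_classes=2)
        tcfg = TrainConfig(patch_size=16, patches_per_volume=4,
                           batch_size=2, learning_rate=1e-3,
                           max_iterations=10, seed=11)
        a = train(self._stream(), ucfg, tcfg)
        b = train(self._stream(), ucfg, tcfg)
        assert a.loss_trace == b.loss_trace

    def test_checkpoint_roundtrip(self, tmp_path):
        ucfg = toy_config(levels=2, convs_per_level=1, base_features=4,
                          n_classes=2)
        tcfg = TrainConfig(patch_size=16, patches_per_volume=4,
                           batch_size=2, max_iterations=5, seed=1)
        path = tmp_path / "ckpt.npz"
        res = train(self._stream(), ucfg, tcfg, checkpoint_path=path)
        loaded = load_checkpoint(path)
        x = np.random.default_rng(0).standard_normal((1, 1, 16, 16, 16))
        assert np.allclose(res.network.forward(x),
                           loaded.network.forward(x))


class TestPredictFullVolume:
    @pytest.fixture(scope="class")
    def net(self):
        return build_unet(toy_config(levels=2, convs_per_level=1,
                                     base_features=4, n_classes=10),
                          np.random.default_rng(42))

    def test_deterministic_in_eval_mode(self, net, rng):
        img = Image(rng.random((20, 20, 20)))
        a = predict_full_volume(net, img)
        b = predict_full_volume(net, img)
        assert np.array_equal(a.voxels, b.voxels)

    def test_palette_subset_of_classes(self, net, rng):
        img = Image(rng.random((20, 20, 20)))
        pred = predict_full_volume(net, img)
        assert set(pred.present_labels()) <= set(range(10))
        assert pred.shape == img.shape

    def test_padding_cropped_for_odd_shapes(self, net, rng):
        img = Image(rng.random((19, 21, 17)))
        pred = predict_full_volume(net, img)
        assert pred.shape == img.shape

    def test_interior_consistent_between_patch_and_volume(self, rng):
        """Fully-convolutional consistency: predicting a patch agrees with
        the same region of a larger volume away from the receptive-field
        margin. Uses running-statistics normalization so the prediction
        does not depend on the surrounding context."""
        cfg = toy_config(levels=2, convs_per_level=1, base_features=4,
                         n_classes=3)
        cfg.eval_norm = "running"
        net = build_unet(cfg, np.random.default_rng(1))
        vol = rng.random((32, 32, 32))
        probs_full = net.forward(vol[None, None])
        inner = vol[8:24, 8:24, 8:24]
        probs_patch = net.forward(inner[None, None])
        m = 6  # receptive-field margin inside the patch
        full_crop = probs_full[:, :, 8 + m:24 - m, 8 + m:24 - m,
                               8 + m:24 - m]
        patch_crop = probs_patch[:, :, m:-m, m:-m, m:-m]
        assert np.array_equal(full_crop.argmax(axis=1),
                              patch_crop.argmax(axis=1))
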