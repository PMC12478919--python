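"""U-Net builder contracts, loss oracles, metric identities, and training
sanity at miniature scale."""

import numpy as np
import pytest

from adstage.phantom import default_class_table, generate_phantom, PhantomSpec
from adstage.segmentation import (
    SegConfigError,
    SegInputError,
    SegTrainConfig,
    UNetConfig,
    balanced_cross_entropy,
    build_unet,
    dice_loss,
    evaluate_segmentation,
    multilayer_config,
    predict_mask,
    resolve_beta,
    train_segmenter,
    vanilla_config,
)


def closed_form_param_count(config: UNetConfig) -> int:
    """Independent parameter-count oracle from layer dimensions alone."""
    k = config.kernel_size

    def conv(cin, cout, kk=k):
        return kk * kk * cin * cout + cout

    def block(cin, cout):
        return conv(cin, cout) + conv(cout, cout)

    total = 0
    cin = 1
    for f in config.filters:
        total += block(cin, f)
        cin = f
    total += block(cin, config.bottleneck_filters)
    cin = config.bottleneck_filters
    for f in reversed(config.filters):
        total += cin * f * 4 + f          # 2x2 transposed conv
        total += block(2 * f, f)
        cin = f
    total += conv(cin, 1, kk=1)           # final 1x1
    return total


class TestBuildUnet:
    def test_output_shape_and_range(self):
        model = build_unet(multilayer_config(64, 4), seed=0)
        x = np.random.default_rng(0).random((2, 64, 64, 1)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (2, 64, 64, 1)
        assert 0.0 < p.min() and p.max() < 1.0

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(SegConfigError):
            multilayer_config(100)          # 100 not divisible by 8

    def test_depth_filters_mismatch_rejected(self):
        with pytest.raises(SegConfigError):
            UNetConfig(depth=2, filters=(4,), bottleneck_filters=8, input_size=16)

    @pytest.mark.parametrize("config", [
        UNetConfig(depth=1, filters=(2,), bottleneck_filters=4, input_size=8),
        multilayer_config(32, 4),
        vanilla_config(32, 2),
    ])
    def test_parameter_count_matches_closed_form(self, config):
        assert build_unet(config, seed=0).n_params == closed_form_param_count(config)

    def test_variant_depths(self):
        assert vanilla_config(224).depth == 4
        assert multilayer_config(224).depth == 3


class TestLosses:
    def test_balanced_bce_hand_value(self):
        # single pixel, y=1, p=0.5, beta=0.5 -> 0.5 * ln 2
        loss = balanced_cross_entropy(np.array([[1.0]]), np.array([[0.5]]), 0.5)
        assert loss == pytest.approx(0.5 * np.log(2.0), rel=1e-9)

    def test_balanced_bce_weight_annihilation(self):
        y = np.zeros((4, 4))
        p = np.full((4, 4), 0.3)
        assert balanced_cross_entropy(y, p, 1.0 - 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_balanced_bce_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert balanced_cross_entropy(y, y, 0.5) < 2e-7 * abs(np.log(1e-7))

    def test_balanced_bce_matches_bruteforce_pixel_sum(self, rng):
        y = (rng.random((8, 8)) > 0.6).astype(float)
        p = np.clip(rng.random((8, 8)), 1e-3, 1 - 1e-3)
        for beta in (0.1, 0.5, 0.9):
            expected = 0.0
            for i in range(8):
                for j in range(8):
                    expected += (-beta * y[i, j] * np.log(p[i, j])
                                 - (1 - beta) * (1 - y[i, j]) * np.log(1 - p[i, j]))
            expected /= 64
            assert balanced_cross_entropy(y, p, beta) == pytest.approx(expected, rel=1e-9)

    def test_balanced_bce_half_weight_is_half_plain_bce(self, rng):
        y = (rng.random((8, 8)) > 0.5).astype(float)
        p = np.clip(rng.random((8, 8)), 1e-3, 1 - 1e-3)
        plain = float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))
        assert balanced_cross_entropy(y, p, 0.5) == pytest.approx(0.5 * plain, rel=1e-9)

    def test_balanced_bce_invalid_beta(self):
        with pytest.raises(SegConfigError):
            balanced_cross_entropy(np.ones((2, 2)), np.ones((2, 2)) * 0.5, 1.5)

    def test_dice_loss_perfect_overlap(self):
        m = np.ones((2, 2))
        assert dice_loss(m, m) == pytest.approx(0.0)

    def test_dice_loss_empty_masks_convention(self):
        z = np.zeros((3, 3))
        assert dice_loss(z, z) == pytest.approx(0.0)

    def test_dice_loss_hand_case(self):
        # |P|=2, |G|=3, overlap 2 -> 1 - (4+1)/(5+1) = 1/6
        g = np.array([[1.0, 1.0, 1.0, 0.0]])
        p = np.array([[1.0, 1.0, 0.0, 0.0]])
        assert dice_loss(g, p) == pytest.approx(1.0 / 6.0, rel=1e-12)

    def test_dice_loss_shape_mismatch(self):
        with pytest.raises(SegInputError):
            dice_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestEvaluateSegmentation:
    def test_identity_masks_all_ones(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        metrics = evaluate_segmentation(m, m)
        assert metrics == type(metrics)(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_complement_masks_all_zero_overlap(self):
        g = np.zeros((4, 4), dtype=np.uint8)
        g[:2] = 1
        metrics = evaluate_segmentation(1 - g, g)
        assert metrics.dice == metrics.iou == metrics.precision == metrics.recall == 0.0

    def test_subset_prediction_bruteforce_counts(self):
        g = np.array([[1, 1, 1, 0]], dtype=np.uint8)
        p = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        m = evaluate_segmentation(p, g)
        assert m.precision == pytest.approx(1.0)
        assert m.recall == pytest.approx(2.0 / 3.0)
        assert m.dice == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)
        assert m.iou == pytest.approx(2.0 / 3.0)

    def test_dice_equals_f1_and_iou_relation_on_random_masks(self, rng):
        for _ in range(50):
            p = (rng.random((12, 12)) > rng.random()).astype(np.uint8)
            g = (rng.random((12, 12)) > rng.random()).astype(np.uint8)
            m = evaluate_segmentation(p, g)
            assert m.dice == m.f1
            assert m.iou <= m.dice + 1e-12
            assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), rel=1e-12)

    def test_shape_and_value_validation(self):
        with pytest.raises(SegInputError):
            evaluate_segmentation(np.ones((2, 2)), np.ones((3, 3)))
        with pytest.raises(SegInputError):
            evaluate_segmentation(np.full((2, 2), 2), np.ones((2, 2)))


class TestPredictMask:
    def test_threshold_semantics(self):
        model = build_unet(UNetConfig(depth=1, filters=(2,), bottleneck_filters=2,
                                      input_size=8), seed=0)
        img = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        everything = predict_mask(model, img, threshold=0.0)
        assert np.all(everything == 1)
        out = predict_mask(model, img, threshold=0.5)
        assert set(np.unique(out)) <= {0, 1}
        assert out.shape == (8, 8)

    def test_size_mismatch_rejected(self):
        model = build_unet(UNetConfig(depth=1, filters=(2,), bottleneck_filters=2,
                                      input_size=8), seed=0)
        with pytest.raises(SegInputError):
            predict_mask(model, np.zeros((16, 16)))


class TestTrainSegmenter:
    def _one_phantom(self):
        params = default_class_table(32)["CN"]
        spec = PhantomSpec(class_label="CN", image_size=32, noise_sigma=0.01,
                           jitter=0.0, seed=3, **params)
        return generate_phantom(spec)

    def test_overfits_single_phantom(self):
        s = self._one_phantom()
        cfg = UNetConfig(depth=2, filters=(8, 16), bottleneck_filters=32,
                         input_size=32)
        model = build_unet(cfg, seed=0)
        x, y = s.image[None], s.gm_mask[None]
        train_segmenter(model, (x, y), (x, y),
                        SegTrainConfig(learning_rate=3e-3, batch_size=1,
                                       epochs=150, seed=0))
        metrics = evaluate_segmentation(predict_mask(model, s.image), s.gm_mask)
        assert metrics.dice >= 0.99

    def test_deterministic_history_and_length(self):
        s = self._one_phantom()
        x, y = s.image[None], s.gm_mask[None]
        cfg = UNetConfig(depth=1, filters=(4,), bottleneck_filters=8, input_size=32)
        histories = []
        for _ in range(2):
            model = build_unet(cfg, seed=1)
            h = train_segmenter(model, (x, y), (x, y),
                                SegTrainConfig(epochs=3, batch_size=1, seed=5))
            histories.append(h)
        assert histories[0]["loss"] == histories[1]["loss"]
        assert len(histories[0]["loss"]) == 3
        assert len(histories[0]["val_dice"]) == 3

    def test_auto_beta_is_background_fraction(self):
        masks = np.zeros((2, 4, 4))
        masks[0, 0, 0] = 1       # 1 of 32 pixels foreground
        assert resolve_beta("auto", masks) == pytest.approx(31 / 32)
        assert resolve_beta(0.7, masks) == 0.7

    def test_input_validation(self):
        cfg = UNetConfig(depth=1, filters=(2,), bottleneck_filters=2, input_size=8)
        model = build_unet(cfg, seed=0)
        with pytest.raises(SegInputError):
            train_segmenter(model, (np.empty((0, 8, 8)), np.empty((0, 8, 8))),
                            (np.zeros((1, 8, 8)), np.zeros((1, 8, 8))),
                            SegTrainConfig(epochs=1))
        with pytest.raises(SegInputError):
            train_segmenter(model, (np.zeros((1, 8, 8)), np.full((1, 8, 8), 0.5)),
                            (np.zeros((1, 8, 8)), np.zeros((1, 8, 8))),
                            SegTrainConfig(epochs=1))
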