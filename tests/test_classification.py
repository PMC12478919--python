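"""Classification stage: feature contracts, head oracles, SVM equivalence,
and the evaluation battery (report, ROC, McNemar)."""

import numpy as np
import pytest

from adstage.classification import (
    CLASSES,
    ClfConfigError,
    ClfInputError,
    HeadTrainConfig,
    MultiScaleConfig,
    MultiScaleHead,
    SmallCNNBackbone,
    SVMGridSpec,
    TrainedSVM,
    apply_scaler,
    evaluate_classifier,
    extract_features,
    fit_scaler,
    grid_search_svm,
    mcnemar_test,
    multi_scale_forward,
    roc_one_vs_rest,
    svm_predict,
    train_head,
)


def make_blobs_2d(rng, n_per_class=20):
    """Well-separated 2D clusters for the three diagnostic classes."""
    centers = {"AD": (0.0, 0.0), "CN": (4.0, 4.0), "MCI": (0.0, 5.0)}
    X, y = [], []
    for cls, (cx, cy) in centers.items():
        X.append(rng.normal((cx, cy), 0.4, size=(n_per_class, 2)))
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestExtractFeatures:
    def test_configured_channel_count_and_stride(self):
        backbone = SmallCNNBackbone(input_size=64, out_channels=16, seed=0)
        fmap = extract_features(backbone, np.zeros((64, 64), dtype=np.float32))
        assert fmap.shape == (8, 8, 16)       # stride 2^3, 16 channels

    def test_batch_shape(self):
        backbone = SmallCNNBackbone(input_size=32, out_channels=8, seed=0)
        fmap = extract_features(backbone, np.zeros((5, 32, 32), dtype=np.float32))
        assert fmap.shape == (5, 4, 4, 8)

    def test_wrong_input_size_rejected(self):
        backbone = SmallCNNBackbone(input_size=64, out_channels=8, seed=0)
        with pytest.raises(ClfInputError):
            extract_features(backbone, np.zeros((32, 32)))


class TestMultiScaleHead:
    def test_feature_length_is_three_branch_channels(self):
        head = MultiScaleHead(16, MultiScaleConfig(branch_channels=128), seed=0)
        fmap = np.random.default_rng(0).random((2, 8, 8, 16)).astype(np.float32)
        assert multi_scale_forward(head, fmap).shape == (2, 384)

    def test_zero_weights_annihilate_output(self):
        head = MultiScaleHead(4, MultiScaleConfig(branch_channels=8), seed=0)
        for b in head.branches:
            b["conv"].weight.data[...] = 0.0
            b["conv"].bias.data[...] = 0.0
        fmap = np.random.default_rng(1).random((3, 8, 8, 4)).astype(np.float32)
        assert np.abs(multi_scale_forward(head, fmap)).max() == 0.0

    def test_single_branch_matches_hand_convolution(self):
        # 1-channel 4x4 map, one 3x3 branch filter with known weights:
        # conv (same pad) -> leaky relu -> 2x2 max-pool -> mean, by hand
        head = MultiScaleHead(1, MultiScaleConfig(branch_channels=1),
                              seed=0, kernel_sizes=(3,))
        rng = np.random.default_rng(2)
        w = rng.normal(size=(3, 3, 1, 1)).astype(np.float32)
        head.branches[0]["conv"].weight.data[...] = w
        head.branches[0]["conv"].bias.data[...] = 0.5
        fmap = rng.random((1, 4, 4, 1)).astype(np.float32)

        padded = np.zeros((6, 6))
        padded[1:5, 1:5] = fmap[0, :, :, 0]
        conv = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                acc = 0.5
                for a in range(3):
                    for b in range(3):
                        acc += padded[i + a, j + b] * w[a, b, 0, 0]
                conv[i, j] = acc
        act = np.where(conv > 0, conv, 0.01 * conv)
        pooled = np.array([[act[0:2, 0:2].max(), act[0:2, 2:4].max()],
                           [act[2:4, 0:2].max(), act[2:4, 2:4].max()]])
        expected = pooled.mean()
        out = multi_scale_forward(head, fmap)
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(expected, rel=1e-5)

    def test_channel_mismatch_rejected(self):
        head = MultiScaleHead(8, MultiScaleConfig(branch_channels=4), seed=0)
        with pytest.raises(ClfConfigError):
            head.forward_features(np.zeros((1, 4, 4, 5), dtype=np.float32))

    def test_config_validation(self):
        with pytest.raises(ClfConfigError):
            MultiScaleConfig(kernel_sizes=(3, 5))
        with pytest.raises(ClfConfigError):
            MultiScaleConfig(kernel_sizes=(3, 4, 7))


class TestTrainHead:
    def _data(self, n=10):
        from adstage.phantom import generate_dataset
        manifest, samples = generate_dataset(n, seed=0, image_size=32)
        X = np.stack([samples[r.id].image for r in manifest.records])
        y = np.array([r.label for r in manifest.records])
        return X, y

    def test_uniform_softmax_loss_is_log3(self):
        head = MultiScaleHead(8, MultiScaleConfig(branch_channels=4), seed=0)
        head.classifier.weight.data[...] = 0.0
        head.classifier.bias.data[...] = 0.0
        from adstage import nn
        fmap = np.random.default_rng(0).random((6, 4, 4, 8)).astype(np.float32)
        logits = head.forward(fmap, training=False)
        onehot = np.eye(3, dtype=np.float32)[[0, 1, 2, 0, 1, 2]]
        loss, _ = nn.softmax_cross_entropy(logits, onehot)
        assert loss == pytest.approx(np.log(3.0), rel=1e-6)

    def test_loss_descends(self):
        X, y = self._data(10)
        backbone = SmallCNNBackbone(input_size=32, out_channels=8, seed=0)
        head = MultiScaleHead(8, MultiScaleConfig(branch_channels=16), seed=0)
        hist = train_head(backbone, head, (X, y),
                          HeadTrainConfig(learning_rate=3e-3, batch_size=8,
                                          epochs=15, seed=0))
        assert hist["loss"][-1] < hist["loss"][0]

    def test_deterministic_given_seed(self):
        X, y = self._data(4)
        finals = []
        for _ in range(2):
            backbone = SmallCNNBackbone(input_size=32, out_channels=8, seed=1)
            head = MultiScaleHead(8, MultiScaleConfig(branch_channels=8), seed=1)
            hist = train_head(backbone, head, (X, y),
                              HeadTrainConfig(epochs=2, seed=3))
            finals.append(hist["loss"][-1])
        assert finals[0] == finals[1]

    def test_empty_data_rejected(self):
        backbone = SmallCNNBackbone(input_size=32, out_channels=8, seed=0)
        head = MultiScaleHead(8, seed=0)
        with pytest.raises(ClfInputError):
            train_head(backbone, head, (np.empty((0, 32, 32)), []),
                       HeadTrainConfig(epochs=1))


class TestScaler:
    def test_training_features_standardized(self, rng):
        X = rng.normal(5.0, 3.0, size=(40, 6))
        scaler = fit_scaler(X)
        Z = apply_scaler(scaler, X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.std(axis=0) - 1.0).max() < 1e-9

    def test_constant_column_passes_through_after_centering(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        Z = apply_scaler(fit_scaler(X), X)
        assert np.allclose(Z[:, 1], 0.0)      # centered, scale-1 convention


class TestSVM:
    def test_decision_matches_kernel_sum_oracle(self, rng):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array(["AD", "AD", "CN", "CN"])
        model = TrainedSVM("rbf", 1.0, "scale").fit(X, y)
        pars = model.class_parameters("AD")
        scores = model.decision_scores(X)
        for r, x in enumerate(X):
            brute = pars["bias"]
            for sv, coef in zip(pars["support_vectors"], pars["dual_coef"]):
                brute += coef * np.exp(-pars["gamma"] * np.sum((sv - x) ** 2))
            assert scores[r, 0] == pytest.approx(brute, abs=1e-10)
        assert list(model.predict(X)) == list(y)

    def test_linear_separable_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array(["AD", "CN"])
        model = TrainedSVM("linear", 1.0, "scale").fit(X, y)
        assert list(model.predict(X)) == ["AD", "CN"]

    def test_score_matrix_shape_three_classes(self, rng):
        X, y = make_blobs_2d(rng, 10)
        model = TrainedSVM("rbf", 1.0, "scale").fit(X, y)
        _, scores = svm_predict(model, X)
        assert scores.shape == (30, 3)

    def test_single_class_rejected(self):
        with pytest.raises(ClfInputError):
            TrainedSVM("rbf", 1.0, "scale").fit(np.zeros((4, 2)), ["AD"] * 4)


class TestGridSearch:
    def test_singleton_grid_returns_that_cell(self, rng):
        X, y = make_blobs_2d(rng, 10)
        grid = SVMGridSpec(kernels=("linear",), C=(1.0,), gamma=("scale",),
                           cv_folds=3)
        model, table = grid_search_svm(X, y, grid, seed=0)
        assert len(table) == 1
        assert (model.kernel, model.C) == ("linear", 1.0)

    def test_tie_break_follows_documented_grid_order(self, rng):
        # fully separable data -> many cells tie at accuracy 1.0; the
        # winner must be rbf with the largest C, stable across runs
        X, y = make_blobs_2d(rng, 15)
        winners = []
        for _ in range(2):
            model, table = grid_search_svm(X, y, SVMGridSpec(cv_folds=3), seed=0)
            winners.append((model.kernel, model.C, model.gamma))
        assert winners[0] == winners[1]
        assert winners[0][0] == "rbf"
        assert winners[0][1] == 10.0
        assert len(table) == 12
        assert table["accuracy"].is_monotonic_decreasing

    def test_single_class_rejected(self):
        with pytest.raises(ClfInputError):
            grid_search_svm(np.zeros((5, 2)), ["AD"] * 5)


class TestEvaluateClassifier:
    def test_perfect_predictions(self):
        y = ["AD", "CN", "MCI"] * 4
        report = evaluate_classifier(y, y)
        assert report.accuracy == 1.0
        assert np.all(np.diag(report.confusion.to_numpy()) == 4)
        for cls in CLASSES:
            assert report.per_class[cls]["f1"] == 1.0

    def test_toy_confusion_matrix_bruteforce(self):
        # true AD rows [8,1,1], CN [0,9,1], MCI [2,0,8]
        true, pred = [], []
        rows = {"AD": [8, 1, 1], "CN": [0, 9, 1], "MCI": [2, 0, 8]}
        for t, counts in rows.items():
            for p, c in zip(CLASSES, counts):
                true += [t] * c
                pred += [p] * c
        report = evaluate_classifier(pred, true)
        assert report.per_class["AD"]["precision"] == pytest.approx(0.8)
        assert report.per_class["AD"]["recall"] == pytest.approx(0.8)
        assert report.accuracy == pytest.approx(25 / 30)
        assert report.confusion.loc["MCI", "AD"] == 2

    def test_all_wrong_floor(self):
        assert evaluate_classifier(["CN", "AD"], ["AD", "CN"]).accuracy == 0.0

    def test_f1_is_harmonic_mean_of_reported_precision_recall(self, rng):
        pred = rng.choice(CLASSES, 60)
        true = rng.choice(CLASSES, 60)
        report = evaluate_classifier(pred, true)
        for cls in CLASSES:
            d = report.per_class[cls]
            if d["precision"] + d["recall"] > 0:
                hm = 2 * d["precision"] * d["recall"] / (d["precision"] + d["recall"])
                assert d["f1"] == pytest.approx(hm, rel=1e-12)

    def test_trace_over_total_equals_accuracy(self, rng):
        pred = rng.choice(CLASSES, 45)
        true = rng.choice(CLASSES, 45)
        report = evaluate_classifier(pred, true)
        cm = report.confusion.to_numpy()
        assert report.accuracy == pytest.approx(np.trace(cm) / cm.sum())

    def test_unknown_label_rejected(self):
        with pytest.raises(ClfInputError):
            evaluate_classifier(["AD"], ["XX"])


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = np.array([[3.0], [2.0], [-1.0], [-2.0]])
        out = roc_one_vs_rest(scores, ["AD", "AD", "CN", "CN"], classes=("AD",))
        assert out["AD"].auc == 1.0

    def test_hand_case_auc_three_quarters(self):
        scores = np.array([[0.9], [0.4], [0.6], [0.1]])
        out = roc_one_vs_rest(scores, ["AD", "AD", "CN", "CN"], classes=("AD",))
        assert out["AD"].auc == pytest.approx(0.75)

    def test_uninformative_scores_auc_half(self):
        scores = np.zeros((6, 1))
        out = roc_one_vs_rest(scores, ["AD", "CN"] * 3, classes=("AD",))
        assert out["AD"].auc == pytest.approx(0.5)

    def test_absent_class_reported_missing(self):
        scores = np.zeros((4, 3))
        out = roc_one_vs_rest(scores, ["AD", "AD", "CN", "CN"])
        assert out["MCI"] is None
        assert out["AD"] is not None

    def test_optimal_threshold_maximizes_tpr_minus_fpr(self):
        scores = np.array([[0.9], [0.8], [0.3], [0.2]])
        out = roc_one_vs_rest(scores, ["AD", "AD", "CN", "CN"], classes=("AD",))
        # any threshold in (0.3, 0.8] separates; smallest qualifying is 0.8
        assert out["AD"].optimal_threshold == pytest.approx(0.8)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ClfInputError):
            roc_one_vs_rest(np.array([[np.nan]]), ["AD"], classes=("AD",))


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        truth = ["AD"] * 10
        a = ["AD"] * 5 + ["CN"] * 5
        b = ["CN"] * 5 + ["AD"] * 5
        res = mcnemar_test(a, b, truth)
        assert (res.b, res.c) == (5, 5)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_statistic(self):
        truth = ["AD"] * 12
        a = ["AD"] * 10 + ["CN"] * 2
        b = ["CN"] * 10 + ["AD"] * 2
        res = mcnemar_test(a, b, truth)
        assert (res.b, res.c) == (10, 2)
        assert res.statistic == pytest.approx(64 / 12)

    def test_no_discordance_degenerate(self):
        res = mcnemar_test(["AD"], ["AD"], ["AD"])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_continuity_correction_variant(self):
        truth = ["AD"] * 12
        a = ["AD"] * 10 + ["CN"] * 2
        b = ["CN"] * 10 + ["AD"] * 2
        res = mcnemar_test(a, b, truth, correction=True)
        assert res.statistic == pytest.approx(49 / 12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClfInputError):
            mcnemar_test(["AD"], ["AD", "CN"], ["AD", "CN"])
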