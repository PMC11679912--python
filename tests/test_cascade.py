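import numpy as np
import pytest

from sctqa.binning import BinScheme, assign_class, derive_regression_ranges
from sctqa.cascade import (
    CascadeModel,
    Estimator,
    PreprocessSpec,
    TrainConfig,
    augment_batch,
    patient_kfold,
    predict_slice,
    predict_volume,
    preprocess_batch,
    preprocess_slice,
    split_patients,
    train_classifier,
    weighted_classification_score,
)
from sctqa.labeling import saturate_mae
from sctqa.phantom import PhantomConfig, corrupt_to_target_mae, generate_gt


class TestPreprocess:
    def setup_method(self):
        self.spec = PreprocessSpec(input_size=(32, 32), hu_window=(-1000, 2000))

    def test_window_low_maps_to_zero(self):
        out = preprocess_slice(np.full((32, 32), -1000.0), self.spec)
        np.testing.assert_array_equal(out, 0.0)

    def test_window_high_maps_to_one(self):
        out = preprocess_slice(np.full((32, 32), 2000.0), self.spec)
        np.testing.assert_array_equal(out, 1.0)

    def test_downsampling_preserves_mean(self, rng):
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.uniform(0, 1000, size=(64, 64)), 4)
        out = preprocess_slice(img, self.spec)
        assert out.shape == (32, 32)
        expected = np.clip((img + 1000) / 3000, 0, 1).mean()
        assert out.mean() == pytest.approx(expected, rel=0.01)

    def test_non_finite_rejected(self):
        img = np.zeros((32, 32))
        img[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            preprocess_slice(img, self.spec)


class TestWeightedScore:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 4, 50)
        assert weighted_classification_score(y, y, 4) == 1.0

    def test_maximal_error(self):
        assert weighted_classification_score([0, 0, 0, 0], [3, 3, 3, 3], 4) == 0.0

    def test_hand_computed_example(self):
        score = weighted_classification_score([0, 1, 2, 3], [0, 2, 2, 3], 4)
        assert score == pytest.approx(1 - 1 / 12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            t = rng.integers(0, 4, 30)
            p = rng.integers(0, 4, 30)
            expected = 1 - sum(abs(int(a) - int(b)) for a, b in zip(t, p)) / (30 * 3)
            assert weighted_classification_score(t, p, 4) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_classification_score([], [], 4)


class TestSplits:
    def test_patient_level_partition(self):
        ids = [f"p{i}" for i in range(20)]
        train, val, test = split_patients(ids, (0.75, 0.10, 0.15), seed=1)
        assert sorted(train + val + test) == sorted(ids)
        assert not (set(train) & set(val)) and not (set(train) & set(test))
        assert len(train) == 15 and len(val) == 2 and len(test) == 3

    def test_kfold_partitions(self):
        ids = [f"p{i}" for i in range(10)]
        folds = patient_kfold(ids, 5, seed=2)
        assert len(folds) == 5
        all_test = [p for _, test in folds for p in test]
        assert sorted(all_test) == sorted(ids)
        for train, test in folds:
            assert not (set(train) & set(test))


class TestAugmentation:
    def test_translation_pads_with_air(self, rng):
        spec = PreprocessSpec()
        batch = np.ones((4, 1, 32, 32))
        out = augment_batch(batch, rng, mirror=False, max_translation_px=4,
                            fill=spec.air_level)
        assert out.shape == batch.shape
        assert set(np.unique(out)) <= {spec.air_level, 1.0}

    def test_zero_translation_no_mirror_is_identity(self, rng):
        batch = rng.uniform(size=(3, 1, 16, 16))
        out = augment_batch(batch, rng, mirror=False, max_translation_px=0, fill=0.0)
        np.testing.assert_array_equal(out, batch)


# --- routing with stub estimators ------------------------------------------

class StubClassifier:
    def __init__(self, probs):
        self.probs = np.asarray(probs)
        self.n_invocations = 0

    def predict_probs(self, batch):
        self.n_invocations += batch.shape[0]
        return np.tile(self.probs, (batch.shape[0], 1))


class StubRegressor:
    def __init__(self, value):
        self.value = value
        self.n_invocations = 0

    def predict_values(self, batch):
        self.n_invocations += batch.shape[0]
        return np.full(batch.shape[0], self.value, dtype=float)


def stub_cascade(probs, reg_values):
    scheme = derive_regression_ranges(BinScheme([0, 25, 50, 75, 100]))
    return CascadeModel(
        scheme=scheme,
        classifier=StubClassifier(probs),
        regressors=[StubRegressor(v) for v in reg_values],
        preprocessing=PreprocessSpec(),
    )


class TestRouting:
    def test_argmax_routes_to_matching_regressor(self):
        model = stub_cascade([0.1, 0.7, 0.1, 0.1], [11, 22, 33, 44])
        rec = predict_slice(model, np.zeros((32, 32)))
        assert rec.class_predicted == 1
        assert rec.mae_predicted == 22
        assert model.regressors[1].n_invocations == 1
        assert all(model.regressors[k].n_invocations == 0 for k in (0, 2, 3))

    def test_tie_breaks_to_lowest_class(self):
        model = stub_cascade([0.25, 0.25, 0.25, 0.25], [11, 22, 33, 44])
        assert predict_slice(model, np.zeros((32, 32))).class_predicted == 0

    def test_negative_regressor_output_clipped_to_zero(self):
        model = stub_cascade([0.9, 0.1, 0, 0], [-3, 0, 0, 0])
        assert predict_slice(model, np.zeros((32, 32))).mae_predicted == 0.0

    def test_output_clipped_to_saturation(self):
        model = stub_cascade([0.9, 0.1, 0, 0], [140, 0, 0, 0])
        assert predict_slice(model, np.zeros((32, 32))).mae_predicted == 100.0

    def test_two_invocations_per_slice_over_volume(self):
        model = stub_cascade([0.1, 0.7, 0.1, 0.1], [11, 22, 33, 44])
        records, pmae = predict_volume(model, np.zeros((32, 32, 20)))
        assert len(records) == 20
        assert model.total_invocations == 40
        np.testing.assert_array_equal(pmae, 22.0)


# --- trained-cascade behavior ----------------------------------------------

class TestTrainedCascade:
    def test_five_estimators(self, tiny_cascade):
        model = tiny_cascade["model"]
        assert model.n_estimators == 5
        assert len(model.regressors) == model.scheme.n_classes == 4

    def test_inference_deterministic(self, tiny_cascade):
        model = tiny_cascade["model"]
        sct = tiny_cascade["pairs"][0].sct
        rec1, pmae1 = predict_volume(model, sct)
        rec2, pmae2 = predict_volume(model, sct)
        np.testing.assert_array_equal(pmae1, pmae2)
        assert [r.mae_predicted for r in rec1] == [r.mae_predicted for r in rec2]

    def test_predictions_within_saturation(self, tiny_cascade):
        model = tiny_cascade["model"]
        records, _ = predict_volume(model, tiny_cascade["pairs"][0].sct)
        sat = model.scheme.saturation
        assert all(0 <= r.mae_predicted <= sat for r in records)

    def test_routed_class_matches_classifier_argmax(self, tiny_cascade):
        model = tiny_cascade["model"]
        sct = tiny_cascade["pairs"][1].sct
        batch = preprocess_batch([sct[:, :, i] for i in range(sct.shape[2])],
                                 model.preprocessing)
        probs = model.classifier.predict_probs(batch)
        records, _ = predict_volume(model, sct)
        np.testing.assert_array_equal(
            probs.argmax(axis=1), [r.class_predicted for r in records]
        )

    def test_best_epoch_checkpoint_returned(self, tiny_cascade):
        """The persisted classifier reproduces the max logged val score."""
        model = tiny_cascade["model"]
        cfg = tiny_cascade["cfg"]
        corpus = tiny_cascade["corpus"]
        log = model.training_logs["classifier"]
        pid = np.array([s.patient_id for s in corpus])
        _, val_ids, _ = split_patients(pid, cfg.split_fractions, cfg.seed)
        val = [s for s in corpus if s.patient_id in val_ids]
        batch = preprocess_batch([s.image for s in val], model.preprocessing)
        pred = model.classifier.predict_probs(batch).argmax(axis=1)
        truth = [
            assign_class(saturate_mae(s.mae_gt, model.scheme.saturation)[0],
                         model.scheme)
            for s in val
        ]
        score = weighted_classification_score(truth, pred, model.scheme.n_classes)
        assert score == pytest.approx(log.val_weighted_score.max())

    def test_regressor_training_sets_respect_relaxed_ranges(self, tiny_cascade):
        model = tiny_cascade["model"]
        for k, reg in enumerate(model.regressors):
            assert reg.target_range == model.scheme.regression_ranges[k]

    def test_save_load_round_trip(self, tiny_cascade, tmp_path):
        model = tiny_cascade["model"]
        sct = tiny_cascade["pairs"][0].sct
        _, ref = predict_volume(model, sct)
        model.save(tmp_path / "pipe")
        reloaded = CascadeModel.load(tmp_path / "pipe")
        assert reloaded.n_estimators == 5
        _, out = predict_volume(reloaded, sct)
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_low_vs_high_corruption_ranked_correctly(self, tiny_cascade):
        """Slices corrupted harder should receive higher predicted MAE."""
        model = tiny_cascade["model"]
        pconf = PhantomConfig(shape=(32, 32, 12), seed=777)
        gt = generate_gt(pconf)
        targets = np.array([10.0, 80.0] * 6)
        sct = corrupt_to_target_mae(gt, targets, seed=778)
        records, _ = predict_volume(model, sct)
        preds = np.array([r.mae_predicted for r in records])
        low, high = preds[targets == 10.0], preds[targets == 80.0]
        agree = np.mean([h > l for h in high for l in low])
        assert agree >= 0.9


class TestTrainingContracts:
    def test_missing_class_in_training_split_rejected(self, tiny_cascade):
        corpus = [s for s in tiny_cascade["corpus"] if s.mae_gt < 40]
        scheme = derive_regression_ranges(BinScheme([0, 25, 50, 75, 100]))
        cfg = TrainConfig(max_epochs=1, seed=0)
        with pytest.raises(ValueError, match="absent from the training split"):
            train_classifier(corpus, scheme, cfg)

    def test_undersized_regression_bin_rejected(self, tiny_cascade):
        from sctqa.cascade import train_regressors

        corpus = tiny_cascade["corpus"]
        scheme = derive_regression_ranges(BinScheme([0, 25, 50, 75, 100]))
        cfg = TrainConfig(max_epochs=1, seed=0, min_regression_samples=10_000)
        with pytest.raises(ValueError, match="regression bin 0"):
            train_regressors(corpus, scheme, cfg)

    def test_regularization_changes_parameter_norms(self, tiny_cascade):
        corpus = tiny_cascade["corpus"]
        scheme = tiny_cascade["model"].scheme
        norms = []
        for l1, l2 in ((0.0, 0.0), (4e-4, 4e-4)):
            cfg = TrainConfig(
                learning_rate=3e-3, l1_weight=l1, l2_weight=l2, max_epochs=3,
                batch_size=16, seed=0, max_translation_px=2,
            )
            est, _ = train_classifier(corpus, scheme, cfg)
            norms.append(est.network.weight_norms()[1])
        assert norms[0] != pytest.approx(norms[1])

    def test_classifier_separates_distinct_corruption_levels(self):
        """Four well-separated corruption levels are classified with a
        validation weighted score of at least 0.9 within 30 epochs."""
        from sctqa.binning import BinScheme
        from sctqa.labeling import build_corpus
        from sctqa.phantom import PhantomConfig, level_mae_sampler, make_dataset

        pconf = PhantomConfig(shape=(32, 32, 40), modality_style="CBCT")
        pairs, _ = make_dataset(10, pconf, level_mae_sampler((10, 35, 60, 85)),
                                seed=21)
        corpus = build_corpus(pairs, saturation=100.0)
        scheme = BinScheme([0, 22, 47, 72, 100])
        cfg = TrainConfig(learning_rate=3e-3, l1_weight=0, l2_weight=0,
                          max_epochs=30, batch_size=16, max_translation_px=2,
                          seed=5)
        _, log = train_classifier(corpus, scheme, cfg)
        assert log.val_weighted_score.max() >= 0.9

    def test_low_bin_regressor_recovers_mae_within_5hu(self):
        """The low-MAE regressor, trained on slices with MAE in its relaxed
        range, recovers validation MAE within 5 HU."""
        import numpy as np

        from sctqa import nn
        from sctqa.binning import BinScheme
        from sctqa.cascade import _corpus_arrays, _train_network
        from sctqa.labeling import build_corpus
        from sctqa.phantom import PhantomConfig, make_dataset, uniform_mae_sampler

        pairs, _ = make_dataset(20, PhantomConfig(shape=(32, 32, 20)),
                                uniform_mae_sampler(0, 52), seed=33)
        corpus = build_corpus(pairs, saturation=100.0)
        scheme = derive_regression_ranges(BinScheme([0, 47, 54, 68, 100]))
        cfg = TrainConfig(learning_rate=3e-3, l1_weight=0, l2_weight=0,
                          max_epochs=150, batch_size=16, max_translation_px=2,
                          seed=5)
        spec = cfg.preprocess
        x, y, pid = _corpus_arrays(corpus, spec)
        tr_ids, va_ids, _ = split_patients(pid, cfg.split_fractions, cfg.seed)
        tr, va = np.isin(pid, tr_ids), np.isin(pid, va_ids)
        lo, hi = scheme.regression_ranges[0]
        scaled = (y - lo) / (hi - lo)
        rng = np.random.default_rng(5)
        net = nn.build_tiny((32, 32), 1, seed=5)
        _train_network(net, x[tr], scaled[tr], x[va], scaled[va],
                       "regression", cfg, spec, rng)
        val_pred = net.forward(x[va])[:, 0] * (hi - lo) + lo
        assert np.abs(val_pred - y[va]).mean() <= 5.0

    def test_constant_label_regression_recovers_constant(self):
        """Degenerate regression: constant targets are learned exactly."""
        from sctqa import nn
        from sctqa.cascade import _train_network

        rng = np.random.default_rng(0)
        pconf = PhantomConfig(shape=(32, 32, 16), seed=5)
        gt = generate_gt(pconf)
        sct = corrupt_to_target_mae(gt, np.full(16, 30.0), seed=6)
        spec = PreprocessSpec()
        x = preprocess_batch([sct[:, :, i] for i in range(16)], spec)
        lo, hi = 0.0, 52.0
        scaled = np.full(16, (30.0 - lo) / (hi - lo))
        cfg = TrainConfig(learning_rate=3e-3, l1_weight=0, l2_weight=0,
                          max_epochs=60, batch_size=8, max_translation_px=2, seed=0)
        net = nn.build_tiny((32, 32), 1, seed=0)
        _train_network(net, x, scaled, x, scaled, "regression", cfg, spec, rng)
        pred_hu = net.forward(x)[:, 0] * (hi - lo) + lo
        assert np.all(np.abs(pred_hu - 30.0) < 1.0)


def test_estimator_rejects_wrong_task_calls():
    from sctqa import nn as _nn

    est = Estimator("classification", "tiny", (32, 32), 4,
                    _nn.build_tiny((32, 32), 4, seed=0))
    with pytest.raises(ValueError, match="not a regressor"):
        est.predict_values(np.zeros((1, 1, 32, 32)))


def test_train_config_validates_split():
    with pytest.raises(ValueError, match="sum to 1"):
        TrainConfig(split_fractions=(0.5, 0.2, 0.2))
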