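"""CNN families: architecture contracts, training mechanics, prediction
semantics, grid enumeration."""

import itertools

import numpy as np
import pytest

from sonosex import cnn


class TestBuildCNN:
    def test_reverse_large_schedule_reads_back(self):
        model = cnn.build_cnn(cnn.CNNConfig(family="reverse", size_variant="L", input_size=64))
        assert model.block_channels == [512, 256, 128, 64]
        assert model.block_channels[0] == 512

    def test_pre_flatten_spatial_dims(self):
        model = cnn.build_cnn(cnn.CNNConfig(family="reverse", size_variant="L", input_size=64))
        assert model.pre_flatten_spatial == (4, 4)  # 64 / 2^4

    def test_single_dropout_immediately_before_flatten(self):
        model = cnn.build_cnn(cnn.CNNConfig(family="forward", size_variant="S", input_size=32))
        idxs = model.dropout_indices
        assert len(idxs) == 1
        from sonosex.cnn import Flatten

        assert isinstance(model.layers[idxs[0] + 1], Flatten)

    def test_zero_weights_give_half_scores(self, rng):
        model = cnn.build_cnn(
            cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,))
        )
        model.zero_all_weights()
        x = rng.random((4, 1, 16, 16)).astype(np.float32)
        assert np.allclose(model.scores(x), 0.5)

    def test_family_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="decreasing"):
            cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(64, 128), input_size=16))
        with pytest.raises(ValueError, match="increasing"):
            cnn.build_cnn(cnn.CNNConfig(family="forward", schedule=(128, 64), input_size=16))

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(8, 4, 2), input_size=36))

    def test_parameter_count_deterministic(self):
        cfg = cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,))
        assert cnn.build_cnn(cfg, seed=0).n_parameters == cnn.build_cnn(cfg, seed=99).n_parameters


def separable_frames(rng, n=16):
    X = np.zeros((n, 16, 16), dtype=np.uint8)
    y = np.array(["F", "M"] * (n // 2))
    for i in range(n):
        X[i, 4:12, 4:12] = (200 if y[i] == "M" else 60) + rng.integers(-10, 10)
    return X, y


class TestTrainModel:
    def test_separable_data_reaches_perfect_train_accuracy(self, rng):
        X, y = separable_frames(rng)
        model = cnn.build_cnn(
            cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,), dropout_rate=0.1)
        )
        hist, _ = cnn.train_model(
            model, X, y, X, y,
            cnn.desk_scale_train_config(max_epochs=200, batch_size=8, learning_rate=3e-3, patience=1000),
        )
        assert hist.table["train_acc"].iloc[-1] == 1.0

    def test_patience_rule_stops_at_epoch_two(self, rng, monkeypatch):
        """Constant validation loss with patience 1, monitoring from 0 ->
        stop at epoch 2."""
        X, y = separable_frames(rng, n=8)
        model = cnn.build_cnn(
            cnn.CNNConfig(family="reverse", schedule=(4, 2), input_size=16, dense_head=(4,))
        )
        monkeypatch.setattr(cnn, "evaluate_loss", lambda *a, **k: (1.0, 0.5))
        hist, _ = cnn.train_model(
            model, X, y, X, y,
            cnn.TrainConfig(max_epochs=50, monitor_start_epoch=0, patience=1, learning_rate=1e-4),
        )
        assert hist.stopped_epoch == 2

    def test_same_seed_reproduces_val_curve(self, rng):
        X, y = separable_frames(rng)
        curves = []
        for _ in range(2):
            model = cnn.build_cnn(
                cnn.CNNConfig(family="reverse", schedule=(4, 2), input_size=16, dense_head=(4,)),
                seed=3,
            )
            hist, _ = cnn.train_model(
                model, X, y, X, y,
                cnn.desk_scale_train_config(max_epochs=10, batch_size=8, seed=3, patience=1000),
            )
            curves.append(hist.table["val_loss"].to_numpy())
        assert np.allclose(curves[0], curves[1], atol=1e-6)

    def test_no_checkpoint_above_gate(self, rng):
        """The checkpoint gate: nothing is saved while validation loss sits
        above the configured quality bar."""
        X, y = separable_frames(rng, n=8)
        model = cnn.build_cnn(
            cnn.CNNConfig(family="reverse", schedule=(4, 2), input_size=16, dense_head=(4,))
        )
        hist, best = cnn.train_model(
            model, X, y, X, y,
            cnn.TrainConfig(max_epochs=5, learning_rate=1e-6, checkpoint_gate=0.01,
                            monitor_start_epoch=0, patience=100),
        )
        assert best is None and hist.best_epoch is None

    def test_single_step_decreases_single_example_loss(self, rng):
        """Gradient-flow sanity: one small-step update strictly decreases the
        loss on the example it was computed from."""
        model = cnn.build_cnn(
            cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,), dropout_rate=0.0)
        )
        x = rng.random((1, 1, 16, 16)).astype(np.float32)
        y = np.array([1.0], dtype=np.float32)
        z = model.forward(x, train=True, rng=rng)
        loss0, dz = cnn.bce_loss_and_grad(z, y)
        model.backward(dz)
        opt = cnn._SGD(model, lr=1e-3, momentum=0.0)
        opt.step(model)
        loss1, _ = cnn.bce_loss_and_grad(model.forward(x), y)
        assert loss1 < loss0

    def test_empty_partition_rejected(self, rng):
        X, y = separable_frames(rng)
        model = cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(4, 2), input_size=16))
        with pytest.raises(ValueError):
            cnn.train_model(model, X[:0], y[:0], X, y, cnn.TrainConfig())

    def test_warm_start_requires_matching_architecture(self, rng):
        X, y = separable_frames(rng)
        donor = cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,)))
        other = cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(16, 8), input_size=16, dense_head=(8,)))
        with pytest.raises(ValueError, match="architecture"):
            other.load_state_dict(donor.state_dict())
        # matching architecture restores exactly
        twin = cnn.build_cnn(
            cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,)), seed=42
        )
        twin.load_state_dict(donor.state_dict())
        assert np.array_equal(twin.layers[0].params["W"], donor.layers[0].params["W"])


class TestPredict:
    @pytest.fixture()
    def zero_model(self):
        model = cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(4, 2), input_size=16, dense_head=(4,)))
        model.zero_all_weights()
        return model

    def test_zero_model_ties_resolve_to_male(self, zero_model, rng):
        X = rng.integers(0, 255, size=(5, 16, 16), dtype=np.uint8)
        labels, scores = cnn.predict(zero_model, X)
        assert np.allclose(scores, 0.5)
        assert (labels == "M").all()

    def test_threshold_bounds(self, zero_model, rng):
        X = rng.integers(0, 255, size=(5, 16, 16), dtype=np.uint8)
        labels0, _ = cnn.predict(zero_model, X, threshold=0.0)
        labels2, _ = cnn.predict(zero_model, X, threshold=1.01)
        assert (labels0 == "M").all() and (labels2 == "F").all()

    def test_scores_invariant_to_frame_order(self, rng):
        model = cnn.build_cnn(cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16, dense_head=(8,)))
        X = rng.integers(0, 255, size=(7, 16, 16), dtype=np.uint8)
        _, s = cnn.predict(model, X)
        perm = rng.permutation(7)
        _, sp = cnn.predict(model, X[perm])
        assert np.allclose(sp, s[perm], atol=1e-6)

    def test_wrong_frame_size_rejected(self, zero_model, rng):
        with pytest.raises(ValueError, match="incompatible"):
            cnn.predict(zero_model, rng.integers(0, 255, size=(2, 20, 20), dtype=np.uint8))


class TestEnumerateGrid:
    def test_full_scale_bookkeeping(self):
        grid = cnn.full_scale_grid()
        specs = cnn.enumerate_grid(grid)
        assert len(grid.structures) == 22
        assert grid.n_combinations == 44
        assert len(specs) == 968

    def test_one_by_one(self):
        grid = cnn.HyperparameterGrid(
            (cnn.CNNConfig(family="reverse", schedule=(8, 4), input_size=16),), (1e-3,), (0.3,), ("adam",)
        )
        assert len(cnn.enumerate_grid(grid)) == 1

    def test_count_matches_nested_loop_oracle(self):
        grid = cnn.full_scale_grid()
        oracle = sum(
            1
            for _ in itertools.product(
                grid.structures, grid.learning_rates, grid.dropout_rates, grid.optimizers
            )
        )
        assert len(cnn.enumerate_grid(grid)) == oracle
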