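import numpy as np
import pytest

from projage.model import (
    ConfigurationError,
    ModelConfig,
    build_model,
    count_parameters,
    ensemble_predict,
    load_checkpoint,
    save_checkpoint,
)
from projage.nn import mse_loss


def full_config(n_channels, seed=0):
    names = tuple(tuple(f"c{i}" for i in range(n_channels)) for _ in range(3))
    return ModelConfig.full(names, seed=seed)


def tiny_config(n_channels=2, seed=0, dropout_rate=0.0):
    names = tuple(tuple(f"c{i}" for i in range(n_channels)) for _ in range(3))
    return ModelConfig.reduced(
        names,
        ((12, 12), (12, 10), (10, 10)),
        n_units=2,
        cap_features=3,
        head_widths=(4,),
        dropout_rate=dropout_rate,
        seed=seed,
    )


class TestParameterCounts:
    @pytest.mark.parametrize("n_channels,expected", [(1, 2_009_261), (2, 2_009_369), (4, 2_009_585)])
    def test_full_scale_counts(self, n_channels, expected):
        assert count_parameters(build_model(full_config(n_channels))) == expected

    def test_per_channel_delta_is_108(self):
        """Adding one input channel per axis adds 3 stacks x 4 filters x 9
        kernel weights = 108 parameters, for every base width."""
        counts = [count_parameters(build_model(full_config(n))) for n in range(1, 9)]
        deltas = np.diff(counts)
        assert list(deltas) == [108] * 7

    def test_four_member_two_channel_ensemble_count(self):
        members = [build_model(full_config(2, seed=s)) for s in range(4)]
        assert sum(count_parameters(m) for m in members) == 8_037_476

    def test_conv_layers_per_stack(self):
        assert full_config(1).conv_layers_per_stack == 13
        assert tiny_config().conv_layers_per_stack == 5

    def test_feature_doubling(self):
        assert full_config(1).feature_widths == (4, 8, 16, 32, 64, 128)


class TestModelConfig:
    def test_mismatched_channel_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig.full((("a",), ("a", "b"), ("a",)))

    def test_unknown_loss_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig.full((("a",),) * 3, loss="huber")

    def test_json_round_trip(self):
        cfg = tiny_config()
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestForwardBackward:
    def test_zero_input_gives_finite_scalar(self):
        model = build_model(tiny_config())
        xs = [np.zeros((2, 2, *s)) for s in model.config.input_shapes]
        out = model.forward(xs, train=False)
        assert out.shape == (2,)
        assert np.isfinite(out).all()

    def test_wrong_channel_count_rejected(self):
        model = build_model(tiny_config(n_channels=2))
        xs = [np.zeros((2, 3, *s)) for s in model.config.input_shapes]
        with pytest.raises(ConfigurationError):
            model.forward(xs, train=False)

    def test_gradients_match_numerical(self, rng):
        """Backprop through conv / batch-norm / dense agrees with central
        finite differences at randomly probed parameters."""
        model = build_model(tiny_config())
        xs = [rng.normal(size=(3, 2, *s)) for s in model.config.input_shapes]
        y = rng.normal(size=3)

        pred = model.forward(xs, train=True)
        _, dpred = mse_loss(pred, y)
        model.backward(dpred)

        def loss_at():
            return mse_loss(model.forward(xs, train=True), y)[0]

        for name, layer, key in model.named_params():
            p, g = layer.params[key], layer.grads[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, old = 1e-6, p[idx]
            p[idx] = old + eps
            lp = loss_at()
            p[idx] = old - eps
            lm = loss_at()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-6, rel=1e-4), name

    def test_gradient_exists_for_every_parameter(self, rng):
        model = build_model(tiny_config(dropout_rate=0.2))
        xs = [rng.normal(size=(4, 2, *s)) for s in model.config.input_shapes]
        pred = model.forward(xs, train=True)
        model.backward(np.ones_like(pred))
        for name, layer, key in model.named_params():
            assert key in layer.grads, name
            assert np.isfinite(layer.grads[key]).all(), name


class TestEnsemble:
    def _stub_models(self, constants):
        models = []
        for c in constants:
            m = build_model(tiny_config())
            m.predict = lambda xs, c=c: np.full(xs[0].shape[0], float(c))  # type: ignore
            models.append(m)
        return models

    def test_mean_of_member_predictions(self):
        models = self._stub_models([1, 2, 3, 6])
        xs = [np.zeros((5, 2, *models[0].config.input_shapes[a])) for a in range(3)]
        np.testing.assert_array_equal(ensemble_predict(models, xs), 3.0)

    def test_single_member_identity(self, rng):
        model = build_model(tiny_config())
        xs = [rng.random((3, 2, *s)) for s in model.config.input_shapes]
        np.testing.assert_array_equal(ensemble_predict([model], xs), model.predict(xs))

    def test_four_copies_equal_single(self, rng):
        model = build_model(tiny_config())
        xs = [rng.random((3, 2, *s)) for s in model.config.input_shapes]
        np.testing.assert_allclose(ensemble_predict([model] * 4, xs), model.predict(xs))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], [])

    def test_mismatched_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ensemble_predict(
                [build_model(tiny_config(1)), build_model(tiny_config(2))], []
            )


class TestCheckpoint:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        model = build_model(tiny_config(seed=3))
        model.target_mean, model.target_sd = 62.5, 10.1
        history = [{"epoch": 0, "train_loss": 1.0, "val_mae": 5.0}]
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, history)
        back, hist = load_checkpoint(path)
        assert hist == history
        assert back.config == model.config
        assert (back.target_mean, back.target_sd) == (62.5, 10.1)
        xs = [rng.random((2, 2, *s)) for s in model.config.input_shapes]
        np.testing.assert_array_equal(back.predict(xs), model.predict(xs))
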