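"""ECNN architecture contracts, gradients, and training behavior."""

import numpy as np
import pytest

from neurofuse import (
    NetworkConfig,
    PhantomSpec,
    build_ecnn,
    forward_classify,
    make_cohort,
    train,
)
from neurofuse.image import InvalidParameterError
from neurofuse.nn.engine import Dropout, softmax_xent


def _observed_branch_shapes(model, x):
    """Run one branch layer-by-layer recording the post-convolution shapes."""
    shapes = []
    h = x[..., :1]
    for layer in model.branches[0]:
        h = layer.forward(h, False)
        if type(layer).__name__ == "Conv2D":
            shapes.append(h.shape[1:])
    return shapes


class TestConfigValidation:
    def test_dropout_band_enforced(self):
        for p in (0.2, 0.55):
            with pytest.raises(InvalidParameterError):
                NetworkConfig(dropout=p)

    def test_input_size_divisibility(self):
        with pytest.raises(InvalidParameterError, match="divisible by 8"):
            NetworkConfig(input_size=60)

    def test_defaults_within_stated_ranges(self):
        cfg = NetworkConfig()
        assert cfg.conv_filters == (32, 64, 128)
        assert cfg.fc_sizes == (256, 128)
        assert 0.3 <= cfg.dropout <= 0.5
        assert 1e-4 <= cfg.learning_rate <= 1e-3
        assert 16 <= cfg.batch_size <= 32


class TestShapeChain:
    def test_canonical_128_chain(self):
        model = build_ecnn(NetworkConfig(input_size=128))
        x = np.zeros((1, 128, 128, 2))
        assert _observed_branch_shapes(model, x) == [
            (128, 128, 32), (64, 64, 64), (32, 32, 128)]
        assert model.branch_shapes() == [(128, 128, 32), (64, 64, 64), (32, 32, 128)]

    def test_64_input_final_map(self):
        model = build_ecnn(NetworkConfig(input_size=64))
        x = np.zeros((1, 64, 64, 2))
        assert _observed_branch_shapes(model, x)[-1] == (16, 16, 128)


@pytest.fixture(scope="module")
def small_model():
    return build_ecnn(NetworkConfig(conv_filters=(4, 6, 8), input_size=16,
                                    fc_sizes=(12, 8), seed=0))


class TestForward:
    def test_probabilities_sum_to_one(self, small_model):
        x = np.random.default_rng(0).normal(size=(5, 16, 16, 2))
        p = small_model.predict_proba(x)
        assert p.shape == (5, 4)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_zero_final_layer_gives_uniform(self, small_model):
        small_model.final.w[...] = 0
        small_model.final.b[...] = 0
        x = np.random.default_rng(1).normal(size=(3, 16, 16, 2))
        assert np.allclose(small_model.predict_proba(x), 0.25)

    def test_batch_permutation_consistency(self, small_model):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 16, 16, 2))
        perm = rng.permutation(6)
        p = small_model.predict_proba(x)
        pp = small_model.predict_proba(x[perm])
        assert np.allclose(pp, p[perm], atol=1e-12)

    def test_single_input_convenience(self, small_model):
        x = np.random.default_rng(3).normal(size=(16, 16, 2))
        p = forward_classify(small_model, x)
        assert p.shape == (4,)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(InvalidParameterError):
            small_model.forward(np.zeros((1, 16, 16, 1)))
        with pytest.raises(InvalidParameterError):
            small_model.forward(np.zeros((1, 24, 24, 2)))


class TestGradients:
    def test_parameter_gradients_match_finite_differences(self):
        model = build_ecnn(NetworkConfig(conv_filters=(2, 3, 4), input_size=8,
                                         fc_sizes=(6, 5), seed=1))
        for layer in model.head:
            if isinstance(layer, Dropout):
                layer.p = 0.0  # deterministic loss for finite differences
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 8, 8, 2))
        y = np.array([0, 2, 3])

        def loss():
            return softmax_xent(model.forward(x, training=True), y)[0]

        base, dlogits = softmax_xent(model.forward(x, training=True), y)
        for _, _, g in model.parameters():
            g[...] = 0
        model.backward(dlogits)
        params = list(model.parameters())
        rng2 = np.random.default_rng(5)
        eps = 1e-6
        for name, value, grad in [params[0], params[3], params[-1], params[-3]]:
            flat_idx = rng2.integers(value.size)
            idx = np.unravel_index(flat_idx, value.shape)
            old = value[idx]
            value[idx] = old + eps
            num = (loss() - base) / eps
            value[idx] = old
            assert num == pytest.approx(grad[idx], rel=2e-3, abs=1e-6), name


class TestTraining:
    def test_separable_phantoms_reach_high_train_accuracy(self):
        spec = PhantomSpec(n_per_class=10, complementary=True, seed=0)
        pairs, _ = make_cohort(spec)
        x = np.stack([np.stack([p.mri.data, p.pet.data], -1) for p in pairs])
        y = np.array([p.label for p in pairs])
        cfg = NetworkConfig(conv_filters=(8, 16, 32), epochs=15,
                            learning_rate=1e-3, dropout=0.3, seed=0)
        model = build_ecnn(cfg)
        fitted = train(model, (x, y), None)
        assert fitted.history[-1]["train_acc"] >= 0.95
        assert fitted.history[-1]["train_loss"] < fitted.history[0]["train_loss"]
        assert len(fitted.history) == cfg.epochs

    def test_same_seed_identical_histories(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(16, 16, 16, 2))
        y = np.tile(np.arange(4), 4)
        runs = []
        for _ in range(2):
            cfg = NetworkConfig(conv_filters=(3, 4, 5), input_size=16,
                                fc_sizes=(8, 6), epochs=3, seed=11)
            fitted = train(build_ecnn(cfg), (x, y), (x[:4], y[:4]))
            runs.append(fitted.history)
        assert runs[0] == runs[1]

    def test_empty_and_single_class_rejected(self):
        cfg = NetworkConfig(conv_filters=(2, 3, 4), input_size=8, fc_sizes=(4, 4))
        model = build_ecnn(cfg)
        with pytest.raises(InvalidParameterError):
            train(model, (np.zeros((0, 8, 8, 2)), np.zeros(0, int)), None)
        with pytest.raises(InvalidParameterError):
            train(model, (np.zeros((4, 8, 8, 2)), np.zeros(4, int)), None)

    def test_checkpoint_roundtrip(self, tmp_path):
        import json

        cfg = NetworkConfig(conv_filters=(2, 3, 4), input_size=8, fc_sizes=(4, 4),
                            epochs=1, seed=0)
        x = np.random.default_rng(0).normal(size=(8, 8, 8, 2))
        y = np.tile(np.arange(4), 2)
        fitted = train(build_ecnn(cfg), (x, y), None)
        path = fitted.save(tmp_path / "model")
        arrays = np.load(path)
        assert len(arrays.files) == len(list(fitted.model.parameters()))
        meta = json.loads((tmp_path / "model.json").read_text())
        assert meta["config"]["conv_filters"] == [2, 3, 4]
        assert len(meta["history"]) == 1
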