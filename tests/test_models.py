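"""Architecture definitions, gradients, training behavior, checkpoints."""

import numpy as np
import pytest

from mwlcnn import models as M
from mwlcnn.nn import (
    AvgPool2D,
    Conv2D,
    Dense,
    Flatten,
    Network,
    OptimizerConfig,
    ReLU,
    make_optimizer,
)

# (channels, height, width) after each conv/pool stage, precomputed by hand
# from the 102 x 10 input under valid padding, stride 1 and floor pooling.
EXPECTED_SHAPES = {
    "CNN1": [(1, 102, 10), (15, 100, 8), (15, 25, 4)],
    "CNN2": [(1, 102, 10), (15, 100, 8), (15, 25, 4), (25, 22, 4), (25, 11, 2), (40, 8, 2)],
    "CNN3": [
        (1, 102, 10), (15, 100, 8), (15, 100, 8), (15, 25, 4), (25, 22, 4),
        (25, 22, 4), (25, 11, 2), (40, 10, 1), (40, 10, 1),
    ],
    "CNN4": [
        (1, 102, 10), (15, 100, 8), (15, 98, 6), (15, 49, 3), (25, 46, 3),
        (25, 42, 3), (25, 21, 3), (40, 20, 2), (40, 19, 1),
    ],
    "CNN5": [
        (1, 102, 10), (15, 100, 8), (15, 98, 6), (15, 96, 4), (15, 24, 2),
        (25, 21, 2), (25, 18, 2), (25, 15, 2), (25, 5, 2), (40, 4, 2),
        (40, 3, 2), (40, 2, 2),
    ],
}


def _toy_data(n=60, n_classes=2, seed=0, shift=2.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 102, 10))
    y = rng.integers(0, n_classes, n)
    for c in range(1, n_classes):
        X[y == c] += shift * c
    return X, y


class TestArchitectures:
    @pytest.mark.parametrize("arch_id", M.ARCH_IDS)
    def test_analytic_shape_audit(self, arch_id):
        spec = M.build_architecture(arch_id, 4)
        assert M.forward_shapes(spec) == EXPECTED_SHAPES[arch_id]

    @pytest.mark.parametrize("arch_id", M.ARCH_IDS)
    def test_forward_pass_matches_audit(self, arch_id):
        spec = M.build_architecture(arch_id, 4)
        net = M._build_network(spec, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, 1, 102, 10))
        probs = net.predict_proba(x)
        assert probs.shape == (2, 4)

    def test_cnn1_structure(self):
        spec = M.build_architecture("CNN1", 4)
        assert spec.stack == (("conv", 3, 3, 0), ("pool", 4, 2))
        assert spec.filter_counts[0] == 15 and spec.fc_width == 256

    def test_cnn3_has_seven_weight_layers_with_1x1_convs(self):
        spec = M.build_architecture("CNN3", 4)
        convs = [e for e in spec.stack if e[0] == "conv"]
        assert len(convs) == 6  # + FC = 7 weight layers before the output
        assert sum(1 for e in convs if e[1] == 1 and e[2] == 1) == 3

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="CNN9"):
            M.build_architecture("CNN9", 4)

    def test_filter_counts_overridable(self):
        spec = M.build_architecture("CNN2", 4, filter_counts=(24, 12, 10))
        shapes = M.forward_shapes(spec)
        assert shapes[1][0] == 24 and shapes[-1][0] == 10

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            M.build_architecture("CNN5", 4, input_shape=(12, 10))


class TestGradients:
    def test_numerical_vs_analytic_on_tiny_network(self):
        rng = np.random.default_rng(0)
        net = Network(
            [Conv2D(1, 2, 3, 3, rng), ReLU(), AvgPool2D(2, 2), Flatten(), Dense(8, 3, rng)]
        )
        x = rng.standard_normal((4, 1, 6, 6))
        y = np.array([0, 1, 2, 1])
        net.loss_and_grad(x, y)
        analytic = [g.copy() for g in net.grads]
        eps = 1e-6
        for p, g in zip(net.params, analytic):
            it = np.nditer(p, flags=["multi_index"])
            for _ in range(min(p.size, 25)):
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp = net.loss_and_grad(x, y)
                p[idx] = orig - eps
                lm = net.loss_and_grad(x, y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(g[idx]), 1e-8)
                assert abs(num - g[idx]) / denom < 1e-4
                it.iternext()


class TestTraining:
    def test_separable_classes_fit_and_loss_decreases(self):
        X, y = _toy_data(shift=2.0)
        spec = M.build_architecture("CNN1", 2)
        model = M.train(
            spec, X, y, OptimizerConfig("nm", learning_rate=1e-3), epochs_n=25,
            batch_size=16, seed=1,
        )
        assert model.train_accuracy_trace[-1] >= 0.95
        assert model.loss_trace[4] < model.loss_trace[0]
        assert (M.predict(model, X) == y).mean() >= 0.95

    def test_zero_learning_rate_changes_nothing(self):
        X, y = _toy_data(n=20)
        spec = M.build_architecture("CNN1", 2)
        rng = np.random.default_rng(3)
        net = M._build_network(spec, rng)
        before = net.get_state()
        opt = make_optimizer(net.params, OptimizerConfig("nm", learning_rate=0.0))
        for _ in range(3):
            net.loss_and_grad(X[:8, None], y[:8])
            opt.step(net.grads)
        for b, a in zip(before, net.params):
            assert np.array_equal(b, a)

    def test_same_seed_bit_identical_traces(self):
        X, y = _toy_data(n=30)
        spec = M.build_architecture("CNN1", 2)
        kw = dict(optimizer=OptimizerConfig("adam"), epochs_n=5, batch_size=8, seed=11)
        m1 = M.train(spec, X, y, **kw)
        m2 = M.train(spec, X, y, **kw)
        assert np.array_equal(m1.loss_trace, m2.loss_trace)
        for p1, p2 in zip(m1.network.params, m2.network.params):
            assert np.array_equal(p1, p2)

    @pytest.mark.parametrize("algorithm", M.OPTIMIZER_IDS)
    def test_every_optimizer_reduces_loss(self, algorithm):
        X, y = _toy_data(n=40, shift=3.0)
        spec = M.build_architecture("CNN1", 2)
        lr = 1e-3 if algorithm in ("nm", "adam") else 1e-2
        model = M.train(
            spec, X, y, OptimizerConfig(algorithm, learning_rate=lr), epochs_n=15,
            batch_size=16, seed=2,
        )
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_single_class_labels_rejected(self):
        X, _ = _toy_data(n=10)
        spec = M.build_architecture("CNN1", 2)
        with pytest.raises(ValueError, match="two classes"):
            M.train(spec, X, np.zeros(10, dtype=int))


class TestPredictProba:
    def test_rows_sum_to_one(self):
        X, y = _toy_data(n=20)
        spec = M.build_architecture("CNN2", 2)
        model = M.train(spec, X, y, epochs_n=2, batch_size=8, seed=0)
        p = M.predict_proba(model, X)
        assert p.shape == (20, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_zeroed_output_layer_gives_uniform_posterior(self):
        spec = M.build_architecture("CNN1", 4)
        net = M._build_network(spec, np.random.default_rng(0))
        net.layers[-1].w[:] = 0.0
        net.layers[-1].b[:] = 0.0
        p = net.predict_proba(np.random.default_rng(1).standard_normal((3, 1, 102, 10)))
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        X, y = _toy_data(n=12)
        spec = M.build_architecture("CNN1", 2)
        model = M.train(spec, X, y, epochs_n=1, batch_size=6, seed=0)
        with pytest.raises(ValueError, match="input"):
            M.predict_proba(model, np.zeros((3, 50, 10)))


def test_checkpoint_round_trip(tmp_path):
    X, y = _toy_data(n=24)
    spec = M.build_architecture("CNN1", 2)
    model = M.train(spec, X, y, epochs_n=3, batch_size=8, seed=5)
    M.save_model(model, tmp_path / "m.npz")
    loaded = M.load_model(tmp_path / "m.npz")
    assert loaded.spec == model.spec
    assert loaded.optimizer_config == model.optimizer_config
    np.testing.assert_array_equal(M.predict_proba(loaded, X), M.predict_proba(model, X))
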