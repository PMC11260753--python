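"""Network contracts, loss identities, noise bounds, training behavior."""

import numpy as np
import pytest

from dusbeat.ssl_model import (
    Adam,
    Conv1dNet,
    ModelConfig,
    TrainConfig,
    add_bounded_noise,
    build_model,
    consistency_step,
    cross_entropy_and_grad,
    kl_divergence,
    predict,
    softmax,
    supervised_step,
    train,
)


@pytest.fixture(scope="module")
def tiny_config():
    return ModelConfig(channels=(4, 4, 4, 4), kernel=5)


@pytest.fixture(scope="module")
def toy_data():
    """Four linearly separated waveform prototypes + mild noise."""
    rng = np.random.default_rng(0)
    protos = np.zeros((4, 350))
    t = np.arange(350) / 1000.0
    protos[0] = 0.05 * rng.standard_normal(350)
    protos[1] = 0.6 * np.sin(2 * np.pi * 150 * t)
    protos[2] = 0.6 * np.sin(2 * np.pi * 250 * t)
    protos[3] = np.where(np.arange(350) < 120, 0.8, 0.0) * rng.standard_normal(350)
    X = np.repeat(protos, 40, axis=0) + 0.02 * rng.standard_normal((160, 350))
    y = np.repeat(np.arange(4), 40)
    return X, y


class TestModelContracts:
    def test_output_is_probability_vector(self, tiny_config):
        model = build_model(tiny_config, seed=1)
        probs = model.predict_proba(np.random.default_rng(0).uniform(-1, 1, (7, 350)))
        assert probs.shape == (7, 4)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_seed_identical_parameters(self, tiny_config):
        a = build_model(tiny_config, seed=3)
        b = build_model(tiny_config, seed=3)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_batch_order_invariance(self, tiny_config):
        model = build_model(tiny_config, seed=4)
        X = np.random.default_rng(1).uniform(-1, 1, (10, 350))
        p = model.predict_proba(X)
        perm = np.random.default_rng(2).permutation(10)
        np.testing.assert_allclose(model.predict_proba(X[perm]), p[perm], atol=1e-12)

    def test_pooling_collapse_rejected(self):
        with pytest.raises(ValueError, match="temporal"):
            ModelConfig(channels=(4,) * 10, n_blocks=10, input_length=350)

    def test_argmax_tie_breaks_to_lowest_index(self, tiny_config):
        model = build_model(tiny_config, seed=5)
        pred = predict(model, np.zeros((3, 350)))
        probs = pred.probabilities
        # manufactured exact tie check on the decision rule itself
        assert np.argmax(np.array([0.25, 0.25, 0.25, 0.25])) == 0
        assert all(pred.labels[i] == np.argmax(probs[i]) for i in range(3))

    def test_gradients_match_finite_differences(self):
        """Backprop agrees with central differences on a micro network."""
        cfg = ModelConfig(n_blocks=2, channels=(2, 3), kernel=3, input_length=20)
        model = build_model(cfg, seed=6)
        X = np.random.default_rng(3).uniform(-1, 1, (4, 20))
        y = np.array([0, 1, 2, 3])

        def loss_at():
            logits = model.forward_logits(X)
            return cross_entropy_and_grad(logits, y)[0]

        logits, cache = model._forward(X, keep_cache=True)
        _, dlogits = cross_entropy_and_grad(logits, y)
        grads = model.backward(cache, dlogits)
        eps = 1e-6
        for name in ("W0", "b1", "Wd", "bd"):
            p = model.params[name]
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            up = loss_at()
            p[idx] -= 2 * eps
            down = loss_at()
            p[idx] += eps
            fd = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestBoundedNoise:
    def test_zero_amplitude_identity(self):
        X = np.random.default_rng(0).uniform(-1, 1, (5, 350))
        out = add_bounded_noise(X, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(out, X)

    def test_hard_bound_respected(self):
        X = np.zeros((20, 350))
        for dist in ("uniform", "gaussian"):
            out = add_bounded_noise(X, 0.07, np.random.default_rng(2), dist)
            assert np.max(np.abs(out)) <= 0.07

    def test_noise_mean_vanishes_at_large_n(self):
        delta = add_bounded_noise(
            np.zeros(100_000), 0.1, np.random.default_rng(3)
        )
        assert abs(delta.mean()) < 3 * 0.1 / np.sqrt(3 * 100_000)

    def test_padding_region_perturbed_by_default(self):
        X = np.zeros((2, 350))
        X[:, :100] = 0.5
        out = add_bounded_noise(X, 0.05, np.random.default_rng(4))
        assert np.any(out[:, 100:] != 0.0)
        out2 = add_bounded_noise(X, 0.05, np.random.default_rng(4),
                                 noise_in_padding=False)
        assert np.all(out2[:, 100:] == 0.0)


class TestLosses:
    def test_uniform_prediction_cross_entropy_is_ln4(self):
        logits = np.zeros((8, 4))
        loss, _ = cross_entropy_and_grad(logits, np.zeros(8, dtype=int))
        assert loss == pytest.approx(np.log(4.0), rel=1e-12)

    def test_confident_correct_prediction_near_zero_loss(self):
        logits = np.full((4, 4), -50.0)
        np.fill_diagonal(logits, 50.0)
        loss, _ = cross_entropy_and_grad(logits, np.arange(4))
        assert loss < 1e-6

    def test_kl_hand_computed_value(self):
        p = np.array([[0.7, 0.1, 0.1, 0.1]])
        q = np.array([[0.25, 0.25, 0.25, 0.25]])
        expected = np.sum(p * np.log(p / q))
        assert kl_divergence(p, q)[0] == pytest.approx(expected, abs=1e-9)

    def test_kl_nonnegative_zero_iff_equal(self):
        rng = np.random.default_rng(5)
        p = softmax(rng.standard_normal((50, 4)))
        q = softmax(rng.standard_normal((50, 4)))
        assert np.all(kl_divergence(p, q) >= 0)
        np.testing.assert_allclose(kl_divergence(p, p), 0.0, atol=1e-12)


class TestTraining:
    def test_supervised_loss_decreases_on_separable_data(self, tiny_config, toy_data):
        X, y = toy_data
        model = build_model(tiny_config, seed=7)
        opt = Adam(model.params, lr=3e-3)
        losses = [supervised_step(model, opt, X, y) for _ in range(50)]
        assert np.mean(losses[-5:]) < 0.5 * np.mean(losses[:5])

    def test_consistency_loss_zero_at_zero_amplitude(self, tiny_config, toy_data):
        X, _ = toy_data
        model = build_model(tiny_config, seed=8)
        opt = Adam(model.params, lr=1e-3)
        tc = TrainConfig(noise_amplitude=0.0)
        loss = consistency_step(model, opt, X[:16], tc, np.random.default_rng(0))
        assert loss == 0.0

    def test_zero_consistency_weight_reproduces_supervised_trajectory(
        self, tiny_config, toy_data
    ):
        """semi mode with weight 0 is bit-identical to supervised mode."""
        X, y = toy_data
        tc = TrainConfig(epochs=3, consistency_weight=0.0, seed=9,
                         batch_size_labeled=32)
        m1 = build_model(tiny_config, seed=10)
        train(m1, X, y, X.copy(), "semi", tc)
        m2 = build_model(tiny_config, seed=10)
        train(m2, X, y, None, "supervised", tc)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_training_reproducible_under_seed(self, tiny_config, toy_data):
        X, y = toy_data
        tc = TrainConfig(epochs=2, seed=11)
        m1 = build_model(tiny_config, seed=12)
        train(m1, X, y, X, "semi", tc)
        m2 = build_model(tiny_config, seed=12)
        train(m2, X, y, X, "semi", tc)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_semi_mode_requires_unlabeled_pool(self, tiny_config, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError, match="unlabeled"):
            train(build_model(tiny_config, seed=0), X, y, None, "semi",
                  TrainConfig(epochs=1))

    def test_overfit_run_recovers_training_labels(self, tiny_config, toy_data):
        X, y = toy_data
        model = build_model(tiny_config, seed=13)
        train(model, X, y, None, "supervised", TrainConfig(epochs=30, seed=13))
        pred = predict(model, X)
        assert np.mean(pred.labels == y) > 0.9
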