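"""Poisson deep network: forward/loss/gradient correctness and training."""

import numpy as np
import pandas as pd
import pytest

from countgs import (
    NetworkParams,
    NetworkSpec,
    PoissonDeepNet,
    TrainConfig,
    TrainedNetwork,
    UnivariatePoissonDeepNet,
    forward,
    gradients,
    init_params,
    mpdn_loss,
    train,
)
from countgs.nnet import DomainError


class TestInit:
    def test_deterministic_and_glorot_bounded(self):
        spec = NetworkSpec(n_hidden=3, units=(5, 4, 3), n_outputs=2)
        a = init_params(spec, 7, seed=4)
        b = init_params(spec, 7, seed=4)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        sizes = spec.layer_sizes(7)
        for w, (fi, fo) in zip(a.weights, zip(sizes[:-1], sizes[1:])):
            limit = np.sqrt(6.0 / (fi + fo))
            assert np.all(np.abs(w) <= limit)
        for bias in a.biases:
            assert not bias.any()


class TestForward:
    def test_zero_params_give_unit_rates(self):
        spec = NetworkSpec(n_hidden=2, units=3, n_outputs=4)
        p = init_params(spec, 5, seed=0)
        for w in p.weights:
            w[:] = 0.0
        out = forward(spec, p, np.random.default_rng(0).normal(size=(6, 5)))
        assert np.allclose(out, 1.0)

    def test_relu_kills_negative_net_input(self):
        spec = NetworkSpec(n_hidden=1, units=1, n_outputs=1)
        p = NetworkParams([np.array([[1.0]]), np.array([[5.0]])],
                          [np.array([-3.0]), np.array([0.0])])
        # x=2 -> net input 2-3 = -1 -> ReLU 0 -> output exp(0) = 1
        assert forward(spec, p, np.array([[2.0]]))[0, 0] == pytest.approx(1.0)

    def test_matches_hand_computed_chain(self):
        spec = NetworkSpec(n_hidden=1, units=2, n_outputs=1)
        W1 = np.array([[0.5, -1.0], [0.25, 0.75]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.5], [-0.5]])
        b2 = np.array([0.3])
        p = NetworkParams([W1, W2], [b1, b2])
        x = np.array([[1.0, 2.0]])
        h = np.maximum(x @ W1 + b1, 0.0)
        expected = np.exp(h @ W2 + b2)
        assert forward(spec, p, x)[0, 0] == pytest.approx(expected[0, 0], abs=1e-12)

    def test_outputs_strictly_positive(self):
        rng = np.random.default_rng(3)
        spec = NetworkSpec(n_hidden=2, units=4, n_outputs=3)
        p = init_params(spec, 6, seed=1)
        assert np.all(forward(spec, p, rng.normal(size=(20, 6))) > 0)

    def test_shape_mismatch_rejected(self):
        spec = NetworkSpec(n_hidden=1, units=2, n_outputs=1)
        p = init_params(spec, 4, seed=0)
        with pytest.raises(DomainError):
            forward(spec, p, np.zeros((3, 5)))


class TestLoss:
    def test_perfect_prediction_closed_form(self):
        Y = np.array([[1.0, 1.0]])
        assert mpdn_loss(Y, Y) == pytest.approx(2.0)  # sum_t (y - y log y), y=1

    def test_zero_weights_zero_penalty(self):
        spec = NetworkSpec(n_hidden=1, units=2, n_outputs=1, l1_lambda=0.01)
        p = init_params(spec, 3, seed=0)
        for w in p.weights:
            w[:] = 0.0
        base = mpdn_loss(np.array([[2.0]]), np.array([[1.0]]))
        with_pen = mpdn_loss(np.array([[2.0]]), np.array([[1.0]]), p, 0.01)
        assert base == with_pen

    def test_matches_independent_elementwise_sum(self):
        rng = np.random.default_rng(5)
        Y = rng.poisson(3.0, size=(3, 2)).astype(float)
        Yhat = rng.uniform(0.5, 5.0, size=(3, 2))
        # independent re-implementation: scalar loops
        total = 0.0
        for i in range(3):
            for t in range(2):
                total += Yhat[i, t] - Y[i, t] * np.log(Yhat[i, t])
        assert mpdn_loss(Y, Yhat) == pytest.approx(total / 3, abs=1e-12)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(DomainError):
            mpdn_loss(np.array([[1.0]]), np.array([[0.0]]))


class TestGradients:
    def test_output_bias_gradient_at_zero_params(self):
        spec = NetworkSpec(n_hidden=1, units=3, n_outputs=2)
        p = init_params(spec, 4, seed=0)
        for w in p.weights:
            w[:] = 0.0
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        Y = rng.poisson(2.0, size=(50, 2)).astype(float)
        g = gradients(spec, p, X, Y)
        # analytic: d loss / d b_out = mean(exp(0) - y) = 1 - ybar per trait
        np.testing.assert_allclose(g.biases[-1], 1.0 - Y.mean(axis=0), atol=1e-12)

    def test_empty_batch_rejected(self):
        spec = NetworkSpec(n_hidden=1, units=2, n_outputs=1)
        p = init_params(spec, 3, seed=0)
        with pytest.raises(DomainError):
            gradients(spec, p, np.zeros((0, 3)), np.zeros((0, 1)))

    def test_finite_difference_agreement(self):
        from countgs.experiments import gradient_check

        assert gradient_check(n_networks=30, seed=0) <= 1e-4


class TestUnivariateReduction:
    def test_t1_paths_identical(self):
        """With one trait and shared parameters the univariate front end and
        the multivariate path agree bit for bit on forward, loss, gradients."""
        rng = np.random.default_rng(11)
        spec = NetworkSpec(n_hidden=2, units=5, n_outputs=1)
        p = init_params(spec, 6, seed=3)
        X = rng.normal(size=(12, 6))
        y = rng.poisson(2.0, size=(12, 1)).astype(float)

        f_multi = forward(spec, p, X)
        uni = UnivariatePoissonDeepNet(y, X, spec)
        multi = PoissonDeepNet(y, X, spec)
        cfg = TrainConfig(max_epochs=0, seed=5)
        r_u = uni.fit(cfg, init=p)
        r_m = multi.fit(cfg, init=p)
        assert np.array_equal(r_u.predict(X), r_m.predict(X))
        assert np.array_equal(r_u.predict(X), f_multi)
        l_u = mpdn_loss(y, r_u.predict(X), p, 0.01)
        l_m = mpdn_loss(y, r_m.predict(X), p, 0.01)
        assert l_u == l_m
        g_u = gradients(spec, p, X, y, 0.01)
        g_m = gradients(spec, p, X, y, 0.01)
        for a, b in zip(g_u.weights + g_u.biases, g_m.weights + g_m.biases):
            assert np.array_equal(a, b)

    def test_univariate_rejects_multi_output_spec(self):
        with pytest.raises(ValueError):
            UnivariatePoissonDeepNet(
                np.zeros((4, 1)), np.zeros((4, 2)),
                NetworkSpec(n_hidden=1, units=2, n_outputs=2),
            )


class TestTraining:
    @pytest.fixture
    def linear_counts(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(500, 10))
        B = rng.normal(scale=0.2, size=(10, 2))
        Y = rng.poisson(np.exp(1.0 + X @ B))
        return X, Y.astype(float)

    def test_zero_epochs_returns_init(self, linear_counts):
        X, Y = linear_counts
        spec = NetworkSpec(n_hidden=1, units=8, n_outputs=2)
        p0 = init_params(spec, 10, seed=1)
        net = train(spec, X, Y, TrainConfig(max_epochs=0, seed=2), init=p0)
        for a, b in zip(net.params.weights, p0.weights):
            assert np.array_equal(a, b)
        assert len(net.history) == 0

    def test_same_seed_identical_training(self, linear_counts):
        X, Y = linear_counts
        spec = NetworkSpec(n_hidden=1, units=8, n_outputs=2, dropout_rate=0.1)
        cfg = TrainConfig(max_epochs=20, batch_size=64, seed=9)
        a = train(spec, X, Y, cfg)
        b = train(spec, X, Y, cfg)
        pd.testing.assert_frame_equal(a.history, b.history)
        for wa, wb in zip(a.params.weights, b.params.weights):
            assert np.array_equal(wa, wb)

    def test_loss_decreases_on_linear_data(self, linear_counts):
        """Training reaches well below the starting loss on most seeds."""
        X, Y = linear_counts
        wins = 0
        for s in range(5):
            spec = NetworkSpec(n_hidden=1, units=64, n_outputs=2)
            net = train(
                spec, X, Y,
                TrainConfig(max_epochs=150, batch_size=64, seed=s,
                            early_stopping_patience=150),
            )
            h = net.history
            if h["train_loss"].iloc[-1] <= 0.7 * h["train_loss"].iloc[0]:
                wins += 1
        assert wins >= 4

    def test_dropout_off_equals_dropout_removed(self, linear_counts, monkeypatch):
        """dropout_rate=0 must follow the exact same code path (and RNG
        stream) as a build with dropout deleted."""
        import countgs.nnet as nn

        X, Y = linear_counts
        cfg = TrainConfig(max_epochs=8, batch_size=64, seed=3)
        spec = NetworkSpec(n_hidden=2, units=8, n_outputs=2, dropout_rate=0.0)
        a = train(spec, X, Y, cfg)

        original = nn._forward_hidden

        def no_dropout_forward(spec_, params, X_, dropout_masks=None, clip=False):
            assert dropout_masks is None  # dropout must never engage
            return original(spec_, params, X_, None, clip)

        monkeypatch.setattr(nn, "_forward_hidden", no_dropout_forward)
        b = train(spec, X, Y, cfg)
        pd.testing.assert_frame_equal(a.history, b.history)

    def test_early_stopping_restores_best(self, linear_counts):
        X, Y = linear_counts
        spec = NetworkSpec(n_hidden=1, units=16, n_outputs=2)
        net = train(
            spec, X, Y,
            TrainConfig(max_epochs=400, batch_size=64, seed=4,
                        early_stopping_patience=10),
        )
        if net.stopped_early:
            assert net.best_epoch <= len(net.history)
            best = net.history["val_loss"].min()
            assert net.history.loc[net.best_epoch - 1, "val_loss"] == pytest.approx(best)

    def test_nan_loss_aborts_with_epoch(self, linear_counts):
        X, Y = linear_counts
        spec = NetworkSpec(n_hidden=1, units=8, n_outputs=2)
        with pytest.raises(RuntimeError, match="epoch"):
            train(spec, X, Y, TrainConfig(max_epochs=50, batch_size=64,
                                          learning_rate=1e6, seed=0))

    def test_save_load_round_trip(self, tmp_path, linear_counts):
        X, Y = linear_counts
        spec = NetworkSpec(n_hidden=2, units=6, n_outputs=2, l1_lambda=0.01)
        net = train(spec, X, Y, TrainConfig(max_epochs=5, batch_size=64, seed=6))
        net.save(tmp_path / "model")
        again = TrainedNetwork.load(tmp_path / "model")
        for a, b in zip(net.params.weights, again.params.weights):
            assert np.array_equal(a, b)
        assert np.array_equal(net.predict(X), again.predict(X))
        assert again.best_epoch == net.best_epoch


class TestModelFrontEnd:
    def test_fit_and_summary(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        Y = rng.poisson(2.0, size=(80, 2))
        model = PoissonDeepNet(Y, X, NetworkSpec(n_hidden=1, units=4, n_outputs=2))
        res = model.fit(TrainConfig(max_epochs=5, batch_size=32, seed=0))
        text = res.summary()
        assert "hidden layers" in text and "best epoch" in text
        assert res.predict().shape == (80, 2)

    def test_count_validation(self):
        with pytest.raises(DomainError):
            PoissonDeepNet(
                np.array([[0.5]]), np.zeros((1, 2)),
                NetworkSpec(n_hidden=1, units=2, n_outputs=1),
            )
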