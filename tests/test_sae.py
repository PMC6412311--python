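import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from rpistack.io_formats import ValidationError
from rpistack.sae import (
    AeLayer,
    SaeConfig,
    SaeModel,
    fine_tune,
    head_predict,
    kl_divergence,
    layer_loss_and_grads,
    sae_encode,
    sae_loss,
    sae_train,
)


def _zero_layer(n_in, n_hid):
    return AeLayer(
        w_enc=np.zeros((n_in, n_hid)),
        b_enc=np.zeros(n_hid),
        w_dec=np.zeros((n_hid, n_in)),
        b_dec=np.zeros(n_in),
    )


def _random_layer(rng, n_in, n_hid):
    return AeLayer(
        w_enc=rng.normal(scale=0.5, size=(n_in, n_hid)),
        b_enc=rng.normal(scale=0.1, size=n_hid),
        w_dec=rng.normal(scale=0.5, size=(n_hid, n_in)),
        b_dec=rng.normal(scale=0.1, size=n_in),
    )


class TestKlDivergence:
    def test_identity_is_zero(self):
        assert kl_divergence(0.05, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        # p ln(p/p̂) + (1-p) ln((1-p)/(1-p̂)) at p=0.05, p̂=0.10
        assert kl_divergence(0.05, 0.10) == pytest.approx(0.0167065, abs=1e-6)

    def test_symmetric_limit_near_half(self):
        eps = 1e-4
        up = kl_divergence(0.5, 0.5 + eps)
        down = kl_divergence(0.5, 0.5 - eps)
        assert up == pytest.approx(down, rel=1e-6)
        assert up < 1e-6

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.001, max_value=0.999),
    )
    def test_nonnegative_with_equality_iff_match(self, p, p_hat):
        val = kl_divergence(p, p_hat)
        assert val >= 0.0
        if abs(p - p_hat) > 1e-6:
            assert val > 0.0

    def test_p_outside_unit_interval_rejected(self):
        for p in (0.0, 1.0, -0.1, 1.7):
            with pytest.raises(ValidationError):
                kl_divergence(p, 0.5)


class TestLoss:
    def test_perfect_reconstruction_is_zero(self):
        # zero weights, inputs at sigmoid(0) = 0.5: exact reconstruction
        cfg = SaeConfig(layer_sizes=(3,), weight_decay=0.0, sparsity_weight=0.0)
        model = SaeModel(layers=[_zero_layer(4, 3)], config=cfg)
        X = np.full((5, 4), 0.5)
        assert sae_loss(model, X, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weight_closed_form(self, rng):
        cfg = SaeConfig(layer_sizes=(3,), weight_decay=0.0, sparsity_weight=0.0)
        layer = _zero_layer(4, 3)
        layer.b_dec = rng.normal(size=4)
        model = SaeModel(layers=[layer], config=cfg)
        X = rng.random((6, 4))
        expected = np.sum((expit(layer.b_dec)[None, :] - X) ** 2)
        assert sae_loss(model, X, cfg) == pytest.approx(expected, rel=1e-12)

    def test_penalty_decomposition_is_exact(self, rng):
        base = SaeConfig(
            layer_sizes=(5, 3), weight_decay=0.0, sparsity_weight=0.0
        )
        full = SaeConfig(
            layer_sizes=(5, 3), weight_decay=0.31, sparsity_weight=2.7
        )
        layers = [_random_layer(rng, 6, 5), _random_layer(rng, 5, 3)]
        model = SaeModel(layers=layers, config=full)
        X = rng.random((9, 6))
        diff = sae_loss(model, X, full) - sae_loss(model, X, base)
        # recompute the penalties directly
        expected = 0.0
        cur = X
        for layer in layers:
            expected += 0.31 * (np.sum(layer.w_enc**2) + np.sum(layer.w_dec**2))
            H = layer.encode(cur)
            expected += 2.7 * float(
                np.sum(kl_divergence(full.sparsity_target, H.mean(axis=0)))
            )
            cur = H
        assert diff == pytest.approx(expected, rel=1e-10)

    def test_increasing_beta_never_decreases_loss(self, rng):
        layers = [_random_layer(rng, 4, 3)]
        X = rng.random((7, 4))
        losses = []
        for beta in (0.0, 1.0, 5.0):
            cfg = SaeConfig(layer_sizes=(3,), weight_decay=0.0, sparsity_weight=beta)
            losses.append(sae_loss(SaeModel(layers=layers, config=cfg), X, cfg))
        assert losses[0] <= losses[1] <= losses[2]


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Full layer loss (reconstruction + weight decay + KL sparsity)."""
        cfg = SaeConfig(
            layer_sizes=(3,),
            weight_decay=0.05,
            sparsity_weight=1.5,
            sparsity_target=0.2,
            dropout_rate=0.0,
        )
        layer = _random_layer(rng, 4, 3)
        X = rng.random((6, 4))
        _, grads = layer_loss_and_grads(layer, X, cfg)
        eps = 1e-6
        for name in ("w_enc", "b_enc", "w_dec", "b_dec"):
            param = getattr(layer, name)
            numeric = np.zeros_like(param)
            it = np.nditer(param, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                up, _ = layer_loss_and_grads(layer, X, cfg)
                param[idx] = orig - eps
                down, _ = layer_loss_and_grads(layer, X, cfg)
                param[idx] = orig
                numeric[idx] = (up - down) / (2 * eps)
            scale = max(1.0, float(np.abs(numeric).max()))
            np.testing.assert_allclose(
                grads[name] / scale, numeric / scale, atol=1e-5
            )


class TestTraining:
    def test_loss_non_increasing_without_penalties(self, rng):
        cfg = SaeConfig(
            layer_sizes=(6,),
            weight_decay=0.0,
            sparsity_weight=0.0,
            dropout_rate=0.0,
            batch_size=200,  # full batch
            epochs=30,
            learning_rate=0.05,
            seed=3,
        )
        X = rng.random((40, 10))
        model = sae_train(X, cfg)
        losses = np.array(model.history[0])
        assert (np.diff(losses) <= 0.05 * losses[:-1]).all()
        assert losses[-1] < losses[0]

    def test_encode_dimension_and_range(self, rng, fast_sae_config):
        X = rng.random((30, 12))
        model = sae_train(X, fast_sae_config)
        H = sae_encode(model, X)
        assert H.shape == (30, fast_sae_config.layer_sizes[-1])
        assert ((H > 0) & (H < 1)).all()

    def test_seed_determinism_bit_identical(self, rng, fast_sae_config):
        X = rng.random((25, 12))
        H1 = sae_encode(sae_train(X, fast_sae_config), X)
        H2 = sae_encode(sae_train(X, fast_sae_config), X)
        np.testing.assert_array_equal(H1, H2)

    def test_encode_ignores_dropout_rate(self, rng):
        X = rng.random((20, 8))
        cfg = SaeConfig(layer_sizes=(5,), epochs=5, dropout_rate=0.0, seed=1)
        model = sae_train(X, cfg)
        H = sae_encode(model, X)
        model.config = SaeConfig(layer_sizes=(5,), epochs=5, dropout_rate=0.9, seed=1)
        np.testing.assert_array_equal(sae_encode(model, X), H)

    def test_zero_input_zero_weights_encodes_to_half(self):
        cfg = SaeConfig(layer_sizes=(3,))
        model = SaeModel(layers=[_zero_layer(4, 3)], config=cfg)
        np.testing.assert_array_equal(sae_encode(model, np.zeros((2, 4))), 0.5)

    def test_single_layer_matches_hand_forward(self, rng):
        cfg = SaeConfig(layer_sizes=(3,))
        layer = _random_layer(rng, 2, 3)
        model = SaeModel(layers=[layer], config=cfg)
        X = rng.random((2, 2))
        np.testing.assert_allclose(
            sae_encode(model, X), expit(X @ layer.w_enc + layer.b_enc)
        )

    def test_width_mismatch_rejected(self, rng, fast_sae_config):
        model = sae_train(rng.random((10, 6)), fast_sae_config)
        with pytest.raises(ValidationError):
            sae_encode(model, rng.random((4, 7)))


class TestFineTune:
    def test_linearly_separable_reaches_high_accuracy(self, rng):
        n = 120
        y = (rng.random(n) < 0.5).astype(int)
        X = np.clip(0.5 + (y[:, None] - 0.5) * 0.6 + rng.normal(scale=0.05, size=(n, 6)), 0, 1)
        cfg = SaeConfig(
            layer_sizes=(8,), epochs=60, dropout_rate=0.0, learning_rate=0.5,
            batch_size=40, seed=5,
        )
        model = sae_train(X, cfg)
        tuned = fine_tune(model, X, y, cfg)
        acc = np.mean((head_predict(tuned, X) >= 0.5).astype(int) == y)
        assert acc >= 0.95

    def test_zero_epochs_leaves_parameters_unchanged(self, rng, fast_sae_config):
        X = rng.random((20, 10))
        y = np.array([0, 1] * 10)
        model = sae_train(X, fast_sae_config)
        before = copy.deepcopy(model.layers)
        cfg0 = SaeConfig(**{**fast_sae_config.__dict__, "epochs": 0})
        tuned = fine_tune(model, X, y, cfg0)
        for lay_b, lay_t in zip(before, tuned.layers):
            np.testing.assert_array_equal(lay_b.w_enc, lay_t.w_enc)
            np.testing.assert_array_equal(lay_b.b_enc, lay_t.b_enc)

    def test_single_class_labels_rejected(self, rng, fast_sae_config):
        X = rng.random((10, 10))
        model = sae_train(X, fast_sae_config)
        with pytest.raises(ValidationError):
            fine_tune(model, X, np.ones(10), fast_sae_config)

    def test_fine_tune_does_not_mutate_input_model(self, rng, fast_sae_config):
        X = rng.random((20, 10))
        y = np.array([0, 1] * 10)
        model = sae_train(X, fast_sae_config)
        before = copy.deepcopy(model.layers[0].w_enc)
        fine_tune(model, X, y, fast_sae_config)
        np.testing.assert_array_equal(model.layers[0].w_enc, before)
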