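import math

import numpy as np
import pytest

from eegimpute.transformer import (RegressorModel, TransformerConfig,
                                   fit_regressor, positional_encoding,
                                   self_attention)

FEATURES = [f"f{i}" for i in range(6)]


def make_model(seed=0, **kwargs):
    cfg = TransformerConfig(seed=seed, **kwargs)
    return RegressorModel.initialise(FEATURES, cfg,
                                     np.random.default_rng(seed))


class TestPositionalEncoding:
    def test_position_zero_is_alternating_zero_one(self):
        P = positional_encoding(3, 8)
        assert np.all(P[0, 0::2] == 0.0)
        assert np.all(P[0, 1::2] == 1.0)

    def test_hand_computed_entry(self):
        P = positional_encoding(2, 4)
        assert P[1, 0] == pytest.approx(math.sin(1.0), abs=1e-12)
        assert P[1, 1] == pytest.approx(math.cos(1.0), abs=1e-12)
        assert P[1, 2] == pytest.approx(math.sin(1.0 / 100.0), abs=1e-12)

    @pytest.mark.parametrize("n,d", [(1, 2), (16, 8), (512, 64)])
    def test_matches_closed_form_everywhere(self, n, d):
        P = positional_encoding(n, d)
        for pos in range(0, n, max(1, n // 7)):
            for i in range(d // 2):
                angle = pos / 10000.0 ** (2.0 * i / d)
                assert abs(P[pos, 2 * i] - math.sin(angle)) < 1e-12
                assert abs(P[pos, 2 * i + 1] - math.cos(angle)) < 1e-12
        assert np.abs(P).max() <= 1.0

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 5)


class TestSelfAttention:
    def test_rows_of_softmax_sum_to_one_via_uniform_values(self):
        # with V = identity the output rows are the attention weights
        rng = np.random.default_rng(0)
        Q, K = rng.normal(size=(2, 5, 5))
        out = self_attention(Q, K, np.eye(5))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out >= 0).all()

    def test_single_token_returns_v(self):
        rng = np.random.default_rng(1)
        Q, K, V = rng.normal(size=(3, 1, 4))
        np.testing.assert_allclose(self_attention(Q, K, V), V, atol=1e-15)

    def test_matches_explicit_exponential_evaluation(self):
        rng = np.random.default_rng(2)
        Q, K, V = rng.normal(size=(3, 3, 2))
        out = self_attention(Q, K, V)
        dk = 2
        expected = np.zeros((3, 2))
        for i in range(3):
            logits = [sum(Q[i, a] * K[j, a] for a in range(dk))
                      / math.sqrt(dk) for j in range(3)]
            exps = [math.exp(l) for l in logits]
            w = [e / sum(exps) for e in exps]
            for c in range(2):
                expected[i, c] = sum(w[j] * V[j, c] for j in range(3))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            self_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 3)))


class TestEncodeRow:
    def test_token_rows_are_normalised_before_gain_bias(self):
        model = make_model()
        x = np.linspace(0.5, 2.0, len(FEATURES))
        # gain is 1 and bias 0 at initialisation, so Z - P is the LN output
        Z = model.encode_row(x)
        from eegimpute.transformer import positional_encoding as pe
        E = Z - pe(len(FEATURES), model.cfg.d_model)
        np.testing.assert_allclose(E.mean(axis=1), 0.0, atol=1e-5)
        # variance sits at sigma^2/(sigma^2+eps), just below 1
        np.testing.assert_allclose(E.var(axis=1), 1.0, atol=5e-3)

    def test_z_minus_e_equals_positional_encoding(self):
        model = make_model()
        x = np.ones(len(FEATURES))
        Z = model.encode_row(x)
        E = model._embed(x[None, :]).data[0] \
            - positional_encoding(len(FEATURES), model.cfg.d_model)
        np.testing.assert_allclose(
            Z - E, positional_encoding(len(FEATURES), model.cfg.d_model),
            atol=1e-6)

    def test_embedding_locality(self):
        model = make_model()
        a = np.zeros(len(FEATURES))
        b = a.copy()
        b[3] = 2.5
        Za, Zb = model.encode_row(a), model.encode_row(b)
        diff = np.abs(Za - Zb).sum(axis=1)
        assert diff[3] > 0
        others = np.delete(np.arange(len(FEATURES)), 3)
        np.testing.assert_allclose(diff[others], 0.0, atol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            make_model().encode_row(np.ones(3))


class TestEncoderLayer:
    def test_single_head_equals_attention_composed_with_wo(self):
        model = make_model(seed=3, n_heads=1)
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(len(FEATURES), model.cfg.d_model)
                       ).astype(np.float32)
        got = model.multi_head_attention(Z, layer=0)
        Q = Z @ model.params["L0_Wq"].data
        K = Z @ model.params["L0_Wk"].data
        V = Z @ model.params["L0_Wv"].data
        expected = self_attention(Q, K, V) @ model.params["L0_Wo"].data
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_output_shape_preserved_across_layers(self):
        model = make_model(seed=5, n_layers=2)
        Z = np.random.default_rng(6).normal(
            size=(len(FEATURES), model.cfg.d_model))
        for layer in range(2):
            Z = model.encoder_forward(Z, layer)
            assert Z.shape == (len(FEATURES), model.cfg.d_model)

    def test_zero_ffn_second_weight_reduces_to_bias(self):
        model = make_model(seed=7)
        model.params["L0_W2"].data[:] = 0.0
        model.params["L0_b2"].data[:] = 0.25
        Z = np.random.default_rng(8).normal(
            size=(len(FEATURES), model.cfg.d_model)).astype(np.float32)
        got = model.encoder_forward(Z, 0)
        # reproduce: attention sub-layer, then LayerNorm(Z' + b2)
        att = model.multi_head_attention(Z, 0)
        Z1 = (Z + att)
        g, b = model.params["L0_ln1_g"].data, model.params["L0_ln1_b"].data
        mu = Z1.mean(-1, keepdims=True)
        Z1n = (Z1 - mu) / np.sqrt(Z1.var(-1, keepdims=True) + 1e-5) * g + b
        Z2 = Z1n + 0.25
        mu2 = Z2.mean(-1, keepdims=True)
        g2, b2 = model.params["L0_ln2_g"].data, model.params["L0_ln2_b"].data
        expected = (Z2 - mu2) / np.sqrt(Z2.var(-1, keepdims=True) + 1e-5) \
            * g2 + b2
        np.testing.assert_allclose(got, expected, atol=1e-4)


class TestFitAndPredict:
    QUICK = dict(max_epochs=25, batch_size=64, lr=3e-3, dropout=0.0,
                 n_layers=1, d_model=16, n_heads=2, d_ff=32)

    def test_same_seed_reproduces_training_exactly(self, rng):
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6)
        m1 = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=1, **self.QUICK))
        m2 = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=1, **self.QUICK))
        assert m1.train_log == m2.train_log
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_best_validation_loss_is_monotone_minimum(self, rng):
        X = rng.normal(size=(100, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=100)
        m = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=2, **self.QUICK))
        val = [e["val_mse"] for e in m.train_log]
        assert min(val) == np.minimum.accumulate(val)[-1]

    def test_constant_target_predicted_exactly(self, rng):
        X = rng.normal(size=(60, 6))
        y = np.full(60, 3.7)
        m = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=3, **self.QUICK))
        np.testing.assert_allclose(m.predict(X), 3.7, atol=1e-3)

    def test_linear_function_learnable(self, rng):
        X = rng.normal(size=(600, 6))
        w = rng.normal(size=6)
        y = X @ w
        m = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=4, max_epochs=60, batch_size=128, lr=3e-3, dropout=0.0,
            n_layers=1))
        X_new = rng.normal(size=(200, 6))
        pred = m.predict(X_new)
        resid = pred - X_new @ w
        r2 = 1 - np.sum(resid ** 2) / np.sum(
            (X_new @ w - (X_new @ w).mean()) ** 2)
        assert r2 > 0.95

    def test_prediction_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 6))
        y = X.sum(axis=1)
        m = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=5, max_epochs=3, **{k: v for k, v in self.QUICK.items()
                                     if k != "max_epochs"}))
        perm = rng.permutation(40)
        np.testing.assert_allclose(m.predict(X)[perm], m.predict(X[perm]),
                                   atol=1e-6)

    def test_all_zero_rows_give_finite_predictions(self, rng):
        X = rng.normal(size=(40, 6))
        m = fit_regressor(X, X.sum(axis=1), FEATURES, TransformerConfig(
            seed=6, max_epochs=3, **{k: v for k, v in self.QUICK.items()
                                     if k != "max_epochs"}))
        assert np.isfinite(m.predict(np.zeros((5, 6)))).all()

    def test_input_validation(self, rng):
        X = rng.normal(size=(40, 6))
        y = X.sum(axis=1)
        cfg = TransformerConfig(seed=0, **self.QUICK)
        with pytest.raises(ValueError, match="complete"):
            bad = X.copy()
            bad[0, 0] = np.nan
            fit_regressor(bad, y, FEATURES, cfg)
        with pytest.raises(ValueError, match="at least 10"):
            fit_regressor(X[:5], y[:5], FEATURES, cfg)
        m = fit_regressor(X, y, FEATURES, cfg)
        with pytest.raises(ValueError):
            m.predict(X[:, :4])

    @pytest.mark.parametrize("pooling", ["mean", "max", "attention"])
    def test_all_pooling_modes_train_and_predict(self, rng, pooling):
        X = rng.normal(size=(50, 6))
        y = X.sum(axis=1)
        cfg = TransformerConfig(seed=7, pooling=pooling, max_epochs=3,
                                batch_size=32, n_layers=1, d_model=16,
                                n_heads=2, d_ff=32, dropout=0.0)
        m = fit_regressor(X, y, FEATURES, cfg)
        assert np.isfinite(m.predict(X)).all()

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(40, 6))
        y = X.sum(axis=1)
        m = fit_regressor(X, y, FEATURES, TransformerConfig(
            seed=8, max_epochs=3, **{k: v for k, v in self.QUICK.items()
                                     if k != "max_epochs"}))
        m.save(tmp_path / "model")
        again = RegressorModel.load(tmp_path / "model")
        np.testing.assert_array_equal(m.predict(X), again.predict(X))


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(d_model=30, n_heads=4), dict(dropout=1.0),
        dict(val_fraction=0.7), dict(pooling="cls")])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            TransformerConfig(**bad)
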