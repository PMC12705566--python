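"""Attention arithmetic, patching, encoder blocks and classifier training."""

import math

import numpy as np
import pytest

from eemstress.attention import (
    AttentionConfig,
    MHAWeights,
    ViTClassifier,
    attention_weights,
    encoder_block_forward,
    multi_head_attention,
    num_patches,
    patchify,
    scaled_dot_product_attention,
)
from eemstress.models import train_attention_classifier, train_baseline


class TestScaledDotProductAttention:
    def test_singleton_key_returns_value_row(self, rng):
        Q = rng.standard_normal((5, 3))
        K = rng.standard_normal((1, 3))
        V = rng.standard_normal((1, 4))
        out = scaled_dot_product_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V, (5, 1)))

    def test_zero_query_gives_uniform_weights(self, rng):
        K = rng.standard_normal((7, 3))
        V = rng.standard_normal((7, 2))
        out, W = scaled_dot_product_attention(np.zeros((1, 3)), K, V, return_weights=True)
        np.testing.assert_allclose(W, 1.0 / 7)
        np.testing.assert_allclose(out[0], V.mean(axis=0))

    def test_two_by_two_against_direct_formula(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.eye(2)
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = scaled_dot_product_attention(Q, K, V)
        # independent hand computation of softmax([[1,0],[0,1]]/sqrt(2)) @ V
        s = 1.0 / math.sqrt(2.0)
        e = math.exp(s)
        w_same = e / (e + 1.0)
        expected = np.array([[w_same, 1 - w_same], [1 - w_same, w_same]])
        np.testing.assert_allclose(out, expected @ V, rtol=1e-12)

    def test_rows_stochastic(self, rng):
        W = attention_weights(rng.standard_normal((9, 4)), rng.standard_normal((6, 4)))
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-6)
        assert (W >= 0).all()

    def test_temperature_monotone(self):
        # larger logit gap -> more peaked weights
        K = np.array([[1.0], [0.0]])
        V = np.eye(2)
        w_small = scaled_dot_product_attention(np.array([[1.0]]), K, V)[0, 0]
        w_large = scaled_dot_product_attention(np.array([[5.0]]), K, V)[0, 0]
        assert w_large > w_small > 0.5

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))
        with pytest.raises(ValueError, match="token"):
            scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((2, 3)), np.zeros((5, 4)))


class TestMultiHead:
    def test_single_head_identity_projection_reduces_to_sdpa(self, rng):
        x = rng.standard_normal((6, 4))
        out = multi_head_attention(x, MHAWeights.identity(4), n_heads=1)
        np.testing.assert_allclose(out, scaled_dot_product_attention(x, x, x))

    def test_output_shape_preserved(self, rng):
        x = rng.standard_normal((10, 8))
        w = MHAWeights.identity(8)
        for h in (1, 2, 4):
            assert multi_head_attention(x, w, h).shape == x.shape

    def test_permutation_equivariance(self, rng):
        x = rng.standard_normal((7, 8))
        w = MHAWeights(*[rng.standard_normal((8, 8)) for _ in range(4)], *[rng.standard_normal(8) for _ in range(4)])
        perm = rng.permutation(7)
        out = multi_head_attention(x, w, 2)
        out_p = multi_head_attention(x[perm], w, 2)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestPatchify:
    def test_default_grid_patch_count(self):
        cfg = AttentionConfig()
        x = np.zeros((67, 511))
        P = patchify(x, cfg)
        assert P.shape == (144, 8 * 32)  # ceil(67/8) * ceil(511/32) = 9 * 16
        assert num_patches((67, 511), cfg) == 144

    def test_1d_window_count(self):
        cfg = AttentionConfig()
        P = patchify(np.zeros(511), cfg)
        assert P.shape == (32, 16)  # ceil(511/16)
        assert num_patches((511,), cfg) == 32

    def test_zero_input_zero_patches(self, rng):
        cfg = AttentionConfig()
        assert not patchify(np.zeros((67, 511)), cfg).any()

    def test_patch_values_preserved(self, rng):
        cfg = AttentionConfig(patch_size_2d=(2, 3))
        x = rng.standard_normal((4, 6))
        P = patchify(x, cfg)
        np.testing.assert_array_equal(P[0], x[:2, :3].ravel())

    def test_short_feature_vector_single_token(self):
        cfg = AttentionConfig()
        assert patchify(np.arange(7.0), cfg).shape == (1, 7)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            patchify(np.zeros((3, 4)), AttentionConfig(patch_size_2d=(8, 32)))


class TestEncoderBlock:
    def params(self, d, m, rng):
        return {
            "ln1_g": np.ones(d), "ln1_b": np.zeros(d),
            "Wq": rng.standard_normal((d, d)) * 0.1, "Wk": rng.standard_normal((d, d)) * 0.1,
            "Wv": rng.standard_normal((d, d)) * 0.1, "Wo": rng.standard_normal((d, d)) * 0.1,
            "bq": np.zeros(d), "bk": np.zeros(d), "bv": np.zeros(d), "bo": np.zeros(d),
            "ln2_g": np.ones(d), "ln2_b": np.zeros(d),
            "W1": rng.standard_normal((d, m)) * 0.1, "b1": np.zeros(m),
            "W2": rng.standard_normal((m, d)) * 0.1, "b2": np.zeros(d),
        }

    def test_shape_preserved_and_composable(self, rng):
        p = self.params(8, 16, rng)
        x = rng.standard_normal((5, 8))
        y = encoder_block_forward(x, p, n_heads=2)
        assert y.shape == x.shape
        z = encoder_block_forward(y, p, n_heads=2)
        assert z.shape == x.shape

    def test_layernorm_normalizes_rows(self, rng):
        from eemstress.attention import _ln_forward

        x = rng.standard_normal((6, 8)) * 5 + 3
        out, _ = _ln_forward(x, np.ones(8), np.zeros(8))
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = AttentionConfig(
            embed_dim=8, n_heads=2, depth=1, mlp_hidden=12, dropout_rate=0.0,
            n_classes=3, seed=0,
        )
        net = ViTClassifier(patch_dim=5, n_patches=4, config=cfg)
        X = rng.standard_normal((3, 4, 5))
        y = np.array([0, 2, 1])
        _, grads = net.loss_and_grads(X, y)
        for key in ("We", "b0.Wq", "b0.W2", "Wh2", "cls", "pos", "b0.ln1_g"):
            p = net.params[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            p[idx] += eps
            lp, _ = net.loss_and_grads(X, y)
            p[idx] -= 2 * eps
            lm, _ = net.loss_and_grads(X, y)
            p[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7), key


class TestTraining:
    def test_linearly_separable_toy_reaches_100(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(3, 0.3, (20, 4))])
        y = np.array([0] * 20 + [1] * 20)
        cfg = AttentionConfig(epochs=50, early_stopping=False, seed=0)
        clf = train_attention_classifier(X, y, cfg, view="features")
        assert (clf.predict(X) == y).all()

    def test_determinism_and_bit_stable_inference(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 6)) + np.array([0, 1, 2] * 10)[:, None]
        y = np.array([0, 1, 2] * 10)
        cfg = AttentionConfig(epochs=15, early_stopping=False, seed=7)
        c1 = train_attention_classifier(X, y, cfg, view="features")
        c2 = train_attention_classifier(X, y, cfg, view="features")
        p1, p2 = c1.predict_proba(X), c2.predict_proba(X)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(p1, c1.predict_proba(X))  # repeated inference

    def test_probabilities_sum_to_one_and_loss_decreases(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (36, 5)) + np.repeat([0, 2, 4], 12)[:, None]
        y = np.repeat([0, 10, 100], 12)
        cfg = AttentionConfig(epochs=25, early_stopping=False, seed=3)
        clf = train_attention_classifier(X, y, cfg, view="features")
        P = clf.predict_proba(X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        sm = clf.smoothed_loss
        assert sm[-1] <= sm[0]
        assert list(clf.classes) == [0, 10, 100]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_attention_classifier(np.zeros((10, 3)), np.zeros(10), view="features")


class TestBaselines:
    def test_knn_k1_memorizes_training_set(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.integers(0, 3, 30)
        clf = train_baseline(X, y, "KNN", {"n_neighbors": 1})
        assert (clf.predict(X) == y).all()

    def test_rf_reproducible_and_probabilistic(self, rng):
        X = rng.standard_normal((40, 5)) + np.repeat([0, 2], 20)[:, None]
        y = np.repeat([0, 1], 20)
        c1 = train_baseline(X, y, "RF", seed=3)
        c2 = train_baseline(X, y, "RF", seed=3)
        np.testing.assert_array_equal(c1.predict_proba(X), c2.predict_proba(X))
        np.testing.assert_allclose(c1.predict_proba(X).sum(axis=1), 1.0)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError, match="baseline"):
            train_baseline(np.zeros((4, 2)), [0, 0, 1, 1], "SVM")
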