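import numpy as np
import pytest

from persal.autodiff import Tensor
from persal.interest import cosine_similarity
from persal.model import (
    FeatureTensor,
    PsmModel,
    PsmModelConfig,
    UserToken,
    UsmModel,
    cross_attend,
    describe_layers,
    load_checkpoint,
    save_checkpoint,
)
from persal.nn import MultiHeadAttention


def small_image(w=32, h=32, seed=0):
    return np.random.default_rng(seed).uniform(size=(h, w, 3))


class TestAutodiffGradients:
    """Finite-difference checks of the reverse-mode engine on the exact op
    set the models use."""

    def _check(self, params, fwd, tol=1e-5):
        loss = fwd()
        loss.backward()
        for name, p in params.items():
            idx = tuple(0 for _ in p.shape)
            g = p.grad[idx]
            eps = 1e-6
            p.data[idx] += eps
            lp = float(fwd().data)
            p.data[idx] -= 2 * eps
            lm = float(fwd().data)
            p.data[idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert abs(g - fd) < tol, f"{name}: analytic {g} vs numeric {fd}"

    def test_conv_pool_upsample_chain(self, rng):
        from persal.nn import Conv2d

        X = rng.normal(size=(2, 8, 8))
        T = rng.normal(size=(4, 4))
        r = np.random.default_rng(7)
        conv1, conv2 = Conv2d(2, 3, 3, 1, r), Conv2d(3, 1, 3, 1, r)

        def fwd():
            h = conv1(Tensor(X)).relu().maxpool2().upsample2()
            h = conv2(h).relu().maxpool2().reshape(4, 4)
            return (h - Tensor(T)).square().mean()

        self._check(
            {"w1": conv1.weight, "b1": conv1.bias, "w2": conv2.weight}, fwd
        )

    def test_transformer_decoder_block(self, rng):
        from persal.nn import TransformerDecoderBlock

        blk = TransformerDecoderBlock(8, 2, np.random.default_rng(3))
        X, ctx = rng.normal(size=(5, 8)), rng.normal(size=(1, 8))
        W = rng.normal(size=(5, 8))

        def fwd():
            return (blk(Tensor(X), Tensor(ctx)) - Tensor(W)).square().mean()

        names = ["self_attn.w_q.weight", "cross_attn.w_v.weight",
                 "ff.fc1.weight", "cross_attn.w_o.bias"]
        params = {k: blk.named_parameters()[k] for k in names}
        self._check(params, fwd)

    def test_softmax_rows_sum_to_one(self, rng):
        x = Tensor(rng.normal(size=(4, 7)))
        np.testing.assert_allclose(x.softmax(axis=-1).data.sum(axis=-1), 1.0)


class TestDimensionAlgebra:
    def test_feature_grid_is_input_over_16(self):
        cfg = PsmModelConfig(input_size=(64, 48), channel_scale=1 / 16,
                             M=8, enc_layers=1, dec_layers=1, heads=4, seed=0)
        ft = UsmModel(cfg).encode_image(small_image(64, 48))
        assert (ft.W, ft.H, ft.C) == (4, 3, cfg.C)

    def test_32x32_at_sixteenth_width_gives_2x2x32(self, tiny_cfg):
        ft = UsmModel(tiny_cfg).encode_image(small_image())
        assert (ft.W, ft.H, ft.C) == (2, 2, 32)

    def test_full_width_channel_count_is_512(self):
        cfg = PsmModelConfig(channel_scale=1.0, heads=256)
        assert cfg.C == 512
        assert cfg.d_k == 2

    def test_512_heads_make_dk_one(self):
        cfg = PsmModelConfig(channel_scale=1.0, heads=512)
        assert cfg.d_k == 1

    def test_indivisible_input_rejected_with_padding_hint(self):
        with pytest.raises(ValueError, match="pad"):
            PsmModelConfig(input_size=(30, 32))

    def test_heads_must_divide_channels(self):
        with pytest.raises(ValueError, match="divisible"):
            PsmModelConfig(channel_scale=1 / 16, heads=5)

    def test_matrix_view_roundtrip_row_major(self, rng):
        t = Tensor(rng.normal(size=(6, 3, 4)))
        ft = FeatureTensor(t)
        mat = ft.as_matrix()
        assert mat.shape == (12, 6)
        # row y*W + x carries pixel (x, y)
        np.testing.assert_array_equal(mat.data[1 * 4 + 2], t.data[:, 1, 2])
        back = FeatureTensor.from_matrix(mat, 3, 4)
        np.testing.assert_array_equal(back.tensor.data, t.data)


class TestEncoderDecoder:
    def test_zero_image_zero_biases_gives_zero_features(self, tiny_cfg):
        model = UsmModel(tiny_cfg)
        for p in model.named_parameters().values():
            if p.data.ndim == 1:
                p.data[:] = 0.0
        ft = model.encode_image(np.zeros((32, 32, 3)))
        np.testing.assert_array_equal(ft.tensor.data, 0.0)

    def test_decoder_output_nonnegative_and_16x_feature_dims(self, tiny_cfg, rng):
        model = UsmModel(tiny_cfg)
        ft = model.encode_image(small_image())
        out = model.decode_features(ft)
        assert out.shape == (32, 32)  # 16 x (2, 2)
        assert np.all(out.data >= 0)

    def test_zero_features_zero_biases_decode_to_zero(self, tiny_cfg):
        model = UsmModel(tiny_cfg)
        for p in model.named_parameters().values():
            if p.data.ndim == 1:
                p.data[:] = 0.0
        ft = FeatureTensor(Tensor(np.zeros((32, 2, 2))))
        out = model.decode_features(ft)
        np.testing.assert_array_equal(out.data, 0.0)


class TestUserEncoding:
    def test_full_scale_token_width_512_from_800(self):
        cfg = PsmModelConfig(channel_scale=1.0, M=800, enc_layers=4,
                             dec_layers=1, heads=256, seed=0)
        model = PsmModel(cfg)
        token = model.encode_user(np.zeros(800))
        assert token.tensor.shape == (1, 512)

    def test_length_mismatch_rejected(self, tiny_cfg):
        model = PsmModel(tiny_cfg)
        with pytest.raises(ValueError, match="length"):
            model.encode_user(np.zeros(tiny_cfg.M + 1))

    def test_single_token_self_attention_weight_is_one(self, rng):
        attn = MultiHeadAttention(8, 2, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 8)))
        q = attn.w_q(x).reshape(1, 2, 4).transpose(1, 0, 2)
        k = attn.w_k(x).reshape(1, 2, 4).transpose(1, 0, 2)
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / attn.scale)
        np.testing.assert_allclose(logits.softmax(axis=-1).data, 1.0)

    def test_determinism_and_input_sensitivity(self, tiny_cfg, rng):
        model = PsmModel(tiny_cfg)
        a = rng.integers(0, 2, tiny_cfg.M).astype(float)
        b = 1.0 - a
        t1 = model.encode_user(a).tensor.data
        t2 = model.encode_user(a).tensor.data
        t3 = model.encode_user(b).tensor.data
        np.testing.assert_array_equal(t1, t2)
        assert not np.allclose(t1, t3)

    def test_zero_encoder_layers_makes_emb_equal_enc(self):
        cfg = PsmModelConfig(input_size=(32, 32), channel_scale=1 / 16, M=12,
                             enc_layers=0, dec_layers=1, heads=4, seed=3)
        model = PsmModel(cfg)
        emb, enc = model.probe_user_characteristics(np.ones(12))
        np.testing.assert_array_equal(emb, enc)

    def test_probe_self_similarity_is_one(self, tiny_cfg, rng):
        model = PsmModel(tiny_cfg)
        v = rng.integers(0, 2, tiny_cfg.M).astype(float)
        emb, enc = model.probe_user_characteristics(v)
        assert cosine_similarity(emb, emb) == pytest.approx(1.0)
        assert cosine_similarity(enc, enc) == pytest.approx(1.0)

    def test_probe_similarity_matrix_symmetric_unit_diagonal(self, tiny_cfg, rng):
        model = PsmModel(tiny_cfg)
        vecs = [rng.integers(0, 2, tiny_cfg.M).astype(float) for _ in range(8)]
        encs = [model.probe_user_characteristics(v)[1].ravel() for v in vecs]
        n = len(encs)
        mat = np.array([[cosine_similarity(encs[i], encs[j]) for j in range(n)]
                        for i in range(n)])
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-12)


class TestCrossAttention:
    def test_single_key_output_is_broadcast_of_v(self, rng):
        C, heads = 16, 4
        attn = MultiHeadAttention(C, heads, np.random.default_rng(1))
        ft = FeatureTensor(Tensor(rng.normal(size=(C, 3, 5))))
        user = UserToken(Tensor(rng.normal(size=(1, C))))
        out = cross_attend(ft, user, attn).as_matrix().data
        # brute-force oracle: with one key, softmax weight is exactly 1 and
        # each row equals concat_h(V_h) @ W_o + b_o, independent of Q
        v = user.tensor.data @ attn.w_v.weight.data.T + attn.w_v.bias.data
        expected_row = v @ attn.w_o.weight.data.T + attn.w_o.bias.data
        np.testing.assert_allclose(out, np.repeat(expected_row, 15, axis=0),
                                   atol=1e-6)

    def test_both_logit_scales_agree_for_single_key(self, rng):
        C = 8
        a1 = MultiHeadAttention(C, 2, np.random.default_rng(5), "sqrt_dk")
        a2 = MultiHeadAttention(C, 2, np.random.default_rng(5), "dk")
        x, ctx = Tensor(rng.normal(size=(4, C))), Tensor(rng.normal(size=(1, C)))
        np.testing.assert_allclose(a1(x, ctx).data, a2(x, ctx).data, atol=1e-12)


class TestFullModel:
    def test_predict_psm_nonnegative_and_deterministic(self, tiny_cfg, rng):
        model = PsmModel(tiny_cfg)
        img = small_image()
        v = rng.integers(0, 2, tiny_cfg.M).astype(float)
        m1 = model.predict_psm(img, v)
        m2 = model.predict_psm(img, v)
        assert np.all(m1.values >= 0)
        assert m1.values.shape == (32, 32)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_identical_interest_identical_maps(self, tiny_cfg, rng):
        model = PsmModel(tiny_cfg)
        img = small_image()
        v = rng.integers(0, 2, tiny_cfg.M).astype(float)
        np.testing.assert_array_equal(
            model.predict_psm(img, v).values,
            model.predict_psm(img, v.copy()).values,
        )

    def test_tap_is_independent_of_interest(self, tiny_cfg):
        model = PsmModel(tiny_cfg)
        img = small_image()
        t1 = model.enc_output_tap(img)
        # the tap never touches the user mechanism, so mutating it is inert
        model.user_linear.weight.data[:] = 99.0
        t2 = model.enc_output_tap(img)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_gradients_reach_user_linear_and_image_encoder(self, tiny_cfg, rng):
        from persal.train import mse_loss

        model = PsmModel(tiny_cfg)
        v = rng.integers(0, 2, tiny_cfg.M).astype(float)
        loss = mse_loss(model.forward(small_image(), v),
                        rng.uniform(size=(32, 32)))
        loss.backward()
        named = model.named_parameters()
        assert np.abs(named["user_linear.weight"].grad).max() > 0
        assert np.abs(named["encoder.layers.0.weight"].grad).max() > 0

    def test_checkpoint_roundtrip(self, tiny_cfg, tmp_path, rng):
        model = PsmModel(tiny_cfg)
        img = small_image()
        v = rng.integers(0, 2, tiny_cfg.M).astype(float)
        p = tmp_path / "m.npz"
        save_checkpoint(model, p)
        back = load_checkpoint(p)
        np.testing.assert_array_equal(
            back.predict_psm(img, v).values, model.predict_psm(img, v).values
        )

    def test_describe_lists_13_convs_and_4_pools(self, tiny_cfg):
        text = describe_layers(UsmModel(tiny_cfg))
        assert text.count("MaxPool2D") == 4
        assert text.count("UpSample") == 4
        # 13 encoder convs + 13 decoder convs + 1x1 output head
        assert text.count("Conv2D") == 27
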