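import numpy as np
import pytest

import pancseg.autograd as ag
from pancseg.autograd import Tensor
from pancseg.network import (
    ChannelAttention,
    DenseBlock2D,
    HybridAttention,
    ModelConfig,
    SpatialAttention,
    build_model,
    channel_pool,
    count_parameters,
    load_model,
    predict_slice,
    save_model,
    zero_parameters,
)

SMALL = dict(in_size=(32, 32), n_blocks=3, base_channels=4, dense_layers=2, n3d_blocks=1)


class TestModelConfig:
    def test_defaults_valid(self):
        cfg = ModelConfig()
        assert cfg.in_size == (224, 224)
        assert cfg.n_blocks == 4 and cfg.n3d_blocks == 2

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(in_size=(100, 100), n_blocks=4)

    def test_n3d_bound(self):
        with pytest.raises(ValueError):
            ModelConfig(n3d_blocks=5, n_blocks=4)

    def test_attention_values(self):
        with pytest.raises(ValueError):
            ModelConfig(attention="dual")


class TestChannelPool:
    def test_small_example(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # (C=1, 2, 2)
        gap, gmp = channel_pool(x)
        assert gap[0] == pytest.approx(2.5)
        assert gmp[0] == pytest.approx(4.0)

    def test_constant_channel(self):
        x = np.full((3, 4, 4), 7.0)
        gap, gmp = channel_pool(x)
        np.testing.assert_allclose(gap, 7.0)
        np.testing.assert_allclose(gmp, 7.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(2, 5, 6, 7))
        gap, gmp = channel_pool(x)
        for n in range(2):
            for c in range(5):
                s, mx = 0.0, -np.inf
                for i in range(6):
                    for j in range(7):
                        s += x[n, c, i, j]
                        mx = max(mx, x[n, c, i, j])
                assert gap[n, c] == pytest.approx(s / 42)
                assert gmp[n, c] == pytest.approx(mx)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            channel_pool(np.zeros((3, 0, 4)))


class TestAttentionModules:
    @pytest.mark.parametrize("c,h,w", [(4, 16, 16), (8, 8, 12)])
    def test_zeroed_branches_are_half_gates(self, rng, c, h, w):
        """With zero weights the sigmoid emits 0.5, so each branch halves X
        and their sum restores X."""
        x = Tensor(rng.normal(size=(1, c, h, w)))
        y = Tensor(rng.normal(size=(1, 2 * c, h // 2, w // 2)))
        mrng = np.random.default_rng(0)
        sa = zero_parameters(SpatialAttention(c, mrng))
        ca = zero_parameters(ChannelAttention(c, mrng))
        hy = zero_parameters(HybridAttention(c, mrng))
        np.testing.assert_allclose(sa(x, y).data, 0.5 * x.data, atol=1e-6)
        np.testing.assert_allclose(ca(x, y).data, 0.5 * x.data, atol=1e-6)
        np.testing.assert_allclose(hy(x, y).data, x.data, atol=1e-6)

    def test_zero_input_gated_to_zero(self, rng):
        c = 4
        x = Tensor(np.zeros((1, c, 8, 8)))
        y = Tensor(rng.normal(size=(1, 2 * c, 4, 4)))
        mod = HybridAttention(c, np.random.default_rng(1))
        np.testing.assert_allclose(mod(x, y).data, 0.0, atol=1e-7)

    def test_output_shape_follows_x(self, rng):
        for c, h, w in [(2, 8, 8), (4, 16, 24), (8, 32, 32)]:
            x = Tensor(rng.normal(size=(2, c, h, w)))
            y = Tensor(rng.normal(size=(2, 2 * c, h // 2, w // 2)))
            out = HybridAttention(c, np.random.default_rng(0))(x, y)
            assert out.shape == x.shape

    def test_branches_are_gates(self, rng):
        """Each branch multiplies X by weights in (0, 1): elementwise
        magnitude never exceeds X's."""
        c = 4
        x = Tensor(rng.normal(size=(1, c, 8, 8)))
        y = Tensor(rng.normal(size=(1, 2 * c, 4, 4)))
        mrng = np.random.default_rng(2)
        for mod in (SpatialAttention(c, mrng), ChannelAttention(c, mrng)):
            out = mod(x, y)
            assert (np.abs(out.data) <= np.abs(x.data) + 1e-7).all()

    def test_shape_ratio_enforced(self, rng):
        mod = SpatialAttention(4, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        bad_y = Tensor(rng.normal(size=(1, 8, 8, 8)))
        with pytest.raises(ValueError, match="attention"):
            mod(x, bad_y)


class TestDenseBlock:
    def test_spatial_shape_preserved(self, rng):
        cfg = ModelConfig(**SMALL)
        blk = DenseBlock2D(8, 16, cfg, np.random.default_rng(0))
        out = blk(Tensor(rng.normal(size=(1, 8, 12, 14)).astype(np.float32)))
        assert out.shape == (1, 16, 12, 14)

    def test_zero_weights_zero_output(self, rng):
        cfg = ModelConfig(**{**SMALL, "norm": "none"})
        blk = zero_parameters(DenseBlock2D(4, 8, cfg, np.random.default_rng(0)))
        out = blk(Tensor(np.zeros((1, 4, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_receptive_field_spans_13(self):
        """Six stacked 3x3 convolutions reach at least 13x13: a far-away
        input perturbation reaches the centre output."""
        cfg = ModelConfig(in_size=(32, 32), n_blocks=3, base_channels=4,
                          dense_layers=6, n3d_blocks=1, norm="none")
        blk = DenseBlock2D(1, 4, cfg, np.random.default_rng(3))
        for p in blk.parameters():  # positive weights so ReLU cannot sever the path
            p.data[...] = np.abs(p.data)
        base = np.zeros((1, 1, 15, 15), dtype=np.float64)
        out0 = blk(Tensor(base)).data[0, :, 7, 7]
        bumped = base.copy()
        bumped[0, 0, 1, 1] = 10.0  # 6 pixels away from centre
        out1 = blk(Tensor(bumped)).data[0, :, 7, 7]
        assert np.abs(out1 - out0).max() > 0


class TestSegModel:
    def test_forward_shape_and_range(self, rng):
        m = build_model(ModelConfig(**SMALL), seed=0)
        x = rng.random((2, 3, 32, 32), dtype=np.float32)
        out = m.forward(x)
        assert out.shape == (2, 1, 32, 32)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_deterministic_eval(self, rng):
        m = build_model(ModelConfig(**SMALL), seed=0)
        x = rng.random((1, 3, 32, 32), dtype=np.float32)
        a = predict_slice(m, x, scale=1.0)
        b = predict_slice(m, x, scale=1.0)
        np.testing.assert_array_equal(a, b)

    def test_batched_equals_one_by_one(self, rng):
        m = build_model(ModelConfig(**SMALL), seed=0)
        x = rng.random((3, 3, 32, 32), dtype=np.float32)
        batched = predict_slice(m, x, scale=1.0)
        single = np.stack([predict_slice(m, x[i], scale=1.0) for i in range(3)])
        np.testing.assert_allclose(batched, single, atol=1e-5)

    def test_attention_none_builds_and_runs(self, rng):
        m = build_model(ModelConfig(**{**SMALL, "attention": "none"}), seed=0)
        out = m.forward(rng.random((1, 3, 32, 32), dtype=np.float32))
        assert out.shape == (1, 1, 32, 32)

    @pytest.mark.parametrize("kw", [{}, {"n3d_blocks": 2}, {"n_blocks": 2}])
    def test_shape_contract_across_configs(self, rng, kw):
        cfg = ModelConfig(**{**SMALL, **kw})
        m = build_model(cfg, seed=1)
        out = m.forward(rng.random((1, 3, 32, 32), dtype=np.float32))
        assert out.shape == (1, 1, 32, 32)

    def test_hybrid_has_more_parameters_than_plain(self):
        hybrid = build_model(ModelConfig(**SMALL), seed=0)
        plain = build_model(ModelConfig(**{**SMALL, "attention": "none"}), seed=0)
        assert count_parameters(hybrid) > count_parameters(plain)

    def test_wrong_input_size_rejected(self, rng):
        m = build_model(ModelConfig(**SMALL), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            m.forward(rng.random((1, 3, 16, 16), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path, rng):
        m = build_model(ModelConfig(**SMALL), seed=0)
        x = rng.random((1, 3, 32, 32), dtype=np.float32)
        before = predict_slice(m, x, scale=1.0)
        save_model(m, str(tmp_path / "ckpt"))
        m2 = load_model(str(tmp_path / "ckpt"))
        np.testing.assert_array_equal(predict_slice(m2, x, scale=1.0), before)
        assert m2.config == m.config
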