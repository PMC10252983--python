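"""Network primitives, attention blocks, architecture accounting."""

import numpy as np
import pytest

from oracles import additive_gate_loop, conv2d_loop, spatial_attention_loop
from skintex.nn import (AdditiveAttentionGate, AttentionGateSpec, BatchNorm2d,
                        Conv2d, ModelConfig, SpatialAttention, Tensor,
                        build_model, count_parameters, maxpool2x2, mse_loss,
                        upsample_bilinear2x, zero_pad_input)
from skintex.nn.unet import PROPOSED, REDUCED, REDUCED_ATTN, VANILLA


class TestZeroPad:
    def test_zero_is_identity(self):
        img = np.random.default_rng(0).random((5, 6, 3))
        assert zero_pad_input(img, 0) is not None
        assert np.array_equal(zero_pad_input(img, 0), img)

    def test_frame_of_zeros(self):
        out = zero_pad_input(np.ones((4, 4)), 2)
        assert out.shape == (6, 6)
        assert out[0].sum() == 0 and out[-1].sum() == 0
        assert out[:, 0].sum() == 0 and out[:, -1].sum() == 0
        assert np.array_equal(out[1:-1, 1:-1], np.ones((4, 4)))

    def test_mass_preserved(self):
        img = np.random.default_rng(1).random((8, 8, 3))
        assert zero_pad_input(img, 6).sum() == pytest.approx(img.sum())

    def test_odd_padding_rejected(self):
        with pytest.raises(ValueError):
            zero_pad_input(np.ones((4, 4)), 3)


class TestSpatialAttention:
    def test_zero_weights_halve_input(self):
        rng = np.random.default_rng(0)
        sa = SpatialAttention(rng)
        sa.conv.weight.data[:] = 0.0
        sa.conv.bias.data[:] = 0.0
        x = Tensor(rng.normal(0, 1, (1, 4, 8, 8)))
        out = sa(x)
        assert np.allclose(out.data, x.data / 2.0, atol=1e-12)

    def test_constant_input_gives_spatially_constant_output(self):
        rng = np.random.default_rng(1)
        sa = SpatialAttention(rng)
        x = Tensor(np.full((1, 3, 9, 9), 0.7, dtype=np.float64))
        att = sa.attention_map(x).data[0, 0]
        interior = att[3:-3, 3:-3]  # away from conv zero-padding effects
        assert np.ptp(interior) < 1e-9

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        sa = SpatialAttention(rng)
        sa.conv.weight.data = rng.normal(0, 0.4, sa.conv.weight.data.shape)
        sa.conv.bias.data = rng.normal(0, 0.4, sa.conv.bias.data.shape)
        x = rng.normal(0, 1, (1, 3, 8, 8))
        out = sa(Tensor(x)).data[0]
        expected = spatial_attention_loop(
            x[0], sa.conv.weight.data, sa.conv.bias.data
        )
        assert np.abs(out - expected).max() < 1e-5

    def test_gate_bounded(self):
        rng = np.random.default_rng(3)
        sa = SpatialAttention(rng)
        x = Tensor(rng.normal(0, 3, (2, 5, 8, 8)))
        att = sa.attention_map(x).data
        assert (att > 0).all() and (att < 1).all()


class TestAdditiveGate:
    def _gate(self, rng, enc_ch=2, dec_ch=2, inter=2):
        return AdditiveAttentionGate(enc_ch, dec_ch, AttentionGateSpec(inter), rng)

    def test_zero_weights_give_half_gate(self):
        rng = np.random.default_rng(0)
        g = self._gate(rng)
        for p in g.parameters():
            p.data[:] = 0.0
        enc = Tensor(rng.normal(0, 1, (1, 2, 4, 4)))
        q = Tensor(rng.normal(0, 1, (1, 2, 4, 4)))
        out = g(enc, q)
        assert np.allclose(out.data, enc.data / 2.0, atol=1e-12)

    def test_large_bias_saturates_gate(self):
        rng = np.random.default_rng(1)
        g = self._gate(rng)
        for p in g.parameters():
            p.data[:] = 0.0
        g.phi.bias.data[:] = 20.0        # b -> large
        g.psi.weight.data[:] = 1.0       # pass the pre-activation through
        enc = Tensor(rng.normal(0, 1, (1, 2, 4, 4)))
        q = Tensor(rng.normal(0, 1, (1, 2, 4, 4)))
        gate = g.gate_map(enc, q).data
        assert (gate > 0.9999).all()

    def test_matches_equation_loop_oracle(self):
        rng = np.random.default_rng(2)
        g = self._gate(rng, enc_ch=2, dec_ch=2, inter=3)
        for p in g.parameters():
            p.data = rng.normal(0, 0.7, p.data.shape)
        enc = rng.normal(0, 1, (1, 2, 4, 4))
        q = rng.normal(0, 1, (1, 2, 4, 4))
        gate = g.gate_map(Tensor(enc), Tensor(q)).data[0, 0]
        expected = additive_gate_loop(
            enc[0], q[0],
            g.theta.weight.data[:, :, 0, 0],
            g.phi.weight.data[:, :, 0, 0],
            g.phi.bias.data,
            g.psi.weight.data[0, :, 0, 0],
            float(g.psi.bias.data[0]),
        )
        assert np.abs(gate - expected).max() < 1e-5

    def test_gate_bounded(self):
        rng = np.random.default_rng(3)
        g = self._gate(rng, 4, 4, 2)
        gate = g.gate_map(Tensor(rng.normal(0, 2, (1, 4, 6, 6))),
                          Tensor(rng.normal(0, 2, (1, 4, 6, 6)))).data
        assert (gate > 0).all() and (gate < 1).all()


class TestGradients:
    """Analytic gradients vs central differences (float64)."""

    def _numcheck(self, run, params, rng, tol=1e-5):
        loss = run()
        loss.backward()
        grads = [p.grad.copy() for p in params]
        for p, ana in zip(params, grads):
            flat = p.data.ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size),
                                  replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = float(run().data)
                flat[idx] = orig - eps
                lm = float(run().data)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                a = ana.ravel()[idx]
                assert abs(num - a) <= tol * max(1.0, abs(num), abs(a))

    def test_conv_bn_pool_upsample_gate_chain(self):
        rng = np.random.default_rng(7)
        conv = Conv2d(2, 3, 3, rng, bias=True, dtype=np.float64)
        bn = BatchNorm2d(3)
        bn.weight.data = bn.weight.data.astype(np.float64) + 0.2
        bn.bias.data = bn.bias.data.astype(np.float64)
        gate = AdditiveAttentionGate(3, 3, AttentionGateSpec(2), rng)
        for p in gate.parameters():
            p.data = rng.normal(0, 0.5, p.data.shape)
        sa = SpatialAttention(rng)
        sa.conv.weight.data = rng.normal(0, 0.3, sa.conv.weight.data.shape)
        sa.conv.bias.data = rng.normal(0, 0.3, sa.conv.bias.data.shape)
        x = rng.normal(0, 1, (2, 2, 8, 8))
        target = rng.normal(0, 1, (2, 3, 8, 8))

        def run():
            y = bn(conv(Tensor(x))).relu()
            y = sa(y)
            q = upsample_bilinear2x(maxpool2x2(y))
            return mse_loss(gate(y, q), target)

        params = (list(conv.parameters()) + list(bn.parameters())
                  + list(gate.parameters()) + list(sa.parameters()))
        self._numcheck(run, params, rng)


class TestArchitecture:
    def test_unit_parameter_counts(self):
        rng = np.random.default_rng(0)
        assert count_parameters(Conv2d(1, 1, 3, rng, bias=True)) == 10
        assert count_parameters(BatchNorm2d(16)) == 32

    def test_quarter_scaling(self):
        full = count_parameters(build_model(VANILLA))
        half = count_parameters(build_model(REDUCED))
        assert 3.9 <= full / half <= 4.1

    def test_attention_overhead_near_reference(self):
        extra = count_parameters(build_model(REDUCED_ATTN)) - count_parameters(
            build_model(REDUCED)
        )
        assert abs(extra - 0.9e6) < 0.15e6

    def test_padding_is_weight_neutral(self):
        a = build_model(REDUCED_ATTN, seed=5).state_dict()
        b = build_model(PROPOSED, seed=5).state_dict()
        assert a.keys() == b.keys()
        for k in a:
            assert np.array_equal(a[k], b[k])

    @pytest.mark.parametrize("hw,z", [(32, 0), (32, 8), (24, 8)])
    def test_shape_contract(self, hw, z):
        cfg = ModelConfig(depth=3, base_channels=4, pad_Z=z,
                          use_spatial_attention=True,
                          use_additive_attention=True)
        model = build_model(cfg, seed=0)
        x = Tensor(np.zeros((1, 3, hw + z, hw + z), dtype=np.float32))
        out = model(x)
        assert out.shape == (1, 2, hw + z, hw + z)

    def test_indivisible_input_raises(self):
        model = build_model(ModelConfig(depth=3, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model(Tensor(np.zeros((1, 3, 30, 30), dtype=np.float32)))

    def test_forward_determinism(self):
        cfg = ModelConfig(depth=2, base_channels=4)
        x = np.random.default_rng(0).random((1, 3, 16, 16)).astype(np.float32)
        a = build_model(cfg, seed=3)(Tensor(x)).data
        b = build_model(cfg, seed=3)(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_transposed_conv_variant_runs(self):
        cfg = ModelConfig(depth=3, base_channels=4,
                          upsample_mode="transposed_conv")
        model = build_model(cfg, seed=0)
        out = model(Tensor(np.zeros((1, 3, 16, 16), dtype=np.float32)))
        assert out.shape == (1, 2, 16, 16)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(pad_Z=3)
        with pytest.raises(ValueError):
            ModelConfig(depth=1)
        with pytest.raises(ValueError):
            ModelConfig(upsample_mode="nearest")
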