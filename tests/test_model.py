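"""Architecture contracts: shapes, attention gating, determinism.

The attention gate's multiplicative core is pinned by an exhaustive
element-wise oracle (scalar loops, including a hand-written bilinear
upsampler); the full network is checked against an independent
parameter-count walker and, with gates forced to identity, against a
manually composed plain-UNet forward pass.
"""

import numpy as np
import pytest

import sporeseg.autograd as ag
from sporeseg.autograd import Tensor
from sporeseg.io_annotation import GrayImage
from sporeseg.model import (
    DoubleConv,
    ModelConfig,
    SpatialAttentionGate,
    SporeUNet,
    build_model,
    load_model,
    predict_mask,
    save_model,
)


from oracles import bilinear_up2x_scalar as _bilinear_up2x_scalar


class TestDoubleConv:
    @pytest.mark.parametrize("in_ch,out_ch,size", [(1, 8, 16), (8, 16, 8)])
    def test_spatial_size_preserved_channels_set(self, in_ch, out_ch, size, rng):
        block = DoubleConv(in_ch, out_ch, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, in_ch, size, size)).astype(np.float32))
        out = block(x)
        assert out.shape == (2, out_ch, size, size)

    def test_deterministic_given_weights(self, rng):
        block = DoubleConv(2, 4, np.random.default_rng(0))
        block.eval()
        x = Tensor(rng.standard_normal((1, 2, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, block(x).data)


class TestAttentionGate:
    def _gate(self, c_x=2, c_g=3, c_int=2, seed=0, dtype=np.float64):
        return SpatialAttentionGate(c_x, c_g, c_int, np.random.default_rng(seed),
                                    dtype=dtype)

    def test_output_shape_matches_skip_and_psi_in_unit_interval(self, rng):
        gate = self._gate(c_x=4, c_g=6, c_int=2)
        x = Tensor(rng.standard_normal((2, 4, 16, 16)))
        g = Tensor(rng.standard_normal((2, 6, 8, 8)))
        out = gate(x, g)
        assert out.shape == x.shape  # drop-in on the skip path
        assert gate.last_psi.shape == (2, 1, 8, 8)
        assert (gate.last_psi > 0).all() and (gate.last_psi < 1).all()

    def test_gated_product_matches_elementwise_loop_oracle(self):
        # 100 random weight draws on a 4x4x2 toy tensor
        for seed in range(100):
            rng = np.random.default_rng(seed)
            gate = self._gate(seed=seed)
            x = rng.standard_normal((1, 2, 4, 4))
            g = rng.standard_normal((1, 3, 2, 2))
            gate(Tensor(x), Tensor(g))
            psi = gate.last_psi[0, 0]
            assert ((psi > 0) & (psi < 1)).all()
            psi_up = _bilinear_up2x_scalar(psi)
            for c in range(2):
                for i in range(4):
                    for j in range(4):
                        expected = x[0, c, i, j] * psi_up[i, j]
                        assert abs(gate.last_gated[0, c, i, j] - expected) < 1e-10

    def test_forcing_psi_to_zero_zeroes_gated_product(self, rng):
        gate = self._gate()
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = -40.0  # sigmoid(-40) ~ 4e-18
        x = Tensor(rng.standard_normal((1, 2, 4, 4)))
        g = Tensor(rng.standard_normal((1, 3, 2, 2)))
        gate(x, g)
        assert np.abs(gate.last_gated).max() < 1e-15

    def test_spatial_mismatch_rejected(self, rng):
        gate = self._gate()
        x = Tensor(rng.standard_normal((1, 2, 4, 4)))
        g_bad = Tensor(rng.standard_normal((1, 3, 3, 3)))
        with pytest.raises(ValueError, match="gating"):
            gate(x, g_bad)


def _expected_param_count(cfg: ModelConfig) -> int:
    """Walk the architecture shapes independently of the implementation."""

    def double_conv(cin, cout):
        return (9 * cin * cout + cout + 2 * cout) + (9 * cout * cout + cout + 2 * cout)

    def channel_attn(c):
        mid = max(c // 8, 1)
        return (c * mid + mid) + (mid * c + c)

    def gate(c_x, c_g, c_int):
        theta = 4 * c_x * c_int + c_int
        phi = c_g * c_int + c_int
        psi = c_int + 1
        out_conv = c_x * c_x + c_x
        bn = 2 * c_x
        return theta + phi + psi + out_conv + bn

    d, b = cfg.depth, cfg.base_channels
    enc = [b * 2**i for i in range(d)]
    bott = b * 2**d
    total = 0
    cin = 1
    for c in enc:
        total += double_conv(cin, c)
        cin = c
    total += double_conv(enc[-1], bott)
    if cfg.channel_attention:
        total += sum(channel_attn(c) for c in enc)
    if cfg.spatial_attention:
        for i, c in enumerate(enc):
            c_g = enc[i + 1] if i + 1 < d else bott
            total += gate(c, c_g, max(int(c * cfg.inter_channels_ratio), 1))
    deeper = bott
    for c in reversed(enc):
        total += double_conv(deeper + c, c)
        deeper = c
    total += enc[0] * cfg.output_channels + cfg.output_channels
    return total


class TestSporeUNet:
    CFG = ModelConfig(depth=3, base_channels=8, input_size=(32, 32))

    def test_output_shape_matches_input(self, rng):
        net = SporeUNet(self.CFG, seed=0)
        x = Tensor(rng.standard_normal((2, 1, 32, 32)).astype(np.float32))
        assert net(x).shape == (2, 1, 32, 32)

    def test_zero_input_gives_finite_output(self):
        net = SporeUNet(self.CFG, seed=0)
        out = net(Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32)))
        assert np.isfinite(out.data).all()

    @pytest.mark.parametrize(
        "cfg",
        [
            ModelConfig(depth=2, base_channels=4, input_size=(16, 16)),
            ModelConfig(depth=3, base_channels=8, input_size=(32, 32)),
            ModelConfig(depth=4, base_channels=64, input_size=(256, 256)),
            ModelConfig(depth=3, base_channels=8, input_size=(32, 32),
                        channel_attention=False),
            ModelConfig(depth=3, base_channels=8, input_size=(32, 32),
                        spatial_attention=False, channel_attention=False),
        ],
    )
    def test_parameter_count_matches_shape_walker(self, cfg):
        net = SporeUNet(cfg, seed=0)
        assert sum(p.data.size for p in net.parameters()) == _expected_param_count(cfg)

    def test_seeded_construction_and_forward_reproducible(self, rng):
        a = SporeUNet(self.CFG, seed=9)
        b = SporeUNet(self.CFG, seed=9)
        x = Tensor(rng.standard_normal((1, 1, 32, 32)).astype(np.float32))
        np.testing.assert_array_equal(a(x).data, b(x).data)

    def test_identity_gates_reduce_to_plain_unet_composition(self, rng):
        """With attention bypassed, forward equals a hand-composed plain
        UNet built from the model's own conv blocks."""
        net = SporeUNet(self.CFG, seed=3).eval()
        for gate in net.gates:
            gate.force_identity = True
        for ca in net.channel_attns:
            ca.force_identity = True
        x = Tensor(rng.standard_normal((1, 1, 32, 32)).astype(np.float32))
        got = net(x).data

        h = x
        skips = []
        for enc in net.encoders:
            h = enc(h)
            skips.append(h)
            h = ag.max_pool2x2(h)
        h = net.bottleneck(h)
        for level in range(net.config.depth - 1, -1, -1):
            h = ag.upsample_bilinear2x(h)
            h = ag.concat_channels([skips[level], h])
            h = net.decoders[net.config.depth - 1 - level](h)
        expected = net.head(h).data
        np.testing.assert_array_equal(got, expected)

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(depth=4, base_channels=8, input_size=(100, 100))


class TestPredictMask:
    NET = None

    @classmethod
    def _net(cls):
        if cls.NET is None:
            cls.NET = SporeUNet(
                ModelConfig(depth=3, base_channels=4, input_size=(64, 64)), seed=0
            )
        return cls.NET

    def test_exact_input_size(self, rng):
        mask = predict_mask(self._net(), GrayImage(rng.standard_normal((64, 64))))
        assert mask.shape == (64, 64)

    def test_large_frame_tiled_back_to_original_size(self, rng):
        mask = predict_mask(self._net(), GrayImage(rng.standard_normal((150, 200))))
        assert mask.shape == (150, 200)

    def test_non_multiple_size_padded_and_cropped(self, rng):
        mask = predict_mask(self._net(), GrayImage(rng.standard_normal((50, 37))))
        assert mask.shape == (50, 37)

    def test_threshold_one_gives_all_background(self, rng):
        mask = predict_mask(
            self._net(), GrayImage(rng.standard_normal((64, 64))), threshold=1.0
        )
        assert not mask.pixels.any()


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = ModelConfig(depth=2, base_channels=4, input_size=(16, 16))
    net = build_model(cfg, seed=4)
    x = Tensor(rng.standard_normal((1, 1, 16, 16)).astype(np.float32))
    net.eval()
    before = net(x).data
    save_model(net, tmp_path / "ckpt.npz")
    restored = load_model(tmp_path / "ckpt.npz").eval()
    np.testing.assert_array_equal(before, restored(x).data)
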