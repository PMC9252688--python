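"""Network blocks against naive loop-based oracles, plus model contracts."""

import numpy as np
import pytest

from echoseg.autograd import Tensor
from echoseg.errors import ConfigError
from echoseg.network import (
    RSCAB,
    SCAB,
    ArchConfig,
    AttentionUNet,
    ChannelAttention,
    ResidualBlock,
    SpatialAttention,
    build_model,
    load_checkpoint,
    predict_probs,
    save_checkpoint,
)

from _reference import (
    ref_bn_eval,
    ref_channel_gate,
    ref_conv2d,
    ref_sigmoid,
    ref_spatial_gate,
)

BIG_BIAS = 500.0  # sigmoid(500) == 1.0 exactly in float64


def _randomize(module, rng, scale=0.5):
    for _, p in module.named_parameters():
        p.data = rng.standard_normal(p.data.shape) * scale


class TestResidualBlock:
    def test_zero_branch_identity(self, rng):
        # residual branch weights all zero + identity skip -> u = v exactly
        block = ResidualBlock(3, 3, kernel_size=3)
        v = rng.standard_normal((2, 3, 5, 5))
        out = block(Tensor(v))
        np.testing.assert_array_equal(out.data, v)

    def test_projection_present_iff_channels_differ(self):
        assert ResidualBlock(2, 4).project is not None
        assert ResidualBlock(4, 4).project is None
        assert ResidualBlock(4, 4, force_projection=True).project is not None

    def test_matches_loop_oracle(self, rng):
        block = ResidualBlock(1, 2, kernel_size=3).eval()
        _randomize(block, rng)
        for bn in (block.bn1, block.bn2):
            bn.running_mean = rng.standard_normal(bn.running_mean.shape) * 0.1
            bn.running_var = rng.uniform(0.5, 1.5, bn.running_var.shape)
        v = rng.standard_normal((1, 1, 4, 4))

        out = block(Tensor(v)).data

        c = ref_conv2d(v, block.conv1.weight.data)
        c = np.maximum(ref_bn_eval(c, block.bn1.weight.data, block.bn1.bias.data,
                                   block.bn1.running_mean, block.bn1.running_var), 0)
        c = ref_conv2d(c, block.conv2.weight.data)
        c = np.maximum(ref_bn_eval(c, block.bn2.weight.data, block.bn2.bias.data,
                                   block.bn2.running_mean, block.bn2.running_var), 0)
        expected = c + ref_conv2d(v, block.project.weight.data)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_identity_jacobian_with_zero_branch(self, rng):
        # with c = 0 the input-output Jacobian is the identity: du/dv = 1
        block = ResidualBlock(2, 2, kernel_size=3)
        v0 = rng.standard_normal((1, 2, 3, 3))
        eps = 1e-6
        base = block(Tensor(v0)).data
        for idx in [(0, 0, 0, 0), (0, 1, 2, 1), (0, 0, 1, 2)]:
            vp = v0.copy()
            vp[idx] += eps
            jac_col = (block(Tensor(vp)).data - base) / eps
            expected = np.zeros_like(v0)
            expected[idx] = 1.0
            np.testing.assert_allclose(jac_col, expected, atol=1e-6)

    @pytest.mark.parametrize("kernel", [2, 3, 6])
    def test_shape_preserved_for_even_and_odd_kernels(self, rng, kernel):
        block = ResidualBlock(2, 3, kernel_size=kernel)
        _randomize(block, rng)
        out = block(Tensor(rng.standard_normal((1, 2, 8, 8))))
        assert out.shape == (1, 3, 8, 8)

    def test_channel_mismatch_raises(self, rng):
        block = ResidualBlock(3, 3)
        with pytest.raises(ValueError, match="channel"):
            block(Tensor(rng.standard_normal((1, 2, 4, 4))))


class TestSpatialAttention:
    def test_gate_in_unit_interval(self, rng):
        att = SpatialAttention()
        _randomize(att, rng, scale=2.0)
        g = att.gate(Tensor(rng.standard_normal((2, 3, 6, 6)) * 10)).data
        assert g.min() >= 0.0 and g.max() <= 1.0
        assert g.shape == (2, 1, 6, 6)

    def test_identity_gate_passes_input(self, rng):
        att = SpatialAttention()
        att.conv.bias.data = np.array([BIG_BIAS])
        b = rng.standard_normal((1, 4, 5, 5))
        np.testing.assert_array_equal(att(Tensor(b)).data, b)

    def test_matches_oracle(self, rng):
        att = SpatialAttention(kernel_size=3)
        _randomize(att, rng)
        b = rng.standard_normal((2, 3, 4, 4))
        out = att(Tensor(b)).data
        gate = ref_spatial_gate(b, att.conv.weight.data, att.conv.bias.data)
        np.testing.assert_allclose(out, b * gate, atol=1e-6)

    def test_high_magnitude_region_gets_higher_gate(self, rng):
        att = SpatialAttention(kernel_size=3)
        # positive-bias construction: all-positive conv weights on the max/mean
        # maps, so larger activations can only raise the pre-sigmoid score
        att.conv.weight.data = np.full_like(att.conv.weight.data, 0.3)
        b = np.zeros((1, 2, 8, 8))
        b[0, :, 2:4, 2:4] = 5.0
        g = att.gate(Tensor(b)).data[0, 0]
        assert g[2, 2] >= g[6, 6]


class TestChannelAttention:
    def test_identical_channels_equal_gates(self, rng):
        # channel-permutation symmetry: with channel-symmetric MLP weights,
        # identical channels must receive identical gate values
        att = ChannelAttention(4, reduction=2)
        att.fc1.weight.data = np.full_like(att.fc1.weight.data, 0.3)
        att.fc1.bias.data = np.full_like(att.fc1.bias.data, 0.1)
        att.fc2.weight.data = np.full_like(att.fc2.weight.data, -0.2)
        att.fc2.bias.data = np.full_like(att.fc2.bias.data, 0.05)
        plane = rng.standard_normal((1, 1, 5, 5))
        b = np.repeat(plane, 4, axis=1)
        g = att.gate(Tensor(b)).data[0, :, 0, 0]
        np.testing.assert_allclose(g, g[0])

    def test_identity_gate_passes_input(self, rng):
        att = ChannelAttention(4, reduction=2)
        att.fc2.bias.data = np.full(4, BIG_BIAS / 2)  # summed over two paths
        b = rng.standard_normal((2, 4, 3, 3))
        np.testing.assert_array_equal(att(Tensor(b)).data, b)

    def test_matches_hand_computed_bottleneck(self, rng):
        att = ChannelAttention(2, reduction=2)
        _randomize(att, rng)
        b = rng.standard_normal((2, 2, 4, 4))
        gate = att.gate(Tensor(b)).data
        expected = ref_channel_gate(
            b, att.fc1.weight.data, att.fc1.bias.data,
            att.fc2.weight.data, att.fc2.bias.data,
        )
        np.testing.assert_allclose(gate, expected, atol=1e-6)

    def test_gate_range(self, rng):
        att = ChannelAttention(8, reduction=4)
        _randomize(att, rng, scale=3.0)
        g = att.gate(Tensor(rng.standard_normal((2, 8, 4, 4)) * 20)).data
        assert g.min() >= 0.0 and g.max() <= 1.0

    def test_too_aggressive_reduction_rejected(self):
        with pytest.raises(ConfigError, match="hidden"):
            ChannelAttention(2, reduction=4)


class TestSCAB:
    def test_output_shape_equals_input(self, rng):
        scab = SCAB(4, spatial_kernel=3, reduction=2)
        _randomize(scab, rng)
        b = rng.standard_normal((2, 4, 6, 6))
        assert scab(Tensor(b)).shape == b.shape

    def test_identity_configuration(self, rng):
        # both gates forced to one; projection averages the two copies
        scab = SCAB(3, spatial_kernel=3, reduction=3)
        scab.spatial.conv.bias.data = np.array([BIG_BIAS])
        scab.channel.fc2.bias.data = np.full(3, BIG_BIAS / 2)
        w = np.zeros((3, 6, 1, 1))
        for c in range(3):
            w[c, c, 0, 0] = 0.5
            w[c, c + 3, 0, 0] = 0.5
        scab.project.weight.data = w
        b = rng.standard_normal((1, 3, 5, 5))
        np.testing.assert_allclose(scab(Tensor(b)).data, b, atol=1e-12)

    def test_matches_composed_oracle(self, rng):
        scab = SCAB(2, spatial_kernel=3, reduction=2)
        _randomize(scab, rng)
        b = rng.standard_normal((1, 2, 3, 3))
        out = scab(Tensor(b)).data

        s_gate = ref_spatial_gate(b, scab.spatial.conv.weight.data,
                                  scab.spatial.conv.bias.data)
        c_gate = ref_channel_gate(
            b, scab.channel.fc1.weight.data, scab.channel.fc1.bias.data,
            scab.channel.fc2.weight.data, scab.channel.fc2.bias.data,
        )
        cat = np.concatenate([b * s_gate, b * c_gate], axis=1)
        expected = ref_conv2d(cat, scab.project.weight.data,
                              scab.project.bias.data)
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestRSCAB:
    def test_output_shape_contract(self, rng):
        block = RSCAB(2, 4, spatial_kernel=3, reduction=2)
        _randomize(block, rng)
        d = rng.standard_normal((2, 2, 6, 6))
        assert block(Tensor(d)).shape == (2, 4, 6, 6)

    def test_degenerate_gates_reduce_to_residual_concat(self, rng):
        # gates to one, 1x1 convs to identity-preserving weights: the block
        # returns 0.5*(d_att + d) = d when d_att = d
        block = RSCAB(3, 3, spatial_kernel=3, reduction=3)
        eye = np.eye(3)[:, :, None, None]
        block.raise_conv.weight.data = eye.copy()
        block.scab.spatial.conv.bias.data = np.array([BIG_BIAS])
        block.scab.channel.fc2.bias.data = np.full(3, BIG_BIAS / 2)
        w = np.zeros((3, 6, 1, 1))
        for c in range(3):
            w[c, c, 0, 0] = 0.5
            w[c, c + 3, 0, 0] = 0.5
        block.scab.project.weight.data = w
        fuse = np.zeros((3, 6, 1, 1))
        for c in range(3):
            fuse[c, c, 0, 0] = 0.5
            fuse[c, c + 3, 0, 0] = 0.5
        block.fuse_conv.weight.data = fuse
        d = rng.standard_normal((1, 3, 4, 4))
        np.testing.assert_allclose(block(Tensor(d)).data, d, atol=1e-12)

    def test_matches_composed_oracle(self, rng):
        block = RSCAB(2, 3, spatial_kernel=3, reduction=3)
        _randomize(block, rng)
        d = rng.standard_normal((1, 2, 3, 3))
        out = block(Tensor(d)).data

        raised = ref_conv2d(d, block.raise_conv.weight.data,
                            block.raise_conv.bias.data)
        scab = block.scab
        s_gate = ref_spatial_gate(raised, scab.spatial.conv.weight.data,
                                  scab.spatial.conv.bias.data)
        c_gate = ref_channel_gate(
            raised, scab.channel.fc1.weight.data, scab.channel.fc1.bias.data,
            scab.channel.fc2.weight.data, scab.channel.fc2.bias.data,
        )
        cat = np.concatenate([raised * s_gate, raised * c_gate], axis=1)
        d_att = ref_conv2d(cat, scab.project.weight.data, scab.project.bias.data)
        fused = np.concatenate([d_att, d], axis=1)
        expected = ref_conv2d(fused, block.fuse_conv.weight.data,
                              block.fuse_conv.bias.data)
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestModel:
    def test_forward_contract(self):
        model = build_model(ArchConfig(depth=3, base_channels=4), seed=0)
        out = predict_probs(model, np.random.default_rng(0).uniform(0, 1, (64, 64)))
        assert out.shape == (1, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    @pytest.mark.parametrize("attention", ["scab", "rscab", "none"])
    def test_shape_preserved_across_attention_modes(self, attention):
        arch = ArchConfig(depth=2, base_channels=4, attention=attention,
                          input_size=(16, 16))
        model = build_model(arch, seed=1)
        out = predict_probs(model, np.random.default_rng(1).uniform(0, 1, (16, 16)))
        assert out.shape == (1, 16, 16)

    def test_parameter_count_closed_form(self):
        # depth 2, base 4, kernel 3, attention on the single skip:
        # enumerate every layer's weight shapes independently
        arch = ArchConfig(depth=2, base_channels=4, kernel_size=3,
                          input_size=(16, 16))
        model = build_model(arch, seed=0)

        def conv(cin, cout, k, bias=True):
            return cout * cin * k * k + (cout if bias else 0)

        def bn(c):
            return 2 * c

        enc0 = conv(1, 4, 3, bias=False) + bn(4) + conv(4, 4, 3, bias=False) \
            + bn(4) + conv(1, 4, 1, bias=False)
        enc1 = conv(4, 8, 3, bias=False) + bn(8) + conv(8, 8, 3, bias=False) \
            + bn(8) + conv(4, 8, 1, bias=False)
        up = conv(8, 4, 3, bias=False) + bn(4)
        scab = conv(2, 1, 7) + conv(4, 1, 1) + conv(1, 4, 1) + conv(8, 4, 1)
        dec = conv(8, 4, 3, bias=False) + bn(4) + conv(4, 4, 3, bias=False) \
            + bn(4) + conv(8, 4, 1, bias=False)
        head = conv(4, 1, 1)
        assert model.num_parameters() == enc0 + enc1 + up + scab + dec + head

    def test_forward_deterministic(self):
        model = build_model(ArchConfig(depth=2, base_channels=4,
                                       input_size=(16, 16)), seed=2)
        x = np.random.default_rng(3).uniform(0, 1, (16, 16))
        a = predict_probs(model, x)
        b = predict_probs(model, x)
        np.testing.assert_array_equal(a, b)

    def test_indivisible_input_rejected(self):
        model = build_model(ArchConfig(depth=3, base_channels=4), seed=0)
        with pytest.raises(ConfigError, match="divisible"):
            model(Tensor(np.zeros((1, 1, 30, 30))))

    def test_arch_validation(self):
        with pytest.raises(ConfigError, match="divisible"):
            ArchConfig(depth=4, input_size=(20, 20))
        with pytest.raises(ConfigError, match="attention"):
            ArchConfig(attention="cbam")

    def test_checkpoint_roundtrip(self, tmp_path):
        arch = ArchConfig(depth=2, base_channels=4, input_size=(16, 16))
        model = build_model(arch, seed=4)
        x = np.random.default_rng(5).uniform(0, 1, (16, 16))
        before = predict_probs(model, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.arch == arch
        np.testing.assert_array_equal(predict_probs(restored, x), before)
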