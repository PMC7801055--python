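"""Architecture tests: MSFF splitting, CCA fusion, initialization, shapes."""

import numpy as np
import pytest

from ffunet import (CCA, FFUNet, LossConfig, MSFF, ModelConfig,
                    architecture_summary, balanced_focal_loss, build_model,
                    count_parameters, msff_channel_plan)
from ffunet.errors import ConfigurationError, ShapeError
from ffunet.model import DownsampleConv
from ffunet.nn import Conv2d, Tensor


class TestDownsample:
    def test_halves_spatial_and_sets_channels(self, rng):
        cfg = ModelConfig()
        d = DownsampleConv(16, 32, cfg, rng)
        out = d(Tensor(rng.normal(size=(1, 16, 64, 64))))
        assert out.data.shape == (1, 32, 32, 32)

    def test_depth4_encoder_reaches_16x16_from_256(self):
        # 256 / 2^4 = 16: four stride-2 stages
        size = 256
        for _ in range(4):
            size //= 2
        assert size == 16

    def test_all_zero_input_biasless_gives_zero(self, rng):
        conv = Conv2d(4, 8, 3, stride=2, bias=False, rng=rng)
        out = conv(Tensor(np.zeros((1, 4, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_odd_spatial_size_rejected(self, rng):
        d = DownsampleConv(4, 8, ModelConfig(), rng)
        with pytest.raises(ShapeError):
            d(Tensor(np.zeros((1, 4, 7, 8))))


class TestMSFF:
    def test_channel_plan_c27(self):
        retained, final = msff_channel_plan(27)
        assert retained == [9, 6, 4] and final == 8
        assert sum(retained) + final == 27  # exact conservation

    @pytest.mark.parametrize("c", [9, 16, 27, 48, 81])
    def test_channel_conservation_identity(self, c):
        retained, final = msff_channel_plan(c)
        assert sum(retained) + final == c

    def test_block_conv_widths_follow_plan(self, rng):
        blk = MSFF(27, 32, ModelConfig(), rng)
        assert blk.retained_widths == [9, 6, 4]
        assert blk.final_pass_width == 8
        assert [k.conv.out_channels for k in blk.keep_convs] == [9, 6, 4]
        assert [p.conv.out_channels for p in blk.pass_convs] == [18, 12, 8]

    def test_output_shape_contract(self, rng):
        blk = MSFF(27, 32, ModelConfig(), rng)
        blk.eval()
        out = blk(Tensor(rng.normal(size=(1, 27, 32, 32))))
        assert out.data.shape == (1, 32, 32, 32)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            MSFF(8, 16, ModelConfig(), rng)

    def test_receptive_field_exceeds_plain_3x3(self, rng):
        """Backprop footprint probe: injecting a gradient at the centre
        output pixel reaches input pixels farther than 1 step away."""
        blk = MSFF(9, 9, ModelConfig(), rng)
        blk.eval()
        x = Tensor(rng.normal(size=(1, 9, 17, 17)), requires_grad=True)
        out = blk(x)
        g = np.zeros_like(out.data)
        g[0, :, 8, 8] = 1.0
        out.backward(g)
        footprint = np.abs(x.grad).sum(axis=(0, 1)) > 0
        rows = np.where(footprint.any(axis=1))[0]
        # plain 3x3 conv reaches rows 7..9 only
        assert rows.min() < 7 and rows.max() > 9


class TestCCA:
    def test_squeeze_and_output_channel_arithmetic(self, rng):
        cca = CCA(ld_channels=64, skip_channels=32, cfg=ModelConfig(), rng=rng)
        assert cca.squeeze_channels == 16  # c/r with c=32, r=2
        cca.eval()
        ld = Tensor(rng.normal(size=(1, 64, 8, 8)))
        sk = Tensor(rng.normal(size=(1, 32, 16, 16)))
        out = cca((ld, sk))
        assert out.data.shape == (1, 64, 16, 16)  # 2c channels

    def test_all_zero_inputs_give_all_zero_output(self, rng):
        cca = CCA(16, 8, ModelConfig(), rng)
        cca.eval()
        out = cca((Tensor(np.zeros((1, 16, 4, 4))),
                   Tensor(np.zeros((1, 8, 8, 8)))))
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("a,b", [(0.7, 0.4), (0.7, -1.2), (-0.3, -0.5)])
    def test_single_channel_identity_weights_hand_computation(self, a, b, rng):
        """With all 1x1 weights set to 1, biases 0, and batch-norm in identity
        mode, the forward pass matches hand evaluation: each branch's squeeze
        path reduces to an (eval-mode) RReLU of its constant, the gate is
        RReLU of the branch sum, and the outputs are gate*a and gate*b."""
        cca = CCA(1, 1, ModelConfig(reduction_r=2, depth=1, base_channels=9),
                  rng=rng)
        cca.eval()
        for conv in (cca.proj, cca.ld_squeeze, cca.ld_excite,
                     cca.sk_squeeze, cca.sk_excite):
            conv.weight.data = np.ones_like(conv.weight.data)
            conv.bias.data = np.zeros_like(conv.bias.data)
        cca.ld_bn.eps = 0.0
        cca.sk_bn.eps = 0.0
        ld = Tensor(np.full((1, 1, 4, 4), a))
        sk = Tensor(np.full((1, 1, 8, 8), b))
        out = cca((ld, sk)).data
        mid = (cca.gate_act.lower + cca.gate_act.upper) / 2
        rr = lambda v: v if v >= 0 else mid * v
        gate = rr(rr(a) + rr(b))
        np.testing.assert_allclose(out[0, 0], gate * a, atol=1e-12)
        np.testing.assert_allclose(out[0, 1], gate * b, atol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        cca = CCA(16, 8, ModelConfig(), rng)
        with pytest.raises(ShapeError):
            cca((Tensor(np.zeros((1, 16, 4, 4))),
                 Tensor(np.zeros((1, 8, 10, 10)))))  # not 2x of LD


class TestBuildModel:
    def test_same_config_same_parameter_count(self, tiny_model_config):
        a = build_model(tiny_model_config, seed=0)
        b = build_model(tiny_model_config, seed=999)
        assert count_parameters(a) == count_parameters(b)

    def test_depth_equals_number_of_cca_modules(self):
        model = build_model(ModelConfig(depth=4, base_channels=9))
        n_cca = sum(isinstance(m, CCA) for m in model.modules())
        assert n_cca == 4

    def test_he_initialization_variance(self):
        """Empirical weight variance within 20% of 2/fan_in for every
        convolution with at least 1000 weights."""
        model = build_model(ModelConfig(depth=3, base_channels=16), seed=0)
        checked = 0
        for m in model.modules():
            if isinstance(m, Conv2d) and m.weight.data.size >= 1000:
                fan_in = m.in_channels * m.kernel_size**2
                ratio = m.weight.data.var() / (2.0 / fan_in)
                assert 0.8 < ratio < 1.2, f"He variance off: {ratio:.3f}"
                checked += 1
        assert checked >= 5

    def test_parameter_count_increases_with_width(self):
        counts = [count_parameters(build_model(ModelConfig(depth=2,
                                                           base_channels=b)))
                  for b in (9, 12, 16)]
        assert counts[0] < counts[1] < counts[2]

    def test_no_pooling_operators_in_graph(self, tiny_model_config):
        """Downsampling happens only through stride-2 convolutions."""
        model = build_model(tiny_model_config)
        allowed_strides = {1, 2}
        for m in model.modules():
            assert "pool" not in type(m).__name__.lower()
            if isinstance(m, Conv2d):
                assert m.stride in allowed_strides

    def test_architecture_summary_totals(self, tiny_model_config):
        model = build_model(tiny_model_config)
        s = architecture_summary(model)
        assert s["total_parameters"] == count_parameters(model)
        assert sum(l["parameters"] for l in s["layers"]) == s["total_parameters"]


class TestForward:
    def test_shape_and_range_contract(self, rng, tiny_model_config):
        model = build_model(tiny_model_config).eval()
        out = model(Tensor(rng.normal(size=(2, 3, 32, 32))))
        assert out.data.shape == (2, 1, 32, 32)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_indivisible_input_names_required_multiple(self, tiny_model_config):
        model = build_model(tiny_model_config)
        with pytest.raises(ShapeError, match="divisible by 4"):
            model(Tensor(np.zeros((1, 3, 30, 30))))

    def test_eval_mode_is_deterministic(self, rng, tiny_model_config):
        model = build_model(tiny_model_config).eval()
        x = Tensor(rng.normal(size=(1, 3, 16, 16)))
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_multilabel_head_by_config(self, rng):
        model = build_model(ModelConfig(depth=2, base_channels=9,
                                        out_classes=4)).eval()
        out = model(Tensor(rng.normal(size=(1, 3, 16, 16))))
        assert out.data.shape == (1, 4, 16, 16)

    def test_gradient_flows_to_every_parameter(self, rng, tiny_model_config):
        """No dead branches: MSFF splitting and CCA gating leave every
        learnable parameter with a finite gradient under the training loss."""
        model = build_model(tiny_model_config, seed=1).train()
        x = Tensor(rng.normal(size=(2, 3, 16, 16)))
        y = (rng.uniform(size=(2, 1, 16, 16)) < 0.2).astype(float)
        loss = balanced_focal_loss(model(x), y,
                                   LossConfig(w=0.2, reduction="mean"))
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.isfinite(p.grad).all(), f"non-finite gradient for {name}"


class TestCountParameters:
    def test_lone_conv_hand_count(self, rng):
        conv = Conv2d(3, 16, 3, rng=rng)
        assert conv.weight.data.size + conv.bias.data.size == 3 * 16 * 9 + 16 == 448

    def test_count_is_architecture_determined(self, tiny_model_config):
        a = build_model(tiny_model_config, seed=7)
        b = build_model(tiny_model_config, seed=8)
        assert count_parameters(a) == count_parameters(b)
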