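"""Architecture checks: block geometry, ECA kernel rule, BiGRU reversal
oracle, B-spline/KAN brute-force oracles, variants, parameter counting and
gradient flow."""

import json

import numpy as np
import pytest

from maknet.autodiff import Parameter, Tensor
from maknet.imbalance import cross_entropy
from maknet.network import (BiGRU, ConvBlock, ECALayer, GRUDirection, KanLayer,
                            MLPBlock, ModelConfig, MultiScaleBlock, VARIANTS,
                            bspline_basis, build_model, count_parameters,
                            eca_kernel_size, make_grid)


# --------------------------------------------------------------------------
# convolutional blocks
# --------------------------------------------------------------------------


class TestConvBlock:
    def test_pool_arithmetic_grows_length_by_one(self):
        block = ConvBlock(1, 4, 3, np.random.default_rng(0))
        out = block(Tensor(np.random.default_rng(1).normal(size=(2, 1, 300))),
                    training=False)
        assert out.shape == (2, 4, 301)

    def test_zero_input_zero_output_in_inference_mode(self):
        block = ConvBlock(2, 3, 3, np.random.default_rng(0))
        out = block(Tensor(np.zeros((2, 2, 50))), training=False)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_build_determinism(self):
        a = ConvBlock(1, 4, 3, np.random.default_rng(5))
        b = ConvBlock(1, 4, 3, np.random.default_rng(5))
        for (_, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_channel_mismatch_is_a_shape_error(self):
        block = ConvBlock(2, 3, 3, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channel mismatch"):
            block(Tensor(np.zeros((1, 5, 40))), training=False)


class TestMultiScale:
    def test_fusion_weights_softmax_normalized(self):
        msb = MultiScaleBlock(3, 4, (3, 11, 21, 31), 0.0, np.random.default_rng(0))
        w = msb.fusion_weights().data
        assert abs(w.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(w, 0.25)  # uniform at initialization

    def test_degenerate_weighting_ignores_other_branches(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(2, 3, 40)))
        msb = MultiScaleBlock(3, 4, (3, 11, 21, 31), 0.0, np.random.default_rng(2))
        msb.fusion_logits.data[:] = [60.0, 0.0, 0.0, 0.0]  # softmax ~ (1,0,0,0)
        ref = msb(x, training=False, drop_rng=np.random.default_rng(0)).data
        for branch in msb.branches[1:]:  # other branches must not matter
            branch.weight.data[:] = np.random.default_rng(9).normal(size=branch.weight.shape)
        out = msb(x, training=False, drop_rng=np.random.default_rng(0)).data
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_tied_branches_equal_any_single_branch(self):
        rng = np.random.default_rng(3)
        x = Tensor(rng.normal(size=(2, 3, 40)))
        msb = MultiScaleBlock(3, 4, (3, 11, 21, 31), 0.0, np.random.default_rng(4))
        # embed the k=3 kernel at the centre of every wider kernel
        w3 = msb.branches[0].weight.data
        b3 = msb.branches[0].bias.data
        for branch in msb.branches[1:]:
            k = branch.weight.data.shape[2]
            branch.weight.data[:] = 0.0
            branch.weight.data[:, :, k // 2 - 1 : k // 2 + 2] = w3
            branch.bias.data[:] = b3
        outs = [branch(x).data for branch in msb.branches]
        for o in outs[1:]:
            np.testing.assert_allclose(o, outs[0], atol=1e-10)

    def test_even_kernel_is_config_error(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(ms_kernels=(3, 10, 21, 31))


class TestMLPBlock:
    def test_partial_ratio_one_is_full_convolution(self):
        block = MLPBlock(4, 1.0, np.random.default_rng(0))
        assert block.n_partial == 4

    def test_untouched_channels_pass_identity(self):
        rng = np.random.default_rng(1)
        block = MLPBlock(8, 0.25, np.random.default_rng(2))
        x = Tensor(rng.normal(size=(2, 8, 30)))
        out = block(x, training=False)
        main = block.conv2(block.bn(block.conv1(x), False).relu())
        partial_part = out.data - main.data
        np.testing.assert_allclose(partial_part[:, block.n_partial :],
                                   x.data[:, block.n_partial :], atol=1e-12)

    def test_partial_branch_parameter_scaling(self):
        # C=8, ratio 1/4, k=3: partial conv has 2*2*3+2 = 14 parameters,
        # approximately ratio^2 of the 8*8*3+8 = 200 full-conv parameters
        block = MLPBlock(8, 0.25, np.random.default_rng(0))
        n_partial = sum(p.data.size for _, p in block.partial_conv.named_parameters())
        n_full = sum(p.data.size for _, p in block.conv1.named_parameters())
        assert n_partial == 14 and n_full == 200
        assert abs(n_partial / n_full - 0.25**2) < 0.01


class TestECA:
    @pytest.mark.parametrize("channels,expected", [(64, 3), (256, 5), (2, 1)])
    def test_adaptive_kernel_size(self, channels, expected):
        assert eca_kernel_size(channels, 2.0, 1.0) == expected

    def test_zero_weights_scale_every_channel_by_half(self):
        eca = ECALayer(8, 2.0, 1.0, np.random.default_rng(0))
        eca.weight.data[:] = 0.0
        x = np.random.default_rng(1).normal(size=(2, 8, 20))
        out = eca(Tensor(x))
        np.testing.assert_allclose(out.data, 0.5 * x, atol=1e-12)

    def test_identical_channels_get_identical_weights(self):
        eca = ECALayer(6, 2.0, 1.0, np.random.default_rng(0))
        x = np.tile(np.random.default_rng(2).normal(size=(1, 1, 25)), (1, 6, 1))
        ratio = eca(Tensor(x)).data / x
        np.testing.assert_allclose(ratio, np.broadcast_to(ratio[:, :1], ratio.shape),
                                    atol=1e-12)

    def test_weights_lie_in_unit_interval(self):
        eca = ECALayer(5, 2.0, 1.0, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(3, 5, 15)) + 1.0
        ratio = eca(Tensor(x)).data / x
        assert np.all(ratio > 0) and np.all(ratio < 1)


class TestBiGRU:
    def test_zero_input_zero_state_gives_zero_output(self):
        gru = GRUDirection(3, 4, np.random.default_rng(0), reverse=False)
        out = gru(Tensor(np.zeros((2, 10, 3))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_output_width_is_twice_hidden(self):
        bigru = BiGRU(5, 7, 2, np.random.default_rng(1))
        out = bigru(Tensor(np.random.default_rng(2).normal(size=(2, 12, 5))))
        assert out.shape == (2, 12, 14)

    def test_backward_direction_matches_reversal_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 15, 4))
        bwd = GRUDirection(4, 5, np.random.default_rng(4), reverse=True)
        out = bwd(Tensor(x)).data
        fwd = GRUDirection(4, 5, np.random.default_rng(4), reverse=False)
        oracle = fwd(Tensor(x[:, ::-1].copy())).data[:, ::-1]
        np.testing.assert_allclose(out, oracle, atol=1e-6)


# --------------------------------------------------------------------------
# B-splines and KAN
# --------------------------------------------------------------------------


def cox_de_boor_reference(u, knots, i, k):
    """Textbook recursive Cox-de Boor, written independently of the
    vectorized implementation."""
    if k == 0:
        if knots[i] <= u < knots[i + 1]:
            return 1.0
        # close the last interior interval so u == hi is covered
        hi = knots[-1]
        if u == hi and knots[i] < knots[i + 1] <= hi and knots[i + 1] == hi:
            return 1.0
        return 0.0
    out = 0.0
    d1 = knots[i + k] - knots[i]
    if d1 > 0:
        out += (u - knots[i]) / d1 * cox_de_boor_reference(u, knots, i, k - 1)
    d2 = knots[i + k + 1] - knots[i + 1]
    if d2 > 0:
        out += (knots[i + k + 1] - u) / d2 * cox_de_boor_reference(u, knots, i + 1, k - 1)
    return out


class TestBSpline:
    def test_partition_of_unity(self):
        knots = make_grid(-1, 1, 5, 3)
        u = np.random.default_rng(0).uniform(-1, 1, 500)
        b = bspline_basis(u, knots, 3)
        np.testing.assert_allclose(b.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(b >= 0)

    def test_order_zero_is_interval_indicator(self):
        knots = make_grid(0, 1, 4, 0)
        b = bspline_basis(np.array([0.1, 0.3, 0.99, 1.0]), knots, 0)
        np.testing.assert_array_equal(b.sum(axis=-1), 1.0)
        assert np.array_equal(b[0], [1, 0, 0, 0])
        assert np.array_equal(b[3], [0, 0, 0, 1])  # right edge owned by last bin

    def test_matches_recursive_reference(self):
        knots = make_grid(-1, 1, 5, 3)
        u = np.random.default_rng(1).uniform(-1, 1, 1000)
        b = bspline_basis(u, knots, 3)
        for j in (0, 137, 499, 998):
            ref = [cox_de_boor_reference(u[j], knots, i, 3) for i in range(8)]
            np.testing.assert_allclose(b[j], ref, atol=1e-12)

    def test_out_of_range_clamped(self):
        knots = make_grid(-1, 1, 5, 3)
        b_out = bspline_basis(np.array([3.0, -4.0]), knots, 3)
        b_edge = bspline_basis(np.array([1.0, -1.0]), knots, 3)
        np.testing.assert_array_equal(b_out, b_edge)


class TestKanLayer:
    def test_zero_coefficients_reduce_to_silu_sums(self):
        layer = KanLayer(3, 2, 5, 3, (-1, 1), np.random.default_rng(0))
        layer.coeffs.data[:] = 0.0
        layer.w_base.data[:] = 1.0
        layer.bias.data[:] = 0.0
        x = np.random.default_rng(1).uniform(-1, 1, (4, 3))
        out = layer(Tensor(x)).data
        silu = x / (1 + np.exp(-x))
        np.testing.assert_allclose(out, np.tile(silu.sum(axis=1)[:, None], (1, 2)),
                                   atol=1e-12)

    def test_one_to_one_layer_matches_hand_evaluation(self):
        layer = KanLayer(1, 1, 5, 3, (-1, 1), np.random.default_rng(2))
        u = np.random.default_rng(3).uniform(-1, 1, 100)
        out = layer(Tensor(u[:, None])).data[:, 0]
        knots = layer.knots
        hand = []
        for ui in u:
            basis = [cox_de_boor_reference(ui, knots, i, 3) for i in range(8)]
            spline = float(np.dot(layer.coeffs.data[0, 0], basis))
            silu = ui / (1 + np.exp(-ui))
            hand.append(layer.w_base.data[0, 0] * silu
                        + layer.w_spline.data[0, 0] * spline
                        + layer.bias.data[0])
        np.testing.assert_allclose(out, hand, atol=1e-10)

    def test_spline_fit_approximates_sine(self):
        layer = KanLayer(1, 1, 10, 3, (-1, 1), np.random.default_rng(4))
        layer.w_base.data[:] = 0.0
        layer.w_spline.data[:] = 1.0
        layer.bias.data[:] = 0.0
        u = np.linspace(-1, 1, 400)
        basis = bspline_basis(u, layer.knots, 3)
        coef, *_ = np.linalg.lstsq(basis, np.sin(u), rcond=None)
        layer.coeffs.data[0, 0] = coef
        out = layer(Tensor(u[:, None])).data[:, 0]
        assert np.max(np.abs(out - np.sin(u))) < 0.01


class TestKanExport:
    def test_export_round_trips_through_json(self):
        layer = KanLayer(2, 3, 5, 3, (-1, 1), np.random.default_rng(5))
        rec = layer.export()
        rec2 = json.loads(json.dumps(rec))
        assert rec == rec2

    def test_zero_coefficient_edge_curve_is_scaled_silu(self):
        layer = KanLayer(1, 1, 5, 3, (-1, 1), np.random.default_rng(6))
        layer.coeffs.data[:] = 0.0
        rec = layer.export()
        u = np.asarray(rec["sample_u"])
        curve = np.asarray(rec["curves"])[0, 0]
        np.testing.assert_allclose(curve, layer.w_base.data[0, 0] * u / (1 + np.exp(-u)),
                                   atol=1e-12)

    def test_rebuild_from_export_is_forward_identical(self):
        layer = KanLayer(4, 2, 5, 3, (-1, 1), np.random.default_rng(7))
        rebuilt = KanLayer.from_export(layer.export())
        x = np.random.default_rng(8).uniform(-1, 1, (6, 4))
        np.testing.assert_allclose(layer(Tensor(x)).data, rebuilt(Tensor(x)).data,
                                   atol=1e-12)


# --------------------------------------------------------------------------
# the assembled model
# --------------------------------------------------------------------------


class TestBuildModel:
    def test_softmax_output_on_full_model(self, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        probs = model.forward(np.random.default_rng(0).normal(size=(2, 1, 300)))
        assert probs.shape == (2, 5)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs.data >= 0)

    def test_all_eight_variants_run(self, tiny_model_cfg):
        x = np.random.default_rng(1).normal(size=(2, 300))
        assert len(VARIANTS) == 8
        for variant in VARIANTS:
            model = build_model(tiny_model_cfg, variant)
            assert model.forward(x).shape == (2, 5)

    def test_unknown_variant_lists_valid_names(self, tiny_model_cfg):
        with pytest.raises(ValueError, match="no_kan"):
            build_model(tiny_model_cfg, "bogus")

    def test_seeded_build_determinism(self, tiny_model_cfg):
        a, b = build_model(tiny_model_cfg), build_model(tiny_model_cfg)
        for (_, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    @pytest.mark.parametrize("length", [64, 128, 300])
    def test_shape_contract_across_input_lengths(self, length):
        cfg = ModelConfig(input_len=length, stem_channels=(2, 3), ms_out_channels=4,
                          gru_hidden=3, gru_layers=1, kan_hidden=6, seed=0)
        model = build_model(cfg)
        probs = model.forward(np.random.default_rng(2).normal(size=(2, length)))
        assert probs.shape == (2, 5)


class TestCountParameters:
    def test_single_convolution_hand_count(self):
        from maknet.network import Conv1d

        class Wrap:
            def __init__(self):
                self.conv = Conv1d(1, 2, 3, np.random.default_rng(0))

            def parameters(self):
                return self.conv.parameters()

        assert count_parameters(Wrap()) == 8  # 2*1*3 weights + 2 biases

    def test_kan_layer_closed_form(self):
        layer = KanLayer(2, 3, 5, 3, (-1, 1), np.random.default_rng(0))

        class Wrap:
            def parameters(self):
                return layer.parameters()

        # out*in*(G+k) coefficients + 2*out*in edge weights + out node biases
        assert count_parameters(Wrap()) == 3 * 2 * 8 + 2 * 3 * 2 + 3


class TestGradientFlow:
    def test_finite_difference_agreement_in_every_block_type(self):
        cfg = ModelConfig(input_len=64, stem_channels=(2, 3), ms_out_channels=4,
                          gru_hidden=3, gru_layers=1, kan_hidden=5,
                          dropout=0.0, seed=2)
        model = build_model(cfg)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 64))
        y = np.array([1, 3])

        def loss_value():
            return cross_entropy(model.forward(x, training=True), y).item()

        loss = cross_entropy(model.forward(x, training=True), y)
        for p in model.parameters():
            p.grad = None
        loss.backward()

        picker = np.random.default_rng(0)
        checked = set()
        for name, p in model.named_parameters():
            block = name.split(".")[0]
            idx = tuple(picker.integers(0, s) for s in p.data.shape)
            g = p.grad[idx] if p.grad is not None else 0.0
            eps = 1e-6
            old = p.data[idx]
            p.data[idx] = old + eps
            lp = loss_value()
            p.data[idx] = old - eps
            lm = loss_value()
            p.data[idx] = old
            fd = (lp - lm) / (2 * eps)
            if abs(fd) < 1e-9 and abs(g) < 1e-9:
                continue
            assert abs(fd - g) / max(abs(fd), abs(g)) < 1e-3, name
            checked.add(block)
        assert {"stem", "multiscale", "attention", "bigru", "kan_layers"} <= checked
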