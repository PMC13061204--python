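"""Architecture tests: shape contracts, block-level oracles, parameter
accounting, calibration, checkpointing.

Every block's forward pass is cross-checked against an independent
re-implementation built from explicit shift-and-multiply convolutions, so the
im2col engine and the network wiring are verified separately.
"""

import numpy as np
import pytest

from hacrnet import nn
from hacrnet.model import (
    CAAM,
    CRAB,
    HAM,
    MFAB,
    ChannelAttention,
    ConfigError,
    ModelConfig,
    REFERENCE_CONFIG,
    ResidualBlock,
    SpatialAttention,
    build_model,
    calibrate_config,
    count_from_config,
    count_parameters,
    load_checkpoint,
    parameter_shapes,
    save_checkpoint,
)

from oracles import (
    count_oracle,
    crab_ref,
    forward,
    layer_ref,
    mfab_ref,
    prelu_ref,
    sigmoid_ref,
    zero_,
)


# ---------------------------------------------------------------------------
# configuration invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "overrides, message",
    [
        ({"scale": 3}, "scale"),
        ({"base_channels": 6, "ca_reduction": 4}, "ca_reduction"),
        ({"base_channels": 6, "ca_reduction": 2, "sa_reduction": 4}, "sa_reduction"),
        ({"crab_width": 10}, "crab_width"),
        ({"caam_count": 0}, "caam_count"),
        ({"use_mfab": False, "use_crab": False}, "use_mfab/use_crab"),
    ],
)
def test_invalid_config_names_violated_invariant(overrides, message):
    cfg = ModelConfig(**overrides)
    with pytest.raises(ConfigError, match=message):
        cfg.validate()


def test_config_dict_round_trip(tiny_cfg):
    assert ModelConfig.from_dict(tiny_cfg.to_dict()) == tiny_cfg
    with pytest.raises(ConfigError, match="unknown"):
        ModelConfig.from_dict({"bogus_key": 1})


# ---------------------------------------------------------------------------
# attention blocks
# ---------------------------------------------------------------------------


class TestChannelAttention:
    def test_gap_of_constant_channels_is_exact(self, rng):
        ca = ChannelAttention(2, 2, rng)
        x = np.stack([np.full((3, 3), 0.7), np.full((3, 3), -0.2)])[None]
        pooled = nn.global_avg_pool(nn.Tensor(x)).data
        np.testing.assert_allclose(pooled.ravel(), [0.7, -0.2], atol=1e-12)

    def test_mask_strictly_in_unit_interval(self, rng):
        ca = ChannelAttention(4, 2, rng)
        mask = forward(ca, rng.standard_normal((2, 4, 5, 5)))
        assert mask.shape == (2, 4, 1, 1)
        assert np.all(mask > 0) and np.all(mask < 1)

    def test_hand_fixed_weights_match_scalar_arithmetic(self, rng):
        """2-channel 2x2 instance computed step by step with plain scalars."""
        ca = ChannelAttention(2, 2, rng)
        ca.reduce.weight.data[...] = np.array([[[[0.5]], [[-1.0]]]])  # 1x2x1x1
        ca.reduce.bias.data[...] = [0.1]
        ca.act.slope.data[...] = [0.2]
        ca.expand.weight.data[...] = np.array([[[[2.0]]], [[[-0.5]]]])  # 2x1x1x1
        ca.expand.bias.data[...] = [0.0, 0.3]
        x = np.array([[[[0.2, 0.4], [0.6, 0.8]], [[1.0, 1.0], [1.0, 1.0]]]])
        g1, g2 = 0.5, 1.0  # channel means
        pre = 0.5 * g1 - 1.0 * g2 + 0.1  # = -0.65
        mid = 0.2 * pre  # PReLU, negative input
        expected = sigmoid_ref(np.array([2.0 * mid + 0.0, -0.5 * mid + 0.3]))
        np.testing.assert_allclose(forward(ca, x).ravel(), expected, atol=1e-7)

    def test_indivisible_reduction_rejected(self, rng):
        with pytest.raises(ConfigError, match="divisible"):
            ChannelAttention(6, 4, rng)


class TestSpatialAttention:
    def test_mask_shape_and_range(self, rng):
        sa = SpatialAttention(4, 2, rng)
        mask = forward(sa, rng.standard_normal((2, 4, 9, 9)))
        assert mask.shape == (2, 1, 9, 9)
        assert np.all(mask > 0) and np.all(mask < 1)

    def test_zero_weights_give_half_mask(self, rng):
        sa = SpatialAttention(1, 1, rng)
        zero_(sa)
        mask = forward(sa, rng.standard_normal((1, 1, 5, 5)))
        np.testing.assert_allclose(mask, 0.5, atol=1e-12)


class TestHAM:
    def test_identity_masks_recover_shallow_features(self, tiny_cfg, rng):
        ham = HAM(tiny_cfg, np.random.default_rng(0))
        x = rng.random((1, 1, 6, 6))
        shallow = prelu_ref(ham.act, layer_ref(ham.conv, x))
        ones = lambda t: nn.Tensor(np.ones((1, 1, 1, 1)))
        ham.ca = ones
        ham.sa = ones
        np.testing.assert_allclose(forward(ham, x), shallow, atol=1e-6)

    def test_composition_matches_manual_chain(self, tiny_cfg, rng):
        """HAM equals channel attention then spatial attention applied by hand."""
        ham = HAM(tiny_cfg, np.random.default_rng(1))
        x = rng.random((1, 1, 4, 4))
        out = forward(ham, x)
        f = prelu_ref(ham.act, layer_ref(ham.conv, x))
        fc = forward(ham.ca, f)
        fp = fc * f
        ms = forward(ham.sa, fp)
        np.testing.assert_allclose(out, ms * fp, atol=1e-6)

    def test_output_channels_and_dims(self, small_cfg, rng):
        ham = HAM(small_cfg, np.random.default_rng(2))
        out = forward(ham, rng.random((2, 1, 10, 12)))
        assert out.shape == (2, small_cfg.base_channels, 10, 12)


# ---------------------------------------------------------------------------
# residual block / MFAB / CRAB line-by-line oracles
# ---------------------------------------------------------------------------


class TestResidualBlock:
    def test_zero_weights_identity(self, rng):
        rb = ResidualBlock(3, np.random.default_rng(0))
        zero_(rb)
        x = rng.standard_normal((1, 3, 4, 4))
        np.testing.assert_allclose(forward(rb, x), x, atol=1e-12)

    def test_single_pixel_scalar_arithmetic(self):
        rb = ResidualBlock(1, np.random.default_rng(0))
        rb.act1.slope.data[...] = 0.5
        rb.conv1.weight.data[...] = 0.0
        rb.conv1.weight.data[0, 0, 1, 1] = 2.0
        rb.conv1.bias.data[...] = 0.1
        rb.act2.slope.data[...] = 0.25
        rb.conv2.weight.data[...] = 0.0
        rb.conv2.weight.data[0, 0, 1, 1] = -1.0
        rb.conv2.bias.data[...] = 0.05
        x = np.array([[[[-0.4]]]])
        a1 = 0.5 * -0.4           # PReLU
        c1 = 2.0 * a1 + 0.1       # centre-tap conv
        a2 = c1 if c1 >= 0 else 0.25 * c1
        c2 = -1.0 * a2 + 0.05
        np.testing.assert_allclose(forward(rb, x).item(), -0.4 + c2, atol=1e-9)

    def test_reference_oracle(self, rng):
        rb = ResidualBlock(2, np.random.default_rng(3))
        x = rng.standard_normal((1, 2, 4, 4))
        expected = x + layer_ref(
            rb.conv2, prelu_ref(rb.act2, layer_ref(rb.conv1, prelu_ref(rb.act1, x)))
        )
        np.testing.assert_allclose(forward(rb, x), expected, atol=1e-6)


class TestMFAB:
    def test_all_zero_weights_give_zero_output(self, rng):
        block = MFAB(2, 2, np.random.default_rng(0))
        zero_(block)
        out = forward(block, rng.standard_normal((1, 2, 4, 4)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_branch_isolation(self, rng):
        """With A2 and attention zeroed the output is A1 * 0.5 + HF."""
        block = MFAB(2, 2, np.random.default_rng(1))
        zero_(block.a2_conv1)
        zero_(block.a2_conv2)
        zero_(block.att_reduce)
        zero_(block.att_expand)  # att = sigmoid(0) = 0.5 exactly
        x = rng.standard_normal((1, 2, 4, 4))
        a1 = layer_ref(block.a1_conv2, prelu_ref(block.a1_act2, layer_ref(block.a1_conv1, prelu_ref(block.a1_act1, x))))
        np.testing.assert_allclose(
            forward(block, x), 0.5 * a1 + layer_ref(block.hf, x), atol=1e-6
        )

    def test_line_by_line_oracle(self, rng):
        block = MFAB(1, 1, np.random.default_rng(2))
        x = rng.standard_normal((1, 1, 3, 3))
        np.testing.assert_allclose(forward(block, x), mfab_ref(block, x), atol=1e-6)


class TestCRAB:
    def test_zero_descriptor_path_gives_1p5_h(self, rng):
        block = CRAB(2, 2, np.random.default_rng(0))
        for layer in (block.fc_a, block.fc_b, block.fc_c, block.fc_d):
            zero_(layer)
        x = rng.standard_normal((1, 2, 4, 4))
        h = layer_ref(block.conv, x)
        np.testing.assert_allclose(forward(block, x), 1.5 * h, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = CRAB(4, 3, np.random.default_rng(1))
        x = rng.standard_normal((2, 4, 5, 6))
        assert forward(block, x).shape == x.shape

    def test_line_by_line_oracle(self, rng):
        block = CRAB(2, 2, np.random.default_rng(2))
        x = rng.standard_normal((1, 2, 2, 2))
        np.testing.assert_allclose(forward(block, x), crab_ref(block, x), atol=1e-6)


class TestCAAM:
    def test_zeroed_fusion_is_exact_identity(self, small_cfg, rng):
        caam = CAAM(small_cfg, np.random.default_rng(0))
        zero_(caam.fusion)
        x = rng.standard_normal((1, small_cfg.base_channels, 6, 6)).astype(np.float32)
        out = caam(nn.Tensor(x)).data
        assert np.max(np.abs(out - x)) <= 1e-6

    def test_channel_count_preserved(self, small_cfg, rng):
        caam = CAAM(small_cfg, np.random.default_rng(1))
        x = rng.standard_normal((2, small_cfg.base_channels, 5, 5))
        assert forward(caam, x).shape == x.shape

    def test_composition_matches_monolithic_reference(self, tiny_cfg, rng):
        caam = CAAM(tiny_cfg, np.random.default_rng(2))
        x = rng.standard_normal((1, 4, 4, 4))
        res = x + layer_ref(
            caam.res.conv2,
            prelu_ref(caam.res.act2, layer_ref(caam.res.conv1, prelu_ref(caam.res.act1, x))),
        )
        cin = layer_ref(caam.shared, res)
        fused = np.concatenate([mfab_ref(caam.mfab, cin), crab_ref(caam.crab, cin)], axis=1)
        expected = layer_ref(caam.fusion, fused) + x
        np.testing.assert_allclose(forward(caam, x), expected, atol=1e-6)

    @pytest.mark.parametrize("toggles", [(True, False), (False, True)])
    def test_single_branch_fusion(self, toggles, rng):
        use_mfab, use_crab = toggles
        cfg = ModelConfig(
            base_channels=4, caam_count=1, ca_reduction=2, sa_reduction=2,
            crab_width=2, use_mfab=use_mfab, use_crab=use_crab,
        )
        caam = CAAM(cfg, np.random.default_rng(3))
        assert caam.fusion.in_channels == 4
        x = rng.standard_normal((1, 4, 4, 4))
        assert forward(caam, x).shape == x.shape


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("scale, shape", [(2, (1, 1, 8, 8)), (4, (1, 1, 8, 10)), (2, (2, 1, 12, 8))])
def test_output_dims_are_scale_times_input(tiny_cfg, rng, scale, shape):
    model = build_model(tiny_cfg.replace(scale=scale))
    out = model.predict(rng.random(shape, dtype=np.float32))
    assert out.shape == (shape[0], 1, scale * shape[2], scale * shape[3])


def test_zeroed_fusions_reduce_to_ham_plus_reconstruction(tiny_cfg, rng):
    model = build_model(tiny_cfg.replace(caam_count=3))
    for caam in model.caams:
        zero_(caam.fusion)
    x = rng.random((1, 1, 6, 6), dtype=np.float32)
    with nn.no_grad():
        f1 = model.ham(nn.Tensor(x))
        expected = model.upsampler(f1, f1).data
    np.testing.assert_allclose(model.predict(x), expected, atol=1e-6)


def test_forward_is_bit_deterministic(tiny_cfg, rng):
    x = rng.random((1, 1, 8, 8), dtype=np.float32)
    a = build_model(tiny_cfg).predict(x)
    b = build_model(tiny_cfg).predict(x)
    np.testing.assert_array_equal(a, b)


def test_forward_rejects_bad_inputs(tiny_cfg):
    model = build_model(tiny_cfg)
    with pytest.raises(ValueError, match="channels"):
        model.predict(np.zeros((1, 2, 8, 8), dtype=np.float32))
    bad = np.zeros((1, 1, 8, 8), dtype=np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        model.predict(bad)


def test_upsampler_rejects_mismatched_skip(tiny_cfg, rng):
    model = build_model(tiny_cfg)
    f = nn.Tensor(rng.standard_normal((1, 4, 6, 6)))
    skip = nn.Tensor(rng.standard_normal((1, 4, 5, 6)))
    with pytest.raises(ValueError, match="identical shapes"):
        model.upsampler(f, skip)


def test_zero_final_conv_gives_zero_output(tiny_cfg, rng):
    model = build_model(tiny_cfg)
    zero_(model.upsampler.final)
    out = model.predict(rng.random((1, 1, 8, 8), dtype=np.float32))
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_gradient_reaches_every_parameter(tiny_cfg, rng):
    # seed chosen so every PReLU sees at least one negative input; slopes on
    # all-positive pooled descriptors would have a legitimately zero gradient
    model = build_model(tiny_cfg.replace(caam_count=2, seed=1))
    x = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)
    target = rng.random((2, 1, 16, 16)).astype(np.float32)
    loss = nn.mean_abs(nn.sub(model(x), nn.Tensor(target)))
    loss.backward()
    dead = [
        name
        for name, p in model.named_parameters()
        if p.grad is None or np.linalg.norm(p.grad) == 0.0
    ]
    assert not dead, f"parameters with no gradient: {dead}"


# ---------------------------------------------------------------------------
# parameter accounting and calibration
# ---------------------------------------------------------------------------


CONFIG_GRID = [
    ModelConfig(base_channels=c, caam_count=n, scale=s, ca_reduction=r,
                sa_reduction=r, crab_width=max(c // 2, 1),
                use_mfab=um, use_crab=uc)
    for c, n, s, r in [(4, 1, 2, 2), (4, 2, 4, 2), (8, 1, 2, 4), (8, 3, 4, 2),
                       (16, 2, 2, 4), (16, 1, 4, 8), (12, 2, 2, 2), (6, 2, 2, 3)]
    for um, uc in [(True, True), (True, False)]
]


@pytest.mark.parametrize("cfg", CONFIG_GRID)
def test_count_matches_enumeration_and_oracle(cfg):
    model = build_model(cfg)
    built = count_parameters(model)
    assert built == count_from_config(cfg) == count_oracle(cfg)
    # the enumeration names every parameter the builder creates
    assert dict(parameter_shapes(cfg)) == {
        k: p.data.shape for k, p in model.named_parameters()
    }


def test_count_closed_form_single_conv_plus_prelu(rng):
    class One(nn.Module):
        def __init__(self):
            self.conv = nn.Conv2d(1, 1, 3, rng)
            self.act = nn.PReLU(1)

    assert count_parameters(One()) == 9 + 1 + 1


def test_reference_config_hits_printed_total():
    assert count_from_config(REFERENCE_CONFIG) == 1_674_251
    assert round(count_parameters(build_model(REFERENCE_CONFIG)) / 1000) == 1674


def test_calibrate_exact_target_gives_zero_residual():
    space = [ModelConfig(base_channels=c, caam_count=2, ca_reduction=2,
                         sa_reduction=2, crab_width=c // 2) for c in (4, 8, 12)]
    target = count_from_config(space[1])
    cfg, achieved = calibrate_config(target, search_space=iter(space))
    assert achieved == target and cfg.base_channels == 8


def test_calibrate_count_monotone_in_width():
    counts = [
        count_from_config(ModelConfig(base_channels=c, caam_count=2,
                                      ca_reduction=2, sa_reduction=2,
                                      crab_width=c // 2))
        for c in (8, 16, 24, 32, 40)
    ]
    assert counts == sorted(counts)


def test_calibrate_empty_space_errors():
    with pytest.raises(ConfigError, match="empty"):
        calibrate_config(1000, search_space=iter([]))


def test_deeper_model_has_strictly_more_parameters():
    c7 = count_from_config(REFERENCE_CONFIG.replace(caam_count=7))
    c10 = count_from_config(REFERENCE_CONFIG)
    assert c10 > c7


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def test_checkpoint_round_trip(tiny_cfg, tmp_path, rng):
    model = build_model(tiny_cfg)
    x = rng.random((1, 1, 8, 8), dtype=np.float32)
    before = model.predict(x)
    save_checkpoint(model, tmp_path / "m.npz")
    restored = load_checkpoint(tmp_path / "m.npz", cfg=tiny_cfg)
    np.testing.assert_array_equal(before, restored.predict(x))


def test_checkpoint_config_mismatch_names_first_key(tiny_cfg, tmp_path):
    model = build_model(tiny_cfg)
    save_checkpoint(model, tmp_path / "m.npz")
    with pytest.raises(ConfigError, match="base_channels"):
        load_checkpoint(tmp_path / "m.npz", cfg=tiny_cfg.replace(base_channels=8))
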