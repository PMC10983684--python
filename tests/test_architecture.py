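"""Attention-module oracles, architecture contracts, and exact
parameter/MAC accounting against independent closed-form arithmetic."""

import numpy as np
import pytest

from noseleaf import nn
from noseleaf.architecture import (CBAM, ChannelAttention, ModelConfig,
                                   ResidualCBAMBlock, SpatialAttention,
                                   build_reference_vgg16, build_vgg16_cbam,
                                   count_macs, count_parameters, layer_budget,
                                   load_checkpoint, save_checkpoint, softmax)
from noseleaf.nn import Tensor


# --- channel attention -------------------------------------------------------

def test_channel_attention_zero_input_gives_half():
    cam = ChannelAttention(8, reduction_ratio=2)
    w = cam(Tensor(np.zeros((3, 8, 4, 4), np.float32)))
    np.testing.assert_allclose(w.data, 0.5)


def test_channel_attention_shape_and_range(rng):
    cam = ChannelAttention(256, reduction_ratio=16)
    w = cam(Tensor(rng.normal(size=(2, 256, 28, 28)).astype(np.float32)))
    assert w.shape == (2, 256, 1, 1)
    assert np.all(w.data > 0) and np.all(w.data < 1)


def test_channel_attention_hand_executed_oracle():
    """C=2, r=1, hand-set perceptron weights on a 2x2 map, checked against
    the pooled/perceptron/sigmoid formula evaluated step by step."""
    cam = ChannelAttention(2, reduction_ratio=1)
    w1 = np.array([[1.0, -0.5], [0.25, 2.0]], np.float32)   # (in=2, hidden=2)
    w2 = np.array([[0.5, 1.0], [-1.0, 0.75]], np.float32)   # (hidden=2, out=2)
    cam.fc1.weight.data[:] = w1
    cam.fc2.weight.data[:] = w2
    x = np.array([[[[1.0, 2.0], [3.0, 4.0]],
                   [[-1.0, 0.0], [5.0, -2.0]]]], np.float32)
    # oracle: explicit pools + perceptron + sum + sigmoid
    avg = x.mean(axis=(2, 3))[0]           # (2,)
    mx = x.max(axis=(2, 3))[0]
    def mlp(v):
        return np.maximum(v @ w1, 0) @ w2
    expected = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
    got = cam(Tensor(x)).data[0, :, 0, 0]
    np.testing.assert_allclose(got, expected, rtol=1e-5)


def test_channel_attention_validation_errors():
    with pytest.raises(ValueError, match="not divisible"):
        ChannelAttention(6, reduction_ratio=4)
    cam = ChannelAttention(4, reduction_ratio=2)
    bad = np.zeros((1, 4, 2, 2), np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        cam(Tensor(bad))


# --- spatial attention -------------------------------------------------------

def test_spatial_attention_shape_range_and_zero_conv(rng):
    sam = SpatialAttention(7)
    w = sam(Tensor(rng.normal(size=(1, 8, 5, 5)).astype(np.float32)))
    assert w.shape == (1, 1, 5, 5)
    assert np.all((w.data > 0) & (w.data < 1))
    sam.conv.weight.data[:] = 0
    sam.conv.bias.data[:] = 0
    w = sam(Tensor(np.full((1, 8, 5, 5), 3.0, np.float32)))
    np.testing.assert_allclose(w.data, 0.5)


def test_spatial_attention_hand_convolution_oracle(rng):
    sam = SpatialAttention(3)
    kernel = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
    sam.conv.weight.data[:] = kernel
    sam.conv.bias.data[:] = 0.3
    x = rng.normal(size=(1, 4, 3, 3)).astype(np.float32)
    # brute-force oracle: channel max/mean then direct dense convolution
    stacked = np.stack([x[0].max(axis=0), x[0].mean(axis=0)])  # (2, 3, 3)
    padded = np.pad(stacked, ((0, 0), (1, 1), (1, 1)))
    expected = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            expected[i, j] = (padded[:, i:i + 3, j:j + 3] * kernel[0]).sum() + 0.3
    expected = 1 / (1 + np.exp(-expected))
    got = sam(Tensor(x)).data[0, 0]
    np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-5)


def test_spatial_attention_rejects_even_kernel():
    with pytest.raises(ValueError, match="odd"):
        SpatialAttention(4)


# --- CBAM and residual block -------------------------------------------------

def test_cbam_zero_input_and_shape(rng):
    cbam = CBAM(16, reduction_ratio=4, sam_kernel=3)
    out = cbam(Tensor(np.zeros((1, 16, 6, 6), np.float32)))
    np.testing.assert_allclose(out.data, 0.0)
    x = rng.normal(size=(2, 16, 14, 14)).astype(np.float32)
    assert cbam(Tensor(x)).shape == x.shape


def test_cbam_composes_the_two_attention_oracles(rng):
    cbam = CBAM(4, reduction_ratio=2, sam_kernel=3)
    x = rng.normal(size=(1, 4, 3, 3)).astype(np.float32)
    out = cbam(Tensor(x))
    cw = cbam.channel(Tensor(x)).data
    xprime = x * cw
    sw = cbam.spatial(Tensor(xprime)).data
    np.testing.assert_allclose(out.data, xprime * sw, rtol=1e-5, atol=1e-6)
    np.testing.assert_allclose(cbam.last_channel_weights.data, cw)
    np.testing.assert_allclose(cbam.last_spatial_weights.data, sw, rtol=1e-5)


def test_residual_block_identity_with_zero_conv(rng):
    blk = ResidualCBAMBlock(8, kernel_size=3, reduction_ratio=2, sam_kernel=3)
    blk.conv.weight.data[:] = 0
    blk.conv.bias.data[:] = 0
    x = np.abs(rng.normal(size=(2, 8, 5, 5))).astype(np.float32)
    out = blk(Tensor(x))
    np.testing.assert_allclose(out.data, x, rtol=1e-6)


def test_residual_block_shape_preserved_and_channel_check(rng):
    blk = ResidualCBAMBlock(16, reduction_ratio=4)
    x = rng.normal(size=(1, 16, 14, 14)).astype(np.float32)
    assert blk(Tensor(x)).shape == (1, 16, 14, 14)
    with pytest.raises(ValueError, match="expects 16 channels"):
        blk(Tensor(np.zeros((1, 8, 14, 14), np.float32)))


def test_residual_block_256_parameter_closed_form():
    blk = ResidualCBAMBlock(256)     # 7x7 conv, r=16, 7x7 spatial kernel
    conv = 256 * 256 * 49 + 256
    perceptron = 2 * 256 * 16        # bias-free shared two-layer perceptron
    sam = 2 * 49 + 1
    assert count_parameters(blk) == conv + perceptron + sam == 3_219_811


# --- full architectures ------------------------------------------------------

def test_vgg16_cbam_total_parameter_count():
    model = build_vgg16_cbam()
    assert count_parameters(model) == 31_353_869
    millions = count_parameters(model) / 1e6
    assert f"{millions:.2f} M" == "31.35 M"


def test_reference_vgg16_parameter_counts():
    ref = build_reference_vgg16(1000)
    conv = sum(cin * cout * 9 + cout for cin, cout in
               [(3, 64), (64, 64), (64, 128), (128, 128), (128, 256),
                (256, 256), (256, 256), (256, 512), (512, 512), (512, 512),
                (512, 512), (512, 512), (512, 512)])
    bn = 2 * (64 * 2 + 128 * 2 + 256 * 3 + 512 * 6)
    fc = (25088 * 4096 + 4096) + (4096 * 4096 + 4096) + (4096 * 1000 + 1000)
    assert conv == 14_714_688 and fc == 123_642_856
    assert count_parameters(ref) == conv + bn + fc == 138_365_992
    small = build_reference_vgg16(7)
    assert count_parameters(ref) - count_parameters(small) == 4096 * 993 + 993


def test_parameter_ratio_matches_published_value():
    ratio = 100 * count_parameters(build_vgg16_cbam()) \
        / count_parameters(build_reference_vgg16(1000))
    assert round(ratio, 1) == 22.7


def test_softmax_normalization_and_input_size_agnosticism(rng):
    model = build_vgg16_cbam(ModelConfig(input_size=(64, 64)))
    model.eval()
    for size in (64, 48):
        probs = model.predict_proba(
            rng.normal(size=(2, 3, size, size)).astype(np.float32) * 0.1)
        assert probs.shape == (2, 7)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)
    with pytest.raises(ValueError, match="at least 32"):
        model.forward(Tensor(np.zeros((1, 3, 16, 16), np.float32)))


def test_model_config_validation():
    with pytest.raises(ValueError, match="num_classes"):
        ModelConfig(num_classes=1)
    with pytest.raises(ValueError, match="divide"):
        ModelConfig(reduction_ratio=24)
    with pytest.raises(ValueError, match="odd"):
        ModelConfig(sam_kernel=4)


# --- accounting ---------------------------------------------------------------

def test_count_parameters_simple_cases():
    assert count_parameters(nn.Sequential()) == 0
    nn.manual_seed(0)
    assert count_parameters(nn.Conv2d(3, 64, 3)) == 3 * 64 * 9 + 64 == 1_792


def test_count_macs_single_conv_and_empty():
    nn.manual_seed(0)
    conv = nn.Conv2d(256, 256, 7, padding=3)
    x = np.zeros((1, 256, 28, 28), np.float32)
    with nn.no_grad(), nn.profiling() as recs:
        conv(Tensor(x))
    assert sum(r.macs for r in recs) == 784 * 256 * 256 * 49 == 2_517_630_976
    assert count_macs(nn.Sequential(nn.ReLU(), nn.MaxPool2d(2)),
                      (8, 8)) == 0


def _closed_form_vgg16_cbam_macs(h=224, w=224):
    """Independent per-layer arithmetic for the default architecture."""
    total = 0
    cin, hh, ww = 3, h, w
    plan = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
            512, 512, 512, "M", 512, 512, 512, "M"]
    blocks = {3: 256, 4: 512}           # residual block after pools 3 and 4
    pools = 0
    for item in plan:
        if item == "M":
            hh, ww = hh // 2, ww // 2
            pools += 1
            if pools in blocks:
                c = blocks[pools]
                total += hh * ww * c * c * 49          # block conv
                total += 2 * (c * (c // 16) * 2)       # attention perceptron
                total += hh * ww * 1 * 2 * 49          # spatial attention conv
        else:
            total += hh * ww * item * cin * 9
            cin = item
    total += hh * ww * 1024 * 512                      # 1x1 head conv
    total += 1024 * 7                                  # classifier
    return total


def test_vgg16_cbam_mac_count_matches_closed_form():
    got = count_macs(build_vgg16_cbam(), (224, 224))
    assert got == _closed_form_vgg16_cbam_macs()
    assert abs(got - 2.047e10) / 2.047e10 < 0.01


def test_layer_budget_totals_are_consistent():
    model = build_vgg16_cbam(ModelConfig(input_size=(64, 64)))
    rows = layer_budget(model, (64, 64))
    assert sum(r.param_count for r in rows) == count_parameters(model)
    assert all(r.param_count >= 0 and r.mac_count >= 0 for r in rows)


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = ModelConfig(input_size=(48, 48))
    model = build_vgg16_cbam(cfg, init_seed=3)
    x = rng.normal(size=(1, 3, 48, 48)).astype(np.float32) * 0.1
    before = model.predict_proba(x)
    save_checkpoint(model, tmp_path / "ckpt.npz", cfg)
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    np.testing.assert_array_equal(restored.predict_proba(x), before)
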