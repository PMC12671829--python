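"""Enhancement units: scalar brute-force oracles on 1x1-spatial inputs,
channel bookkeeping, and the zero-init residual identity."""

import math

import numpy as np
import pytest

from julite import nn
from julite.nn import Tensor
from julite.rcam import (CascadedRCAM, CascadedRCAMSpec, ConvBNHSwish,
                         ConvBNHSwishSpec, EfficientRCAM, EfficientRCAMSpec,
                         cascaded_rcam, conv_bn_hswish, efficient_rcam)


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def _hswish(v):
    return v * min(max(0.0, v + 3.0), 6.0) / 6.0


def test_conv_bn_hswish_zero_everything_gives_zero():
    nn.manual_seed(0)
    block = ConvBNHSwish(2, ConvBNHSwishSpec(3, 4))
    block.conv.weight.data[:] = 0
    out = conv_bn_hswish(np.zeros((1, 2, 4, 4)), block.eval())
    assert np.allclose(out, 0.0)


def test_conv_bn_hswish_same_padding_preserves_spatial(rng):
    nn.manual_seed(0)
    block = ConvBNHSwish(3, ConvBNHSwishSpec(3, 5)).eval()
    out = conv_bn_hswish(rng.normal(size=(2, 3, 7, 9)), block)
    assert out.shape == (2, 5, 7, 9)


def test_conv_bn_hswish_matches_scalar_oracle():
    """1x1x1x1 input with hand-set weight and frozen BN statistics."""
    nn.manual_seed(0)
    block = ConvBNHSwish(1, ConvBNHSwishSpec(1, 1))
    block.conv.weight.data[:] = 1.7
    block.bn.weight.data[:] = 1.3
    block.bn.bias.data[:] = -0.2
    block.bn.register_buffer("running_mean", np.array([0.4]))
    block.bn.register_buffer("running_var", np.array([2.0]))
    block.eval()
    x = 0.9
    conv = 1.7 * x
    norm = 1.3 * (conv - 0.4) / math.sqrt(2.0 + block.bn.eps) - 0.2
    expected = _hswish(norm)
    got = conv_bn_hswish(np.array(x).reshape(1, 1, 1, 1), block)
    assert got.ravel()[0] == pytest.approx(expected, abs=1e-12)


def _rcam_block(c=2):
    nn.manual_seed(0)
    return EfficientRCAM(EfficientRCAMSpec(
        channels=c, depth_kernel=3, gate_kernel=3, group_count=1,
        reduction_ratio=1, internal_compression=None))


def test_efficient_rcam_zero_input_with_zero_biases_gives_zero():
    block = _rcam_block()
    block.depth_conv.bias.data[:] = 0
    block.fc1.bias.data[:] = 0
    block.fc2.bias.data[:] = 0
    out = efficient_rcam(np.zeros((1, 2, 3, 3)), block)
    assert np.allclose(out, 0.0)


def test_identity_depthwise_reduces_to_zero_init_attention(rng):
    """Center-tap depthwise kernel + zero gate -> out = F + 0.5 (s (.) F)."""
    block = _rcam_block(c=4)
    block.depth_conv.weight.data[:] = 0
    block.depth_conv.weight.data[:, 0, 1, 1] = 1.0
    block.depth_conv.bias.data[:] = 0
    x = rng.normal(size=(2, 4, 5, 5))
    with nn.no_grad():
        pooled = nn.global_avg_pool(Tensor(x))
        s = block.fc2(block.fc1(pooled).relu()).sigmoid().data
    out = efficient_rcam(x, block)
    assert np.allclose(out, x + 0.5 * s[:, :, None, None] * x, atol=1e-12)


def test_zero_init_residual_identity_for_any_input(rng):
    """efficient_rcam(F) - DepthConv(F) = 0.5 (s (.) DepthConv(F))."""
    block = _rcam_block(c=4)
    x = rng.normal(size=(1, 4, 6, 6))
    with nn.no_grad():
        d = block.depth_conv(Tensor(x)).data
        pooled = nn.global_avg_pool(Tensor(d))
        s = block.fc2(block.fc1(pooled).relu()).sigmoid().data
    out = efficient_rcam(x, block)
    assert np.allclose(out - d, 0.5 * s[:, :, None, None] * d, atol=1e-12)


def test_efficient_rcam_matches_scalar_oracle():
    """1x2x1x1 input, hand-set depthwise, SE and gate weights."""
    block = _rcam_block(c=2)
    block.depth_conv.weight.data[:] = 0
    block.depth_conv.weight.data[:, 0, 1, 1] = [1.5, -0.5]
    block.depth_conv.bias.data = np.array([0.2, -0.1])
    w1 = np.array([[0.5, -0.3], [0.2, 0.7]])
    w2 = np.array([[1.0, -1.0], [0.4, 0.6]])
    block.fc1.weight.data = w1.copy()
    block.fc1.bias.data[:] = 0
    block.fc2.weight.data = w2.copy()
    block.fc2.bias.data[:] = 0
    gw = np.zeros((2, 2, 3, 3))
    gw[0, :, 1, 1] = [0.3, -0.4]
    gw[1, :, 1, 1] = [0.8, 0.1]
    block.gate_conv.weight.data = gw.copy()
    block.gate_conv.bias.data = np.array([0.05, -0.05])

    f = np.array([0.7, -1.3])
    d = np.array([1.5, -0.5]) * f + np.array([0.2, -0.1])
    hidden = np.maximum(w1 @ d, 0.0)
    s = np.array([_sigmoid(w2[c] @ hidden) for c in range(2)])
    weighted = s * d
    gate = _sigmoid((gw[:, :, 1, 1] @ weighted + np.array([0.05, -0.05])).mean())
    expected = gate * weighted + d

    got = efficient_rcam(f.reshape(1, 2, 1, 1), block)
    assert np.allclose(got.ravel(), expected, atol=1e-9)


def test_cascaded_rcam_halves_channels_preserves_spatial(rng):
    nn.manual_seed(0)
    block = CascadedRCAM(CascadedRCAMSpec(
        in_channels=8, adapt_kernel=1,
        inner=EfficientRCAMSpec(channels=8, group_count=2, reduction_ratio=2)))
    block.eval()
    out = cascaded_rcam(rng.normal(size=(2, 8, 5, 7)), block)
    assert out.shape == (2, 4, 5, 7)
    assert np.isfinite(out).all()


def test_cascaded_rcam_320_to_160():
    nn.manual_seed(0)
    block = CascadedRCAM(CascadedRCAMSpec(in_channels=320))
    block.eval()
    out = cascaded_rcam(np.zeros((1, 320, 2, 2)), block)
    assert out.shape[1] == 160


def test_cascaded_rcam_rejects_odd_channels():
    with pytest.raises(ValueError):
        CascadedRCAMSpec(in_channels=7).validate()


def test_cascaded_rcam_matches_scalar_composition():
    """Eq-level check: tail output equals ConvBNHSwish applied to the sum of
    input and the enhancement unit's output, composed by hand."""
    nn.manual_seed(3)
    block = CascadedRCAM(CascadedRCAMSpec(
        in_channels=2, adapt_kernel=1,
        inner=EfficientRCAMSpec(channels=2, group_count=1, reduction_ratio=1)))
    # freeze BN with nontrivial statistics
    block.adapt.bn.register_buffer("running_mean", np.array([0.1]))
    block.adapt.bn.register_buffer("running_var", np.array([1.5]))
    block.adapt.bn.weight.data[:] = 1.1
    block.adapt.bn.bias.data[:] = 0.05
    block.eval()
    x = np.array([0.4, -0.9]).reshape(1, 2, 1, 1)
    rcam_out = efficient_rcam(x, block.rcam)
    fused = (x + rcam_out).ravel()
    w = block.adapt.conv.weight.data.reshape(1, 2)
    conv = float((w @ fused)[0])
    norm = 1.1 * (conv - 0.1) / math.sqrt(1.5 + block.adapt.bn.eps) + 0.05
    expected = _hswish(norm)
    got = cascaded_rcam(x, block)
    assert got.ravel()[0] == pytest.approx(expected, abs=1e-9)


def test_composite_outputs_finite_for_extreme_inputs():
    nn.manual_seed(0)
    block = CascadedRCAM(CascadedRCAMSpec(
        in_channels=4, inner=EfficientRCAMSpec(channels=4, group_count=1,
                                               reduction_ratio=2))).eval()
    x = np.array([1e6, -1e6, 1e-6, 0.0] * 4).reshape(1, 4, 2, 2)
    assert np.isfinite(cascaded_rcam(x, block)).all()
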