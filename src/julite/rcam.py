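"""Residual coordinate-attention enhancement units and the compressing tail.

EfficientRCAM applies a depthwise convolution to sharpen fine texture
(crack lines, mold patches, peck edges), then the same channel-then-spatial
attention cascade as :class:`julite.attention.CoordAtt`, with the residual
taken to the depthwise output:

    D   = DepthConv(F_in; K_depth)
    out = gate (.) (s (.) D) + D

CascadedRCAM fuses the enhanced features with the original input and
compresses channels 2x with a ConvBNHSwish adaptation conv:

    out = ConvBNHSwish(F_in + EfficientRCAM(F_in); K_adapt, C/2)

The 2x (rather than the conventional 4x) compression keeps more of the
weak-texture information that low-contrast defects live in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import CoordAtt, CoordAttConfig
from .nn import Tensor

__all__ = [
    "CascadedRCAM", "CascadedRCAMSpec", "ConvBNHSwish", "ConvBNHSwishSpec",
    "EfficientRCAM", "EfficientRCAMSpec", "cascaded_rcam", "conv_bn_hswish",
    "efficient_rcam",
]


@dataclass(frozen=True)
class ConvBNHSwishSpec:
    kernel_size: int
    out_channels: int
    stride: int = 1
    depthwise: bool = False

    def validate(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")


class ConvBNHSwish(nn.Module):
    """Convolution -> batch norm -> hard-swish (conv carries no bias)."""

    def __init__(self, in_channels: int, spec: ConvBNHSwishSpec):
        super().__init__()
        spec.validate()
        if spec.depthwise and spec.out_channels != in_channels:
            raise ValueError("depthwise requires out_channels == in_channels")
        groups = in_channels if spec.depthwise else 1
        self.conv = nn.Conv2d(in_channels, spec.out_channels, spec.kernel_size,
                              stride=spec.stride, groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(spec.out_channels)
        self.act = nn.HSwish()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


@dataclass(frozen=True)
class EfficientRCAMSpec:
    """channels C; depthwise kernel K_depth; gate conv kernel K_g and groups g;
    SE ratio r; optional 1x1 squeeze factor on the attention pathway."""

    channels: int
    depth_kernel: int = 3
    gate_kernel: int = 3
    group_count: int | None = None
    reduction_ratio: int = 4
    internal_compression: int | None = None

    def attention_config(self) -> CoordAttConfig:
        return CoordAttConfig(
            channels=self.channels,
            reduction_ratio=self.reduction_ratio,
            group_count=self.group_count,
            kernel_size=self.gate_kernel,
        )

    def validate(self):
        if self.depth_kernel % 2 == 0:
            raise ValueError("depth_kernel must be odd")
        self.attention_config().validate()
        if self.internal_compression is not None:
            if self.internal_compression < 1 or self.channels % self.internal_compression:
                raise ValueError("internal_compression must divide channels")


class EfficientRCAM(nn.Module):
    """Depthwise feature sharpening + coordinate attention, residual to the
    depthwise output.  Channel count is preserved."""

    def __init__(self, spec: EfficientRCAMSpec):
        super().__init__()
        spec.validate()
        self.spec = spec
        c = spec.channels
        self.depth_conv = nn.Conv2d(c, c, spec.depth_kernel, groups=c, bias=True)
        acfg = spec.attention_config()
        self.fc1 = nn.Linear(c, c // spec.reduction_ratio)
        self.fc2 = nn.Linear(c // spec.reduction_ratio, c)
        if spec.internal_compression:
            cc = c // spec.internal_compression
            self.squeeze = nn.Conv2d(c, cc, 1, bias=False)
            self.gate_conv = nn.Conv2d(cc, cc, spec.gate_kernel,
                                       groups=_divisor_groups(cc, acfg.resolved_groups()),
                                       bias=True)
        else:
            self.squeeze = None
            self.gate_conv = nn.Conv2d(c, c, spec.gate_kernel,
                                       groups=acfg.resolved_groups(), bias=True)
        self.gate_conv.weight.data[:] = 0.0
        self.gate_conv.bias.data[:] = 0.0

    def spatial_gate(self, weighted):
        path = self.squeeze(weighted) if self.squeeze is not None else weighted
        return nn.channel_mean(self.gate_conv(path)).sigmoid()

    def forward(self, x):
        if x.shape[1] != self.spec.channels:
            raise ValueError(f"expected {self.spec.channels} channels, got {x.shape[1]}")
        d = self.depth_conv(x)
        pooled = nn.global_avg_pool(d)
        s = self.fc2(self.fc1(pooled).relu()).sigmoid()
        weighted = s.reshape(s.shape[0], s.shape[1], 1, 1) * d
        gate = self.spatial_gate(weighted)
        return gate * weighted + d


def _divisor_groups(channels: int, wanted: int) -> int:
    g = min(wanted, channels)
    while channels % g:
        g -= 1
    return g


@dataclass(frozen=True)
class CascadedRCAMSpec:
    in_channels: int
    adapt_kernel: int = 1
    inner: EfficientRCAMSpec | None = None

    @property
    def out_channels(self) -> int:
        return self.in_channels // 2

    def validate(self):
        if self.in_channels % 2:
            raise ValueError("in_channels must be even (2x compression)")
        if self.inner is not None and self.inner.channels != self.in_channels:
            raise ValueError("inner unit channels must match in_channels")


class CascadedRCAM(nn.Module):
    """Residual fusion of input and enhanced features, then 2x channel
    compression via ConvBNHSwish; spatial dims unchanged."""

    def __init__(self, spec: CascadedRCAMSpec):
        super().__init__()
        spec.validate()
        self.spec = spec
        inner = spec.inner or EfficientRCAMSpec(channels=spec.in_channels)
        self.rcam = EfficientRCAM(inner)
        self.adapt = ConvBNHSwish(
            spec.in_channels,
            ConvBNHSwishSpec(kernel_size=spec.adapt_kernel,
                             out_channels=spec.out_channels))

    def forward(self, x):
        return self.adapt(x + self.rcam(x))


# -- array-level conveniences ---------------------------------------------

def _run(module: nn.Module, feature_map) -> np.ndarray:
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(np.asarray(feature_map))
    with nn.no_grad():
        return module(x).data


def conv_bn_hswish(feature_map, block: ConvBNHSwish) -> np.ndarray:
    return _run(block, feature_map)


def efficient_rcam(feature_map, block: EfficientRCAM) -> np.ndarray:
    return _run(block, feature_map)


def cascaded_rcam(feature_map, block: CascadedRCAM) -> np.ndarray:
    return _run(block, feature_map)
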