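"""Network assembly: MobileNetV2 stages, selective attention embedding,
the compressing attention tail, and parameter/MAC accounting.

The classifier follows the inverted-residual / linear-bottleneck recipe:
a stride-2 stem (3 -> 32), seven stages of inverted residual blocks with
the channel chain 32 -> 16 -> 24 -> 32 -> 64 -> 96 -> 160 -> 320, then --
instead of the standard 320 -> 1280 pointwise head -- a CascadedRCAM tail
compressing 320 -> 160, global average pooling and a linear head.  A
coordinate-attention block is embedded after the final block of each stage
except the first (selective embedding, mode "a"); mode "b" additionally
embeds attention after the stem, inside every inverted residual (after its
depthwise conv) and after the tail.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .attention import CoordAtt, CoordAttConfig, _default_groups
from .nn import Tensor
from .rcam import (CascadedRCAM, CascadedRCAMSpec, ConvBNHSwish,
                   ConvBNHSwishSpec, EfficientRCAM, EfficientRCAMSpec)

__all__ = [
    "ABLATION_VARIANTS", "InvertedResidual", "JuLiteMobileAtt", "ModelSpec",
    "StageSpec", "TABLE_STAGES", "ablation_spec", "build_ju_lite_mobileatt",
    "build_mobilenetv2_reference", "count_macs", "count_parameters",
    "make_divisible",
]


def make_divisible(value: float, divisor: int = 8) -> int:
    """Round channel counts to multiples of `divisor`, never below it and
    never down by more than 10% (the MobileNet convention)."""
    new = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if new < 0.9 * value:
        new += divisor
    return new


@dataclass(frozen=True)
class StageSpec:
    """One stage of inverted residual blocks.

    `coordatt_block_index` is the 0-based block after which a coordinate
    attention module is inserted (None = no attention in this stage).
    """

    block_count: int
    in_channels: int
    out_channels: int
    expand_ratio: int
    strides: tuple[int, ...]
    coordatt_block_index: int | None = None

    def validate(self):
        if self.block_count != len(self.strides):
            raise ValueError("block_count must equal len(strides)")
        if self.coordatt_block_index is not None and not (
                0 <= self.coordatt_block_index < self.block_count):
            raise ValueError("coordatt_block_index out of range")
        if any(s not in (1, 2) for s in self.strides):
            raise ValueError("strides must be 1 or 2")


#: The seven-stage configuration: (blocks, in, out, expand, strides,
#: attention position = final block of every stage except the first).
TABLE_STAGES: tuple[StageSpec, ...] = (
    StageSpec(1, 32, 16, 1, (1,), None),
    StageSpec(2, 16, 24, 6, (2, 1), 1),
    StageSpec(3, 24, 32, 6, (2, 1, 1), 2),
    StageSpec(4, 32, 64, 6, (2, 1, 1, 1), 3),
    StageSpec(3, 64, 96, 6, (1, 1, 1), 2),
    StageSpec(3, 96, 160, 6, (2, 1, 1), 2),
    StageSpec(1, 160, 320, 6, (1,), 0),
)


@dataclass(frozen=True)
class AttentionDefaults:
    """Frozen hyperparameters of the embedded coordinate-attention blocks."""

    reduction_ratio: int = 4
    group_width: int = 8          # channels per group of the gate conv
    kernel_size: int = 5


@dataclass(frozen=True)
class TailDefaults:
    """Frozen hyperparameters of the compressing attention tail."""

    adapt_kernel: int = 1
    depth_kernel: int = 3
    gate_kernel: int = 3
    group_width: int = 8
    reduction_ratio: int = 8
    internal_compression: int | None = 2


@dataclass(frozen=True)
class ModelSpec:
    num_classes: int = 6
    width_multiplier: float = 1.0
    stem_channels: int = 32
    stages: tuple[StageSpec, ...] = TABLE_STAGES
    attention: AttentionDefaults = field(default_factory=AttentionDefaults)
    tail: TailDefaults = field(default_factory=TailDefaults)
    enable_coordatt: bool = True
    enable_efficient_rcam: bool = True
    enable_cascaded_rcam: bool = True
    embedding_mode: str = "a"

    def validate(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.embedding_mode not in ("a", "b"):
            raise ValueError("embedding_mode must be 'a' or 'b'")
        chain_in = self.stem_channels
        for st in self.stages:
            st.validate()
            if st.in_channels != chain_in:
                raise ValueError(
                    f"stage input channels {st.in_channels} break the chain "
                    f"(expected {chain_in})")
            chain_in = st.out_channels

    def scaled(self, channels: int) -> int:
        if self.width_multiplier == 1.0:
            return channels
        return make_divisible(channels * self.width_multiplier)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = [asdict(s) for s in self.stages]
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(
                StageSpec(**{**s, "strides": tuple(s["strides"])}) for s in d["stages"])
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = AttentionDefaults(**d["attention"])
        if "tail" in d and isinstance(d["tail"], dict):
            d["tail"] = TailDefaults(**d["tail"])
        return ModelSpec(**d)


def _fit_ratio(channels: int, ratio: int) -> int:
    r = min(ratio, channels)
    while channels % r:
        r -= 1
    return r


def _att_config(channels: int, att: AttentionDefaults) -> CoordAttConfig:
    return CoordAttConfig(
        channels=channels,
        reduction_ratio=_fit_ratio(channels, att.reduction_ratio),
        group_count=_default_groups(channels, att.group_width),
        kernel_size=att.kernel_size,
    )


class ConvBNReLU6(nn.Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, groups=1):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, kernel_size,
                              stride=stride, groups=groups, bias=False)
        self.bn = nn.BatchNorm2d(out_channels)
        self.act = nn.ReLU6()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class InvertedResidual(nn.Module):
    """1x1 expand -> 3x3 depthwise (stride) -> 1x1 linear project, with an
    identity skip when stride 1 and matching channels.  `inner_attention`
    (embedding mode "b") inserts coordinate attention after the depthwise
    conv, at the expanded channel count."""

    def __init__(self, in_channels: int, out_channels: int, expand_ratio: int,
                 stride: int, inner_attention: AttentionDefaults | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        hidden = in_channels * expand_ratio
        self.use_skip = stride == 1 and in_channels == out_channels
        self.expand = (ConvBNReLU6(in_channels, hidden, 1)
                       if expand_ratio != 1 else nn.Identity())
        self.depthwise = ConvBNReLU6(hidden, hidden, 3, stride=stride, groups=hidden)
        self.inner_att = (CoordAtt(_att_config(hidden, inner_attention))
                          if inner_attention is not None else nn.Identity())
        self.project = nn.Conv2d(hidden, out_channels, 1, bias=False)
        self.project_bn = nn.BatchNorm2d(out_channels)

    def forward(self, x):
        y = self.depthwise(self.expand(x))
        y = self.inner_att(y)
        y = self.project_bn(self.project(y))
        return y + x if self.use_skip else y


def inverted_residual(feature_map, in_channels, out_channels, expand_ratio,
                      stride) -> np.ndarray:
    """One-off inverted residual application (array in, array out)."""
    block = InvertedResidual(in_channels, out_channels, expand_ratio, stride)
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(np.asarray(feature_map))
    with nn.no_grad():
        return block(x).data


def _build_stages(spec: ModelSpec, with_attention: bool) -> nn.Sequential:
    inner = spec.attention if (with_attention and spec.embedding_mode == "b") else None
    stages = []
    for st in spec.stages:
        blocks = []
        c_in = spec.scaled(st.in_channels)
        c_out = spec.scaled(st.out_channels)
        for b, stride in enumerate(st.strides):
            blocks.append(InvertedResidual(
                c_in if b == 0 else c_out, c_out, st.expand_ratio, stride,
                inner_attention=inner))
            if with_attention and st.coordatt_block_index == b:
                blocks.append(CoordAtt(_att_config(c_out, spec.attention)))
        stages.append(nn.Sequential(*blocks))
    return nn.Sequential(*stages)


class JuLiteMobileAtt(nn.Module):
    """The full lightweight attention classifier (ablation-configurable)."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        spec.validate()
        self.spec = spec
        stem_c = spec.scaled(spec.stem_channels)
        self.stem = ConvBNHSwish(3, ConvBNHSwishSpec(3, stem_c, stride=2))
        self.stem_att = (CoordAtt(_att_config(stem_c, spec.attention))
                         if spec.enable_coordatt and spec.embedding_mode == "b"
                         else nn.Identity())
        self.stages = _build_stages(spec, with_attention=spec.enable_coordatt)
        c_last = spec.scaled(spec.stages[-1].out_channels)
        c_feat = c_last // 2
        t = spec.tail
        rcam_spec = EfficientRCAMSpec(
            channels=c_last, depth_kernel=t.depth_kernel, gate_kernel=t.gate_kernel,
            group_count=_default_groups(c_last, t.group_width),
            reduction_ratio=_fit_ratio(c_last, t.reduction_ratio),
            internal_compression=t.internal_compression)
        adapt_spec = ConvBNHSwishSpec(t.adapt_kernel, c_feat)
        if spec.enable_cascaded_rcam:
            self.tail = CascadedRCAM(CascadedRCAMSpec(
                in_channels=c_last, adapt_kernel=t.adapt_kernel, inner=rcam_spec))
        elif spec.enable_efficient_rcam:
            self.tail = nn.Sequential(EfficientRCAM(rcam_spec),
                                      ConvBNHSwish(c_last, adapt_spec))
        else:
            self.tail = ConvBNHSwish(c_last, adapt_spec)
        self.tail_att = (CoordAtt(_att_config(c_feat, spec.attention))
                         if spec.enable_coordatt and spec.embedding_mode == "b"
                         else nn.Identity())
        self.classifier = nn.Linear(c_feat, spec.num_classes)
        self.feature_channels = c_feat

    def features(self, x: Tensor) -> Tensor:
        """Final convolutional representation (the Grad-CAM target)."""
        y = self.stem_att(self.stem(x))
        y = self.stages(y)
        return self.tail_att(self.tail(y))

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(nn.global_avg_pool(self.features(x)))


class MobileNetV2Reference(nn.Module):
    """Standard width-1.0 MobileNetV2: stem, the seven stages, 1x1 conv
    320 -> 1280, pooled linear head."""

    def __init__(self, num_classes: int = 6):
        super().__init__()
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        spec = ModelSpec(num_classes=num_classes, enable_coordatt=False)
        self.stem = ConvBNReLU6(3, 32, 3, stride=2)
        self.stages = _build_stages(spec, with_attention=False)
        self.head_conv = ConvBNReLU6(320, 1280, 1)
        self.classifier = nn.Linear(1280, num_classes)

    def features(self, x: Tensor) -> Tensor:
        return self.head_conv(self.stages(self.stem(x)))

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(nn.global_avg_pool(self.features(x)))


def build_ju_lite_mobileatt(spec: ModelSpec | None = None,
                            seed: int | None = None) -> JuLiteMobileAtt:
    if seed is not None:
        nn.manual_seed(seed)
    return JuLiteMobileAtt(spec or ModelSpec())


def build_mobilenetv2_reference(num_classes: int = 6,
                                seed: int | None = None) -> MobileNetV2Reference:
    if seed is not None:
        nn.manual_seed(seed)
    return MobileNetV2Reference(num_classes)


ABLATION_VARIANTS = ("baseline", "efficient_rcam", "cascaded_rcam", "all")


def ablation_spec(variant: str, **overrides) -> ModelSpec:
    """Model spec for one ablation variant.

    baseline:       no attention, plain compressing tail conv
    efficient_rcam: enhancement unit at the tail, no residual fusion wrapper
    cascaded_rcam:  full residual-fusion tail, no stage attention
    all:            stage attention + full tail (the default model)
    """
    flags = {
        "baseline": dict(enable_coordatt=False, enable_efficient_rcam=False,
                         enable_cascaded_rcam=False),
        "efficient_rcam": dict(enable_coordatt=False, enable_efficient_rcam=True,
                               enable_cascaded_rcam=False),
        "cascaded_rcam": dict(enable_coordatt=False, enable_efficient_rcam=True,
                              enable_cascaded_rcam=True),
        "all": dict(enable_coordatt=True, enable_efficient_rcam=True,
                    enable_cascaded_rcam=True),
    }
    if variant not in flags:
        raise ValueError(f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    return replace(ModelSpec(**overrides), **flags[variant])


def count_parameters(model: nn.Module) -> int:
    """Total size of all trainable arrays."""
    return int(sum(p.data.size for p in model.parameters()))


def count_macs(model: nn.Module, input_hw: tuple[int, int] = (224, 224)) -> float:
    """Multiply-accumulate count of one forward pass on a 3-channel input.

    Convolution layers contribute K*K*(C_in/groups)*C_out*H_out*W_out, linear
    layers in*out; other ops are not counted (the convention of the
    lightweight-CNN literature's "FLOPs (G)" columns).
    """
    was_training = next(iter(model.modules())).training
    model.eval()
    h, w = input_hw
    with nn.no_grad():
        model(Tensor(np.zeros((1, 3, h, w), dtype=np.float32)))
    total = 0
    for m in model.modules():
        if isinstance(m, (nn.Conv2d, nn.Linear)):
            total += m.macs()
    if was_training:
        model.train()
    return float(total)


def model_stats(model: nn.Module, input_hw=(224, 224)) -> dict:
    return {
        "params": count_parameters(model),
        "params_m": round(count_parameters(model) / 1e6, 2),
        "macs": count_macs(model, input_hw),
        "macs_g": round(count_macs(model, input_hw) / 1e9, 2),
    }
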