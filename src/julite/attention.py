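"""Two-stage coordinate attention (channel-then-spatial) for defect features.

The block first rescales channels with a squeeze-and-excitation (SE)
bottleneck, separating defect-related channels from background texture, then
applies a grouped-convolution spatial gate: a K x K grouped conv on the
channel-weighted features, averaged over channels and squashed through a
sigmoid, yields a single-channel map that localizes direction-sensitive
structure (e.g. linear cracks, peck clusters).  A residual connection
preserves the original features:

    out = gate (.) (s (.) F) + F,
    s    = sigmoid(FC2(ReLU(FC1(avgpool(F))))),
    gate = sigmoid(mean_c(GroupConv(s (.) F; K, g)))

With the gate convolution zero-initialized the spatial gate is exactly 0.5
everywhere, so the block starts training as a mild residual amplifier
(out = F + 0.5 s F), stabilizing early optimization of deep stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.functional import hswish  # re-exported: the activation used throughout

__all__ = ["CoordAtt", "CoordAttConfig", "coordatt_forward", "hswish", "se_weights"]


def _default_groups(channels: int, target_group_width: int = 8) -> int:
    """Largest group count giving ~`target_group_width` channels per group."""
    g = max(channels // target_group_width, 1)
    while channels % g:
        g -= 1
    return g


@dataclass(frozen=True)
class CoordAttConfig:
    """Hyperparameters of one coordinate-attention block.

    reduction_ratio: SE bottleneck ratio r (FC1: C -> C/r, FC2: C/r -> C).
    group_count:     groups g of the spatial gate conv; None -> C/8 clamped
                     to a divisor of C.
    kernel_size:     odd K of the gate conv.
    zero_init_gate:  start the gate conv at zero (gate = 0.5 everywhere).
    """

    channels: int
    reduction_ratio: int = 4
    group_count: int | None = None
    kernel_size: int = 5
    zero_init_gate: bool = True

    def resolved_groups(self) -> int:
        return self.group_count if self.group_count is not None else _default_groups(self.channels)

    def validate(self) -> None:
        c, r, g, k = self.channels, self.reduction_ratio, self.resolved_groups(), self.kernel_size
        if c < 1 or r < 1 or c % r:
            raise ValueError(f"reduction_ratio {r} must divide channels {c}")
        if c % g:
            raise ValueError(f"group_count {g} must divide channels {c}")
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {k}")


class CoordAtt(nn.Module):
    """SE channel weighting cascaded with a grouped-conv spatial gate."""

    def __init__(self, cfg: CoordAttConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c, r = cfg.channels, cfg.reduction_ratio
        self.fc1 = nn.Linear(c, c // r)
        self.fc2 = nn.Linear(c // r, c)
        self.gate_conv = nn.Conv2d(c, c, cfg.kernel_size, stride=1,
                                   groups=cfg.resolved_groups(), bias=True)
        if cfg.zero_init_gate:
            self.gate_conv.weight.data[:] = 0.0
            self.gate_conv.bias.data[:] = 0.0

    def channel_weights(self, x: Tensor) -> Tensor:
        """SE weights s in (0,1), shape (N, C)."""
        pooled = nn.global_avg_pool(x)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def spatial_gate(self, weighted: Tensor) -> Tensor:
        """Single-channel gate in (0,1), shape (N, 1, H, W)."""
        return nn.channel_mean(self.gate_conv(weighted)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        s = self.channel_weights(x)
        weighted = s.reshape(s.shape[0], s.shape[1], 1, 1) * x
        gate = self.spatial_gate(weighted)
        return gate * weighted + x


def se_weights(feature_map: np.ndarray | Tensor, block: CoordAtt) -> np.ndarray:
    """Per-(sample, channel) SE weights of `block` on `feature_map`."""
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(np.asarray(feature_map))
    with nn.no_grad():
        return block.channel_weights(x).data


def coordatt_forward(feature_map: np.ndarray | Tensor, block: CoordAtt) -> np.ndarray:
    """Apply a coordinate-attention block; array in, array out."""
    x = feature_map if isinstance(feature_map, Tensor) else Tensor(np.asarray(feature_map))
    with nn.no_grad():
        return block(x).data
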