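"""Multi-scale context blocks: ASPP and the CBAM-ASPP bottleneck.

ASPP (atrous spatial pyramid pooling) runs parallel 3x3 convolutions at
several dilation rates — default [1, 2, 4, 8] — over the same input,
concatenates the branch outputs along channels and fuses them with a 1x1
convolution (batch norm + ReLU).  A dilation rate r gives an effective
receptive field of 3 + 2*(r-1) per branch without extra parameters.

CBAM-ASPP is ASPP followed by CBAM refinement; it sits at the encoder/
decoder junction of the segmentation network to inject multi-scale context
before up-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks_attention import Cbam
from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential, Tensor, concat

__all__ = ["AsppConfig", "Aspp", "CbamAspp"]


@dataclass(frozen=True)
class AsppConfig:
    in_channels: int
    out_channels: int
    rates: tuple[int, ...] = (1, 2, 4, 8)
    branch_channels: int | None = None      # default: in_channels // len(rates)
    global_pool_branch: bool = False        # classic DeepLab image-level branch

    def __post_init__(self):
        if not self.rates:
            raise ValueError("rates must be non-empty")
        if any(r <= 0 for r in self.rates):
            raise ValueError(f"dilation rates must be positive, got {self.rates}")
        if list(self.rates) != sorted(set(self.rates)):
            raise ValueError("rates must be strictly increasing")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")

    @property
    def resolved_branch_channels(self) -> int:
        if self.branch_channels is not None:
            return self.branch_channels
        return max(self.in_channels // len(self.rates), 1)


class Aspp(Module):
    """Parallel dilated 3x3 branches, channel concat, 1x1 fusion conv."""

    def __init__(self, cfg: AsppConfig, *, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        bc = cfg.resolved_branch_channels
        mods = []
        for r in cfg.rates:
            mods.append(Sequential(
                Conv2d(cfg.in_channels, bc, 3, dilation=r, padding="same",
                       bias=False, rng=rng),
                BatchNorm2d(bc), ReLU()))
        self.branches = Sequential(*mods)
        n_merge = bc * len(cfg.rates) + (bc if cfg.global_pool_branch else 0)
        if cfg.global_pool_branch:
            self.pool_proj = Sequential(
                Conv2d(cfg.in_channels, bc, 1, bias=False, rng=rng),
                BatchNorm2d(bc), ReLU())
        self.fuse = Sequential(
            Conv2d(n_merge, cfg.out_channels, 1, bias=False, rng=rng),
            BatchNorm2d(cfg.out_channels), ReLU())

    def forward(self, x: Tensor) -> Tensor:
        outs = [branch(x) for branch in self.branches.mods]
        if self.cfg.global_pool_branch:
            B, C, H, W = x.shape
            pooled = x.mean(axis=(2, 3), keepdims=True)
            proj = self.pool_proj(pooled)
            ones = Tensor(np.ones((1, 1, H, W), np.float32))
            outs.append(proj * ones)
        return self.fuse(concat(outs, axis=1))


class CbamAspp(Module):
    """ASPP followed by CBAM channel/spatial refinement."""

    def __init__(self, cfg: AsppConfig, *, cbam_reduction: int = 16,
                 spatial_first: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.aspp = Aspp(cfg, rng=rng)
        self.cbam = Cbam(cfg.out_channels, cbam_reduction,
                         spatial_first=spatial_first, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cbam(self.aspp(x))
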