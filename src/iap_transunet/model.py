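"""The IAP-TransUNet segmentation network.

A U-shaped hybrid: a ResNet-50-style CNN pyramid (optionally gated by ECA
after every stage) produces skips at 1/2, 1/4 and 1/8 resolution and a
1/16 feature map; the 1/16 map is tokenised, positionally encoded and run
through a 12-layer transformer encoder; the tokens are folded back to a
map, refined by a CBAM-ASPP bottleneck, and decoded by four cascaded
(bilinear up-sample -> skip concat -> 3x3 conv) stages whose convolutions
are depthwise-separable when ``use_dsc`` is set; a 3x3 convolution maps the
full-resolution features to per-class logits.

The three boolean toggles (``use_eca``, ``use_cbam_aspp``, ``use_dsc``) are
independent; all off reproduces the TransUNet baseline and all on the full
model, with the six intermediate combinations forming the structural
ablation grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .blocks_attention import EcaAttention, EcaConfig
from .blocks_multiscale import AsppConfig, CbamAspp
from .blocks_sepconv import DepthwiseSeparableConv2d
from .nn import (BatchNorm2d, Conv2d, GroupNorm2d, Identity, LayerNorm, Module,
                 ReLU, Sequential, Tensor, concat, upsample_bilinear)
from .vit_core import EncoderConfig, TransformerEncoder, sinusoidal_pe

__all__ = ["ModelConfig", "IapTransUNet", "build_model", "PRESETS"]

#: encoder presets: (embedding dim, MLP hidden dim, attention heads).
#: "paper-text" follows the stated dims (512 / 2048); 512 does not divide by
#: 12, so this preset runs 8 heads (d_head 64). "wide" is the ViT-Base-like
#: 768 / 3072 with 12 heads.
PRESETS = {
    "paper-text": (512, 2048, 8),
    "wide": (768, 3072, 12),
}

_RESNET_BLOCKS = (3, 4, 6, 3)           # bottleneck blocks per stage
_RESNET_WIDTHS = (256, 512, 1024, 2048)  # stage output channels at width 1.0
_STEM_WIDTH = 64


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int
    in_channels: int = 3
    input_size: int = 256
    patch_size: int = 16
    preset: str = "paper-text"
    n_layers: int = 12
    decoder_channels: tuple[int, ...] = (256, 128, 64, 16)
    use_eca: bool = True
    use_cbam_aspp: bool = True
    use_dsc: bool = True
    width_multiplier: float = 1.0
    aspp_rates: tuple[int, ...] = (1, 2, 4, 8)
    cbam_reduction: int = 16
    cbam_spatial_first: bool = False
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    first_decoder_groups: int | None = None   # None = full depthwise
    eca_placement: str = "stage"              # "stage" | "block" (encoder CNN)
    dropout: float = 0.1
    norm: str = "batch"                       # "batch" | "group"
    pos_encoding: str = "sinusoidal"          # "sinusoidal" | "learned"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}, "
                             f"got {self.preset!r}")
        if self.patch_size != 16:
            raise ValueError("patch_size: the CNN pyramid tokenises at 1/16, "
                             "so patch_size must be 16")
        if self.input_size % self.patch_size:
            raise ValueError(f"input_size ({self.input_size}) must be divisible "
                             f"by patch_size ({self.patch_size})")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder_channels must list the four stage widths")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.norm not in ("batch", "group"):
            raise ValueError(f"norm must be 'batch' or 'group', got {self.norm!r}")
        if self.eca_placement not in ("stage", "block"):
            raise ValueError(f"eca_placement must be 'stage' or 'block', "
                             f"got {self.eca_placement!r}")

    # -- resolved (width-scaled) dimensions -------------------------------
    def _scale(self, c: int) -> int:
        return max(int(round(c * self.width_multiplier)), 1)

    @property
    def embed_dim(self) -> int:
        dim, _, heads = PRESETS[self.preset]
        scaled = self._scale(dim)
        return max(round(scaled / heads), 1) * heads

    @property
    def mlp_dim(self) -> int:
        return self._scale(PRESETS[self.preset][1])

    @property
    def n_heads(self) -> int:
        return PRESETS[self.preset][2]

    @property
    def stem_width(self) -> int:
        return self._scale(_STEM_WIDTH)

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(self._scale(w) for w in _RESNET_WIDTHS)

    @property
    def decoder_widths(self) -> tuple[int, ...]:
        # the multiplier thins the backbone and transformer only; the decoder
        # ladder is an explicit config field and is used as given
        return tuple(self.decoder_channels)

    @property
    def n_tokens(self) -> int:
        return (self.input_size // self.patch_size) ** 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("decoder_channels", "aspp_rates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _norm(cfg: ModelConfig, channels: int) -> Module:
    return BatchNorm2d(channels) if cfg.norm == "batch" else GroupNorm2d(channels)


class _Bottleneck(Module):
    """ResNet bottleneck: 1x1 reduce -> 3x3 -> 1x1 expand, residual add."""

    def __init__(self, cfg: ModelConfig, in_ch: int, out_ch: int, *,
                 stride: int = 1, rng: np.random.Generator):
        super().__init__()
        mid = max(out_ch // 4, 1)
        self.conv1 = Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn1 = _norm(cfg, mid)
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, padding=1, bias=False,
                            rng=rng)
        self.bn2 = _norm(cfg, mid)
        self.conv3 = Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.bn3 = _norm(cfg, out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, padding=0, bias=False,
                       rng=rng),
                _norm(cfg, out_ch))
        else:
            self.proj = Identity()

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        return (y + self.proj(x)).relu()


class _ConvBlock(Module):
    """Decoder 3x3 conv (standard or depthwise-separable) + norm + ReLU,
    optionally followed by an ECA gate."""

    def __init__(self, cfg: ModelConfig, in_ch: int, out_ch: int, *,
                 groups: int | None = None, rng: np.random.Generator):
        super().__init__()
        if cfg.use_dsc:
            self.conv = DepthwiseSeparableConv2d(in_ch, out_ch, 3,
                                                 groups=groups, rng=rng)
        else:
            self.conv = Conv2d(in_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn = _norm(cfg, out_ch)
        self.eca = (EcaAttention(out_ch, EcaConfig(cfg.eca_gamma, cfg.eca_b),
                                 rng=rng)
                    if cfg.use_eca else Identity())

    def forward(self, x: Tensor) -> Tensor:
        return self.eca(self.bn(self.conv(x)).relu())


class IapTransUNet(Module):
    """Full encoder-transformer-decoder segmentation network."""

    def __init__(self, cfg: ModelConfig, *, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        eca_cfg = EcaConfig(cfg.eca_gamma, cfg.eca_b)

        # --- CNN pyramid -------------------------------------------------
        w0, stages = cfg.stem_width, cfg.stage_widths
        self.stem = Sequential(
            Conv2d(cfg.in_channels, w0, 7, stride=2, padding=3, bias=False,
                   rng=rng),
            _norm(cfg, w0), ReLU())
        stage_mods = []
        eca_mods = [EcaAttention(w0, eca_cfg, rng=rng) if cfg.use_eca
                    else Identity()]
        per_block = cfg.use_eca and cfg.eca_placement == "block"
        in_ch = w0
        for si, (n_blocks, out_ch) in enumerate(zip(_RESNET_BLOCKS, stages)):
            stride = 2 if si < 3 else 1     # stage 4 stays at 1/16
            blocks: list[Module] = []
            for bi in range(n_blocks):
                blocks.append(_Bottleneck(cfg, in_ch if bi == 0 else out_ch,
                                          out_ch,
                                          stride=stride if bi == 0 else 1,
                                          rng=rng))
                if per_block:
                    blocks.append(EcaAttention(out_ch, eca_cfg, rng=rng))
            stage_mods.append(Sequential(*blocks))
            eca_mods.append(EcaAttention(out_ch, eca_cfg, rng=rng)
                            if cfg.use_eca and not per_block else Identity())
            in_ch = out_ch
        self.stages = Sequential(*stage_mods)
        self.stage_eca = Sequential(*eca_mods)

        # --- tokenisation + transformer ----------------------------------
        dim = cfg.embed_dim
        self.patch_embed = Conv2d(stages[-1], dim, 1, bias=True, rng=rng)
        if cfg.pos_encoding == "learned":
            self.pos_table = Tensor(
                (rng.standard_normal((1, cfg.n_tokens, dim)) * 0.02)
                .astype(np.float32), requires_grad=True)
        else:
            self.pos_table = Tensor(sinusoidal_pe(cfg.n_tokens, dim)[None])
        enc_cfg = EncoderConfig(dim=dim, n_layers=cfg.n_layers,
                                n_heads=cfg.n_heads, mlp_dim=cfg.mlp_dim,
                                dropout=cfg.dropout)
        self.encoder = TransformerEncoder(enc_cfg, rng=rng)
        self.final_norm = LayerNorm(dim)  # closing LN of the pre-norm stack

        # --- bottleneck ---------------------------------------------------
        if cfg.use_cbam_aspp:
            self.neck = CbamAspp(
                AsppConfig(in_channels=dim, out_channels=dim,
                           rates=tuple(cfg.aspp_rates)),
                cbam_reduction=cfg.cbam_reduction,
                spatial_first=cfg.cbam_spatial_first, rng=rng)
        else:
            self.neck = Identity()

        # --- decoder ------------------------------------------------------
        dec = cfg.decoder_widths
        skip_ch = [stages[1], stages[0], w0]   # at 1/8, 1/4, 1/2
        self.conv_head = _ConvBlock(cfg, dim, dec[0],
                                    groups=cfg.first_decoder_groups, rng=rng)
        outs = [dec[1], dec[2], dec[3], dec[3]]
        ins = [dec[0] + skip_ch[0], dec[1] + skip_ch[1],
               dec[2] + skip_ch[2], dec[3]]
        self.decoder_blocks = Sequential(
            *[_ConvBlock(cfg, ci, co, rng=rng) for ci, co in zip(ins, outs)])

        # --- segmentation head -------------------------------------------
        self.seg_head = Conv2d(dec[3], cfg.num_classes, 3, padding=1, bias=True,
                               rng=rng)

    # -- pipeline stages --------------------------------------------------
    def hybrid_encode(self, image: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Image -> (transformer tokens, [skip 1/2, skip 1/4, skip 1/8])."""
        B, C, H, W = image.shape
        if H != self.cfg.input_size or W != self.cfg.input_size:
            raise ValueError(f"input spatial size {(H, W)} does not match "
                             f"configured input_size {self.cfg.input_size}")
        if C != self.cfg.in_channels:
            raise ValueError(f"input has {C} channels, config expects "
                             f"{self.cfg.in_channels}")
        x = self.stage_eca.mods[0](self.stem(image))
        skips = [x]                                    # 1/2
        for i, stage in enumerate(self.stages.mods):
            x = self.stage_eca.mods[i + 1](stage(x))
            if i < 2:
                skips.append(x)                        # 1/4, 1/8
        feat = self.patch_embed(x)                     # (B, dim, H/16, W/16)
        Bf, D, h, w = feat.shape
        tokens = feat.reshape(Bf, D, h * w).transpose(0, 2, 1)
        tokens = tokens + self.pos_table
        tokens = self.final_norm(self.encoder(tokens))
        return tokens, skips[::-1]                     # [1/8, 1/4, 1/2]

    def bottleneck(self, tokens: Tensor) -> Tensor:
        """Fold tokens back to a map and refine with CBAM-ASPP (if enabled)."""
        B, N, D = tokens.shape
        side = int(round(np.sqrt(N)))
        if side * side != N:
            raise ValueError(f"token count {N} is not a perfect square")
        fmap = tokens.transpose(0, 2, 1).reshape(B, D, side, side)
        return self.neck(fmap)

    def decode(self, bottom: Tensor, skips: list[Tensor]) -> Tensor:
        """Cascaded up-sampling with skip fusion back to full resolution."""
        x = self.conv_head(bottom)
        for i, block in enumerate(self.decoder_blocks.mods):
            x = upsample_bilinear(x, 2)
            if i < len(skips):
                x = concat([x, skips[i]], axis=1)
            x = block(x)
        return x

    def forward(self, image: Tensor) -> Tensor:
        """(B, C, H, W) image -> (B, num_classes, H, W) logits."""
        tokens, skips = self.hybrid_encode(image)
        return self.seg_head(self.decode(self.bottleneck(tokens), skips))


def build_model(cfg: ModelConfig, *, seed: int = 0) -> IapTransUNet:
    """Instantiate the network from a config with seeded initialisation."""
    return IapTransUNet(cfg, seed=seed)
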