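"""The DHMF-MLP segmentation network: encoder, HMSF bottleneck, decoder,
the six ablation variants, parameter counting, and checkpoint I/O.

The U-shaped layout follows the UNeXt convention the architecture extends:
three convolutional encoder stages (3x3 conv + batch norm + ReLU + 2x2 max
pool) followed by two stages of strided overlapped patch embedding with a
tokenized-MLP block, at channel widths (32, 64, 128, 160, 256). The encoder
pyramid feeds both the skip connections and the HMSF bottleneck; the decoder
up-samples bilinearly, merges each skip by channel concatenation + 1x1
projection, and mirrors the encoder (Tok-MLP blocks on the two deepest
decoder stages, plain convolutions below).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from . import nn
from .blocks import TokMLPBlock
from .hmsf import HMSF
from .nn import engine
from .nn.engine import Tensor, as_tensor

VARIANTS = ("full", "no_axial", "no_lp_no_axial", "no_asam", "no_dsla", "backbone_only")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    channels : per-stage widths C1..C5.
    tok_hidden : token embedding width inside Tok-MLP blocks.
    grid_d : grid size of the axial MLP (d x d tiles).
    input_size : (H, W); must be divisible by 32 (five halvings).
    """

    channels: tuple[int, ...] = (32, 64, 128, 160, 256)
    tok_hidden: int = 768
    grid_d: int = 8
    in_channels: int = 3
    num_classes: int = 1
    input_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input size ({h},{w}) must be divisible by 32")
        if len(self.channels) != 5:
            raise ValueError("exactly five channel widths are required")

    def scaled(self, divisor: int) -> "ModelConfig":
        """Width-reduced copy (channels and token width divided)."""
        return ModelConfig(channels=tuple(c // divisor for c in self.channels),
                           tok_hidden=self.tok_hidden // divisor,
                           grid_d=self.grid_d, in_channels=self.in_channels,
                           num_classes=self.num_classes, input_size=self.input_size)

    def to_dict(self) -> dict:
        return {"channels": list(self.channels), "tok_hidden": self.tok_hidden,
                "grid_d": self.grid_d, "in_channels": self.in_channels,
                "num_classes": self.num_classes, "input_size": list(self.input_size)}

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(channels=tuple(d["channels"]), tok_hidden=d["tok_hidden"],
                           grid_d=d["grid_d"], in_channels=d["in_channels"],
                           num_classes=d["num_classes"], input_size=tuple(d["input_size"]))


@dataclass(frozen=True)
class AblationSpec:
    """Which named components are active.

    ``full`` keeps everything; ``no_axial`` keeps only ASAM inside DSLA
    (learnable mu); ``no_lp_no_axial`` keeps ASAM with mu fixed at 0.5 (no
    learnable scalar); ``no_asam`` keeps only the axial MLP; ``no_dsla``
    keeps the fusion plumbing with every DSLA call replaced by the identity;
    ``backbone_only`` drops HMSF entirely (the decoder consumes f5).
    """

    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"valid names: {', '.join(VARIANTS)}")

    @property
    def with_hmsf(self) -> bool:
        return self.variant != "backbone_only"

    @property
    def with_dsla(self) -> bool:
        return self.variant not in ("backbone_only", "no_dsla")

    @property
    def with_asam(self) -> bool:
        return self.variant in ("full", "no_axial", "no_lp_no_axial")

    @property
    def with_axial(self) -> bool:
        return self.variant in ("full", "no_asam")

    @property
    def learnable_mu(self) -> bool:
        return self.variant != "no_lp_no_axial"


class _ConvStage(nn.Module):
    """3x3 conv + BN + ReLU + 2x2 max pool."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, rng, padding=1)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x):
        return engine.block_maxpool(engine.relu(self.bn(self.conv(x))), 2, 2)


class _PatchEmbed(nn.Module):
    """Overlapped patch embedding: 3x3 conv, stride 2, + layer norm."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, rng, stride=2, padding=1)
        self.norm = nn.LayerNorm2d(c_out)

    def forward(self, x):
        return self.norm(self.conv(x))


class Encoder(nn.Module):
    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        c = config.channels
        self.stage1 = _ConvStage(config.in_channels, c[0], rng)
        self.stage2 = _ConvStage(c[0], c[1], rng)
        self.stage3 = _ConvStage(c[1], c[2], rng)
        self.embed4 = _PatchEmbed(c[2], c[3], rng)
        self.tok4 = TokMLPBlock(c[3], rng, hidden=config.tok_hidden)
        self.embed5 = _PatchEmbed(c[3], c[4], rng)
        self.tok5 = TokMLPBlock(c[4], rng, hidden=config.tok_hidden)
        self.config = config

    def forward(self, image) -> list[Tensor]:
        image = as_tensor(image)
        b, c, h, w = image.shape
        if c != self.config.in_channels or (h, w) != tuple(self.config.input_size):
            raise ValueError(f"expected ({self.config.in_channels},"
                             f"{self.config.input_size[0]},{self.config.input_size[1]}) "
                             f"input, got ({c},{h},{w})")
        f1 = self.stage1(image)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.tok4(self.embed4(f3))
        f5 = self.tok5(self.embed5(f4))
        return [f1, f2, f3, f4, f5]


class _UpStage(nn.Module):
    """Bilinear x2 up-sampling, 3x3 conv + BN + ReLU, optional skip merge by
    concatenation + 1x1 projection, optional Tok-MLP refinement."""

    def __init__(self, c_in: int, c_out: int, rng, merge_skip: bool,
                 tok_hidden: int | None, name: str):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, rng, padding=1)
        self.bn = nn.BatchNorm2d(c_out)
        self.merge = nn.Conv2d(2 * c_out, c_out, 1, rng) if merge_skip else None
        self.tok = TokMLPBlock(c_out, rng, hidden=tok_hidden) if tok_hidden else None
        self.name = name

    def forward(self, x, skip=None):
        x = engine.relu(self.bn(self.conv(engine.upsample_bilinear2x(x))))
        if self.merge is not None:
            if skip is None or skip.shape != x.shape:
                got = None if skip is None else tuple(skip.shape)
                raise ValueError(f"decoder stage {self.name}: skip shape {got} "
                                 f"does not match {tuple(x.shape)}")
            x = self.merge(engine.concat([x, skip], axis=1))
        if self.tok is not None:
            x = self.tok(x)
        return x


class Decoder(nn.Module):
    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        c = config.channels
        th = config.tok_hidden
        self.up1 = _UpStage(c[4], c[3], rng, True, th, "up1 (skip f4)")
        self.up2 = _UpStage(c[3], c[2], rng, True, th, "up2 (skip f3)")
        self.up3 = _UpStage(c[2], c[1], rng, True, None, "up3 (skip f2)")
        self.up4 = _UpStage(c[1], c[0], rng, True, None, "up4 (skip f1)")
        self.up5 = _UpStage(c[0], c[0], rng, False, None, "up5")
        self.head = nn.Conv2d(c[0], config.num_classes, 1, rng)

    def forward(self, bottleneck, skips) -> Tensor:
        f1, f2, f3, f4 = skips[:4]
        x = self.up1(bottleneck, f4)
        x = self.up2(x, f3)
        x = self.up3(x, f2)
        x = self.up4(x, f1)
        x = self.up5(x)
        return self.head(x)


class DHMFMLP(nn.Module):
    """Full network: encode -> (HMSF) -> decode, under an ablation spec."""

    def __init__(self, config: ModelConfig = ModelConfig(),
                 spec: AblationSpec = AblationSpec(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.spec = spec
        self.encoder = Encoder(config, rng)
        if spec.with_hmsf:
            h, w = config.input_size
            stage_sizes = tuple((h >> i, w >> i) for i in range(1, 6))
            self.hmsf = HMSF(rng, channels=config.channels, stage_sizes=stage_sizes,
                             d=config.grid_d, with_dsla=spec.with_dsla,
                             with_asam=spec.with_asam, with_axial=spec.with_axial,
                             learnable_mu=spec.learnable_mu)
        else:
            self.hmsf = None
        self.decoder = Decoder(config, rng)

    def forward(self, image) -> Tensor:
        features = self.encoder(image)
        bottleneck = self.hmsf(features) if self.hmsf is not None else features[-1]
        return self.decoder(bottleneck, features)

    def predict_proba(self, image) -> np.ndarray:
        """Foreground probabilities in (0,1), shape (B,1,H,W)."""
        return engine.sigmoid(self.forward(image)).data


def build_variant(variant: str | AblationSpec, config: ModelConfig = ModelConfig(),
                  seed: int = 0) -> DHMFMLP:
    spec = variant if isinstance(variant, AblationSpec) else AblationSpec(variant)
    return DHMFMLP(config=config, spec=spec, seed=seed)


def count_parameters(model: nn.Module) -> tuple[int, float]:
    """Total learnable array elements and the total in millions, rounded
    half-up to two decimals (the convention used for reporting)."""
    total = sum(int(np.prod(p.data.shape)) if p.data.shape else 1
                for p in model.parameters())
    millions = float((Decimal(total) / Decimal(10 ** 6)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))
    return total, millions


# ------------------------------------------------------------- checkpointing

def save_checkpoint(model: DHMFMLP, path) -> None:
    """Single-file archive of named weight arrays plus a config echo."""
    meta = json.dumps({"config": model.config.to_dict(),
                       "variant": model.spec.variant})
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> DHMFMLP:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = build_variant(meta["variant"], ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model
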