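"""The TU-Net architecture.

A hybrid encoder–decoder segmentation network for 2-D grayscale (ultrasound)
images.  A convolutional encoder produces skip features at strides 1–8 and a
bottleneck at stride 16.  The bottleneck feeds a *parallel attention*
mechanism with two branches:

* a **transformer branch** — the bottleneck grid is tokenized (one token per
  stride-16 position, i.e. one 16x16 input-image patch), linearly projected
  to width ``embed_dim``, summed with learned position embeddings, and passed
  through ``num_layers`` pre-norm multi-head self-attention blocks
  (global context);
* a **convolutional branch** — four cascaded 3x3 atrous convolutions with
  dilation rates (1, 3, 5, 7) followed by pyramid pooling over receptive
  fields (2, 4, 8, 16) (multiscale local context).

The two branch outputs are fused (concatenation + 1x1 convolution by
default) and decoded back to input resolution through upsample/skip-concat/
double-conv stages, ending in a single-channel sigmoid probability map.

Ablation variants mirror the reduced architectures used to isolate each
component: ``no_attention`` (plain U-Net-style encoder–decoder),
``no_transformer`` (conv branch only, "AU-Net"), ``transformer_only_bottleneck``
(transformer branch only, "T-Net"), and ``patch_input_transformer`` (a pure
ViT on raw image patches with a linear per-patch decoder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .autodiff import Tensor, concatenate

__all__ = [
    "ModelConfig", "ConfigError", "TUNet", "PatchTransformerNet", "build_model",
    "ABLATIONS",
]

ABLATIONS = (
    "full",
    "no_attention",
    "no_transformer",
    "transformer_only_bottleneck",
    "patch_input_transformer",
)


class ConfigError(ValueError):
    """Raised when a ModelConfig is internally inconsistent."""


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    Defaults follow the reference architecture: five encoder widths
    (64, 128, 256, 512, 1024), 16-px patches, a 12-layer ViT-Base-style
    transformer (D=768, 12 heads, MLP 3072), atrous rates (1, 3, 5, 7) and
    pyramid fields (2, 4, 8, 16).
    """

    in_channels: int = 1
    base_channels: tuple = (64, 128, 256, 512, 1024)
    patch_size: int = 16
    embed_dim: int = 768
    num_layers: int = 12
    num_heads: int = 12
    mlp_dim: int = 3072
    atrous_rates: tuple = (1, 3, 5, 7)
    pool_fields: tuple = (2, 4, 8, 16)
    ablation: str = "full"
    atrous_mode: str = "cascade"      # or "parallel" (classic ASPP)
    fusion: str = "concat"            # or "add"
    image_size: int = 320             # reference grid for position embeddings

    def validate(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ConfigError(f"ablation: unknown variant {self.ablation!r}")
        if len(self.base_channels) != 5 or any(c <= 0 for c in self.base_channels):
            raise ConfigError("base_channels: need 5 positive stage widths")
        if self.num_layers < 0:
            raise ConfigError("num_layers: must be >= 0")
        if self.embed_dim % self.num_heads:
            raise ConfigError(
                f"embed_dim: {self.embed_dim} not divisible by num_heads {self.num_heads}")
        if len(self.atrous_rates) != 4:
            raise ConfigError("atrous_rates: must have length 4")
        if len(self.pool_fields) != 4:
            raise ConfigError("pool_fields: must have length 4")
        if self.patch_size <= 0:
            raise ConfigError("patch_size: must be positive")
        if self.ablation != "patch_input_transformer" and self.patch_size % 16:
            raise ConfigError(
                "patch_size: must be a multiple of 16 so each token covers a whole "
                "number of stride-16 bottleneck positions")
        if self.image_size % self.patch_size:
            raise ConfigError(
                f"image_size: {self.image_size} not divisible by patch_size {self.patch_size}")
        if self.base_channels[-1] % 4:
            raise ConfigError("base_channels: bottleneck width must divide by 4 "
                              "(pyramid branch reduction)")
        bottleneck = self.image_size // 16
        if self.ablation in ("full", "no_transformer") and \
                max(self.pool_fields) > bottleneck:
            raise ConfigError(
                f"pool_fields: largest field {max(self.pool_fields)} exceeds the "
                f"{bottleneck}x{bottleneck} bottleneck of a {self.image_size}px input")
        if self.atrous_mode not in ("cascade", "parallel"):
            raise ConfigError(f"atrous_mode: unknown mode {self.atrous_mode!r}")
        if self.fusion not in ("concat", "add"):
            raise ConfigError(f"fusion: unknown mode {self.fusion!r}")


def tiny_config(**overrides) -> ModelConfig:
    """A reduced configuration for CPU-scale experiments on 64-px phantoms."""
    base = dict(base_channels=(8, 16, 32, 64, 128), embed_dim=64, num_layers=2,
                num_heads=4, mlp_dim=128, pool_fields=(1, 2, 2, 4), image_size=64)
    base.update(overrides)
    return ModelConfig(**base)


# --------------------------------------------------------------------- blocks

class DoubleConv(nn.Module):
    """Two 3x3 conv + BN + ReLU layers with an optional residual shortcut."""

    def __init__(self, cin: int, cout: int, rng, residual: bool = False):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.residual = residual
        self.shortcut = nn.Conv2d(cin, cout, 1, rng, bias=False) if residual else None

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        if self.residual:
            h = h + self.shortcut(x)
        return h.relu()


class Encoder(nn.Module):
    """Residual stage stack: skips at strides 1, 2, 4, 8; bottleneck at 16."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        chans = [cfg.in_channels] + list(cfg.base_channels)
        self.stages = nn.ModuleList(
            [DoubleConv(chans[i], chans[i + 1], rng, residual=True)
             for i in range(5)])

    def forward(self, x):
        skips = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = x.max_pool2d(2)
            x = stage(x)
            if i < 4:
                skips.append(x)
        return skips, x


class PatchEmbed(nn.Module):
    """Non-overlapping patch tokenization + linear projection + position emb.

    Position embeddings live on a fixed reference token grid and are
    bilinearly resized when the input produces a different grid, so one
    weight set serves all input sizes.
    """

    def __init__(self, in_ch: int, patch_px: int, dim: int, ref_grid: int, rng):
        super().__init__()
        self.patch_px = patch_px
        self.proj = nn.Linear(in_ch * patch_px * patch_px, dim, rng)
        self.pos = nn.Parameter(
            rng.standard_normal((1, dim, ref_grid, ref_grid), dtype=nn.DTYPE) * 0.02)
        self.ref_grid = ref_grid

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        p = self.patch_px
        if h % p or w % p:
            raise ConfigError(f"patch_size: input {h}x{w} not divisible by {p}")
        gh, gw = h // p, w // p
        tok = x.reshape(b, c, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
        tok = tok.reshape(b, gh * gw, c * p * p)
        tok = self.proj(tok)
        pos = self.pos
        if (gh, gw) != (self.ref_grid, self.ref_grid):
            pos = pos.upsample_bilinear((gh, gw))
        d = tok.shape[-1]
        pos_seq = pos.reshape(1, d, gh * gw).transpose(0, 2, 1)
        return tok + pos_seq


class TransformerBranch(nn.Module):
    """Patch embedding + L pre-norm transformer blocks + final LayerNorm."""

    def __init__(self, in_ch: int, patch_px: int, cfg: ModelConfig, ref_grid: int, rng):
        super().__init__()
        self.embed = PatchEmbed(in_ch, patch_px, cfg.embed_dim, ref_grid, rng)
        self.blocks = nn.ModuleList(
            [nn.TransformerBlock(cfg.embed_dim, cfg.num_heads, cfg.mlp_dim, rng)
             for _ in range(cfg.num_layers)])
        self.norm = nn.LayerNorm(cfg.embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        """Return a (B, D, gh, gw) token grid."""
        b = x.shape[0]
        gh = x.shape[2] // self.embed.patch_px
        gw = x.shape[3] // self.embed.patch_px
        z = self.embed(x)
        for blk in self.blocks:
            z = blk(z)
        z = self.norm(z)
        d = z.shape[-1]
        return z.transpose(0, 2, 1).reshape(b, d, gh, gw)


class AtrousBlock(nn.Module):
    """Four 3x3 dilated convolutions with rates ``rates``.

    ``cascade`` chains the branches (each consumes the previous output) and
    concatenates all four stage outputs; ``parallel`` applies all four to the
    input (classic ASPP).  Either way a 1x1 convolution restores the input
    channel width.
    """

    def __init__(self, channels: int, rates, rng, mode: str = "cascade"):
        super().__init__()
        self.rates = tuple(rates)
        self.mode = mode
        self.branches = nn.ModuleList()
        for r in self.rates:
            self.branches.append(nn.Sequential([
                nn.Conv2d(channels, channels, 3, rng, dilation=r),
                nn.BatchNorm2d(channels),
            ]))
        self.reduce = nn.Conv2d(4 * channels, channels, 1, rng)

    def forward(self, x):
        outs = []
        h = x
        for br in self.branches:
            src = h if self.mode == "cascade" else x
            y = br(src).relu()
            outs.append(y)
            h = y
        return self.reduce(concatenate(outs, axis=1))


class PyramidPoolBlock(nn.Module):
    """Pyramid pooling over four receptive fields.

    Each field: average-pool (kernel = stride = field, ceil mode), 1x1 conv to
    C/4 channels, bilinear upsample to the input size.  The four branch
    outputs are concatenated with the input and reduced by a 1x1 convolution.
    """

    def __init__(self, channels: int, fields, rng):
        super().__init__()
        self.fields = tuple(fields)
        red = channels // 4
        self.convs = nn.ModuleList(
            [nn.Conv2d(channels, red, 1, rng) for _ in self.fields])
        self.reduce = nn.Conv2d(channels + 4 * red, channels, 1, rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if max(self.fields) > min(h, w):
            raise ConfigError(
                f"pool_fields: field {max(self.fields)} exceeds feature map {h}x{w}")
        outs = [x]
        for f, conv in zip(self.fields, self.convs):
            y = conv(x.avg_pool2d(f))
            outs.append(y.upsample_bilinear((h, w)))
        return self.reduce(concatenate(outs, axis=1))


class Decoder(nn.Module):
    """(upsample x2, concat skip, double conv) repeated to stride 1 + 1x1 head."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        chans = list(cfg.base_channels)
        self.stages = nn.ModuleList()
        for lo, hi in zip(chans[:-1][::-1], chans[1:][::-1]):
            self.stages.append(DoubleConv(hi + lo, lo, rng))
        self.head = nn.Conv2d(chans[0], 1, 1, rng)

    def forward(self, bottleneck, skips):
        if len(skips) != len(self.stages):
            raise ValueError(
                f"decoder expects {len(self.stages)} skip levels, got {len(skips)}")
        x = bottleneck
        for stage, skip in zip(self.stages, skips[::-1]):
            x = x.upsample_bilinear((skip.shape[2], skip.shape[3]))
            x = stage(concatenate([x, skip], axis=1))
        return self.head(x)


# ---------------------------------------------------------------- full models

class TUNet(nn.Module):
    """Encoder + parallel attention bottleneck + decoder."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c_top = cfg.base_channels[-1]
        ref_grid = cfg.image_size // cfg.patch_size
        self.encoder = Encoder(cfg, rng)
        use_tr = cfg.ablation in ("full", "transformer_only_bottleneck")
        use_conv = cfg.ablation in ("full", "no_transformer")
        self.transformer = (
            TransformerBranch(c_top, cfg.patch_size // 16, cfg, ref_grid, rng)
            if use_tr else None)
        self.token_proj = nn.Conv2d(cfg.embed_dim, c_top, 1, rng) if use_tr else None
        self.atrous = (AtrousBlock(c_top, cfg.atrous_rates, rng, cfg.atrous_mode)
                       if use_conv else None)
        self.pyramid = (PyramidPoolBlock(c_top, cfg.pool_fields, rng)
                        if use_conv else None)
        if cfg.ablation == "full" and cfg.fusion == "concat":
            self.fuse = nn.Conv2d(2 * c_top, c_top, 1, rng)
        else:
            self.fuse = None
        self.decoder = Decoder(cfg, rng)

    # exposed stages -------------------------------------------------------
    def encode(self, x: Tensor):
        return self.encoder(x)

    def conv_branch(self, bottleneck: Tensor) -> Tensor:
        return self.pyramid(self.atrous(bottleneck))

    def attention(self, bottleneck: Tensor) -> Tensor:
        """Apply the parallel attention mechanism to the bottleneck map."""
        abl = self.cfg.ablation
        if abl == "no_attention":
            return bottleneck
        if abl == "no_transformer":
            return self.conv_branch(bottleneck)
        tok = self.token_proj(self.transformer(bottleneck))
        if abl == "transformer_only_bottleneck":
            return tok
        conv = self.conv_branch(bottleneck)
        if self.cfg.fusion == "add":
            return tok + conv
        return self.fuse(concatenate([tok, conv], axis=1))

    def logits(self, x: Tensor) -> Tensor:
        skips, bottleneck = self.encoder(x)
        return self.decoder(self.attention(bottleneck), skips)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=nn.DTYPE))
        return self.logits(x).sigmoid()

    # reporting ------------------------------------------------------------
    def parameter_report(self) -> dict:
        """Trainable-parameter count per top-level component."""
        report = {}
        for name, mod in self._modules.items():
            report[name] = mod.num_parameters()
        report["total"] = self.num_parameters()
        return report

    def transformer_branch_parameters(self) -> int:
        """Parameters belonging exclusively to the transformer branch
        (patch embedding, transformer stack, token projection, fusion conv)."""
        n = 0
        for mod in (self.transformer, self.token_proj, self.fuse):
            if mod is not None:
                n += mod.num_parameters()
        return n


class PatchTransformerNet(nn.Module):
    """Pure patch-input transformer segmenter (the 'T-Net' input ablation).

    Raw P x P image patches are embedded, run through the transformer stack,
    and each output token is linearly decoded to its P^2 pixel logits.
    """

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        ref_grid = cfg.image_size // cfg.patch_size
        self.transformer = TransformerBranch(
            cfg.in_channels, cfg.patch_size, cfg, ref_grid, rng)
        self.head = nn.Linear(cfg.embed_dim, cfg.patch_size ** 2, rng)

    def logits(self, x: Tensor) -> Tensor:
        b, _, h, w = x.shape
        p = self.cfg.patch_size
        grid = self.transformer(x)                      # (b, D, gh, gw)
        gh, gw = grid.shape[2], grid.shape[3]
        tokens = grid.reshape(b, grid.shape[1], gh * gw).transpose(0, 2, 1)
        pix = self.head(tokens)                         # (b, N, p*p)
        pix = pix.reshape(b, gh, gw, p, p).transpose(0, 1, 3, 2, 4)
        return pix.reshape(b, 1, gh * p, gw * p)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=nn.DTYPE))
        return self.logits(x).sigmoid()

    def parameter_report(self) -> dict:
        return {name: mod.num_parameters() for name, mod in self._modules.items()} | {
            "total": self.num_parameters()}


def build_model(cfg: ModelConfig, seed: int = 0):
    """Instantiate the configured network with seeded initialization."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    if cfg.ablation == "patch_input_transformer":
        return PatchTransformerNet(cfg, rng)
    return TUNet(cfg, rng)
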