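"""The segmentation model family: vanilla / reduced U-Net with optional
bottleneck spatial attention, additive attention gates on skip connections,
and zero-padded input for implicit positional learning.

The network consumes a zero-padded 3-channel image of size
(Z+H) x (Z+W) x 3 and regresses a 2-channel map of the same spatial size —
channel 0 the wrinkle texture target, channel 1 the pore target, produced
in concatenated form by a final 1x1 convolution with no output activation
(training minimizes MSE against continuous 0-255 ground truth).

Channel plan (``bilinear_then_conv`` upsampling, depth *d*, base *b*):
encoder widths b, 2b, ..., b*2^(d-2) with a halved bottleneck b*2^(d-2);
each decoder level upsamples bilinearly, concatenates the skip, and applies
a double conv. With d=5, b=64 this is the standard 17.3 M-parameter vanilla
configuration; b=32 gives the quarter-sized reduced model (4.3 M). The
attention-equipped reduced model adds the two attention mechanisms for
~0.9 M extra parameters (5.2 M total); input zero-padding adds none.

The border of zeros acts as an absolute positional anchor: convolution
stacks can infer where a pixel sits relative to the image frame, which the
model exploits to keep wrinkle predictions in the forehead/eye zones and
pore predictions in the butterfly zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modules import (BatchNorm2d, Conv2d, ConvTranspose2x2, DoubleConv,
                      Module, ModuleList)
from .tensor import (Tensor, channel_max, channel_mean, concat, maxpool2x2,
                     upsample_bilinear2x)

__all__ = ["ModelConfig", "AttentionGateSpec", "SpatialAttention",
           "AdditiveAttentionGate", "SkinUNet", "build_model",
           "count_parameters", "zero_pad_input", "VANILLA", "REDUCED",
           "REDUCED_ATTN", "PROPOSED"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture descriptor; the trainable-parameter count is a pure
    function of this object."""

    depth: int = 5
    base_channels: int = 64
    use_spatial_attention: bool = False
    use_additive_attention: bool = False
    pad_Z: int = 0
    in_channels: int = 3
    out_channels: int = 2
    upsample_mode: str = "bilinear_then_conv"
    name: str = ""

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.pad_Z < 0 or self.pad_Z % 2:
            raise ValueError("pad_Z must be even and >= 0")
        if self.upsample_mode not in ("bilinear_then_conv", "transposed_conv"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")


#: the four ablation rows at full scale
VANILLA = ModelConfig(depth=5, base_channels=64, name="unet")
REDUCED = ModelConfig(depth=5, base_channels=32, name="reduced")
REDUCED_ATTN = ModelConfig(depth=5, base_channels=32, use_spatial_attention=True,
                           use_additive_attention=True, name="reduced_attn")
PROPOSED = ModelConfig(depth=5, base_channels=32, use_spatial_attention=True,
                       use_additive_attention=True, pad_Z=32, name="proposed")


@dataclass(frozen=True)
class AttentionGateSpec:
    inter_channels: int
    activation: str = "relu"
    gate_nonlinearity: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.inter_channels < 1:
            raise ValueError("inter_channels must be >= 1")
        if self.activation != "relu" or self.gate_nonlinearity != "sigmoid":
            raise ValueError("only relu activation / sigmoid gate supported")


def zero_pad_input(image: np.ndarray, Z: int) -> np.ndarray:
    """Surround an (H, W[, C]) image with Z/2 zeros on every side."""
    if Z < 0 or Z % 2:
        raise ValueError("Z must be even and >= 0")
    if Z == 0:
        return np.asarray(image)
    z = Z // 2
    pad = [(z, z), (z, z)] + [(0, 0)] * (np.asarray(image).ndim - 2)
    return np.pad(np.asarray(image), pad)


class SpatialAttention(Module):
    """Per-pixel gating from channel-wise max + mean pooling.

    The two pooled maps are concatenated (2 channels), passed through a
    single 7x7 convolution and a sigmoid, and the resulting attention map
    in (0, 1) is broadcast-multiplied onto the input features.
    """

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng, bias=True)

    def attention_map(self, x: Tensor) -> Tensor:
        pooled = concat([channel_max(x), channel_mean(x)], axis=1)
        return self.conv(pooled).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x)


class AdditiveAttentionGate(Module):
    """Additive attention on a skip connection.

    Encoder features act as key and value, processed decoder features as
    query; the gate is sigmoid(psi(relu(W1 k + W2 q + b))) with 1x1
    projections (psi reduces to a single channel), and the encoder features
    are multiplied by the gate before concatenation.
    """

    def __init__(self, enc_ch: int, dec_ch: int, spec: AttentionGateSpec,
                 rng: np.random.Generator):
        super().__init__()
        inter = spec.inter_channels
        self.theta = Conv2d(enc_ch, inter, 1, rng, bias=False)  # W1 on key
        self.phi = Conv2d(dec_ch, inter, 1, rng, bias=True)     # W2 q + b
        self.psi = Conv2d(inter, 1, 1, rng, bias=True)

    def gate_map(self, encoder_feats: Tensor, query: Tensor) -> Tensor:
        pre = self.theta(encoder_feats) + self.phi(query)
        return self.psi(pre.relu()).sigmoid()

    def forward(self, encoder_feats: Tensor, query: Tensor) -> Tensor:
        return encoder_feats * self.gate_map(encoder_feats, query)


class _Down(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.block = DoubleConv(in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(maxpool2x2(x))


class _Up(Module):
    """One decoder level: upsample, (optionally gate the skip), concatenate,
    double conv. With additive attention the decoder branch is processed by
    upsample -> conv3x3 -> BN -> ReLU before serving as the gate query."""

    def __init__(self, dec_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator, bilinear: bool, attention: bool):
        super().__init__()
        self.bilinear = bilinear
        self.attention = attention
        if bilinear:
            q_ch = dec_ch
        else:
            self.upconv = ConvTranspose2x2(dec_ch, dec_ch // 2, rng)
            q_ch = dec_ch // 2
        if attention:
            self.qconv = Conv2d(q_ch, q_ch, 3, rng, bias=False)
            self.qbn = BatchNorm2d(q_ch)
            self.gate = AdditiveAttentionGate(
                skip_ch, q_ch, AttentionGateSpec(max(1, skip_ch // 2)), rng
            )
        in_ch = q_ch + skip_ch
        mid = in_ch // 2 if bilinear else None
        self.block = DoubleConv(in_ch, out_ch, rng, mid_ch=mid)

    def forward(self, skip: Tensor, x: Tensor) -> Tensor:
        x = upsample_bilinear2x(x) if self.bilinear else self.upconv(x)
        if x.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder/skip spatial mismatch: {x.shape[2:]} vs {skip.shape[2:]}"
            )
        if self.attention:
            q = self.qbn(self.qconv(x)).relu()
            skip = self.gate(skip, q)
            x = q
        return self.block(concat([skip, x], axis=1))


class SkinUNet(Module):
    """U-shaped encoder-decoder regressing 2-channel wrinkle/pore maps."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        object.__setattr__(self, "config", config)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        d, b = config.depth, config.base_channels
        bilinear = config.upsample_mode == "bilinear_then_conv"
        factor = 2 if bilinear else 1
        enc = [b * 2**i for i in range(d - 1)]
        bottleneck = b * 2 ** (d - 1) // factor

        self.inc = DoubleConv(config.in_channels, enc[0], rng)
        downs = ModuleList()
        for i in range(1, d - 1):
            downs.append(_Down(enc[i - 1], enc[i], rng))
        downs.append(_Down(enc[-1], bottleneck, rng))
        self.downs = downs
        if config.use_spatial_attention:
            self.spatial_attention = SpatialAttention(rng)
        ups = ModuleList()
        cur = bottleneck
        for i in range(d - 2, -1, -1):
            out_ch = enc[max(i - 1, 0)] if bilinear else enc[i]
            ups.append(_Up(cur, enc[i], out_ch, rng, bilinear,
                           config.use_additive_attention))
            cur = out_ch
        self.ups = ups
        self.outc = Conv2d(cur, config.out_channels, 1, rng, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        d = self.config.depth
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (d - 1)
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^(depth-1) = {div}; "
                "adjust crop size or pad_Z"
            )
        skips = [self.inc(x)]
        for down in self.downs:
            skips.append(down(skips[-1]))
        x = skips.pop()
        if self.config.use_spatial_attention:
            x = self.spatial_attention(x)
        for up in self.ups:
            x = up(skips.pop(), x)
        return self.outc(x)


def build_model(config: ModelConfig, seed: int = 0) -> SkinUNet:
    """Instantiate a model; identical (config minus pad_Z, seed) pairs give
    bit-identical initial weights — padding is weightless."""
    return SkinUNet(config, seed)


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars (batch-norm running statistics are
    buffers, not parameters)."""
    return int(sum(p.data.size for p in model.parameters()))
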