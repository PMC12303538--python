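"""Residual U-Net backbone.

The encoder halves spatial resolution ``depth`` times while doubling channel
width; the decoder mirrors it with nearest-neighbor upsampling, skip
concatenation and residual blocks.  Two outputs feed the rest of the model:

* ``F`` — the bottleneck feature map, pooled by the class-aware controller;
* ``M`` — the full-resolution decoder feature map (D channels) that the
  dynamic segmentation head convolves with the generated kernels.

Normalization is per-instance rather than per-batch because batches of
partially labeled patches mix classes and domains at batch size 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class BackboneConfig:
    in_channels: int = 3
    base_width: int = 16
    depth: int = 4
    decoder_out_channels: int = 8  # D, the channel count of M

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if self.decoder_out_channels < 2:
            raise ValueError("decoder_out_channels must be >= 2")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_width * (2 ** self.depth)

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "base_width": self.base_width,
                "depth": self.depth,
                "decoder_out_channels": self.decoder_out_channels}

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(**d)


class ResidualUNet(nn.Module):
    """Encoder–decoder with residual blocks and skip connections."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        w = config.base_width
        self.stem = nn.Conv2d(config.in_channels, w, 3, rng, padding=1)
        enc, down = [], []
        ch = w
        for _ in range(config.depth):
            enc.append(nn.ResidualBlock(ch, ch, rng))
            down.append(nn.Conv2d(ch, ch * 2, 3, rng, stride=2, padding=1))
            ch *= 2
        self.encoder_blocks = enc
        self.down_convs = down
        self.bottleneck = nn.ResidualBlock(ch, ch, rng)
        up, dec = [], []
        for _ in range(config.depth):
            up.append(nn.Conv2d(ch, ch // 2, 3, rng, padding=1))
            # decoder block sees [upsampled ∥ skip] = ch//2 + ch//2 channels
            dec.append(nn.ResidualBlock(ch, ch // 2, rng))
            ch //= 2
        self.up_convs = up
        self.decoder_blocks = dec
        self.out_conv = nn.Conv2d(w, config.decoder_out_channels, 1, rng)

    def __call__(self, x: Tensor, zero_bottleneck: bool = False
                 ) -> tuple[Tensor, Tensor]:
        """Forward pass returning (F, M).

        ``zero_bottleneck`` replaces the bottleneck activation with zeros —
        a diagnostic hook used to verify that the skip connections carry
        spatial information on their own.
        """
        cfg = self.config
        n, c, h, wdt = x.shape
        div = 2 ** cfg.depth
        if h % div or wdt % div:
            raise ValueError(f"spatial size {h}x{wdt} must be divisible by "
                             f"2^depth = {div}")
        h_t = self.stem(x)
        skips = []
        for block, down in zip(self.encoder_blocks, self.down_convs):
            h_t = block(h_t)
            skips.append(h_t)
            h_t = down(h_t)
        feature_map = self.bottleneck(h_t)
        h_t = feature_map
        if zero_bottleneck:
            h_t = Tensor(np.zeros_like(feature_map.data))
        for up, block, skip in zip(self.up_convs, self.decoder_blocks,
                                   reversed(skips)):
            h_t = up(nn.upsample_nearest2x(h_t))
            h_t = nn.concat_channels(h_t, skip)
            h_t = block(h_t)
        decoder_feature = self.out_conv(h_t)
        return feature_map, decoder_feature


def backbone_forward(image: np.ndarray, model: ResidualUNet
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode forward for a single H×W×3 image in [0, 1].

    Returns ``(F, M)`` as numpy arrays of shapes
    (C_bottleneck, H/2^depth, W/2^depth) and (D, H, W).
    """
    x = np.asarray(image, dtype=nn.DTYPE)
    if x.ndim != 3 or x.shape[2] != model.config.in_channels:
        raise ValueError(f"expected H×W×{model.config.in_channels} image, "
                         f"got {x.shape}")
    xt = Tensor(x.transpose(2, 0, 1)[None])
    f, m = model(xt)
    return f.data[0], m.data[0]


def global_average_pool(feature_map: np.ndarray) -> np.ndarray:
    """Spatial arithmetic mean per channel: (C, H, W) -> (C,)."""
    f = np.asarray(feature_map)
    if f.ndim != 3 or f.size == 0:
        raise ValueError(f"expected nonempty (C, H, W) array, got {f.shape}")
    return f.mean(axis=(1, 2))
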