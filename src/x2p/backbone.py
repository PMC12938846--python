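"""Shared 2D feature extraction and prompt-guided feature enhancement.

The extractor is a 4-level U-Net with a spatial-pyramid-pooling bottleneck,
producing d-channel features at full input resolution.  The enhancer
cross-attends 8x-downsampled image features (queries) against the prompt
feature crop (keys and values) and adds the upsampled result back residually.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, InstanceNorm, LayerNorm, Linear, Module, Tensor, as_tensor, concat
from .nn import functional as F

__all__ = [
    "attention",
    "MultiHeadCrossAttention",
    "UNetSPP",
    "FeatureEnhancer",
    "sliding_window_split",
]


def attention(q: Tensor, k: Tensor, v: Tensor, scale: float | None = None) -> Tensor:
    """softmax(q k^T * scale) v for token matrices (nq, dk), (nk, dk), (nk, dv)."""
    if scale is None:
        scale = 1.0 / np.sqrt(q.shape[-1])
    weights = F.softmax((q @ k.transpose()) * scale, axis=-1)
    return weights @ v


class MultiHeadCrossAttention(Module):
    """Heads-split attention with output projection, residual and layer norm."""

    def __init__(self, d: int, hidden: int, heads: int, rng: np.random.Generator):
        if hidden % heads:
            raise ValueError("hidden_dim must be divisible by heads")
        self.heads = heads
        self.dh = hidden // heads
        self.wq = Linear(d, hidden, rng, bias=False)
        self.wk = Linear(d, hidden, rng, bias=False)
        self.wv = Linear(d, hidden, rng, bias=False)
        self.wo = Linear(hidden, d, rng)
        self.norm = LayerNorm(d)

    def forward(self, x: Tensor, kv: Tensor) -> Tensor:
        q = self.wq(x)
        k = self.wk(kv)
        v = self.wv(kv)
        outs = []
        for hd in range(self.heads):
            sl = slice(hd * self.dh, (hd + 1) * self.dh)
            outs.append(attention(q[:, sl], k[:, sl], v[:, sl]))
        merged = concat(outs, axis=-1)
        return self.norm(x + self.wo(merged))


class _ConvBlock(Module):
    def __init__(self, cin: int, cout: int, rng, kernel: int = 3):
        self.conv = Conv2d(cin, cout, rng, kernel=kernel)
        self.norm = InstanceNorm(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class UNetSPP(Module):
    """4-level encoder-decoder with skip connections and an SPP bottleneck.

    Fully convolutional: any input whose sides are divisible by 8 works.
    """

    def __init__(
        self,
        out_channels: int = 64,
        level_channels: tuple[int, ...] = (16, 32, 64, 128),
        spp_scales: tuple[int, ...] = (1, 2, 4, 8),
        rng: np.random.Generator | None = None,
        in_channels: int = 1,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        if len(level_channels) != 4:
            raise ValueError("expected 4 level channel counts")
        c1, c2, c3, c4 = level_channels
        self.spp_scales = tuple(spp_scales)
        self.enc = [
            _ConvBlock(in_channels, c1, rng),
            _ConvBlock(c1, c2, rng),
            _ConvBlock(c2, c3, rng),
            _ConvBlock(c3, c4, rng),
        ]
        self.spp_proj = _ConvBlock(c4 * (1 + len(self.spp_scales)), c4, rng, kernel=1)
        self.dec = [
            _ConvBlock(c4 + c3, c3, rng),
            _ConvBlock(c3 + c2, c2, rng),
            _ConvBlock(c2 + c1, c1, rng),
        ]
        self.head = Conv2d(c1, out_channels, rng, kernel=1)

    def forward(self, image) -> Tensor:
        x = as_tensor(image)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        h, w = x.shape[1], x.shape[2]
        if h % 8 or w % 8:
            raise ValueError(f"size error: input {h}x{w} not divisible by 8 for 3 downsamplings")
        skips = []
        for i, block in enumerate(self.enc):
            if i > 0:
                x = F.max_pool2d(x, 2)
            x = block(x)
            if i < 3:
                skips.append(x)
        x = self._spp(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = F.resize_bilinear(x, skip.shape[1], skip.shape[2])
            x = block(concat([x, skip], axis=0))
        return self.head(x)

    def _spp(self, x: Tensor) -> Tensor:
        hb, wb = x.shape[1], x.shape[2]
        pieces = [x]
        for s in self.spp_scales:
            if hb % s == 0 and wb % s == 0:
                pooled = F.avg_pool2d(x, (hb // s, wb // s))
            else:  # non-divisible bottleneck (cropped inputs): smooth fallback
                pooled = F.resize_bilinear(x, s, s)
            pieces.append(F.resize_bilinear(pooled, hb, wb))
        return self.spp_proj(concat(pieces, axis=0))


class FeatureEnhancer(Module):
    """Prompt-guided cross-attention enhancement of image features.

    fi and fp are average-pooled by ``downsample``, given fixed sinusoidal
    positional encodings, and run through ``layers`` cross-attention layers
    (queries = pooled image tokens, keys/values = pooled prompt tokens).  The
    output is bilinearly upsampled and added residually to fi.
    """

    def __init__(
        self,
        d: int = 64,
        hidden: int = 64,
        heads: int = 8,
        layers: int = 4,
        downsample: int = 8,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d = d
        self.downsample = downsample
        self.layers = [MultiHeadCrossAttention(d, hidden, heads, rng) for _ in range(layers)]

    def forward(self, fi: Tensor, fp: Tensor) -> Tensor:
        if fi.shape[0] != fp.shape[0]:
            raise ValueError(
                f"inconsistent inputs: fi has {fi.shape[0]} channels, fp has {fp.shape[0]}"
            )
        s = self.downsample
        fi_small = F.avg_pool2d(fi, s)
        fp_small = F.avg_pool2d(fp, s)
        hq, wq = fi_small.shape[1], fi_small.shape[2]
        hk, wk = fp_small.shape[1], fp_small.shape[2]
        pe_q = F.sinusoidal_positions_2d(self.d, hq, wq, dtype=fi_small.data.dtype)
        pe_k = F.sinusoidal_positions_2d(self.d, hk, wk, dtype=fp_small.data.dtype)
        x = (fi_small + Tensor(pe_q)).reshape(self.d, hq * wq).transpose()
        kv = (fp_small + Tensor(pe_k)).reshape(self.d, hk * wk).transpose()
        for layer in self.layers:
            x = layer(x, kv)
        out_small = x.transpose().reshape(self.d, hq, wq)
        up = F.resize_bilinear(out_small, fi.shape[1], fi.shape[2])
        return fi + up


def sliding_window_split(image: np.ndarray, window: int = 512) -> list[tuple[np.ndarray, int]]:
    """Split a tall (..., h, w) image into (patch, row_offset) windows.

    Consecutive non-overlapping windows top to bottom; the final window is
    anchored to the bottom edge (it may overlap its predecessor).  An image
    no taller than ``window`` yields a single patch at offset 0.
    """
    h = image.shape[-2]
    if h <= window:
        return [(image, 0)]
    offsets = list(range(0, h - window + 1, window))
    if offsets[-1] != h - window:
        offsets.append(h - window)
    return [(image[..., off : off + window, :], off) for off in offsets]
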