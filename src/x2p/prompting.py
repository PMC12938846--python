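"""Prompt mask construction and prompt-derived feature operations.

A prompt is a user-placed point (x0, y0) marking the reference (top-most)
vertebral body center on one view.  From it we build:

* ``Mp`` — a binary square mask of half-width ``r`` around the prompt,
* ``fp`` — the feature crop under ``Mp`` (zero-padded to a fixed 2r x 2r),
* ``Md`` — a unidirectional squared-distance mask ``(y - y0)**2``,
* ``fm`` — features combined with ``Md`` to inject vertical position.

All masks use exact integer arithmetic.  Arrays are (h, w) with x = column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor, pad

__all__ = [
    "Prompt",
    "PromptMasks",
    "binary_prompt_mask",
    "prompt_features",
    "distance_mask",
    "masked_features",
    "build_prompt_masks",
]

DEFAULT_RADIUS = 40  # half-width (px) of the square prompt window


@dataclass(frozen=True)
class Prompt:
    x0: int
    y0: int
    view_id: str = "lat"

    def validate(self, w: int, h: int) -> None:
        if not (0 <= self.x0 < w and 0 <= self.y0 < h):
            raise ValueError(
                f"invalid prompt: ({self.x0}, {self.y0}) outside image of size {w}x{h}"
            )

    def shifted(self, dx: int = 0, dy: int = 0) -> "Prompt":
        return Prompt(self.x0 + dx, self.y0 + dy, self.view_id)


@dataclass
class PromptMasks:
    Mp: np.ndarray  # binary (h, w)
    Md: np.ndarray  # nonnegative int (h, w)
    Md_binary: np.ndarray  # (Md > 0), (h, w)
    r: int


def binary_prompt_mask(prompt: Prompt, w: int, h: int, r: int = DEFAULT_RADIUS) -> np.ndarray:
    """Mp(x, y) = 1 iff x0-r <= x < x0+r and y0-r <= y < y0+r (clipped to image)."""
    if r < 1:
        raise ValueError("prompt radius r must be >= 1")
    prompt.validate(w, h)
    mask = np.zeros((h, w), dtype=np.uint8)
    x_lo, x_hi = max(prompt.x0 - r, 0), min(prompt.x0 + r, w)
    y_lo, y_hi = max(prompt.y0 - r, 0), min(prompt.y0 + r, h)
    mask[y_lo:y_hi, x_lo:x_hi] = 1
    return mask


def prompt_features(fi, Mp: np.ndarray, prompt: Prompt, r: int = DEFAULT_RADIUS):
    """Crop the masked features to the fixed (d, 2r, 2r) prompt window.

    The crop is fi * Mp restricted to the prompt window; parts of the window
    that fall outside the image stay zero.  Accepts an ndarray or Tensor
    (d, h, w) and returns the same kind.
    """
    t = as_tensor(fi)
    if t.ndim != 3 or t.shape[1:] != Mp.shape:
        raise ValueError(f"inconsistent inputs: features {t.shape} vs mask {Mp.shape}")
    h, w = Mp.shape
    masked = t * Tensor(Mp.astype(t.dtype))
    y_lo, y_hi = max(prompt.y0 - r, 0), min(prompt.y0 + r, h)
    x_lo, x_hi = max(prompt.x0 - r, 0), min(prompt.x0 + r, w)
    crop = masked[:, y_lo:y_hi, x_lo:x_hi]
    pad_top = y_lo - (prompt.y0 - r)
    pad_left = x_lo - (prompt.x0 - r)
    fp = pad(
        crop,
        (
            (0, 0),
            (pad_top, 2 * r - (y_hi - y_lo) - pad_top),
            (pad_left, 2 * r - (x_hi - x_lo) - pad_left),
        ),
    )
    return fp if isinstance(fi, Tensor) else fp.data


def distance_mask(prompt: Prompt, w: int, h: int) -> np.ndarray:
    """Md(x, y) = (y - y0)**2, independent of x.  Exact integer arithmetic."""
    prompt.validate(w, h)
    dy = np.arange(h, dtype=np.int64) - prompt.y0
    return np.broadcast_to((dy * dy)[:, None], (h, w)).copy()


def masked_features(fe, Md: np.ndarray, normalize: bool = True):
    """fm = fe * (Md > 0) + Md_hat, broadcast over channels.

    The additive term is Md / h**2 when ``normalize`` (keeps it on the scale
    of unit features) or the raw squared distance otherwise.  The prompt row
    (where Md == 0) is zeroed in every channel.
    """
    t = as_tensor(fe)
    if t.ndim != 3 or t.shape[1:] != Md.shape:
        raise ValueError(f"inconsistent inputs: features {t.shape} vs mask {Md.shape}")
    h = Md.shape[0]
    md_binary = (Md > 0).astype(t.dtype)
    md_hat = Md.astype(np.float64) / float(h * h) if normalize else Md.astype(np.float64)
    fm = t * Tensor(md_binary) + Tensor(md_hat.astype(t.dtype))
    return fm if isinstance(fe, Tensor) else fm.data


def build_prompt_masks(prompt: Prompt, w: int, h: int, r: int = DEFAULT_RADIUS) -> PromptMasks:
    Mp = binary_prompt_mask(prompt, w, h, r)
    Md = distance_mask(prompt, w, h)
    return PromptMasks(Mp=Mp, Md=Md, Md_binary=(Md > 0).astype(np.uint8), r=r)
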