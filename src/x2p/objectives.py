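"""Ground-truth heatmap construction and training losses.

Losses accept NumPy arrays or autodiff Tensors; with Tensor inputs the
returned scalar is differentiable.  Shapes follow the two-view layout
(views, N, S, S) for 2D heatmaps and (N, 3) for 3D coordinates.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "make_gt_heatmap",
    "loss_mse_2d",
    "loss_dice_2d",
    "loss_3d",
    "loss_overall",
]

DICE_EPS = 1e-6


def make_gt_heatmap(
    landmark_2d,
    image_size: tuple[int, int],
    grid: int = 16,
    sigma: float = 1.0,
) -> np.ndarray:
    """Isotropic Gaussian bump on a (grid x grid) map, peak value exactly 1.

    ``landmark_2d`` is (x, y) in image pixels; ``image_size`` is (w, h).  The
    heatmap covers the full image extent, so grid cell (i, j) corresponds to
    the image point mapped through the scale w/grid (align_corners=False
    convention).  ``sigma`` is measured in grid cells.
    """
    x, y = float(landmark_2d[0]), float(landmark_2d[1])
    w, h = image_size
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"invalid GT: landmark ({x}, {y}) outside image {w}x{h}")
    gx = (x + 0.5) * grid / w - 0.5
    gy = (y + 0.5) * grid / h - 0.5
    jj, ii = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")  # (row=j=y, col=i=x)
    if sigma <= 0:  # one-hot limit
        hm = np.zeros((grid, grid))
        hm[int(round(np.clip(gy, 0, grid - 1))), int(round(np.clip(gx, 0, grid - 1)))] = 1.0
        return hm
    d2 = (ii - gx) ** 2 + (jj - gy) ** 2
    hm = np.exp(-0.5 * d2 / sigma**2)
    return hm / hm.max()  # nonempty targets peak at exactly 1


def _pair(pred, gt):
    p = as_tensor(pred)
    g = as_tensor(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return p, g


def loss_mse_2d(pred, gt):
    """Mean squared heatmap error with normalizer 1 / (2 * N * S * S).

    pred, gt: (2 views, N, S, S).
    """
    p, g = _pair(pred, gt)
    n_slots = p.shape[1]
    s1, s2 = p.shape[2], p.shape[3]
    diff = p - g
    out = (diff * diff).sum() * (1.0 / (2 * n_slots * s1 * s2))
    return out if isinstance(pred, Tensor) else float(out.data)


def loss_dice_2d(pred, gt, eps: float = DICE_EPS):
    """1 - mean Dice overlap over 2 views x N slots (squared-denominator form)."""
    p, g = _pair(pred, gt)
    n_slots = p.shape[1]
    inter = (p * g).sum(axis=(2, 3))
    denom = (p * p).sum(axis=(2, 3)) + (g * g).sum(axis=(2, 3))
    dice = (inter * 2.0 + eps) / (denom + eps)
    out = 1.0 - dice.sum() * (1.0 / (2 * n_slots))
    return out if isinstance(pred, Tensor) else float(out.data)


def loss_3d(pred_coords, gt_coords, n_valid: int | None = None):
    """Mean squared 3D distance over the first ``n_valid`` slots (mm^2)."""
    p = as_tensor(pred_coords)
    g = as_tensor(gt_coords)
    nv = g.shape[0] if n_valid is None else int(n_valid)
    if nv == 0:
        raise ValueError("empty target: no vertebrae to supervise")
    diff = p[:nv] - g[:nv]
    out = (diff * diff).sum() * (1.0 / nv)
    return out if isinstance(pred_coords, Tensor) else float(out.data)


def loss_overall(
    pred_heatmaps,
    gt_heatmaps,
    pred_coords,
    gt_coords,
    n_valid: int | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    eps: float = DICE_EPS,
):
    """w1 * MSE2D + w2 * Dice2D + w3 * MSE3D."""
    w1, w2, w3 = weights
    out = (
        loss_mse_2d(pred_heatmaps, gt_heatmaps) * w1
        + loss_dice_2d(pred_heatmaps, gt_heatmaps, eps=eps) * w2
        + loss_3d(pred_coords, gt_coords, n_valid) * w3
    )
    return out
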