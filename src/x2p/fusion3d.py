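"""Multi-view 3D fusion: heatmap rescaling, unprojection, 3D conv head,
per-slot soft-argmax and the max-probability validity rule."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import VolumeGrid, projection_sampler, unproject_features
from .nn import Conv3d, InstanceNorm, Module, Tensor, as_tensor, concat
from .nn import functional as F

__all__ = ["LocalizationResult", "FusionHead", "fuse_and_localize", "validity_filter"]

VIEWS = ("lat", "ap")


@dataclass
class LocalizationResult:
    coords: np.ndarray  # (N, 3) world mm
    heatmaps_2d: dict[str, np.ndarray]  # view -> (N, S, S)
    pmax: dict[str, np.ndarray]  # view -> (N,)
    valid: np.ndarray  # (N,) bool
    coords_tensor: Tensor | None = None  # differentiable coords (training)
    volume_probs: Tensor | None = None  # (N, nx, ny, nz) per-slot softmax
    level_guesses: list[str] = field(default_factory=list)

    @property
    def n_slots(self) -> int:
        return self.coords.shape[0]

    def to_dict(self) -> dict:
        rows = []
        for n in range(self.n_slots):
            rows.append(
                {
                    "slot": n,
                    "level_guess": self.level_guesses[n] if self.level_guesses else f"V{n + 1}",
                    "x_mm": float(self.coords[n, 0]),
                    "y_mm": float(self.coords[n, 1]),
                    "z_mm": float(self.coords[n, 2]),
                    "pmax_lat": float(self.pmax["lat"][n]),
                    "pmax_ap": float(self.pmax["ap"][n]),
                    "valid": bool(self.valid[n]),
                }
            )
        return {"slots": rows}

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class FusionHead(Module):
    """3-block 3D convolutional head mapping the fused volume to N slot heatmaps."""

    def __init__(self, in_channels: int, n_slots: int, hidden: int = 32, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv1 = Conv3d(in_channels, hidden, rng)
        self.norm1 = InstanceNorm(hidden)
        self.conv2 = Conv3d(hidden, hidden, rng)
        self.norm2 = InstanceNorm(hidden)
        self.conv3 = Conv3d(hidden, n_slots, rng)

    def forward(self, vol: Tensor) -> Tensor:
        x = self.norm1(self.conv1(vol)).relu()
        x = self.norm2(self.conv2(x)).relu()
        return self.conv3(x)


def _pmax_valid(pmax: dict[str, np.ndarray], threshold: float, rule: str) -> np.ndarray:
    stacked = np.stack([pmax[v] for v in pmax], axis=0)  # (views, N)
    if rule == "both":
        return (stacked > threshold).all(axis=0)
    if rule == "any":
        return (stacked > threshold).any(axis=0)
    raise ValueError(f"unknown validity rule {rule!r}")


def fuse_and_localize(
    heatmaps: dict[str, Tensor],
    features: dict[str, Tensor],
    cameras: dict,
    grid: VolumeGrid,
    head: FusionHead,
    threshold: float = 0.5,
    rule: str = "both",
    samplers: dict | None = None,
    temperature: float = 1.0,
) -> LocalizationResult:
    """Concat (fe, rescaled h̃) per view, unproject, fuse and localize.

    heatmaps: view -> (N, S, S); features: view -> (d, h, w).  The per-view
    concatenated (d+N)-channel maps are unprojected onto ``grid``, averaged
    across views, passed through the 3D head, and each slot's volume heatmap
    is softmax-normalized and soft-argmaxed into world-mm coordinates.
    """
    fc = {}
    n_slots = None
    for view in VIEWS:
        fe = as_tensor(features[view])
        hm = as_tensor(heatmaps[view])
        n_slots = hm.shape[0]
        hm_big = F.resize_bilinear(hm, fe.shape[1], fe.shape[2])
        fc[view] = concat([fe, hm_big], axis=0)
    if samplers is None:
        shape = (fc["lat"].shape[1], fc["lat"].shape[2])
        samplers = {v: projection_sampler(cameras[v], grid, shape) for v in VIEWS}
    volume = unproject_features(
        [fc[v] for v in VIEWS], [cameras[v] for v in VIEWS], grid, [samplers[v] for v in VIEWS]
    )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    slot_logits = head(volume)  # (N, nx, ny, nz)
    flat = slot_logits.reshape(n_slots, grid.n_voxels)
    if temperature != 1.0:
        flat = flat * (1.0 / temperature)
    probs = F.softmax(flat, axis=1)  # per-slot softmax over voxels
    centers = grid.voxel_centers().astype(probs.data.dtype)
    coords_t = probs @ centers  # (N, 3) probability-weighted voxel centers
    probs_t = probs.reshape(n_slots, *grid.dims)
    pmax = {
        v: np.asarray(heatmaps[v].data if isinstance(heatmaps[v], Tensor) else heatmaps[v])
        .reshape(n_slots, -1)
        .max(axis=1)
        for v in VIEWS
    }
    valid = _pmax_valid(pmax, threshold, rule)
    return LocalizationResult(
        coords=np.asarray(coords_t.data, dtype=np.float64),
        heatmaps_2d={
            v: np.asarray(heatmaps[v].data if isinstance(heatmaps[v], Tensor) else heatmaps[v])
            for v in VIEWS
        },
        pmax=pmax,
        valid=valid,
        coords_tensor=coords_t,
        volume_probs=probs_t,
    )


def validity_filter(
    result: LocalizationResult, threshold: float = 0.5, rule: str = "both"
) -> LocalizationResult:
    """Re-apply the max-probability presence rule with a new threshold/rule."""
    result.valid = _pmax_valid(result.pmax, threshold, rule)
    return result
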