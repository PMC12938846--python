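"""End-to-end network: feature extraction, prompt-guided enhancement, dual
attention context extraction and 3D multi-view fusion."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import prompting
from .backbone import FeatureEnhancer, UNetSPP
from .brickformer import SCEUnit
from .config import RunConfig
from .fusion3d import FusionHead, LocalizationResult, fuse_and_localize
from .geometry import VolumeGrid
from .nn import Module, Tensor, as_tensor
from .nn.modules import DTYPE

__all__ = ["X2PNet", "save_checkpoint", "load_checkpoint"]

VIEWS = ("lat", "ap")


class X2PNet(Module):
    """Biplanar prompt-guided 2D/3D vertebra localizer."""

    def __init__(self, config: RunConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        self.vfe = UNetSPP(
            out_channels=config.d, level_channels=tuple(config.level_channels), rng=rng
        )
        self.fe = FeatureEnhancer(
            d=config.d,
            hidden=config.fe_hidden,
            heads=config.heads,
            layers=config.fe_layers,
            rng=rng,
        )
        self.sce = SCEUnit(
            n_slots=config.n_slots,
            d=config.d,
            embed_size=config.embed_size,
            alpha=config.alpha,
            topk=config.topk,
            heads=config.heads,
            layers=config.sce_layers,
            rng=rng,
        )
        self.head = FusionHead(config.d + config.n_slots, config.n_slots, config.head_hidden, rng)
        self.grid = VolumeGrid.from_box(config.grid_lo, config.grid_hi, config.grid_dims)

    def forward_view(self, image: np.ndarray, prompt: prompting.Prompt):
        """One view: image (h, w) -> (enhanced features fe, heatmaps, embeddings)."""
        h, w = image.shape
        r = self.config.prompt_radius
        fi = self.vfe(as_tensor(image.astype(DTYPE)))
        masks = prompting.build_prompt_masks(prompt, w, h, r)
        fp = prompting.prompt_features(fi, masks.Mp, prompt, r)
        fe_feat = self.fe(fi, fp)
        fm = prompting.masked_features(fe_feat, masks.Md, normalize=self.config.md_normalize)
        e_ctx, heatmaps, selections = self.sce(fm)
        return fe_feat, heatmaps, e_ctx, selections

    def forward(
        self,
        images: dict[str, np.ndarray],
        cameras: dict,
        prompts: dict[str, prompting.Prompt],
        samplers: dict | None = None,
    ) -> dict:
        features = {}
        heatmaps = {}
        embeddings = {}
        for view in VIEWS:
            prompt = prompts[view]
            if not isinstance(prompt, prompting.Prompt):
                prompt = prompting.Prompt(int(prompt[0]), int(prompt[1]), view)
            fe_feat, hm, e_ctx, _ = self.forward_view(images[view], prompt)
            features[view] = fe_feat
            heatmaps[view] = hm
            embeddings[view] = e_ctx
        result = fuse_and_localize(
            heatmaps,
            features,
            cameras,
            self.grid,
            self.head,
            threshold=self.config.validity_threshold,
            rule=self.config.validity_rule,
            samplers=samplers,
            temperature=self.config.softargmax_temperature,
        )
        return {
            "result": result,
            "heatmaps": heatmaps,
            "features": features,
            "embeddings": embeddings,
        }

    def localize(self, images, cameras, prompts, samplers=None) -> LocalizationResult:
        return self.forward(images, cameras, prompts, samplers)["result"]

    # grid-normalized coordinates for the 3D loss term (unit-box scale).
    # Normalizing by voxel spacing instead makes the 3D term dominate the
    # heatmap losses early and stalls peak formation (tested; much worse).
    def normalize_coords(self, coords):
        lo = np.asarray(self.config.grid_lo)
        hi = np.asarray(self.config.grid_hi)
        center = ((lo + hi) / 2).astype(DTYPE)
        scale = DTYPE(1.0) / (hi - lo).astype(DTYPE)
        if isinstance(coords, Tensor):
            return (coords - Tensor(center)) * Tensor(scale)
        return (np.asarray(coords) - center) * scale


def save_checkpoint(model: X2PNet, path: Path, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez_compressed(path, **state)
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path: Path) -> X2PNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    config = RunConfig.from_dict(meta["config"])
    model = X2PNet(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
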