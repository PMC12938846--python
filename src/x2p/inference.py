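"""Inference on calibrated image pairs, including sliding-window chaining for
tall inputs: the bottom-most valid vertebra of one window becomes the prompt
of the next."""

from __future__ import annotations

import numpy as np

from .backbone import sliding_window_split
from .fusion3d import LocalizationResult
from .geometry import BehindCameraError, project
from .model import X2PNet
from .nn.tensor import no_grad
from .prompting import Prompt

__all__ = ["infer_pair"]

VIEWS = ("lat", "ap")


def infer_pair(
    model: X2PNet,
    images: dict[str, np.ndarray],
    cameras: dict,
    prompts: dict[str, tuple[int, int]],
    window: int | None = None,
    merge_tol_mm: float = 5.0,
) -> LocalizationResult:
    """Localize vertebrae on one biplanar pair.

    Images no taller than ``window`` (default: the configured input height)
    take the single-window path.  Taller images are split into consecutive
    windows; each window's prompt after the first is the projection of the
    previous window's bottom-most valid 3D prediction.  Valid slots from all
    windows are merged (predictions closer than ``merge_tol_mm`` to an
    already-kept one are dropped) and re-ordered superior to inferior.
    """
    window = window or model.config.image_size[1]
    h = images["lat"].shape[0]
    for view in VIEWS:
        x, y = prompts[view]
        Prompt(int(x), int(y), view).validate(images[view].shape[1], images[view].shape[0])
    if h <= window:
        with no_grad():
            return model.localize(images, cameras, prompts)

    windows = {v: sliding_window_split(images[v], window) for v in VIEWS}
    offsets = [off for _, off in windows["lat"]]
    current_prompts = {v: tuple(prompts[v]) for v in VIEWS}
    kept: list[tuple[np.ndarray, float, float]] = []  # (coords, pmax_lat, pmax_ap)
    for wi, off in enumerate(offsets):
        sub_images = {v: windows[v][wi][0] for v in VIEWS}
        sub_cams = {v: cameras[v].translated(0, off) for v in VIEWS}
        sub_prompts = {}
        usable = True
        for view in VIEWS:
            x, y = current_prompts[view]
            y_local = y - off
            if not (0 <= x < sub_images[view].shape[1] and 0 <= y_local < window):
                usable = False
                break
            sub_prompts[view] = (int(x), int(y_local))
        if not usable:
            continue
        with no_grad():
            result = model.localize(sub_images, sub_cams, sub_prompts)
        valid_idx = np.nonzero(result.valid)[0]
        for n in valid_idx:
            c = result.coords[n]
            if all(np.linalg.norm(c - k[0]) > merge_tol_mm for k in kept):
                kept.append((c, float(result.pmax["lat"][n]), float(result.pmax["ap"][n])))
        if wi + 1 < len(offsets) and valid_idx.size:
            # chain: bottom-most (largest local image y) valid prediction -> next prompt
            bottom = max(
                valid_idx,
                key=lambda n: project(sub_cams["lat"], result.coords[n])[1],
            )
            for view in VIEWS:
                try:
                    uv = project(cameras[view], result.coords[bottom])
                except BehindCameraError:
                    continue
                current_prompts[view] = (int(round(uv[0])), int(round(uv[1])))

    if kept:
        kept.sort(key=lambda k: -k[0][2])  # superior (large z) first
        coords = np.stack([k[0] for k in kept])
        pmax_lat = np.array([k[1] for k in kept])
        pmax_ap = np.array([k[2] for k in kept])
    else:
        coords = np.zeros((0, 3))
        pmax_lat = np.zeros(0)
        pmax_ap = np.zeros(0)
    s = model.config.embed_size
    return LocalizationResult(
        coords=coords,
        heatmaps_2d={v: np.zeros((coords.shape[0], s, s)) for v in VIEWS},
        pmax={"lat": pmax_lat, "ap": pmax_ap},
        valid=np.ones(coords.shape[0], dtype=bool),
        level_guesses=[f"V{i + 1}" for i in range(coords.shape[0])],
    )
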