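"""Run configuration: model, optimizer, dataset and grid settings.

Named presets: ``desk`` (small, CPU-friendly defaults used by the test
suite) and two full-scale profiles — ``longfilm`` (512x512 inputs, d=64,
N=10 slots, alpha=32, k=8; long-film acquisitions spanning many levels) and
``carm`` (N=5, alpha=8, k=4; short C-arm fields of view).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "PRESETS", "load_config", "save_config"]


@dataclass
class RunConfig:
    # data
    dataset_dir: str = ""
    out_dir: str = "runs/default"
    image_size: tuple[int, int] = (128, 128)
    # model
    d: int = 16
    n_slots: int = 5
    embed_size: int = 16
    alpha: int = 8
    topk: int = 4
    heads: int = 8
    fe_layers: int = 4
    fe_hidden: int = 32
    sce_layers: int = 4
    level_channels: tuple[int, ...] = (8, 16, 16, 16)
    head_hidden: int = 6
    prompt_radius: int = 16
    md_normalize: bool = True
    include_reference_slot: bool = True
    # volume grid: axis-aligned world box enclosing the phantom with margin
    # (chains up to ~130 mm long, lateral curvature, +/-15 deg pose rotation)
    grid_lo: tuple[float, float, float] = (-100.0, -100.0, -100.0)
    grid_hi: tuple[float, float, float] = (100.0, 100.0, 100.0)
    grid_dims: tuple[int, int, int] = (64, 64, 64)
    # losses / validity
    loss_sigma: float = 1.0
    loss_eps: float = 1e-6
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    validity_threshold: float = 0.5
    validity_rule: str = "both"
    softargmax_temperature: float = 1.0
    # optimization
    lr: float = 1e-3
    lr_step_epoch: int | None = None  # optional step decay: lr *= lr_step_factor
    lr_step_factor: float = 0.4
    weight_decay: float = 0.05
    batch_size: int = 2
    epochs: int = 100
    crop_augment: bool = True
    crop_height: int = 96
    min_crop_vertebrae: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in known:
                raise KeyError(f"unknown config key: {key}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


def _desk() -> RunConfig:
    return RunConfig()


def _longfilm() -> RunConfig:
    return RunConfig(
        image_size=(512, 512),
        d=64,
        n_slots=10,
        alpha=32,
        topk=8,
        fe_hidden=64,
        level_channels=(16, 32, 64, 128),
        head_hidden=32,
        prompt_radius=40,
        epochs=100,
        batch_size=2,
        weight_decay=0.05,
    )


def _carm() -> RunConfig:
    cfg = _longfilm()
    cfg.n_slots = 5
    cfg.alpha = 8
    cfg.topk = 4
    return cfg


PRESETS = {"desk": _desk, "longfilm": _longfilm, "carm": _carm}


def load_config(path: Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    preset = data.pop("preset", None)
    cfg = PRESETS[preset]() if preset else RunConfig()
    base = cfg.to_dict()
    base.update(data)
    return RunConfig.from_dict(base)


def save_config(cfg: RunConfig, path: Path) -> None:
    data = {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.to_dict().items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
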