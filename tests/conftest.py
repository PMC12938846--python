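import numpy as np
import pytest

from x2p.config import RunConfig
from x2p.phantoms import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_run_config(**overrides) -> RunConfig:
    """A very small profile for fast unit tests (not the desk profile)."""
    base = dict(
        image_size=(64, 64),
        d=8,
        n_slots=3,
        embed_size=8,
        alpha=8,
        topk=2,
        heads=2,
        fe_layers=2,
        fe_hidden=8,
        sce_layers=2,
        level_channels=(4, 8, 8, 8),
        head_hidden=4,
        prompt_radius=8,
        grid_lo=(-60.0, -60.0, -60.0),
        grid_hi=(60.0, 60.0, 60.0),
        grid_dims=(24, 24, 24),
        crop_augment=False,
        epochs=2,
        lr=1e-3,
        seed=0,
    )
    base.update(overrides)
    return RunConfig(**base)


def tiny_phantom_config(**overrides) -> PhantomConfig:
    base = dict(
        vol_dims=(48, 48, 48),
        spacing_mm=4.0,
        n_vertebrae=(3, 3),
        image_px=(64, 64),
        drr_steps=64,
        detector_size_m=(0.4, 0.4),
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small on-disk dataset shared across tests that only read it."""
    from x2p.phantoms import make_dataset

    out = tmp_path_factory.mktemp("tiny_ds")
    cfg = tiny_phantom_config()
    manifest = make_dataset(out, 8, seed=11, split=(0.5, 0.25, 0.25), config=cfg, force=True)
    return out, manifest, cfg
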