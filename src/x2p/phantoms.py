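"""Synthetic biplanar spine phantoms: attenuation volumes, DRR rendering,
pose perturbation and exact landmark annotation.

The generator builds a chain of ellipsoidal "vertebral bodies" along a smooth
vertical curve inside an isotropic attenuation volume, renders perspective
line-integral projections (digitally reconstructed radiographs) onto the two
views of a calibrated biplanar rig, and records the exactly projected 2D
landmarks together with the per-view prompt (the top-most body's center).
"""

from __future__ import annotations

import csv
import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import Landmark3D, ProjectionMatrix, make_biplanar_cameras, project

__all__ = [
    "PhantomConfig",
    "SpinePhantom",
    "BiplanarSample",
    "generate_phantom",
    "render_drr",
    "perturb_pose",
    "make_biplanar_sample",
    "make_dataset",
    "load_sample",
    "load_manifest",
]


@dataclass
class PhantomConfig:
    vol_dims: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 2.0
    n_vertebrae: tuple[int, int] = (3, 5)  # inclusive range
    body_radius_mm: tuple[float, float] = (8.0, 12.0)  # lateral semi-axes
    body_height_mm: tuple[float, float] = (7.0, 10.0)  # vertical semi-axis
    gap_mm: tuple[float, float] = (4.0, 8.0)
    curvature_amplitude_mm: float = 4.0
    intensity: tuple[float, float] = (0.8, 1.2)
    implant_prob: float = 0.0
    deformity_prob: float = 0.0
    deformity_amplitude_mm: float = 12.0
    rot_vertical_deg: float = 15.0  # pose perturbation ranges (+/-)
    rot_coronal_deg: float = 5.0
    rot_sagittal_deg: float = 5.0
    noise_sigma: float = 0.0  # additive Gaussian on rendered images
    drr_steps: int = 192  # ray-marching steps per ray
    image_px: tuple[int, int] = (128, 128)
    detector_size_m: tuple[float, float] = (0.4, 0.4)
    source_to_detector_mm: float = 1200.0
    source_to_object_mm: float = 800.0

    def cameras(self) -> tuple[ProjectionMatrix, ProjectionMatrix]:
        return make_biplanar_cameras(
            self.detector_size_m,
            self.image_px,
            self.source_to_detector_mm,
            self.source_to_object_mm,
        )


@dataclass
class SpinePhantom:
    volume: np.ndarray  # (nx, ny, nz) attenuation, >= 0
    spacing_mm: float
    origin: np.ndarray  # world mm of voxel (0, 0, 0)
    landmarks: list[Landmark3D]
    meta: dict = field(default_factory=dict)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin - 0.5 * self.spacing_mm
        hi = self.origin + (np.array(self.volume.shape) - 0.5) * self.spacing_mm
        return lo, hi


@dataclass
class BiplanarSample:
    images: dict[str, np.ndarray]  # view -> (h, w) float in [0, 1]
    cameras: dict[str, ProjectionMatrix]
    landmarks_3d: list[Landmark3D]
    landmarks_2d: dict[str, np.ndarray]  # view -> (n, 2) px
    prompts: dict[str, tuple[int, int]]  # view -> (x, y) px
    meta: dict = field(default_factory=dict)


def generate_phantom(config: PhantomConfig, seed: int) -> SpinePhantom:
    """Deterministically generate one spine phantom for a seed."""
    rng = np.random.default_rng(seed)
    dims = np.array(config.vol_dims, dtype=int)
    sp = float(config.spacing_mm)
    origin = -(dims - 1) / 2.0 * sp  # volume centered on the world origin
    extent = dims * sp

    lo_n, hi_n = config.n_vertebrae
    n = int(rng.integers(lo_n, hi_n + 1))
    radii = rng.uniform(*config.body_radius_mm, size=n)
    heights = rng.uniform(*config.body_height_mm, size=n)
    gaps = rng.uniform(*config.gap_mm, size=max(n - 1, 0))
    chain_len = 2 * heights.sum() + gaps.sum()
    if chain_len > 0.9 * extent[2] or radii.max() * 2 > 0.5 * min(extent[0], extent[1]):
        raise ValueError(
            f"config error: chain of {n} bodies (length {chain_len:.0f} mm) "
            f"does not fit the {extent} mm volume"
        )

    deformity = bool(rng.random() < config.deformity_prob)
    implant = bool(rng.random() < config.implant_prob)
    amp = config.curvature_amplitude_mm * rng.uniform(0.3, 1.0)
    amp_lat = config.deformity_amplitude_mm if deformity else amp
    phase = rng.uniform(0, 2 * np.pi)

    # centroids superior (largest z) to inferior along a smooth curve
    zs = np.empty(n)
    z_cursor = chain_len / 2.0
    for i in range(n):
        zs[i] = z_cursor - heights[i]
        z_cursor -= 2 * heights[i] + (gaps[i] if i < n - 1 else 0.0)
    span = max(chain_len, 1.0)
    if config.curvature_amplitude_mm == 0 and not deformity:
        xs = np.zeros(n)
        ys = np.zeros(n)
    else:
        xs = amp_lat * np.sin(np.pi * (zs - zs.min()) / span + phase)
        ys = amp * 0.5 * np.cos(np.pi * (zs - zs.min()) / span + phase)
    centroids = np.stack([xs, ys, zs], axis=1)

    volume = np.zeros(tuple(dims), dtype=np.float32)
    intensities = rng.uniform(*config.intensity, size=n)
    grid_axes = [origin[a] + np.arange(dims[a]) * sp for a in range(3)]
    for i in range(n):
        _add_ellipsoid(
            volume,
            grid_axes,
            center=centroids[i],
            semi_axes=(radii[i], radii[i], heights[i]),
            value=intensities[i],
        )
    if implant:
        host = int(rng.integers(0, n))
        offset = rng.uniform(-0.5, 0.5, size=3) * radii[host]
        _add_ellipsoid(
            volume,
            grid_axes,
            center=centroids[host] + offset,
            semi_axes=(3.0, 3.0, 3.0),
            value=10.0 * intensities[host],
        )

    landmarks = [
        Landmark3D(coords=centroids[i], level_label=f"V{i + 1}", slot_index=i) for i in range(n)
    ]
    meta = {
        "seed": int(seed),
        "n_vertebrae": n,
        "implant": implant,
        "deformity": deformity,
    }
    return SpinePhantom(volume, sp, origin, landmarks, meta)


def _add_ellipsoid(volume, grid_axes, center, semi_axes, value):
    """Add `value` inside an axis-aligned ellipsoid, clipped to the volume."""
    slices = []
    local_axes = []
    for a in range(3):
        ax = grid_axes[a]
        sel = np.nonzero(np.abs(ax - center[a]) <= semi_axes[a])[0]
        if sel.size == 0:
            return
        slices.append(slice(sel[0], sel[-1] + 1))
        local_axes.append((ax[sel[0] : sel[-1] + 1] - center[a]) / semi_axes[a])
    u, v, w = np.meshgrid(*local_axes, indexing="ij")
    inside = u * u + v * v + w * w <= 1.0
    volume[tuple(slices)] += value * inside


def render_drr(
    phantom: SpinePhantom,
    camera: ProjectionMatrix,
    image_px: tuple[int, int],
    n_steps: int = 192,
    normalize: bool = True,
) -> np.ndarray:
    """Perspective line-integral projection of the attenuation volume.

    Each pixel value is the integral of attenuation along the viewing ray
    (fixed per-ray step count over the ray's volume-bounding-box span,
    trilinear volume sampling), optionally min-max normalized to [0, 1].
    Returns an (h, w) float64 image.
    """
    wpx, hpx = int(image_px[0]), int(image_px[1])
    src = camera.center()
    uu, vv = np.meshgrid(np.arange(wpx), np.arange(hpx))
    dirs = camera.ray_direction(uu.ravel().astype(float), vv.ravel().astype(float))
    if not np.all(np.isfinite(dirs)) or np.any(np.linalg.norm(dirs, axis=-1) == 0):
        raise ValueError("camera error: degenerate ray direction")

    lo, hi = phantom.world_bounds()
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - src[None, :]) / dirs
        t2 = (hi[None, :] - src[None, :]) / dirs
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    tmin = np.maximum(tmin, 0.0)
    hit = tmax > tmin
    span = np.where(hit, tmax - tmin, 0.0)

    steps = (np.arange(n_steps) + 0.5) / n_steps  # (S,)
    ts = tmin[:, None] + span[:, None] * steps[None, :]  # (R, S)
    pts = src[None, None, :] + dirs[:, None, :] * ts[..., None]  # (R, S, 3)
    vox = (pts - phantom.origin) / phantom.spacing_mm
    samples = ndimage.map_coordinates(
        phantom.volume,
        vox.reshape(-1, 3).T,
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(-1, n_steps)
    integral = samples.sum(axis=1) * (span / n_steps)
    image = integral.reshape(hpx, wpx)
    if normalize:
        rng_val = image.max() - image.min()
        if rng_val > 0:
            image = (image - image.min()) / rng_val
    return image


def perturb_pose(phantom: SpinePhantom, seed: int, config: PhantomConfig | None = None) -> SpinePhantom:
    """Rigidly rotate volume and landmarks by the same random rotation.

    Angles are sampled uniformly in +/- (vertical, coronal, sagittal) ranges;
    the rotation is about the volume center (world origin of the default
    phantom). A zero-range config is an exact identity.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    a_z = rng.uniform(-config.rot_vertical_deg, config.rot_vertical_deg)
    a_x = rng.uniform(-config.rot_coronal_deg, config.rot_coronal_deg)
    a_y = rng.uniform(-config.rot_sagittal_deg, config.rot_sagittal_deg)
    if a_z == 0.0 and a_x == 0.0 and a_y == 0.0:
        return phantom
    rot = Rotation.from_euler("zxy", [a_z, a_x, a_y], degrees=True)
    R = rot.as_matrix()
    dims = np.array(phantom.volume.shape)
    center = phantom.origin + (dims - 1) / 2.0 * phantom.spacing_mm

    Rinv = R.T
    # output voxel o -> input voxel Rinv @ o + offset (isotropic spacing)
    offset = (Rinv @ (phantom.origin - center) + center - phantom.origin) / phantom.spacing_mm
    volume = ndimage.affine_transform(
        phantom.volume, Rinv, offset=offset, order=1, mode="constant", cval=0.0
    )
    landmarks = [
        Landmark3D(R @ (lm.coords - center) + center, lm.level_label, lm.slot_index)
        for lm in phantom.landmarks
    ]
    meta = dict(phantom.meta, pose_angles_deg=[a_z, a_x, a_y], pose_seed=int(seed))
    return SpinePhantom(volume, phantom.spacing_mm, phantom.origin.copy(), landmarks, meta)


def make_biplanar_sample(
    phantom: SpinePhantom,
    config: PhantomConfig,
    noise_rng: np.random.Generator | None = None,
) -> BiplanarSample:
    """Render both views and annotate exact 2D landmarks and prompts."""
    lat, ap = config.cameras()
    cameras = {"lat": lat, "ap": ap}
    images = {}
    landmarks_2d = {}
    prompts = {}
    coords3d = np.stack([lm.coords for lm in phantom.landmarks])
    for view, cam in cameras.items():
        img = render_drr(phantom, cam, config.image_px, n_steps=config.drr_steps)
        if config.noise_sigma > 0 and noise_rng is not None:
            img = np.clip(img + noise_rng.normal(0, config.noise_sigma, img.shape), 0.0, 1.0)
        images[view] = img
        uv = project(cam, coords3d)
        landmarks_2d[view] = uv
        prompts[view] = (int(round(uv[0, 0])), int(round(uv[0, 1])))
    return BiplanarSample(
        images=images,
        cameras=cameras,
        landmarks_3d=list(phantom.landmarks),
        landmarks_2d=landmarks_2d,
        prompts=prompts,
        meta=dict(phantom.meta),
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def _write_png16(path: Path, image: np.ndarray) -> None:
    arr = np.clip(image, 0.0, 1.0)
    Image.fromarray((arr * 65535).round().astype(np.uint16)).save(path)


def _read_png16(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.float64) / 65535.0


def save_sample(sample: BiplanarSample, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for view, img in sample.images.items():
        _write_png16(out_dir / f"{view}.png", img)
    with open(out_dir / "cameras.json", "w") as fh:
        json.dump([sample.cameras[v].to_dict() for v in ("lat", "ap")], fh, indent=1)
    with open(out_dir / "landmarks.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "slot", "x_mm", "y_mm", "z_mm"])
        for lm in sample.landmarks_3d:
            writer.writerow(
                [lm.level_label, lm.slot_index]
                + [repr(float(c)) for c in lm.coords]  # repr round-trips float64 exactly
            )
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump(
            {
                "landmarks_2d": {v: a.tolist() for v, a in sample.landmarks_2d.items()},
                "prompts": {v: list(p) for v, p in sample.prompts.items()},
                "meta": sample.meta,
            },
            fh,
            indent=1,
        )


def load_sample(sample_dir: Path) -> BiplanarSample:
    sample_dir = Path(sample_dir)
    with open(sample_dir / "cameras.json") as fh:
        cameras = {d["view"]: ProjectionMatrix.from_dict(d) for d in json.load(fh)}
    images = {v: _read_png16(sample_dir / f"{v}.png") for v in cameras}
    landmarks = []
    with open(sample_dir / "landmarks.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            landmarks.append(
                Landmark3D(
                    np.array([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]),
                    row["level"],
                    int(row["slot"]),
                )
            )
    with open(sample_dir / "annotations.json") as fh:
        ann = json.load(fh)
    return BiplanarSample(
        images=images,
        cameras=cameras,
        landmarks_3d=landmarks,
        landmarks_2d={v: np.asarray(a, dtype=np.float64) for v, a in ann["landmarks_2d"].items()},
        prompts={v: tuple(p) for v, p in ann["prompts"].items()},
        meta=ann.get("meta", {}),
    )


def make_dataset(
    out_dir: Path,
    n_samples: int,
    seed: int,
    split: tuple[float, float, float] = (0.76, 0.04, 0.20),
    config: PhantomConfig | None = None,
    force: bool = False,
    perturb: bool = True,
) -> dict:
    """Generate and write a deterministic dataset with disjoint splits.

    Split fractions must sum to 1; counts are assigned by rounding the
    train/val fractions and giving the remainder to the test split.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    config = config or PhantomConfig()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"output dir {out_dir} is not empty (use force)")
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_train = int(round(split[0] * n_samples))
    n_val = int(round(split[1] * n_samples))
    n_test = n_samples - n_train - n_val
    assignments = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_samples, dtype=np.uint32)
    splits: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for i in range(n_samples):
        sample_id = f"sample_{i:04d}"
        phantom = generate_phantom(config, int(child_seeds[2 * i]))
        if perturb:
            phantom = perturb_pose(phantom, int(child_seeds[2 * i + 1]), config)
        noise_rng = np.random.default_rng(int(child_seeds[2 * i + 1]) + 1)
        sample = make_biplanar_sample(phantom, config, noise_rng)
        save_sample(sample, out_dir / sample_id)
        splits[assignments[i]].append(sample_id)

    manifest = {
        "n_samples": n_samples,
        "seed": int(seed),
        "split": list(split),
        "splits": splits,
        "config": asdict(config),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(dataset_dir: Path) -> dict:
    with open(Path(dataset_dir) / "manifest.json") as fh:
        return json.load(fh)
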