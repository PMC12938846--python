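"""Projective camera model, pseudo-3D volume grid, unprojection and soft-argmax.

Conventions (used throughout the package):

* World frame: right-handed, millimetres, ``+z`` = superior.
* Pixel coordinates: 0-based ``(x=column, y=row)``, pixel centers at integer
  coordinates; image row ``y`` increases downward, so superior anatomy
  appears at small ``y``.
* A :class:`ProjectionMatrix` maps homogeneous world points (mm) to
  homogeneous pixels via a 3x4 matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, as_tensor
from .nn.functional import GatherPlan, bilinear_gather, bilinear_sample_plan, softmax

__all__ = [
    "BehindCameraError",
    "ProjectionMatrix",
    "VolumeGrid",
    "Landmark3D",
    "project",
    "make_biplanar_cameras",
    "unproject_features",
    "soft_argmax",
    "projection_sampler",
    "save_cameras",
    "load_cameras",
]

VIEWS = ("lat", "ap")


class BehindCameraError(ValueError):
    """A world point has zero or negative projective depth under a camera."""


@dataclass
class ProjectionMatrix:
    """A 3x4 homogeneous world(mm) -> pixel mapping for one calibrated view."""

    P: np.ndarray
    view_id: str = "lat"

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.shape != (3, 4):
            raise ValueError(f"projection matrix must be 3x4, got {self.P.shape}")
        if np.linalg.matrix_rank(self.P[:, :3]) != 3:
            raise ValueError("left 3x3 submatrix of the projection matrix is rank deficient")

    def project(self, points) -> np.ndarray:
        return project(self, points)

    def center(self) -> np.ndarray:
        """Camera center (the point all rays pass through), world mm."""
        return -np.linalg.solve(self.P[:, :3], self.P[:, 3])

    def ray_direction(self, u, v) -> np.ndarray:
        """Unit world direction of the viewing ray through pixel(s) (u, v)."""
        uv1 = np.stack(np.broadcast_arrays(u, v, np.ones_like(np.asarray(u, float))), axis=-1)
        d = uv1 @ np.linalg.inv(self.P[:, :3]).T
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def translated(self, dx: float, dy: float) -> "ProjectionMatrix":
        """Camera for the image cropped so pixel (dx, dy) becomes (0, 0)."""
        shift = np.array([[1.0, 0.0, -dx], [0.0, 1.0, -dy], [0.0, 0.0, 1.0]])
        return ProjectionMatrix(shift @ self.P, self.view_id)

    def to_dict(self) -> dict:
        return {"view": self.view_id, "P": self.P.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionMatrix":
        return cls(np.asarray(d["P"], dtype=np.float64), d["view"])


def project(camera: ProjectionMatrix, points) -> np.ndarray:
    """Project world points (..., 3) mm to continuous pixel coordinates (..., 2)."""
    pts = np.asarray(points, dtype=np.float64)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    homo = np.concatenate([pts, np.ones((*pts.shape[:-1], 1))], axis=-1)
    proj = homo @ camera.P.T
    depth = proj[..., 2]
    if np.any(depth <= 1e-12):
        raise BehindCameraError("point behind camera: non-positive projective depth")
    uv = proj[..., :2] / depth[..., None]
    return uv[0] if squeeze else uv


@dataclass
class VolumeGrid:
    """Axis-aligned voxel grid; voxel_center(i,j,k) = origin + (i,j,k)*spacing."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)
        ).copy()
        self.dims = tuple(int(d) for d in self.dims)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    @classmethod
    def from_box(cls, lo, hi, dims) -> "VolumeGrid":
        """Grid whose voxel centers evenly fill the box [lo, hi]."""
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        dims = tuple(int(d) for d in np.broadcast_to(dims, (3,)))
        spacing = (hi - lo) / np.maximum(np.array(dims) - 1, 1)
        spacing = np.where(spacing <= 0, 1.0, spacing)
        return cls(lo, spacing, dims)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_center(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=np.float64) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers, shape (nx*ny*nz, 3), C-order over (i, j, k); cached."""
        cached = getattr(self, "_centers", None)
        if cached is None:
            ii, jj, kk = np.meshgrid(*[np.arange(d) for d in self.dims], indexing="ij")
            ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
            cached = self._centers = self.voxel_center(ijk)
        return cached

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "spacing": self.spacing.tolist(),
            "dims": list(self.dims),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeGrid":
        return cls(np.asarray(d["origin"]), np.asarray(d["spacing"]), tuple(d["dims"]))


@dataclass
class Landmark3D:
    coords: np.ndarray
    level_label: str = ""
    slot_index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)


def make_biplanar_cameras(
    detector_size_m: tuple[float, float] = (0.6, 0.6),
    detector_px: tuple[int, int] = (2048, 2048),
    source_to_detector_mm: float = 1200.0,
    source_to_object_mm: float = 800.0,
) -> tuple[ProjectionMatrix, ProjectionMatrix]:
    """Build an orthogonal biplanar rig: LAT looks along +x, AP along +y.

    Both cameras focus on the world origin; the principal point is the
    detector center. Pixel pitch = detector_size / detector_px.
    """
    if (
        min(detector_size_m) <= 0
        or source_to_detector_mm <= 0
        or source_to_object_mm <= 0
        or min(detector_px) < 1
    ):
        raise ValueError("invalid rig: all distances must be positive and detector_px >= 1")
    wpx, hpx = (int(p) for p in detector_px)
    pitch_x = detector_size_m[0] * 1000.0 / wpx  # mm per pixel
    pitch_y = detector_size_m[1] * 1000.0 / hpx
    fx = source_to_detector_mm / pitch_x
    fy = source_to_detector_mm / pitch_y
    cx = (wpx - 1) / 2.0
    cy = (hpx - 1) / 2.0
    K = np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])

    def build(rows: np.ndarray, source: np.ndarray, view: str) -> ProjectionMatrix:
        R = np.asarray(rows, dtype=np.float64)
        t = -R @ np.asarray(source, dtype=np.float64)
        return ProjectionMatrix(K @ np.hstack([R, t[:, None]]), view)

    sod = source_to_object_mm
    # rows are the camera axes (x_cam, y_cam, z_cam) expressed in world coords
    lat = build(
        np.array([[0.0, -1.0, 0.0], [0.0, 0.0, -1.0], [1.0, 0.0, 0.0]]),
        np.array([-sod, 0.0, 0.0]),
        "lat",
    )
    ap = build(
        np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]),
        np.array([0.0, -sod, 0.0]),
        "ap",
    )
    return lat, ap


@dataclass
class ProjectionSampler:
    """Cached bilinear plan for sampling one view's image at grid projections."""

    idx: np.ndarray
    wts: np.ndarray
    image_shape: tuple[int, int] = field(default=(0, 0))
    plan: GatherPlan | None = None


_SAMPLER_CACHE: dict[tuple, ProjectionSampler] = {}


def projection_sampler(
    camera: ProjectionMatrix, grid: VolumeGrid, image_shape: tuple[int, int]
) -> ProjectionSampler:
    """Precompute the unprojection sampling plan (camera and grid are static).

    Plans are memoized on (camera, grid, image shape): a dataset rendered
    with one fixed rig shares a single plan across all its samples, which
    matters — each plan holds two sparse matrices of ~4 nonzeros per voxel.
    """
    key = (
        camera.P.tobytes(),
        grid.origin.tobytes(),
        grid.spacing.tobytes(),
        grid.dims,
        tuple(image_shape),
    )
    cached = _SAMPLER_CACHE.get(key)
    if cached is not None:
        return cached
    h, w = image_shape
    uv = project(camera, grid.voxel_centers())
    idx, wts = bilinear_sample_plan(uv[:, 0], uv[:, 1], w, h)
    sampler = ProjectionSampler(idx, wts, (h, w), GatherPlan(idx, wts, h * w))
    if len(_SAMPLER_CACHE) >= 16:  # bound memory (crop offsets vary cameras)
        _SAMPLER_CACHE.pop(next(iter(_SAMPLER_CACHE)))
    _SAMPLER_CACHE[key] = sampler
    return sampler


def unproject_features(
    feature_maps,
    cameras,
    grid: VolumeGrid,
    samplers=None,
):
    """Fill a pseudo-3D volume by sampling each view at every voxel's projection.

    feature_maps: per-view (C, H, W) arrays or Tensors with a common C.
    Voxels projecting outside an image contribute 0 from that view; views are
    aggregated by elementwise mean. Returns (C, nx, ny, nz) — a Tensor if any
    input is one (differentiable in the feature values), else an ndarray.
    """
    tensors = [as_tensor(f) for f in feature_maps]
    channels = {t.shape[0] for t in tensors}
    if len(channels) != 1:
        raise ValueError(f"inconsistent inputs: channel counts differ across views: {channels}")
    c = channels.pop()
    if samplers is None:
        samplers = [
            projection_sampler(cam, grid, (t.shape[1], t.shape[2]))
            for cam, t in zip(cameras, tensors)
        ]
    acc = None
    for t, s in zip(tensors, samplers):
        sampled = bilinear_gather(t, s.plan if s.plan is not None else s.idx, s.wts)
        acc = sampled if acc is None else acc + sampled
    vol = (acc * (1.0 / len(tensors))).reshape(c, *grid.dims)
    if any(isinstance(f, Tensor) for f in feature_maps):
        return vol
    return vol.data


def soft_argmax(volume, grid: VolumeGrid, temperature: float = 1.0):
    """Probability-weighted mean of voxel centers under softmax(volume / T).

    Differentiable in the heatmap values when given a Tensor; returns a
    3-vector in world mm.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    vol = as_tensor(volume)
    if not np.all(np.isfinite(vol.data)):
        if np.all(np.isneginf(vol.data)):
            raise ValueError("degenerate input: all -inf heatmap")
        raise ValueError("heatmap contains non-finite values")
    flat = vol.reshape(grid.n_voxels)
    probs = softmax(flat * (1.0 / temperature), axis=0)
    centers = grid.voxel_centers().astype(vol.data.dtype)  # (M, 3)
    coords = probs.reshape(1, -1) @ centers
    coords = coords.reshape(3)
    if isinstance(volume, Tensor):
        return coords
    return coords.data


def expected_coords(probs: Tensor, grid: VolumeGrid) -> Tensor:
    """Weighted mean of voxel centers for already-normalized probabilities."""
    centers = grid.voxel_centers().astype(probs.data.dtype)
    return (probs.reshape(1, -1) @ centers).reshape(3)


def save_volume_nifti(volume: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write a (nx, ny, nz) or (C, nx, ny, nz) volume as NIfTI, with the
    grid's origin and spacing carried in the affine."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    data = np.asarray(volume)
    if data.ndim == 4:  # channels last for NIfTI
        data = np.moveaxis(data, 0, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_volume_nifti(path) -> tuple[np.ndarray, VolumeGrid]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    grid = VolumeGrid(affine[:3, 3], np.diag(affine[:3, :3]), data.shape[:3])
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return data, grid


def save_cameras(path, cameras) -> None:
    payload = [cam.to_dict() for cam in cameras]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_cameras(path) -> list[ProjectionMatrix]:
    with open(path) as fh:
        payload = json.load(fh)
    return [ProjectionMatrix.from_dict(d) for d in payload]
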