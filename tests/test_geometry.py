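"""Projective geometry: cameras, unprojection oracle, soft-argmax."""

import json

import numpy as np
import pytest

from x2p.geometry import (
    BehindCameraError,
    ProjectionMatrix,
    VolumeGrid,
    load_cameras,
    make_biplanar_cameras,
    project,
    projection_sampler,
    save_cameras,
    soft_argmax,
    unproject_features,
)


def brute_force_unproject(feature_maps, cameras, grid):
    """Per-voxel loop oracle: project each voxel center, bilinear-sample, mean."""
    c = feature_maps[0].shape[0]
    out = np.zeros((c,) + tuple(grid.dims))
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                center = grid.voxel_center((i, j, k))
                acc = np.zeros(c)
                for feat, cam in zip(feature_maps, cameras):
                    h, w = feat.shape[1:]
                    u, v = project(cam, center)
                    val = np.zeros(c)
                    x0, y0 = int(np.floor(u)), int(np.floor(v))
                    for dx in (0, 1):
                        for dy in (0, 1):
                            cx, cy = x0 + dx, y0 + dy
                            wgt = (u - x0 if dx else 1 - (u - x0)) * (
                                v - y0 if dy else 1 - (v - y0)
                            )
                            if 0 <= cx < w and 0 <= cy < h:
                                val += wgt * feat[:, cy, cx]
                    acc += val
                out[:, i, j, k] = acc / len(feature_maps)
    return out


class TestProject:
    def test_identity_like_camera(self):
        p = ProjectionMatrix(np.hstack([np.eye(3), np.zeros((3, 1))]), "lat")
        np.testing.assert_allclose(project(p, [0.0, 0.0, 1.0]), [0.0, 0.0])

    def test_homogeneous_scale_invariance(self, rng):
        for _ in range(100):
            m = rng.standard_normal((3, 4))
            m[:, :3] += np.eye(3) * 3  # keep full rank / positive depth likely
            pt = rng.standard_normal(3)
            depth = m[2] @ np.append(pt, 1.0)
            if abs(depth) < 1e-3:
                continue
            if depth < 0:
                m = -m
            scale = rng.uniform(0.1, 10)
            uv1 = project(ProjectionMatrix(m), pt)
            uv2 = project(ProjectionMatrix(m * scale), pt)
            np.testing.assert_allclose(uv1, uv2, atol=1e-8)

    def test_behind_camera_raises(self):
        p = ProjectionMatrix(np.hstack([np.eye(3), np.zeros((3, 1))]), "lat")
        with pytest.raises(BehindCameraError):
            project(p, [0.0, 0.0, -1.0])

    def test_batch_shape(self, rng):
        lat, _ = make_biplanar_cameras()
        pts = rng.uniform(-50, 50, (7, 3))
        assert project(lat, pts).shape == (7, 2)


class TestBiplanarRig:
    def test_pixel_pitch_full_scale(self):
        # 0.6 m detector at 2048 px -> 600/2048 mm/px
        lat, ap = make_biplanar_cameras((0.6, 0.6), (2048, 2048), 1200.0, 800.0)
        pitch = 600.0 / 2048
        assert pitch == pytest.approx(0.29296875)
        # one pixel at the detector corresponds to pitch * sod/sdd mm at the object
        uv0 = project(lat, [0.0, 0.0, 0.0])
        uv1 = project(lat, [0.0, 0.0, pitch * 800.0 / 1200.0])
        assert np.hypot(*(uv1 - uv0)) == pytest.approx(1.0, rel=1e-12)

    def test_axes_orthogonal(self):
        lat, ap = make_biplanar_cameras()
        d_lat = lat.ray_direction(1023.5, 1023.5)
        d_ap = ap.ray_direction(1023.5, 1023.5)
        assert abs(float(d_lat @ d_ap)) < 1e-12

    def test_origin_projects_to_detector_center(self):
        lat, ap = make_biplanar_cameras((0.6, 0.6), (2048, 2048), 1200.0, 800.0)
        for cam in (lat, ap):
            np.testing.assert_allclose(project(cam, [0, 0, 0]), [1023.5, 1023.5], atol=1e-9)

    def test_invalid_rig_rejected(self):
        with pytest.raises(ValueError):
            make_biplanar_cameras((0.6, 0.6), (2048, 2048), -5.0, 800.0)

    def test_superior_maps_to_smaller_row(self):
        lat, ap = make_biplanar_cameras()
        for cam in (lat, ap):
            assert project(cam, [0, 0, 50.0])[1] < project(cam, [0, 0, 0.0])[1]

    def test_serialization_roundtrip(self, tmp_path):
        cams = make_biplanar_cameras()
        save_cameras(tmp_path / "cams.json", cams)
        loaded = load_cameras(tmp_path / "cams.json")
        for a, b in zip(cams, loaded):
            assert a.view_id == b.view_id
            np.testing.assert_array_equal(a.P, b.P)


class TestVolumeGrid:
    def test_voxel_center_formula(self):
        g = VolumeGrid(origin=[-10, 0, 5], spacing=[1, 2, 3], dims=(4, 4, 4))
        np.testing.assert_array_equal(g.voxel_center((1, 2, 3)), [-9, 4, 14])

    def test_from_box_covers_box(self):
        g = VolumeGrid.from_box([-10, -10, -10], [10, 10, 10], 5)
        centers = g.voxel_centers()
        np.testing.assert_allclose(centers.min(axis=0), [-10, -10, -10])
        np.testing.assert_allclose(centers.max(axis=0), [10, 10, 10])

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            VolumeGrid(origin=[0, 0, 0], spacing=[0, 1, 1], dims=(2, 2, 2))


class TestUnproject:
    @pytest.fixture
    def small_rig(self):
        lat, ap = make_biplanar_cameras((0.4, 0.4), (16, 16), 1200.0, 800.0)
        grid = VolumeGrid.from_box([-40, -40, -40], [40, 40, 40], 8)
        return lat, ap, grid

    def test_zero_maps_give_zero_volume(self, small_rig):
        lat, ap, grid = small_rig
        feats = [np.zeros((2, 16, 16)), np.zeros((2, 16, 16))]
        vol = unproject_features(feats, [lat, ap], grid)
        assert vol.shape == (2, 8, 8, 8)
        assert np.all(vol == 0)

    def test_matches_brute_force_oracle(self, small_rig, rng):
        lat, ap, grid = small_rig
        feats = [rng.standard_normal((3, 16, 16)), rng.standard_normal((3, 16, 16))]
        vol = unproject_features(feats, [lat, ap], grid)
        ref = brute_force_unproject(feats, [lat, ap], grid)
        np.testing.assert_allclose(vol, ref, atol=1e-12)

    def test_single_pixel_delta_support(self, small_rig, rng):
        lat, ap, grid = small_rig
        delta = np.zeros((1, 16, 16))
        delta[0, 7, 8] = 1.0
        feats = [delta, np.zeros((1, 16, 16))]
        vol = unproject_features(feats, [lat, ap], grid)
        ref = brute_force_unproject(feats, [lat, ap], grid)
        np.testing.assert_allclose(vol, ref, atol=1e-12)
        assert vol.max() > 0

    def test_constant_maps_give_constant_in_view(self, small_rig):
        lat, ap, grid = small_rig
        c = 2.5
        feats = [np.full((1, 16, 16), c), np.full((1, 16, 16), c)]
        vol = unproject_features(feats, [lat, ap], grid)
        uv_lat = project(lat, grid.voxel_centers())
        uv_ap = project(ap, grid.voxel_centers())
        inside = np.ones(grid.n_voxels, dtype=bool)
        for uv in (uv_lat, uv_ap):
            inside &= (uv[:, 0] >= 0) & (uv[:, 0] <= 15) & (uv[:, 1] >= 0) & (uv[:, 1] <= 15)
        np.testing.assert_allclose(vol.reshape(-1)[inside], c, atol=1e-12)

    def test_channel_mismatch_rejected(self, small_rig):
        lat, ap, grid = small_rig
        with pytest.raises(ValueError, match="inconsistent"):
            unproject_features(
                [np.zeros((2, 16, 16)), np.zeros((3, 16, 16))], [lat, ap], grid
            )


def test_nifti_volume_roundtrip(tmp_path, rng):
    from x2p.geometry import load_volume_nifti, save_volume_nifti

    grid = VolumeGrid(origin=[-10, -20, -30], spacing=[2, 2, 2], dims=(6, 5, 4))
    vol = rng.random((3, 6, 5, 4)).astype(np.float32)
    save_volume_nifti(vol, grid, tmp_path / "vol.nii.gz")
    loaded, lgrid = load_volume_nifti(tmp_path / "vol.nii.gz")
    np.testing.assert_allclose(loaded, vol, atol=1e-7)
    np.testing.assert_allclose(lgrid.origin, grid.origin)
    np.testing.assert_allclose(lgrid.spacing, grid.spacing)
    assert lgrid.dims == grid.dims


class TestSoftArgmax:
    @pytest.fixture
    def grid(self):
        return VolumeGrid.from_box([-10, -10, -10], [10, 10, 10], 8)

    def test_one_hot_limit(self, grid):
        vol = np.zeros(grid.dims)
        vol[2, 3, 4] = 1.0
        out = soft_argmax(vol, grid, temperature=1e-4)
        np.testing.assert_allclose(out, grid.voxel_center((2, 3, 4)), atol=1e-9)

    def test_uniform_gives_centroid(self, grid):
        out = soft_argmax(np.ones(grid.dims), grid, temperature=1.0)
        np.testing.assert_allclose(out, grid.voxel_centers().mean(axis=0), atol=1e-9)

    def test_two_equal_peaks_midpoint(self, grid):
        # peaks chosen symmetric about the grid center so the uniform
        # background mass does not bias the probability-weighted mean
        a, b = (1, 2, 3), (6, 5, 4)
        for temp in (0.1, 1.0, 7.0):
            vol = np.full(grid.dims, -50.0)
            vol[a] = 5.0
            vol[b] = 5.0
            out = soft_argmax(vol, grid, temperature=temp)
            mid = (grid.voxel_center(a) + grid.voxel_center(b)) / 2
            np.testing.assert_allclose(out, mid, atol=1e-6)

    def test_output_inside_convex_hull(self, grid, rng):
        lo = grid.voxel_centers().min(axis=0)
        hi = grid.voxel_centers().max(axis=0)
        for _ in range(50):
            vol = rng.standard_normal(grid.dims) * rng.uniform(0.1, 10)
            out = soft_argmax(vol, grid, rng.uniform(0.05, 5))
            assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)

    def test_degenerate_input_rejected(self, grid):
        with pytest.raises(ValueError):
            soft_argmax(np.full(grid.dims, -np.inf), grid, 1.0)
        with pytest.raises(ValueError):
            soft_argmax(np.ones(grid.dims), grid, 0.0)


def peak_image(u: float, v: float, size: int, sigma_px: float = 2.0) -> np.ndarray:
    """A narrow Gaussian splat at continuous pixel (u, v) — a point landmark
    seen through a small imaging PSF.  (A literal one-pixel delta is not
    recoverable under mean-aggregation: a voxel on one view's ray can sample
    bilinear weight ~1 from that view alone and outvote the two-view
    intersection, whose per-view weights can each be < 0.5.)"""
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return np.exp(-((xx - u) ** 2 + (yy - v) ** 2) / (2 * sigma_px**2))[None]


class TestRoundTrip:
    def test_project_peak_unproject_recovers_point(self, rng):
        """project -> peak image -> unproject -> soft-argmax within a voxel."""
        lat, ap = make_biplanar_cameras((0.4, 0.4), (64, 64), 1200.0, 800.0)
        grid = VolumeGrid.from_box([-60, -60, -60], [60, 60, 60], 32)
        spacing = grid.spacing.max()
        samplers = [projection_sampler(c, grid, (64, 64)) for c in (lat, ap)]
        for _ in range(20):
            pt = rng.uniform(-45, 45, 3)
            feats = [peak_image(*project(cam, pt), 64) for cam in (lat, ap)]
            vol = unproject_features(feats, [lat, ap], grid, samplers)
            rec = soft_argmax(vol[0] * 200.0, grid, temperature=1.0)
            assert np.linalg.norm(rec - pt) < spacing
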