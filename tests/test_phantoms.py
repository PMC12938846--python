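"""Phantom generation, DRR rendering, pose perturbation, dataset I/O."""

import numpy as np
import pytest

from conftest import tiny_phantom_config
from x2p.geometry import project
from x2p.phantoms import (
    generate_phantom,
    load_manifest,
    load_sample,
    make_biplanar_sample,
    make_dataset,
    perturb_pose,
    render_drr,
)


class TestGeneratePhantom:
    def test_same_seed_bit_identical(self):
        cfg = tiny_phantom_config()
        a = generate_phantom(cfg, 42)
        b = generate_phantom(cfg, 42)
        np.testing.assert_array_equal(a.volume, b.volume)
        for la, lb in zip(a.landmarks, b.landmarks):
            np.testing.assert_array_equal(la.coords, lb.coords)

    def test_different_seeds_differ(self):
        cfg = tiny_phantom_config()
        a = generate_phantom(cfg, 1)
        b = generate_phantom(cfg, 2)
        assert not np.array_equal(a.volume, b.volume)

    def test_zero_curvature_straight_chain(self):
        cfg = tiny_phantom_config(curvature_amplitude_mm=0.0)
        ph = generate_phantom(cfg, 5)
        xs = [lm.coords[0] for lm in ph.landmarks]
        ys = [lm.coords[1] for lm in ph.landmarks]
        assert len(set(xs)) == 1 and len(set(ys)) == 1

    def test_min_gap_respected_many_seeds(self):
        cfg = tiny_phantom_config(n_vertebrae=(3, 5))
        min_gap = cfg.gap_mm[0]
        for seed in range(1000):
            ph = generate_phantom(cfg, seed)
            coords = np.stack([lm.coords for lm in ph.landmarks])
            gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
            assert np.all(gaps >= min_gap)

    def test_landmarks_ordered_superior_to_inferior(self):
        ph = generate_phantom(tiny_phantom_config(), 9)
        zs = [lm.coords[2] for lm in ph.landmarks]
        assert all(a > b for a, b in zip(zs, zs[1:]))
        assert [lm.slot_index for lm in ph.landmarks] == list(range(len(zs)))

    def test_landmarks_inside_volume(self):
        for seed in range(30):
            ph = generate_phantom(tiny_phantom_config(), seed)
            lo, hi = ph.world_bounds()
            for lm in ph.landmarks:
                assert np.all(lm.coords > lo) and np.all(lm.coords < hi)

    def test_attenuation_nonnegative(self):
        ph = generate_phantom(tiny_phantom_config(implant_prob=1.0), 3)
        assert ph.volume.min() >= 0
        assert ph.meta["implant"]

    def test_infeasible_geometry_rejected(self):
        cfg = tiny_phantom_config(vol_dims=(16, 16, 16), spacing_mm=2.0, n_vertebrae=(5, 5))
        with pytest.raises(ValueError, match="config error"):
            generate_phantom(cfg, 0)

    def test_vertebra_counts_cover_range(self):
        cfg = tiny_phantom_config(n_vertebrae=(3, 5))
        counts = {len(generate_phantom(cfg, s).landmarks) for s in range(60)}
        assert counts == {3, 4, 5}


class TestRenderDrr:
    @pytest.fixture
    def setup(self):
        cfg = tiny_phantom_config()
        ph = generate_phantom(cfg, 7)
        lat, ap = cfg.cameras()
        return cfg, ph, lat

    def test_zero_phantom_zero_image(self, setup):
        cfg, ph, lat = setup
        ph.volume[:] = 0
        img = render_drr(ph, lat, cfg.image_px, n_steps=32)
        assert np.all(img == 0)

    def test_scaling_invariance_after_normalization(self, setup):
        cfg, ph, lat = setup
        img1 = render_drr(ph, lat, cfg.image_px, n_steps=48)
        ph2 = generate_phantom(cfg, 7)
        ph2.volume *= 2.0
        img2 = render_drr(ph2, lat, cfg.image_px, n_steps=48)
        np.testing.assert_allclose(img1, img2, atol=1e-9)

    def test_linearity_before_normalization(self, setup):
        cfg, ph, lat = setup
        raw1 = render_drr(ph, lat, cfg.image_px, n_steps=48, normalize=False)
        ph.volume *= 3.0
        raw3 = render_drr(ph, lat, cfg.image_px, n_steps=48, normalize=False)
        # volume is float32; ray sums carry ~1e-7 relative error
        np.testing.assert_allclose(raw3, 3 * raw1, rtol=1e-5, atol=1e-9)

    def test_single_voxel_peak_lands_at_projection(self):
        cfg = tiny_phantom_config()
        ph = generate_phantom(cfg, 0)
        ph.volume[:] = 0
        idx = (30, 22, 25)
        ph.volume[idx] = 50.0
        center = ph.origin + np.array(idx) * ph.spacing_mm
        for cam in cfg.cameras():
            img = render_drr(ph, cam, cfg.image_px, n_steps=256)
            peak = np.unravel_index(np.argmax(img), img.shape)  # (row, col)
            u, v = project(cam, center)
            assert np.hypot(peak[1] - u, peak[0] - v) <= 1.0

    def test_image_range_and_nonconstant(self, setup):
        cfg, ph, lat = setup
        img = render_drr(ph, lat, cfg.image_px, n_steps=48)
        assert np.all(np.isfinite(img))
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert img.std() > 0


class TestPerturbPose:
    def test_zero_range_is_identity(self):
        cfg = tiny_phantom_config(
            rot_vertical_deg=0.0, rot_coronal_deg=0.0, rot_sagittal_deg=0.0
        )
        ph = generate_phantom(cfg, 3)
        out = perturb_pose(ph, 99, cfg)
        np.testing.assert_array_equal(out.volume, ph.volume)
        for a, b in zip(out.landmarks, ph.landmarks):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_rigid_pairwise_distances(self):
        cfg = tiny_phantom_config()
        ph = generate_phantom(cfg, 4)
        out = perturb_pose(ph, 17, cfg)
        a = np.stack([lm.coords for lm in ph.landmarks])
        b = np.stack([lm.coords for lm in out.landmarks])
        da = np.linalg.norm(a[:, None] - a[None], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_angles_within_bounds_many_seeds(self):
        cfg = tiny_phantom_config(vol_dims=(8, 8, 8), spacing_mm=20.0, n_vertebrae=(3, 3))
        ph = generate_phantom(cfg, 0)
        for seed in range(10_000):
            out = perturb_pose(ph, seed, cfg)
            az, ax, ay = out.meta["pose_angles_deg"]
            assert abs(az) <= cfg.rot_vertical_deg
            assert abs(ax) <= cfg.rot_coronal_deg
            assert abs(ay) <= cfg.rot_sagittal_deg


class TestBiplanarSample:
    def test_landmarks_match_projection_exactly(self):
        cfg = tiny_phantom_config()
        ph = generate_phantom(cfg, 21)
        sample = make_biplanar_sample(ph, cfg)
        for view, cam in sample.cameras.items():
            for n, lm in enumerate(sample.landmarks_3d):
                uv = project(cam, lm.coords)
                assert np.max(np.abs(uv - sample.landmarks_2d[view][n])) < 1e-9

    def test_prompt_is_topmost_landmark(self):
        cfg = tiny_phantom_config()
        sample = make_biplanar_sample(generate_phantom(cfg, 8), cfg)
        for view in ("lat", "ap"):
            expected = np.round(sample.landmarks_2d[view][0]).astype(int)
            assert sample.prompts[view] == tuple(expected)


class TestDataset:
    def test_split_counts(self, tmp_path):
        cfg = tiny_phantom_config()
        manifest = make_dataset(
            tmp_path / "ds", 25, seed=3, split=(0.76, 0.04, 0.20), config=cfg
        )
        assert len(manifest["splits"]["train"]) == 19
        assert len(manifest["splits"]["val"]) == 1
        assert len(manifest["splits"]["test"]) == 5

    def test_disjoint_splits(self, tiny_dataset):
        _, manifest, _ = tiny_dataset
        ids = sum((manifest["splits"][s] for s in ("train", "val", "test")), [])
        assert len(ids) == len(set(ids)) == manifest["n_samples"]

    def test_deterministic_manifest(self, tmp_path):
        cfg = tiny_phantom_config()
        m1 = make_dataset(tmp_path / "a", 6, seed=5, split=(0.5, 0.25, 0.25), config=cfg)
        m2 = make_dataset(tmp_path / "b", 6, seed=5, split=(0.5, 0.25, 0.25), config=cfg)
        assert m1["splits"] == m2["splits"]
        s1 = load_sample(tmp_path / "a" / "sample_0000")
        s2 = load_sample(tmp_path / "b" / "sample_0000")
        np.testing.assert_array_equal(s1.images["lat"], s2.images["lat"])
        np.testing.assert_array_equal(s1.landmarks_2d["ap"], s2.landmarks_2d["ap"])

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        out = tmp_path / "ds"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            make_dataset(out, 2, seed=0, config=tiny_phantom_config())
        make_dataset(out, 2, seed=0, split=(0.5, 0.0, 0.5), config=tiny_phantom_config(), force=True)

    def test_roundtrip_preserves_landmark_projection_identity(self, tiny_dataset):
        ds_dir, manifest, _ = tiny_dataset
        sid = manifest["splits"]["train"][0]
        sample = load_sample(ds_dir / sid)
        for view, cam in sample.cameras.items():
            uv = project(cam, np.stack([lm.coords for lm in sample.landmarks_3d]))
            assert np.max(np.abs(uv - sample.landmarks_2d[view])) < 1e-9

    def test_bad_split_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="sum to 1"):
            make_dataset(tmp_path / "x", 4, seed=0, split=(0.5, 0.2, 0.2))

    def test_manifest_loadable(self, tiny_dataset):
        ds_dir, manifest, _ = tiny_dataset
        assert load_manifest(ds_dir)["splits"] == manifest["splits"]
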