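"""Phantom generators: counts, geometry contracts, voxelization accuracy,
distortion injection, and the calibrated noise model."""

import numpy as np
import pytest
from scipy import stats

from roomct.frames import DistortionModel, Frame, Point3
from roomct.images import BACKGROUND_HU, GridSpec
from roomct.localize import localize_spheres_3d, match_fiducials
from roomct.phantoms import (
    PhantomObject,
    PhantomSpec,
    add_noise,
    inject_distortion,
    make_calibration_phantom,
    make_dot_field,
    make_head_phantom,
    make_validation_phantom,
    rasterize,
)


class TestCalibrationPhantom:
    def test_twelve_spheres_of_20mm(self):
        spec, fids = make_calibration_phantom(1000.0)
        assert len(fids) == 12
        assert all(o.shape == "sphere" and o.size[0] == 20.0 for o in spec.objects)

    def test_span_and_rank(self):
        _, fids = make_calibration_phantom(0.0)
        spans = fids.coords.max(axis=0) - fids.coords.min(axis=0)
        assert np.all(spans >= 150.0)
        centered = fids.coords - fids.coords.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[2] > 1e-2 * s[0]  # full rank: genuinely non-coplanar

    def test_centered_near_requested_y(self):
        _, fids = make_calibration_phantom(850.0)
        assert abs(fids.coords[:, 1].mean() - 850.0) < 20.0


class TestValidationPhantom:
    def test_two_spheres_separated(self):
        _, fids = make_validation_phantom(1000.0)
        assert len(fids) == 2
        assert np.linalg.norm(fids.coords[0] - fids.coords[1]) >= 100.0

    def test_too_small_separation_rejected(self):
        with pytest.raises(ValueError):
            make_validation_phantom(0.0, separation=50.0)

    def test_voxelize_localize_round_trip(self):
        spec, fids = make_validation_phantom(0.0)
        vol = rasterize(spec, spec.default_grid(spacing=(1.0, 1.0, 1.0)), supersample=2)
        found = match_fiducials(localize_spheres_3d(vol, 2), fids)
        assert np.abs(found.coords - fids.coords).max() < 0.2


class TestDotField:
    def test_thirteen_dots_by_default(self):
        assert len(make_dot_field(seed=3)) == 13

    def test_deterministic_under_seed(self):
        a = make_dot_field(seed=7)
        b = make_dot_field(seed=7)
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, make_dot_field(seed=8).coords)

    def test_inside_fov_with_min_separation(self):
        fids = make_dot_field(n=13, fov=250.0, y_extent=300.0, seed=0)
        assert np.all(np.abs(fids.coords[:, [0, 2]]) <= 125.0)
        assert np.all(np.abs(fids.coords[:, 1]) <= 150.0)
        d = np.linalg.norm(fids.coords[:, None] - fids.coords[None], axis=2)
        assert d[~np.eye(13, dtype=bool)].min() >= 20.0


class TestHeadPhantom:
    def test_isocenter_is_fiducial_sphere_center(self):
        spec, iso = make_head_phantom()
        sphere = spec.objects[-1]
        assert sphere.shape == "sphere"
        assert np.array_equal(np.asarray(sphere.center), iso.coords)

    def test_voxelized_image_has_structure(self):
        spec, _ = make_head_phantom()
        grid = spec.default_grid(spacing=(0.98, 0.98, 1.0))
        assert grid.spacing == (0.98, 0.98, 1.0)
        vol = rasterize(spec, grid)
        inside = vol.values[vol.values > BACKGROUND_HU]
        assert inside.size > 0 and inside.std() > 0


class TestRasterize:
    def test_empty_spec_is_background(self):
        vol = rasterize(PhantomSpec("empty", ()), GridSpec((0, 0, 0), (1, 1, 1), (5, 5, 5)))
        assert np.all(vol.values == BACKGROUND_HU)

    def test_sphere_volume_within_2_percent(self):
        obj = PhantomObject("sphere", (0.3, -0.2, 0.1), (20.0,), 1000.0)
        spec = PhantomSpec("s", (obj,))
        grid = GridSpec.covering((-15, -15, -15), (15, 15, 15), 1.0)
        vol = rasterize(spec, grid, supersample=2, background=0.0)
        measured = vol.values.sum() * np.prod(vol.spacing)
        expected = 4.0 / 3.0 * np.pi * 10.0**3 * 1000.0
        assert abs(measured - expected) / expected < 0.02

    def test_resolution_halving_shrinks_discretization_error(self):
        obj = PhantomObject("sphere", (0.0, 0.0, 0.0), (20.0,), 1000.0)
        spec = PhantomSpec("s", (obj,))
        expected = 4.0 / 3.0 * np.pi * 10.0**3 * 1000.0

        def err(spacing):
            grid = GridSpec.covering((-14, -14, -14), (14, 14, 14), spacing)
            vol = rasterize(spec, grid, background=0.0)
            return abs(vol.values.sum() * np.prod(vol.spacing) - expected)

        assert err(0.5) < err(1.0)


class TestInjectDistortion:
    def test_identity_model_is_noop(self):
        p = Point3((1.0, 2.0, 3.0), Frame.CT)
        assert np.array_equal(inject_distortion(p, DistortionModel(0, 0)).coords, p.coords)

    def test_inject_then_correct_is_identity(self, rng):
        model = DistortionModel(m=2.7e-3, c=-0.4)
        for _ in range(20):
            p = Point3(rng.uniform(-500, 1500, 3), Frame.CT)
            rt = model.correct_point(inject_distortion(p, model))
            assert np.abs(rt.coords - p.coords).max() < 1e-9

    def test_volume_pipeline_recovers_center(self):
        """Distort the raster, localize, correct: the original center returns."""
        spec, fids = make_validation_phantom(0.0)
        vol = rasterize(spec, spec.default_grid(spacing=(1.0, 1.0, 1.0)), supersample=2)
        model = DistortionModel(m=-4e-3, c=0.6)
        distorted = inject_distortion(vol, model)
        found = match_fiducials(localize_spheres_3d(distorted, 2), fids)
        corrected = model.correct_set(found)
        assert np.abs(corrected.coords - fids.coords).max() < 0.2


class TestAddNoise:
    def test_zero_noise_unchanged(self):
        _, fids = make_calibration_phantom(0.0)
        assert add_noise(fids, 0.0, 1) is fids

    def test_seed_reproducibility(self):
        _, fids = make_calibration_phantom(0.0)
        a = add_noise(fids, 0.2, 42)
        b = add_noise(fids, 0.2, 42)
        assert np.array_equal(a.coords, b.coords)

    def test_p95_calibration_monte_carlo(self, rng):
        """Empirical 95th pct of |displacement| matches the requested p95."""
        from roomct.frames import FiducialSet

        n = 10000
        fids = FiducialSet(
            tuple(map(str, range(n))), np.zeros((n, 3)), Frame.CT
        )
        noisy = add_noise(fids, 0.2, 7)
        disp = np.linalg.norm(noisy.coords, axis=1)
        assert abs(np.percentile(disp, 95) - 0.2) < 0.01
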