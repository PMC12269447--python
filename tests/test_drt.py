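"""Fan-beam DRT engine: Siddon integrals, point projector, renderer."""

import numpy as np
import pytest

from roomct.drt import (
    ProjectionGeometry,
    hu_to_mu,
    project_point,
    render_topogram,
    siddon_integral,
)
from roomct.images import CTVolume


def water_cube(n=100, spacing=1.0, origin=0.5):
    """n*spacing mm uniform water cube (HU 0 -> mu 1)."""
    return CTVolume(
        np.zeros((n, n, n), dtype=np.float32), (origin, origin, origin), (spacing,) * 3
    )


def dense_integral(vol, s, e, step=0.01):
    """Independent oracle: nearest-voxel sampling at a fixed step."""
    s, e = np.asarray(s, float), np.asarray(e, float)
    L = np.linalg.norm(e - s)
    n = int(L / step)
    ts = (np.arange(n) + 0.5) / n
    pts = s + ts[:, None] * (e - s)
    idx = np.round((pts - vol.origin) / vol.spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
    mu = hu_to_mu(vol.values)
    return float(mu[idx[ok, 0], idx[ok, 1], idx[ok, 2]].sum() * L / n)


class TestSiddon:
    def test_axis_aligned_cube_chord(self):
        vol = water_cube()
        val = siddon_integral(vol, (-50.0, 50.2, 50.2), (150.0, 50.2, 50.2))
        assert val == pytest.approx(100.0, abs=1e-9)

    def test_ray_outside_volume_is_zero(self):
        assert siddon_integral(water_cube(), (-50, 500, 500), (150, 500, 500)) == 0.0

    def test_degenerate_ray_rejected(self):
        with pytest.raises(ValueError):
            siddon_integral(water_cube(), (1, 1, 1), (1, 1, 1))

    def test_random_oblique_rays_match_dense_oracle(self, rng):
        vals = rng.uniform(-1000, 2000, (50, 60, 40)).astype(np.float32)
        vol = CTVolume(vals, (-25, -30, -20), (1.0, 1.1, 0.9))
        for _ in range(60):
            target = rng.uniform(-15, 15, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            s = target - 120 * direction
            e = target + 120 * direction
            a = siddon_integral(vol, s, e)
            b = dense_integral(vol, s, e)
            assert a == pytest.approx(b, rel=5e-3)


class TestProjectPoint:
    GEOM = ProjectionGeometry(90.0, 570.0, -100.0, 1.0, 0.0, 1.0, 100, 201)

    def test_central_plane_unit_magnification(self):
        # alpha=90: source at +X, column direction -Z; d = x, s = -z
        p = project_point(self.GEOM, np.array([0.0, 12.0, -7.5]))
        assert p.col == pytest.approx(7.5, abs=1e-12)
        assert p.row_y == 12.0

    def test_similar_triangles_magnification_two(self):
        geom = ProjectionGeometry(180.0, 570.0, -100.0, 1.0, 0.0, 1.0, 100, 201)
        # alpha=180: source below (-Z), d = -z, s = -x; z = -285 -> magnification 2
        p = project_point(geom, np.array([-10.0, 0.0, -285.0]))
        assert p.col == pytest.approx(20.0, abs=1e-9)

    def test_row_equals_y_regardless_of_geometry(self, rng):
        for alpha in (90.0, 180.0):
            for sad in (570.0, 900.0):
                geom = ProjectionGeometry(alpha, sad, -100.0, 1.0, 0.0, 1.0, 100, 201)
                p = rng.uniform(-100, 100, 3)
                assert project_point(geom, p).row_y == p[1]

    def test_point_at_or_behind_source_rejected(self):
        with pytest.raises(ValueError, match="behind"):
            project_point(self.GEOM, np.array([600.0, 0.0, 0.0]))


class TestRenderTopogram:
    def test_water_slab_fan_chord(self):
        """PA view of a flat slab: each ray's path is thickness/cos(angle)."""
        vals = np.full((121, 21, 30), -1000.0, dtype=np.float32)
        vals[:, :, 5:25] = 0.0  # 20 mm water slab, z in [-10, 10)
        vol = CTVolume(vals, (-60.0, -10.0, -14.5), (1.0, 1.0, 1.0))
        geom = ProjectionGeometry(180.0, 570.0, -50.0, 1.0, -5.0, 1.0, 11, 101)
        topo = render_topogram(vol, geom)
        cols = geom.col_coords()
        for ci in range(20, 81):  # central columns, fully inside the slab footprint
            u = cols[ci]
            secant = np.sqrt(570.0**2 + u**2) / 570.0
            assert topo.pixels[5, ci] == pytest.approx(20.0 * secant, rel=5e-3)

    def test_linearity_in_attenuation(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-1000, 1000, (30, 30, 30)).astype(np.float32)
        b = rng.uniform(-1000, 1000, (30, 30, 30)).astype(np.float32)
        mk = lambda v: CTVolume(v, (-15, -15, -15), (1, 1, 1))
        geom = ProjectionGeometry(90.0, 570.0, -20.0, 1.0, -15.0, 1.0, 30, 41)
        # sum in attenuation space: mu(a+b+1000) = mu(a) + mu(b) when both >= -1000
        t_sum = render_topogram(mk(a + b + 1000.0), geom)
        t_a = render_topogram(mk(a), geom)
        t_b = render_topogram(mk(b), geom)
        assert np.allclose(t_sum.pixels, t_a.pixels + t_b.pixels, atol=1e-9)

    def test_volume_y_shift_moves_rows_exactly(self, point_object_volume):
        vol, _ = point_object_volume
        geom = ProjectionGeometry(90.0, 570.0, -35.0, 1.0, -40.0, 1.0, 81, 71)
        base = render_topogram(vol, geom)
        shifted = render_topogram(vol, geom, volume_shift=(0.0, 7.0, 0.0))
        assert np.allclose(shifted.pixels[7:], base.pixels[:-7], atol=1e-9)

    def test_parallel_limit_matches_orthographic_sum(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(-1000, 1500, (40, 25, 35)).astype(np.float32)
        vol = CTVolume(vals, (-19.5, -12.0, -17.0), (1.0, 1.0, 1.0))
        geom = ProjectionGeometry(90.0, 1e6, -17.0, 1.0, -12.0, 1.0, 25, 35)
        topo = render_topogram(vol, geom)
        mu = hu_to_mu(vals)
        # alpha=90: rays along X; column coordinate u = -z, so columns reverse z
        ortho = mu.sum(axis=0)[:, ::-1]
        assert np.allclose(topo.pixels, ortho, rtol=1e-3)

    def test_disjoint_geometry_warns_all_zero(self):
        vol = water_cube(20)
        geom = ProjectionGeometry(90.0, 570.0, 400.0, 1.0, 500.0, 1.0, 10, 10)
        with pytest.warns(UserWarning, match="all zero"):
            topo = render_topogram(vol, geom)
        assert np.all(topo.pixels == 0)

    @pytest.mark.parametrize("alpha", [90.0, 180.0])
    @pytest.mark.parametrize("resolution", [1.0, 2.0])
    def test_projector_renderer_argmax_agreement(self, point_object_volume, alpha, resolution):
        vol, pos = point_object_volume
        geom = ProjectionGeometry.for_volume(vol, alpha, resolution=resolution, sad=570.0)
        # supersampled rays: a sub-resolution point object must not alias away
        topo = render_topogram(vol, geom, supersample=3)
        r, c = np.unravel_index(np.argmax(topo.pixels), topo.pixels.shape)
        expected = project_point(geom, pos)
        assert abs(geom.row_coords()[r] - expected.row_y) <= 0.5 * resolution + 1e-9
        assert abs(geom.col_coords()[c] - expected.col) <= 0.5 * resolution + 1e-9
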