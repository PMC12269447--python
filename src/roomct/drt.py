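"""Digitally reconstructed topograms: fan-beam forward model and projector.

A topogram is the scout radiograph formed while the source translates along
IEC-Y; per detector row the geometry is a 2D fan in the X-Z plane, so the
row coordinate maps 1:1 to Y.  The virtual detector is the plane through
the rotation axis (the "image at the scanner center of rotation"), so
lateral magnification of a point at signed distance ``d`` toward the source
is ``sad / (sad - d)``.

Source placement for source angle ``alpha`` (degrees, about IEC-Y):
``u = (sin a, 0, cos a)`` points from the axis toward the source, so
alpha = 90 puts the source laterally (+X, LAT view) and alpha = 180 puts it
below the table (-Z, PA view).  The column direction is ``v = (cos a, 0,
-sin a)``.

Ray integrals are exact Siddon-Jacobs voxel traversals of the attenuation
volume; HU map to unit-density water equivalents via
``mu = max(0, (HU + 1000) / 1000)`` so a 100 mm water path integrates to
100 mm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .frames import Frame, Point2, Point3
from .images import CTVolume

__all__ = [
    "ProjectionGeometry",
    "Topogram",
    "hu_to_mu",
    "siddon_integral",
    "project_point",
    "render_topogram",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Fan-beam topogram geometry.

    alpha_deg : source angle about IEC-Y (90 = LAT, 180 = PA)
    sad : source-to-axis distance, mm
    col_origin : lateral coordinate (mm, at the axis plane) of column 0
    col_spacing : mm per column at the axis plane
    row_origin : IEC-Y of row 0, mm
    row_spacing : mm per row
    n_rows, n_cols : raster size
    """

    alpha_deg: float
    sad: float
    col_origin: float
    col_spacing: float
    row_origin: float
    row_spacing: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.sad <= 0:
            raise ValueError("sad must be positive")
        if self.col_spacing <= 0 or self.row_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster must have at least one row and column")

    # unit vector from axis toward the source, in the X-Z plane
    @property
    def u_src(self) -> np.ndarray:
        a = math.radians(self.alpha_deg)
        return np.array([math.sin(a), 0.0, math.cos(a)])

    # column (lateral) direction on the virtual detector
    @property
    def v_col(self) -> np.ndarray:
        a = math.radians(self.alpha_deg)
        return np.array([math.cos(a), 0.0, -math.sin(a)])

    def col_coords(self) -> np.ndarray:
        return self.col_origin + self.col_spacing * np.arange(self.n_cols)

    def row_coords(self) -> np.ndarray:
        return self.row_origin + self.row_spacing * np.arange(self.n_rows)

    def col_index(self, col_mm) -> np.ndarray:
        return (np.asarray(col_mm, dtype=float) - self.col_origin) / self.col_spacing

    def row_index(self, row_y_mm) -> np.ndarray:
        return (np.asarray(row_y_mm, dtype=float) - self.row_origin) / self.row_spacing

    @classmethod
    def for_volume(
        cls,
        vol: CTVolume,
        alpha_deg: float,
        resolution: float = 1.0,
        sad: float = 570.0,
        margin: float = 10.0,
    ) -> "ProjectionGeometry":
        """Geometry whose raster covers the volume footprint at the axis plane."""
        lo, hi = vol.bounds()
        half = max(abs(lo[0]), abs(hi[0]), abs(lo[2]), abs(hi[2])) + margin
        n_cols = int(math.ceil(2 * half / resolution)) + 1
        col_origin = -resolution * (n_cols - 1) / 2.0
        n_rows = int(math.ceil((hi[1] - lo[1]) / resolution)) + 1
        return cls(
            alpha_deg=alpha_deg,
            sad=sad,
            col_origin=col_origin,
            col_spacing=resolution,
            row_origin=float(lo[1]),
            row_spacing=resolution,
            n_rows=n_rows,
            n_cols=n_cols,
        )


@dataclass
class Topogram:
    """2D topogram raster (line-integral units: mm of unit-density water)."""

    pixels: np.ndarray
    geometry: ProjectionGeometry
    frame: Frame = Frame.TOPO2D

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"pixel raster {self.pixels.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite topogram pixels")
        self.frame = Frame.coerce(self.frame)

    def block_downsample(self, factor: int) -> "Topogram":
        f = int(factor)
        if f == 1:
            return self
        nr, nc = self.pixels.shape[0] // f, self.pixels.shape[1] // f
        px = self.pixels[: nr * f, : nc * f].astype(np.float32)
        px = px.reshape(nr, f, nc, f).mean(axis=(1, 3))
        g = self.geometry
        geom = replace(
            g,
            col_origin=g.col_origin + (f - 1) / 2.0 * g.col_spacing,
            col_spacing=g.col_spacing * f,
            row_origin=g.row_origin + (f - 1) / 2.0 * g.row_spacing,
            row_spacing=g.row_spacing * f,
            n_rows=nr,
            n_cols=nc,
        )
        return Topogram(px, geom, self.frame)


def hu_to_mu(values: np.ndarray) -> np.ndarray:
    """Water-linear attenuation ramp: mu = max(0, (HU + 1000) / 1000)."""
    return np.maximum(0.0, (np.asarray(values, dtype=np.float32) + 1000.0) / 1000.0)


@njit(cache=True, fastmath=False)
def _siddon_ray(mu, ox, oy, oz, dx, dy, dz, sx, sy, sz, ex, ey, ez):
    """Exact line integral of mu over segment (s -> e) through the grid.

    Grid support spans voxel faces: [origin - spacing/2, origin +
    (n - 1/2) * spacing] per axis.  Returns sum(mu_k * length_k) in mm.
    """
    nx, ny, nz = mu.shape
    rx = ex - sx
    ry = ey - sy
    rz = ez - sz
    length = math.sqrt(rx * rx + ry * ry + rz * rz)
    if length <= 0.0:
        return 0.0

    # clip the parametric segment t in [0, 1] against the volume slab
    tmin = 0.0
    tmax = 1.0
    blo_x = ox - 0.5 * dx
    bhi_x = ox + (nx - 0.5) * dx
    blo_y = oy - 0.5 * dy
    bhi_y = oy + (ny - 0.5) * dy
    blo_z = oz - 0.5 * dz
    bhi_z = oz + (nz - 0.5) * dz
    for axis in range(3):
        if axis == 0:
            s0, r, blo, bhi = sx, rx, blo_x, bhi_x
        elif axis == 1:
            s0, r, blo, bhi = sy, ry, blo_y, bhi_y
        else:
            s0, r, blo, bhi = sz, rz, blo_z, bhi_z
        if r == 0.0:
            if s0 < blo or s0 > bhi:
                return 0.0
        else:
            t1 = (blo - s0) / r
            t2 = (bhi - s0) / r
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmin >= tmax:
        return 0.0

    # entry voxel
    px = sx + tmin * rx
    py = sy + tmin * ry
    pz = sz + tmin * rz
    ix = int(math.floor((px - blo_x) / dx))
    iy = int(math.floor((py - blo_y) / dy))
    iz = int(math.floor((pz - blo_z) / dz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1

    big = 1e30
    # parametric step to the next voxel face per axis, and t of next crossing
    if rx > 0.0:
        dtx = dx / rx
        tx = (blo_x + (ix + 1) * dx - sx) / rx
        stepx = 1
    elif rx < 0.0:
        dtx = -dx / rx
        tx = (blo_x + ix * dx - sx) / rx
        stepx = -1
    else:
        dtx = big
        tx = big
        stepx = 0
    if ry > 0.0:
        dty = dy / ry
        ty = (blo_y + (iy + 1) * dy - sy) / ry
        stepy = 1
    elif ry < 0.0:
        dty = -dy / ry
        ty = (blo_y + iy * dy - sy) / ry
        stepy = -1
    else:
        dty = big
        ty = big
        stepy = 0
    if rz > 0.0:
        dtz = dz / rz
        tz = (blo_z + (iz + 1) * dz - sz) / rz
        stepz = 1
    elif rz < 0.0:
        dtz = -dz / rz
        tz = (blo_z + iz * dz - sz) / rz
        stepz = -1
    else:
        dtz = big
        tz = big
        stepz = 0

    total = 0.0
    t = tmin
    while t < tmax - 1e-12:
        # next crossing
        if tx <= ty and tx <= tz:
            tnext = tx
        elif ty <= tz:
            tnext = ty
        else:
            tnext = tz
        if tnext > tmax:
            tnext = tmax
        seg = (tnext - t) * length
        if seg > 0.0:
            total += mu[ix, iy, iz] * seg
        t = tnext
        # advance the crossed axis (may cross several faces at a corner)
        advanced = False
        if tx <= t + 1e-15 and stepx != 0:
            ix += stepx
            tx += dtx
            advanced = True
        if ty <= t + 1e-15 and stepy != 0:
            iy += stepy
            ty += dty
            advanced = True
        if tz <= t + 1e-15 and stepz != 0:
            iz += stepz
            tz += dtz
            advanced = True
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            break
        if not advanced:
            break
    return total


@njit(cache=True)
def _render(
    mu,
    ox,
    oy,
    oz,
    dx,
    dy,
    dz,
    rows_y,
    cols_u,
    usx,
    usz,
    vcx,
    vcz,
    sad,
    shift_x,
    shift_y,
    shift_z,
    sub_row,
    sub_col,
):
    n_rows = rows_y.shape[0]
    n_cols = cols_u.shape[0]
    out = np.zeros((n_rows, n_cols), dtype=np.float64)
    n_sub = sub_row.shape[0]
    w = 1.0 / (n_sub * n_sub)
    for r in range(n_rows):
        for c in range(n_cols):
            acc = 0.0
            for a in range(n_sub):
                y = rows_y[r] + sub_row[a]
                for b in range(n_sub):
                    u = cols_u[c] + sub_col[b]
                    # source on the axis-distance circle at this row's Y
                    sx = sad * usx - shift_x
                    sy = y - shift_y
                    sz = sad * usz - shift_z
                    # detector point on the axis plane, extended symmetrically
                    px = u * vcx - shift_x
                    py = y - shift_y
                    pz = u * vcz - shift_z
                    ex = 2.0 * px - sx
                    ey = 2.0 * py - sy
                    ez = 2.0 * pz - sz
                    acc += _siddon_ray(mu, ox, oy, oz, dx, dy, dz, sx, sy, sz, ex, ey, ez)
            out[r, c] = acc * w
    return out


def siddon_integral(vol: CTVolume, src, dst) -> float:
    """Exact attenuation line integral (mm water-equivalent) from src to dst."""
    s = src.coords if isinstance(src, Point3) else np.asarray(src, dtype=float)
    e = dst.coords if isinstance(dst, Point3) else np.asarray(dst, dtype=float)
    if np.allclose(s, e):
        raise ValueError("source and destination coincide")
    mu = hu_to_mu(vol.values).astype(np.float64)
    return float(
        _siddon_ray(
            mu,
            float(vol.origin[0]),
            float(vol.origin[1]),
            float(vol.origin[2]),
            float(vol.spacing[0]),
            float(vol.spacing[1]),
            float(vol.spacing[2]),
            float(s[0]),
            float(s[1]),
            float(s[2]),
            float(e[0]),
            float(e[1]),
            float(e[2]),
        )
    )


def project_point(G: ProjectionGeometry, p) -> Point2:
    """Fan-beam projection of a 3D point onto the virtual detector.

    Row coordinate equals the point's Y exactly (translating source);
    column coordinate is ``s * sad / (sad - d)`` with ``s`` the lateral
    offset along the column direction and ``d`` the signed distance from
    the axis plane toward the source.
    """
    coords = p.coords if isinstance(p, Point3) else np.asarray(p, dtype=float)
    label = p.label if isinstance(p, Point3) else ""
    u = G.u_src
    v = G.v_col
    d = float(coords @ u)
    if G.sad - d <= 0:
        raise ValueError(f"point at distance d={d:.1f} mm is at or behind the source (sad={G.sad})")
    s = float(coords @ v)
    col = s * G.sad / (G.sad - d)
    return Point2(np.array([col, coords[1]]), Frame.TOPO2D, label)


def render_topogram(
    vol: CTVolume,
    G: ProjectionGeometry,
    supersample: int = 1,
    volume_shift=(0.0, 0.0, 0.0),
) -> Topogram:
    """Render the DRT: one fan ray per pixel (optionally supersampled).

    ``volume_shift`` renders the volume as if rigidly translated by that
    vector (mm) without resampling it — the ray endpoints are shifted
    instead, which is exact.
    """
    lo, hi = vol.bounds()
    half_lat = max(abs(lo[0]), abs(hi[0]), abs(lo[2]), abs(hi[2]))
    if G.sad <= half_lat:
        raise ValueError(f"sad={G.sad} mm must exceed the volume's lateral extent ({half_lat:.0f} mm)")
    mu = hu_to_mu(vol.values).astype(np.float64)
    u = G.u_src
    v = G.v_col
    s = int(supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")
    frac = (np.arange(s) + 0.5) / s - 0.5
    shift = np.asarray(volume_shift, dtype=float)
    px = _render(
        mu,
        float(vol.origin[0]),
        float(vol.origin[1]),
        float(vol.origin[2]),
        float(vol.spacing[0]),
        float(vol.spacing[1]),
        float(vol.spacing[2]),
        G.row_coords().astype(np.float64),
        G.col_coords().astype(np.float64),
        float(u[0]),
        float(u[2]),
        float(v[0]),
        float(v[2]),
        float(G.sad),
        float(shift[0]),
        float(shift[1]),
        float(shift[2]),
        (frac * G.row_spacing).astype(np.float64),
        (frac * G.col_spacing).astype(np.float64),
    )
    if not px.any():
        warnings.warn("rendered topogram is all zero: geometry and volume do not intersect")
    return Topogram(px, G)
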