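"""Synthetic phantoms: geometry specs, voxelization, distortion and noise.

This module stands in for the physical calibration hardware: a 12-sphere
geometric phantom scanned at three ranges along the rails, a 2-sphere
validation phantom, a 13-dot field sampling the topogram field of view, and
an anthropomorphic-ish head phantom with a cranial fiducial sphere marking
the isocenter.  Exact object centers play the role of the laser-tracker
reference measurements; controllable longitudinal distortion and
localization noise emulate the scanner's geometric imperfections and the
fiducial localization scatter.

HU conventions (fixed; only contrasts matter): background -1000, ceramic
calibration spheres +1500, CT-dots +800, head soft tissue 0-80.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .frames import DistortionModel, FiducialSet, Frame, Point3
from .images import BACKGROUND_HU, CTVolume, GridSpec

__all__ = [
    "PhantomObject",
    "PhantomSpec",
    "make_calibration_phantom",
    "make_validation_phantom",
    "make_dot_field",
    "make_head_phantom",
    "rasterize",
    "inject_distortion",
    "add_noise",
    "SPHERE_HU",
    "DOT_HU",
]

SPHERE_HU = 1500.0
DOT_HU = 800.0

_SHAPES = ("sphere", "ellipsoid", "box", "cylinder")


@dataclass(frozen=True)
class PhantomObject:
    """One geometric primitive.

    ``size`` semantics: sphere -> diameter (mm); ellipsoid -> semi-axes
    (ax, ay, az) mm; box -> full edge lengths; cylinder (axis along Y) ->
    (diameter, length) mm.
    """

    shape: str
    center: tuple
    size: tuple
    intensity: float

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {_SHAPES}")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        size = np.atleast_1d(np.asarray(self.size, dtype=float))
        object.__setattr__(self, "size", tuple(float(v) for v in size))
        if not np.isfinite(self.intensity):
            raise ValueError("non-finite intensity")

    def half_extent(self) -> np.ndarray:
        if self.shape == "sphere":
            return np.full(3, self.size[0] / 2.0)
        if self.shape == "ellipsoid":
            return np.asarray(self.size)
        if self.shape == "box":
            return np.asarray(self.size) / 2.0
        d, length = self.size
        return np.asarray([d / 2.0, length / 2.0, d / 2.0])

    def inside(self, x, y, z):
        cx, cy, cz = self.center
        if self.shape == "sphere":
            r = self.size[0] / 2.0
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r * r
        if self.shape == "ellipsoid":
            ax, ay, az = self.size
            return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
        if self.shape == "box":
            hx, hy, hz = (s / 2.0 for s in self.size)
            return (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)
        d, length = self.size
        r = d / 2.0
        return ((x - cx) ** 2 + (z - cz) ** 2 <= r * r) & (np.abs(y - cy) <= length / 2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """An ordered list of primitives; later objects overwrite earlier ones."""

    name: str
    objects: tuple

    def __post_init__(self):
        object.__setattr__(self, "objects", tuple(self.objects))

    def bounding_box(self, margin: float = 0.0) -> tuple:
        if not self.objects:
            z = np.zeros(3)
            return z - margin, z + margin
        los, his = [], []
        for obj in self.objects:
            h = obj.half_extent()
            c = np.asarray(obj.center)
            los.append(c - h)
            his.append(c + h)
        return np.min(los, axis=0) - margin, np.max(his, axis=0) + margin

    def default_grid(self, spacing=(0.98, 0.98, 1.0), margin: float = 15.0) -> GridSpec:
        lo, hi = self.bounding_box(margin)
        return GridSpec.covering(lo, hi, spacing)

    def translated(self, shift) -> "PhantomSpec":
        shift = np.asarray(shift, dtype=float)
        objs = [
            PhantomObject(o.shape, tuple(np.asarray(o.center) + shift), o.size, o.intensity)
            for o in self.objects
        ]
        return PhantomSpec(self.name, tuple(objs))


# Canonical 12-sphere layout (mm, relative to the region center): generic
# positions spanning >= 150 mm per axis, non-coplanar, full-rank.
_CAL_LAYOUT = np.array(
    [
        [-80.0, -85.0, -60.0],
        [75.0, -80.0, 45.0],
        [-35.0, -75.0, 70.0],
        [40.0, -88.0, -75.0],
        [-78.0, -20.0, 60.0],
        [80.0, -15.0, -55.0],
        [-30.0, 10.0, -70.0],
        [35.0, 25.0, 65.0],
        [-75.0, 60.0, -20.0],
        [70.0, 82.0, 30.0],
        [-25.0, 85.0, -65.0],
        [30.0, 78.0, 75.0],
    ]
)


def make_calibration_phantom(region_center_y: float = 0.0) -> tuple:
    """Twelve 20 mm spheres around ``region_center_y``; exact centers returned.

    The returned :class:`FiducialSet` is the synthetic analogue of the
    laser-tracker reference: the true sphere centers in the (undistorted)
    CT frame.
    """
    centers = _CAL_LAYOUT + np.array([0.0, region_center_y, 0.0])
    objs = [PhantomObject("sphere", tuple(c), (20.0,), SPHERE_HU) for c in centers]
    labels = tuple(f"S{i + 1:02d}" for i in range(len(objs)))
    spec = PhantomSpec(f"calibration-12sphere@{region_center_y:g}", tuple(objs))
    return spec, FiducialSet(labels, centers, Frame.CT)


def make_validation_phantom(region_center_y: float = 0.0, separation: float = 150.0) -> tuple:
    """The simpler two-sphere validation phantom."""
    if separation < 100.0:
        raise ValueError("validation spheres must be separated by >= 100 mm")
    half = separation / 2.0
    centers = np.array(
        [
            [-40.0, region_center_y - half, -30.0],
            [45.0, region_center_y + half, 35.0],
        ]
    )
    objs = [PhantomObject("sphere", tuple(c), (20.0,), SPHERE_HU) for c in centers]
    spec = PhantomSpec(f"validation-2sphere@{region_center_y:g}", tuple(objs))
    return spec, FiducialSet(("V01", "V02"), centers, Frame.CT)


def make_dot_field(
    n: int = 13,
    fov: float = 250.0,
    y_extent: float = 300.0,
    center_y: float = 0.0,
    seed: int = 0,
    min_separation: float = 20.0,
) -> FiducialSet:
    """Seeded pseudo-random 2 mm CT-dot positions sampling the field of view.

    Dots are drawn inside a box of transverse width ``fov`` (X and Z) and
    longitudinal extent ``y_extent``, with a minimum pairwise separation and
    a guaranteed transverse (depth) spread so that fan-beam magnification is
    observable from the resulting projections.
    """
    rng = np.random.default_rng(seed)
    half = fov / 2.0 - 5.0
    lo = np.array([-half, center_y - y_extent / 2.0, -half])
    hi = np.array([half, center_y + y_extent / 2.0, half])
    for _ in range(200):
        pts = []
        attempts = 0
        while len(pts) < n and attempts < 10000:
            p = rng.uniform(lo, hi)
            if all(np.linalg.norm(p - q) >= min_separation for q in pts):
                pts.append(p)
            attempts += 1
        if len(pts) < n:
            continue
        pts = np.asarray(pts)
        # require genuine depth spread for projection-geometry observability
        if pts[:, 0].std() > 0.15 * half and pts[:, 2].std() > 0.15 * half:
            labels = tuple(f"D{i + 1:02d}" for i in range(n))
            return FiducialSet(labels, pts, Frame.CT)
    raise RuntimeError("could not place dot field with the requested separation")


def dot_field_spec(fiducials: FiducialSet, diameter: float = 2.0) -> PhantomSpec:
    """Phantom spec rendering each dot as a small dense sphere."""
    objs = [PhantomObject("sphere", tuple(c), (diameter,), DOT_HU) for c in fiducials.coords]
    return PhantomSpec("dot-field", tuple(objs))


def make_head_phantom(center_y: float = 0.0) -> tuple:
    """Head phantom with internal structure and a cranial isocenter sphere.

    Nested ellipsoids of distinct HU provide the intensity gradients that
    image registration needs; the small dense sphere at the cranial apex is
    the isocenter fiducial, whose exact center is returned as ground truth.
    """
    c = np.array([0.0, center_y, 0.0])

    def at(offset):
        return tuple(c + np.asarray(offset, dtype=float))

    objs = [
        # outer "skull" shell: two ellipsoids, the inner overwriting the outer
        PhantomObject("ellipsoid", at([0, 0, 0]), (70.0, 90.0, 80.0), 80.0),
        PhantomObject("ellipsoid", at([0, 0, 0]), (63.0, 83.0, 73.0), 40.0),
        # ventricle-like low-HU core, off-center in Y and Z
        PhantomObject("ellipsoid", at([0, 6.0, 6.0]), (12.0, 25.0, 10.0), 0.0),
        # asymmetric internal blobs: break symmetry along every axis
        PhantomObject("sphere", at([25.0, -32.0, 20.0]), (30.0,), 70.0),
        PhantomObject("sphere", at([-30.0, 26.0, -18.0]), (24.0,), 10.0),
        PhantomObject("ellipsoid", at([18.0, 42.0, -26.0]), (10.0, 16.0, 12.0), 65.0),
        PhantomObject("ellipsoid", at([-20.0, -50.0, -30.0]), (14.0, 10.0, 18.0), 20.0),
    ]
    iso_center = at([5.0, 96.0, 12.0])
    objs.append(PhantomObject("sphere", iso_center, (8.0,), SPHERE_HU))
    spec = PhantomSpec("head", tuple(objs))
    return spec, Point3(np.asarray(iso_center), Frame.CT, "ISO")


def rasterize(
    spec: PhantomSpec,
    grid: GridSpec,
    supersample: int = 1,
    background: float = BACKGROUND_HU,
) -> CTVolume:
    """Voxelize a phantom spec onto a grid.

    With ``supersample=1`` each voxel takes the intensity of the last listed
    object covering its center.  With ``supersample=s`` the voxel value is a
    partial-volume blend weighted by the fraction of s^3 subsamples covered,
    which is what makes sub-voxel centroid localization accurate.
    """
    s = int(supersample)
    if s < 1:
        raise ValueError("supersample must be >= 1")
    values = np.full(grid.shape, background, dtype=np.float32)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)
    offsets = (np.arange(s) + 0.5) / s - 0.5  # sub-voxel offsets, voxel units

    for obj in spec.objects:
        h = obj.half_extent() + spacing
        c = np.asarray(obj.center)
        ilo = np.maximum(0, np.floor((c - h - origin) / spacing).astype(int))
        ihi = np.minimum(shape, np.ceil((c + h - origin) / spacing).astype(int) + 1)
        if np.any(ihi <= ilo):
            continue
        xs = origin[0] + spacing[0] * np.arange(ilo[0], ihi[0])
        ys = origin[1] + spacing[1] * np.arange(ilo[1], ihi[1])
        zs = origin[2] + spacing[2] * np.arange(ilo[2], ihi[2])
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
        if s == 1:
            frac = obj.inside(X, Y, Z).astype(np.float32)
        else:
            acc = np.zeros((ihi[0] - ilo[0], ihi[1] - ilo[1], ihi[2] - ilo[2]), dtype=np.float32)
            for ox in offsets:
                for oy in offsets:
                    for oz in offsets:
                        acc += obj.inside(
                            X + ox * spacing[0], Y + oy * spacing[1], Z + oz * spacing[2]
                        )
            frac = acc / (s**3)
        sub = values[ilo[0] : ihi[0], ilo[1] : ihi[1], ilo[2] : ihi[2]]
        values[ilo[0] : ihi[0], ilo[1] : ihi[1], ilo[2] : ihi[2]] = (
            frac * obj.intensity + (1.0 - frac) * sub
        )
    return CTVolume(values, origin, spacing, Frame.CT)


def add_texture(
    vol: CTVolume,
    amplitude: float = 15.0,
    periods=(37.0, 53.0, 71.0),
    threshold: float = -500.0,
    phase_origin=(0.0, 0.0, 0.0),
) -> CTVolume:
    """Superimpose a smooth deterministic intensity modulation inside tissue.

    Piecewise-constant rasters are pathological for histogram-based
    similarity metrics (real CT has anatomical texture); this adds a gentle
    sum-of-sines field (HU) wherever the image exceeds ``threshold``.
    ``phase_origin`` anchors the field to the phantom so that a displaced
    phantom carries its texture with it.
    """
    p0 = np.asarray(phase_origin, dtype=float)
    axes = [vol.axis_coords(i) - p0[i] for i in range(3)]
    field = (
        np.sin(2 * np.pi * axes[0] / periods[0])[:, None, None]
        + np.sin(2 * np.pi * axes[1] / periods[1])[None, :, None]
        + np.sin(2 * np.pi * axes[2] / periods[2])[None, None, :]
    ) * (amplitude / 3.0)
    values = vol.values.astype(np.float32).copy()
    mask = values > threshold
    values[mask] += field.astype(np.float32)[mask]
    return CTVolume(values, vol.origin.copy(), vol.spacing.copy(), vol.frame)


def inject_distortion(obj, model: DistortionModel, background: float = BACKGROUND_HU):
    """Apply the *forward* longitudinal distortion (the inverse of the
    correction) so that ``correct_distortion`` recovers the truth exactly.

    Points move to ``Y -> (Y - c) / (1 + m)``; volumes are resampled along Y
    with the same map (the voxel at image position y shows the material that
    truly sits at ``(1 + m) * y + c``).
    """
    if isinstance(obj, Point3):
        c = obj.coords.copy()
        c[1] = model.uncorrect_y(c[1])
        return Point3(c, obj.frame, obj.label)
    if isinstance(obj, FiducialSet):
        coords = obj.coords.copy()
        coords[:, 1] = model.uncorrect_y(coords[:, 1])
        return obj.with_coords(coords)
    if isinstance(obj, CTVolume):
        y = obj.axis_coords(1)
        y_src = model.correct_y(y)  # where the displayed material truly is
        fidx = (y_src - obj.origin[1]) / obj.spacing[1]
        ny = obj.shape[1]
        lo = np.floor(fidx).astype(int)
        frac = (fidx - lo).astype(np.float32)
        valid = (fidx >= 0) & (fidx <= ny - 1)
        lo_c = np.clip(lo, 0, ny - 1)
        hi_c = np.clip(lo + 1, 0, ny - 1)
        v = obj.values.astype(np.float32)
        out = v[:, lo_c, :] * (1.0 - frac[None, :, None]) + v[:, hi_c, :] * frac[None, :, None]
        out[:, ~valid, :] = background
        return CTVolume(out, obj.origin.copy(), obj.spacing.copy(), obj.frame)
    raise TypeError(f"cannot inject distortion into {type(obj).__name__}")


def noise_sigma(p95: float, ndim: int) -> float:
    """Per-axis Gaussian sigma whose displacement-magnitude 95th pct is p95."""
    if p95 < 0:
        raise ValueError("p95 must be >= 0")
    if p95 == 0:
        return 0.0
    return p95 / stats.chi(ndim).ppf(0.95)


def add_noise(points: FiducialSet, p95: float, seed) -> FiducialSet:
    """Isotropic Gaussian localization noise, calibrated by its 95th-percentile
    displacement magnitude (mm); seeded and reproducible."""
    sigma = noise_sigma(p95, points.ndim)
    if sigma == 0.0:
        return points
    rng = np.random.default_rng(seed)
    return points.with_coords(points.coords + rng.normal(0.0, sigma, points.coords.shape))
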