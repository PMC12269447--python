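"""Raster containers: 3D CT volumes on regular grids.

Arrays are indexed ``values[i, j, k]`` with i -> X (lateral), j -> Y
(longitudinal), k -> Z (vertical).  Physical coordinates are mm; the origin
is the center of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Frame

__all__ = ["GridSpec", "CTVolume", "BACKGROUND_HU"]

BACKGROUND_HU = -1000.0


@dataclass(frozen=True)
class GridSpec:
    """Regular sampling grid: origin (mm), spacing (mm), shape (voxels)."""

    origin: tuple
    spacing: tuple
    shape: tuple

    def __post_init__(self):
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        shape = tuple(int(v) for v in self.shape)
        if len(origin) != 3 or len(spacing) != 3 or len(shape) != 3:
            raise ValueError("origin, spacing and shape must be length-3")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        if any(n < 1 for n in shape):
            raise ValueError(f"shape must be >= 1 per axis, got {shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    @classmethod
    def covering(cls, lo, hi, spacing) -> "GridSpec":
        """Smallest grid whose voxel centers cover the box [lo, hi]."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        shape = np.maximum(1, np.floor((hi - lo) / spacing).astype(int) + 1)
        return cls(tuple(lo), tuple(spacing), tuple(shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def extent(self) -> np.ndarray:
        """Physical size (mm) spanned by voxel centers along each axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)


@dataclass
class CTVolume:
    """A 3D raster with grid geometry and a frame tag."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    frame: Frame = Frame.CT

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.frame = Frame.coerce(self.frame)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.origin), tuple(self.spacing), self.values.shape)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.values.shape[axis])

    def index_to_physical(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def physical_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def bounds(self) -> tuple:
        """(lo, hi) of the volume's physical support (voxel faces), mm."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.asarray(self.shape) - 0.5) * self.spacing
        return lo, hi

    def copy(self) -> "CTVolume":
        return CTVolume(self.values.copy(), self.origin.copy(), self.spacing.copy(), self.frame)

    # -- SimpleITK bridge (array axes [i,j,k]=[x,y,z] <-> sitk [z,y,x]) ---
    def to_sitk(self):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetOrigin(tuple(float(v) for v in self.origin))
        img.SetSpacing(tuple(float(v) for v in self.spacing))
        return img

    @classmethod
    def from_sitk(cls, img, frame: Frame = Frame.CT) -> "CTVolume":
        import SimpleITK as sitk

        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise ValueError(
                "only axis-aligned (identity direction) volumes are supported; "
                f"got direction {direction.tolist()}"
            )
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr, np.asarray(img.GetOrigin()), np.asarray(img.GetSpacing()), frame)


def block_downsample(vol: CTVolume, factor: int) -> CTVolume:
    """Block-mean downsampling by an integer factor (trims ragged edges)."""
    if factor == 1:
        return vol
    f = int(factor)
    nx, ny, nz = (s // f for s in vol.shape)
    if min(nx, ny, nz) < 1:
        raise ValueError(f"volume {vol.shape} too small for factor {factor}")
    v = vol.values[: nx * f, : ny * f, : nz * f].astype(np.float32)
    v = v.reshape(nx, f, ny, f, nz, f).mean(axis=(1, 3, 5))
    # block centers: origin shifts by (f-1)/2 voxels
    origin = vol.origin + (f - 1) / 2.0 * vol.spacing
    return CTVolume(v, origin, vol.spacing * f, vol.frame)
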