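"""Coordinate frames, rigid transforms, and the longitudinal distortion model.

Every point and transform in the package carries an explicit frame tag; all
coordinates are physical millimetres in the IEC-61217 convention adopted
throughout: X lateral, Y longitudinal (the scanner travel direction, zero at
the scanner parking position), Z vertical.

The frames in play:

``f_ISO``
    room-fixed frame at the treatment isocenter,
``f_IMA``
    the same room-fixed frame translated to the remote imaging position,
``s``
    the patient-support (table) frame,
``CT``
    the in-room scanner frame (origin at the parking position),
``pCT``
    the planning-CT frame,
``topo2D``
    2D topogram coordinates (column = lateral mm at the rotation-axis
    plane, row = IEC-Y mm).

The scanner's longitudinal image distortion is modelled as an affine scaling
of the Y coordinate only: a measured position ``Y`` is compensated to
``Y' = (1 + m) * Y + c`` with slope ``m`` (dimensionless) and intercept ``c``
(mm).  Because the distortion depends on where along the rails a scan was
acquired, the pair ``(m, c)`` is calibrated per scan range and interpolated
between calibrated ranges with one quadratic polynomial per coefficient as a
function of the scan-range center.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Frame",
    "FrameMismatchError",
    "Point3",
    "Point2",
    "FiducialSet",
    "RigidTransform",
    "DistortionModel",
    "DistortionInterpolant",
    "apply_rigid",
    "compose",
    "invert",
    "correct_distortion",
    "distortion_at_center",
]

_ORTHO_TOL = 1e-9


class Frame(str, enum.Enum):
    """Named coordinate frame tags."""

    F_ISO = "f_ISO"
    F_IMA = "f_IMA"
    SUPPORT = "s"
    CT = "CT"
    PCT = "pCT"
    TOPO2D = "topo2D"

    @classmethod
    def coerce(cls, value: "Frame | str") -> "Frame":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(f.value for f in cls)
            raise ValueError(f"unknown frame tag {value!r}; valid tags: {valid}") from None


class FrameMismatchError(ValueError):
    """Raised when points/transforms with incompatible frame tags are combined."""


def _check_frame(have: Frame, want: Frame, what: str) -> None:
    if have != want:
        raise FrameMismatchError(f"{what}: expected frame {want.value!r}, got {have.value!r}")


@dataclass(frozen=True)
class Point3:
    """A labelled 3D point (mm) in a named frame."""

    coords: np.ndarray
    frame: Frame
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError(f"point {self.label!r} has non-finite coordinates {c}")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "frame", Frame.coerce(self.frame))

    @property
    def x(self) -> float:
        return float(self.coords[0])

    @property
    def y(self) -> float:
        return float(self.coords[1])

    @property
    def z(self) -> float:
        return float(self.coords[2])


@dataclass(frozen=True)
class Point2:
    """A labelled 2D topogram point: coords = (column mm, row/IEC-Y mm)."""

    coords: np.ndarray
    frame: Frame = Frame.TOPO2D
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float).reshape(2)
        if not np.all(np.isfinite(c)):
            raise ValueError(f"point {self.label!r} has non-finite coordinates {c}")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "frame", Frame.coerce(self.frame))

    @property
    def col(self) -> float:
        return float(self.coords[0])

    @property
    def row_y(self) -> float:
        return float(self.coords[1])


@dataclass(frozen=True)
class FiducialSet:
    """Labelled fiducial coordinates (N x 2 or N x 3, mm) in one frame.

    The container is deliberately dumb: it guarantees finite coordinates,
    unique labels and a single frame tag, and provides label-based alignment
    so that point-based fits never rely on array ordering.
    """

    labels: tuple
    coords: np.ndarray
    frame: Frame

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(f"coords must be N x 2 or N x 3, got shape {coords.shape}")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != coords.shape[0]:
            raise ValueError(f"{len(labels)} labels for {coords.shape[0]} points")
        if len(set(labels)) != len(labels):
            raise ValueError("fiducial labels must be unique")
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite fiducial coordinates")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "frame", Frame.coerce(self.frame))

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    def points(self):
        cls = Point3 if self.ndim == 3 else Point2
        return [cls(c, self.frame, l) for l, c in zip(self.labels, self.coords)]

    def sorted_by_label(self) -> "FiducialSet":
        order = np.argsort(np.asarray(self.labels, dtype=object))
        return FiducialSet(tuple(self.labels[i] for i in order), self.coords[order], self.frame)

    def with_coords(self, coords: np.ndarray, frame: "Frame | None" = None) -> "FiducialSet":
        return FiducialSet(self.labels, coords, frame if frame is not None else self.frame)

    def aligned_with(self, other: "FiducialSet") -> tuple["FiducialSet", "FiducialSet"]:
        """Return (self, other) restricted to shared labels, in matching order."""
        if set(self.labels) != set(other.labels):
            missing = set(self.labels) ^ set(other.labels)
            raise ValueError(f"fiducial label sets differ; unmatched labels: {sorted(missing)}")
        a = self.sorted_by_label()
        b = other.sorted_by_label()
        return a, b


def _validate_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float).reshape(3, 3)
    if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL * 10, rtol=0.0):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has negative determinant (reflection)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """A 6-DoF rigid mapping ``p_to = R @ p_from + t`` between named frames."""

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: Frame
    to_frame: Frame

    def __post_init__(self):
        object.__setattr__(self, "rotation", _validate_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite translation")
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "from_frame", Frame.coerce(self.from_frame))
        object.__setattr__(self, "to_frame", Frame.coerce(self.to_frame))

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls, frame: Frame, to_frame: "Frame | None" = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), frame, to_frame if to_frame is not None else frame)

    @classmethod
    def from_euler_zxy(cls, angles_deg, translation, from_frame, to_frame) -> "RigidTransform":
        """Build from ZXY Euler angles in degrees (the optimizer boundary)."""
        R = Rotation.from_euler("ZXY", np.asarray(angles_deg, dtype=float), degrees=True)
        return cls(R.as_matrix(), translation, from_frame, to_frame)

    def euler_zxy_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler("ZXY", degrees=True)

    # -- algebra ---------------------------------------------------------
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major, mm)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, p):
        """Apply to a Point3, FiducialSet, or raw (..., 3) array.

        Raw arrays skip the frame check (caller asserts responsibility).
        """
        if isinstance(p, Point3):
            _check_frame(p.frame, self.from_frame, "apply_rigid")
            return Point3(self.rotation @ p.coords + self.translation, self.to_frame, p.label)
        if isinstance(p, FiducialSet):
            _check_frame(p.frame, self.from_frame, "apply_rigid")
            if p.ndim != 3:
                raise ValueError("rigid transforms act on 3D fiducial sets")
            return p.with_coords(p.coords @ self.rotation.T + self.translation, self.to_frame)
        arr = np.asarray(p, dtype=float)
        return arr @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, self.to_frame, self.from_frame)


def apply_rigid(T: RigidTransform, p):
    """Map a point (or fiducial set) through ``T``, checking frame tags."""
    return T.apply(p)


def compose(T2: RigidTransform, T1: RigidTransform) -> RigidTransform:
    """The transform applying ``T1`` first, then ``T2`` (``T2 ∘ T1``)."""
    if T1.to_frame != T2.from_frame:
        raise FrameMismatchError(
            f"cannot compose: first transform ends in {T1.to_frame.value!r}, "
            f"second starts in {T2.from_frame.value!r}"
        )
    return RigidTransform(
        T2.rotation @ T1.rotation,
        T2.rotation @ T1.translation + T2.translation,
        T1.from_frame,
        T2.to_frame,
    )


def invert(T: RigidTransform) -> RigidTransform:
    return T.inverse()


@dataclass(frozen=True)
class DistortionModel:
    """Linear longitudinal distortion correction ``Y' = (1 + m) * Y + c``.

    ``m`` is the dimensionless slope of the correction and ``c`` its
    intercept in mm; the correction is invertible for ``m > -1``.
    """

    m: float = 0.0
    c: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.m) and np.isfinite(self.c)):
            raise ValueError("non-finite distortion parameters")
        if self.m <= -1.0:
            raise ValueError(f"distortion slope m={self.m} <= -1 makes the correction non-invertible")

    @property
    def is_identity(self) -> bool:
        return self.m == 0.0 and self.c == 0.0

    def correct_y(self, y):
        """Compensated Y coordinate(s)."""
        return (1.0 + self.m) * np.asarray(y, dtype=float) + self.c

    def uncorrect_y(self, y):
        """Inverse map: the raw image Y whose correction equals ``y``."""
        return (np.asarray(y, dtype=float) - self.c) / (1.0 + self.m)

    def correct_point(self, p: Point3) -> Point3:
        c = p.coords.copy()
        c[1] = self.correct_y(c[1])
        return Point3(c, p.frame, p.label)

    def correct_set(self, fs: FiducialSet) -> FiducialSet:
        coords = fs.coords.copy()
        coords[:, 1] = self.correct_y(coords[:, 1])
        return fs.with_coords(coords)


def correct_distortion(model: DistortionModel, p):
    """Apply the longitudinal distortion compensation to a CT-frame point.

    X and Z pass through unchanged; Y becomes ``(1 + m) * Y + c``.
    """
    if isinstance(p, Point3):
        _check_frame(p.frame, Frame.CT, "correct_distortion")
        return model.correct_point(p)
    if isinstance(p, FiducialSet):
        _check_frame(p.frame, Frame.CT, "correct_distortion")
        return model.correct_set(p)
    raise TypeError(f"cannot correct distortion on {type(p).__name__}")


@dataclass(frozen=True)
class DistortionInterpolant:
    """Quadratic interpolation of (m, c) versus scan-range center.

    ``coeffs_m`` / ``coeffs_c`` are polynomial coefficients in ascending
    order (numpy.polynomial convention) over the scan-range center in mm.
    Evaluation outside ``valid_range`` is tolerated with a warning up to
    10% of the calibrated span and rejected beyond that.
    """

    coeffs_m: np.ndarray
    coeffs_c: np.ndarray
    valid_range: tuple
    fit_rmse_m: float = 0.0
    fit_rmse_c: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "coeffs_m", np.asarray(self.coeffs_m, dtype=float))
        object.__setattr__(self, "coeffs_c", np.asarray(self.coeffs_c, dtype=float))
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"invalid range {self.valid_range}")
        object.__setattr__(self, "valid_range", (float(lo), float(hi)))

    @classmethod
    def fit(cls, centers_y, ms, cs, degree: int = 2) -> "DistortionInterpolant":
        """Fit one polynomial per coefficient over the scan-range centers.

        (m, c) are fit independently; with exactly ``degree + 1`` regions the
        fit is interpolatory and the residual vanishes.
        """
        centers_y = np.asarray(centers_y, dtype=float)
        ms = np.asarray(ms, dtype=float)
        cs = np.asarray(cs, dtype=float)
        if centers_y.size < degree + 1:
            raise ValueError(
                f"need at least {degree + 1} scan-range centers for a degree-{degree} fit, "
                f"got {centers_y.size}"
            )
        pm = np.polynomial.Polynomial.fit(centers_y, ms, degree).convert()
        pc = np.polynomial.Polynomial.fit(centers_y, cs, degree).convert()
        rm = float(np.sqrt(np.mean((pm(centers_y) - ms) ** 2)))
        rc = float(np.sqrt(np.mean((pc(centers_y) - cs) ** 2)))
        return cls(pm.coef, pc.coef, (centers_y.min(), centers_y.max()), rm, rc)

    def at(self, center_y: float) -> DistortionModel:
        lo, hi = self.valid_range
        span = hi - lo
        margin = 0.10 * span
        if center_y < lo - margin or center_y > hi + margin:
            raise ValueError(
                f"scan-range center {center_y} mm is beyond the calibrated range "
                f"[{lo}, {hi}] mm plus the 10% extrapolation margin"
            )
        if not (lo <= center_y <= hi):
            warnings.warn(
                f"extrapolating distortion model at {center_y} mm outside the "
                f"calibrated range [{lo}, {hi}] mm",
                stacklevel=2,
            )
        m = float(np.polynomial.polynomial.polyval(center_y, self.coeffs_m))
        c = float(np.polynomial.polynomial.polyval(center_y, self.coeffs_c))
        return DistortionModel(m=m, c=c)


def distortion_at_center(interp: DistortionInterpolant, center_y: float) -> DistortionModel:
    """Distortion model for a scan centered at ``center_y`` mm from parking."""
    return interp.at(center_y)
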