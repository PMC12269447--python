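"""Calibration computations: frame + distortion joint fit, FRE, topogram
distortion regression, and fan-beam projection-geometry calibration.

The scanner-to-room transform (CT -> f_IMA) is a six-degrees-of-freedom
point-based registration between sphere centers localized in the images and
their reference positions.  Because the scanner compresses/stretches the
longitudinal axis differently depending on where along the rails a scan is
acquired, the fit treats the linear Y-scaling (m_r, c_r) of each scan range
as independent free parameters, nested around a closed-form rigid solution:
for any candidate set of scalings the optimal rigid transform is the
orthogonal-Procrustes solution on the pooled corrected points, and a damped
least-squares search runs over the scalings only.

Note on identifiability: adding a common offset to every intercept c_r is
exactly absorbed by the rigid translation, so the intercepts are determined
only up to that gauge; every prediction the calibration makes (corrected
FRE, interpolated models composed with the transform) is invariant to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .drt import ProjectionGeometry, project_point
from .frames import (
    DistortionInterpolant,
    DistortionModel,
    FiducialSet,
    Frame,
    RigidTransform,
)

__all__ = [
    "FREReport",
    "FrameCalibration",
    "CalibrationRegion",
    "TopogramDistortionFit",
    "ProjectionCalibration",
    "fit_rigid_pointbased",
    "compute_fre",
    "fit_frame_calibration",
    "fit_topogram_distortion",
    "calibrate_projection_geometry",
]


@dataclass(frozen=True)
class FREReport:
    """Fiducial registration error summary (mm)."""

    per_point_error: np.ndarray
    rmse: float
    p95: float

    @classmethod
    def from_errors(cls, errors) -> "FREReport":
        e = np.asarray(errors, dtype=float).ravel()
        if e.size == 0:
            raise ValueError("no errors to summarize")
        if np.any(e < 0):
            raise ValueError("errors must be non-negative")
        return cls(e, float(np.sqrt(np.mean(e**2))), float(np.percentile(e, 95)))


def fit_rigid_pointbased(moving: FiducialSet, fixed: FiducialSet) -> RigidTransform:
    """Closed-form least-squares rigid fit (orthogonal Procrustes / Kabsch).

    Minimizes sum |T m_i - f_i|^2 over rotations and translations; points
    are matched by label.  Degenerate (collinear or < 3 point)
    configurations are rejected.
    """
    moving, fixed = moving.aligned_with(fixed)
    if len(moving) < 3:
        raise ValueError(f"rigid fit needs >= 3 points, got {len(moving)}")
    A = moving.coords
    B = fixed.coords
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    A0 = A - ca
    B0 = B - cb
    s = np.linalg.svd(A0, compute_uv=False)
    if s[1] < 1e-9 * max(1.0, s[0]):
        raise ValueError("degenerate (collinear) fiducial configuration")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    return RigidTransform(R, t, moving.frame, fixed.frame)


def compute_fre(
    moving: FiducialSet,
    fixed: FiducialSet,
    T: RigidTransform,
    model: "DistortionModel | None" = None,
) -> FREReport:
    """FRE of ``T`` (optionally with distortion correction applied first)."""
    moving, fixed = moving.aligned_with(fixed)
    coords = moving.coords
    if model is not None:
        coords = coords.copy()
        coords[:, 1] = model.correct_y(coords[:, 1])
    mapped = coords @ T.rotation.T + T.translation
    return FREReport.from_errors(np.linalg.norm(mapped - fixed.coords, axis=1))


@dataclass(frozen=True)
class CalibrationRegion:
    """One scan range: mean imaging coordinates, reference, and its center."""

    imaging: FiducialSet  # CT frame (raw, distorted)
    reference: FiducialSet  # f_IMA frame (laser-tracker analogue)
    center_y: float


@dataclass(frozen=True)
class FrameCalibration:
    """Result of the joint frame + distortion calibration."""

    transform: RigidTransform  # CT -> f_IMA
    per_region: dict  # region_id -> (DistortionModel, center_y)
    interpolant: "DistortionInterpolant | None"
    topogram_model: "DistortionModel | None" = None
    fre_before: dict = field(default_factory=dict)  # region_id -> FREReport
    fre_after: dict = field(default_factory=dict)
    residual: float = 0.0

    def model_for_center(self, center_y: float) -> DistortionModel:
        if self.interpolant is None:
            raise ValueError("no interpolant available (fewer than 3 calibrated regions)")
        return self.interpolant.at(center_y)

    def with_topogram_model(self, model: DistortionModel) -> "FrameCalibration":
        return replace(self, topogram_model=model)


def _corrected_pool(regions: dict, params: np.ndarray):
    """Apply candidate per-region scalings; return pooled (moving, fixed)."""
    n = len(regions)
    ms = params[:n]
    cs = params[n:]
    mov, fix = [], []
    for (rid, reg), m, c in zip(regions.items(), ms, cs):
        y = reg.imaging.coords.copy()
        y[:, 1] = (1.0 + m) * y[:, 1] + c
        mov.append(y)
        fix.append(reg.reference.coords)
    return np.vstack(mov), np.vstack(fix)


def fit_frame_calibration(regions: dict, fit_interpolant: bool = True) -> FrameCalibration:
    """Jointly fit CT -> f_IMA rigid transform and per-region (m, c) scalings.

    ``regions`` maps region_id -> :class:`CalibrationRegion` whose imaging
    sets are the per-region means over repeated scans.  The scaling search
    is multi-started (zeros and +/-1e-3 slope perturbations) around a nested
    closed-form rigid solution; with >= 3 regions a quadratic interpolant of
    (m, c) versus scan-range center is fitted as well.
    """
    regions = dict(regions)
    n = len(regions)
    if n < 1:
        raise ValueError("need at least one region")
    aligned = {}
    for rid, reg in regions.items():
        imaging, reference = reg.imaging.aligned_with(reg.reference)
        if len(imaging) < 3:
            raise ValueError(f"region {rid!r} has fewer than 3 fiducials")
        aligned[rid] = CalibrationRegion(imaging, reference, float(reg.center_y))
    regions = aligned
    frames = {reg.imaging.frame for reg in regions.values()}
    ref_frames = {reg.reference.frame for reg in regions.values()}
    if len(frames) != 1 or len(ref_frames) != 1:
        raise ValueError("all regions must share one imaging frame and one reference frame")
    img_frame = next(iter(frames))
    ref_frame = next(iter(ref_frames))

    def rigid_for(params):
        mov, fix = _corrected_pool(regions, params)
        labels = tuple(str(i) for i in range(mov.shape[0]))
        T = fit_rigid_pointbased(
            FiducialSet(labels, mov, img_frame),
            FiducialSet(labels, fix, ref_frame),
        )
        return T, mov, fix

    def residuals(params):
        T, mov, fix = rigid_for(params)
        return ((mov @ T.rotation.T + T.translation) - fix).ravel()

    x_scale = np.concatenate([np.full(n, 1e-3), np.ones(n)])
    starts = [np.zeros(2 * n)]
    for sign in (+1.0, -1.0):
        s = np.zeros(2 * n)
        s[:n] = sign * 1e-3
        starts.append(s)
    best = None
    for x0 in starts:
        sol = optimize.least_squares(
            residuals, x0, x_scale=x_scale, xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success and best.status <= 0:
        raise RuntimeError(f"frame calibration did not converge: residual {best.cost:.3e}")

    params = best.x.copy()
    # gauge convention: a common offset on all intercepts is exactly absorbed
    # by the rigid translation, so it is unidentifiable; report the
    # minimum-norm representative (zero-mean intercepts) and let the
    # transform carry the common shift.  Residuals are unchanged.
    params[n:] -= params[n:].mean()
    T, mov, fix = rigid_for(params)
    per_region = {}
    fre_before = {}
    fre_after = {}
    for i, (rid, reg) in enumerate(regions.items()):
        model = DistortionModel(m=float(params[i]), c=float(params[n + i]))
        per_region[rid] = (model, reg.center_y)
        # rigid-only baseline for the 'before' numbers
        fre_after[rid] = compute_fre(reg.imaging, reg.reference, T, model)
    n_pooled = sum(len(r.imaging) for r in regions.values())
    pooled_labels = tuple(str(i) for i in range(n_pooled))
    T_raw = fit_rigid_pointbased(
        FiducialSet(
            pooled_labels,
            np.vstack([r.imaging.coords for r in regions.values()]),
            img_frame,
        ),
        FiducialSet(
            pooled_labels,
            np.vstack([r.reference.coords for r in regions.values()]),
            ref_frame,
        ),
    )
    for rid, reg in regions.items():
        fre_before[rid] = compute_fre(reg.imaging, reg.reference, T_raw)

    interpolant = None
    if fit_interpolant:
        if n >= 3:
            centers = np.array([reg.center_y for reg in regions.values()])
            interpolant = DistortionInterpolant.fit(
                centers, params[:n], params[n:], degree=2
            )
        else:
            warnings.warn(
                f"only {n} region(s): quadratic interpolant refused; "
                "per-region models are still returned"
            )
    return FrameCalibration(
        transform=T,
        per_region=per_region,
        interpolant=interpolant,
        fre_before=fre_before,
        fre_after=fre_after,
        residual=float(np.sqrt(2 * best.cost / mov.shape[0])),
    )


@dataclass(frozen=True)
class TopogramDistortionFit:
    """Huber L2-regularized linear model of topogram longitudinal error."""

    model: DistortionModel  # correction: y_ref = (1+m) * y_topo + c
    slope: float  # regression slope of (y_topo - y_ref) vs predictor
    intercept: float  # regression intercept, mm
    rmse: float  # regression residual RMSE, mm
    predictor: str


def _huber_irls(x, e, delta, lam, max_iter=200, tol=1e-14):
    """Minimize sum huber_delta(e - (m x + c)) + lam * m^2 via IRLS."""
    m, c = 0.0, 0.0
    for _ in range(max_iter):
        r = e - (m * x + c)
        a = np.abs(r)
        w = np.where(a <= delta, 1.0, delta / np.maximum(a, 1e-300))
        # weighted ridge normal equations (slope penalized, intercept free)
        sw = w.sum()
        swx = (w * x).sum()
        swxx = (w * x * x).sum()
        swe = (w * e).sum()
        swxe = (w * x * e).sum()
        A = np.array([[swxx + lam, swx], [swx, sw]])
        b = np.array([swxe, swe])
        m_new, c_new = np.linalg.solve(A, b)
        if abs(m_new - m) < tol and abs(c_new - c) < tol * max(1.0, abs(c)):
            m, c = m_new, c_new
            break
        m, c = m_new, c_new
    return float(m), float(c)


def fit_topogram_distortion(
    y_topo,
    y_ref,
    delta: float = 1.0,
    lam: float = 1e-3,
    predictor: str = "reference",
) -> TopogramDistortionFit:
    """Robust linear model of the topogram longitudinal error.

    The error ``y_topo - y_ref`` (reference = distortion-corrected 3DCT
    position) is regressed on position with Huber loss (delta, mm) and an L2
    penalty ``lam`` on the slope only.  The returned
    :class:`DistortionModel` maps topogram Y to reference Y through the
    standard correction form.

    ``predictor`` selects the regressor: ``"reference"`` (default) or
    ``"topogram"``.
    """
    y_topo = np.asarray(y_topo, dtype=float).ravel()
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if y_topo.shape != y_ref.shape:
        raise ValueError("y_topo and y_ref must have the same length")
    if y_topo.size < 2:
        raise ValueError("need at least 2 points to fit the topogram distortion")
    if predictor not in ("reference", "topogram"):
        raise ValueError(f"predictor must be 'reference' or 'topogram', got {predictor!r}")
    e = y_topo - y_ref
    x = y_ref if predictor == "reference" else y_topo
    m, c = _huber_irls(x, e, delta, lam)
    rmse = float(np.sqrt(np.mean((e - (m * x + c)) ** 2)))
    if predictor == "reference":
        # y_topo = (1 + m) y_ref + c  =>  y_ref = (y_topo - c) / (1 + m)
        model = DistortionModel(m=1.0 / (1.0 + m) - 1.0, c=-c / (1.0 + m))
    else:
        # y_ref = y_topo - (m y_topo + c)
        model = DistortionModel(m=-m, c=-c)
    return TopogramDistortionFit(model=model, slope=m, intercept=c, rmse=rmse, predictor=predictor)


@dataclass(frozen=True)
class ProjectionCalibration:
    """Optimized fan-beam geometry and its reprojection residuals."""

    geometry: ProjectionGeometry
    residual_rmse: float  # RMS of per-point 2D residual distances, mm
    per_point_residual: np.ndarray


def calibrate_projection_geometry(
    p3d: FiducialSet,
    p2d: FiducialSet,
    nominal: ProjectionGeometry,
) -> ProjectionCalibration:
    """Fit source angle, SAD, lateral offset and column scale to 3D-2D pairs.

    Correspondence is by label.  Observed 2D coordinates are interpreted in
    the nominal raster's physical mapping; the optimized column origin and
    spacing absorb detector offset and field-of-view scale errors.  Points
    must span depth (not all on the rotation-axis plane), otherwise the
    source distance is unobservable and the fit is rejected.
    """
    p3d, p2d = _align_mixed(p3d, p2d)
    if len(p3d) < 4:
        raise ValueError(f"projection calibration needs >= 4 matched pairs, got {len(p3d)}")
    P = p3d.coords
    obs = p2d.coords  # (col_mm, row_y_mm) in the nominal raster mapping
    d_nom = P @ nominal.u_src
    if np.ptp(d_nom) < 1e-6 * nominal.sad:
        raise ValueError(
            "all calibration points lie on the rotation-axis plane; "
            "source distance is unobservable"
        )

    def predict(theta):
        alpha, sad, col_origin, col_spacing = theta
        G = replace(nominal, alpha_deg=alpha, sad=sad, col_origin=col_origin, col_spacing=col_spacing)
        d = P @ G.u_src
        s = P @ G.v_col
        if np.any(sad - d <= 0):
            return np.full((P.shape[0], 2), 1e6)
        u = s * sad / (sad - d)
        # express in the nominal raster's physical coordinates
        col_mm = nominal.col_origin + (u - col_origin) / col_spacing * nominal.col_spacing
        return np.column_stack([col_mm, P[:, 1]])

    def residuals(theta):
        return (predict(theta) - obs).ravel()

    x0 = np.array([nominal.alpha_deg, nominal.sad, nominal.col_origin, nominal.col_spacing])
    sol = optimize.least_squares(
        residuals,
        x0,
        x_scale=[1.0, 10.0, 1.0, 1e-3],
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    r = (predict(sol.x) - obs).reshape(-1, 2)
    dist = np.linalg.norm(r, axis=1)
    geometry = replace(
        nominal,
        alpha_deg=float(sol.x[0]),
        sad=float(sol.x[1]),
        col_origin=float(sol.x[2]),
        col_spacing=float(sol.x[3]),
    )
    return ProjectionCalibration(
        geometry=geometry,
        residual_rmse=float(np.sqrt(np.mean(dist**2))),
        per_point_residual=dist,
    )


def _align_mixed(p3d: FiducialSet, p2d: FiducialSet):
    """Label-align a 3D set with a 2D set."""
    if set(p3d.labels) != set(p2d.labels):
        missing = set(p3d.labels) ^ set(p2d.labels)
        raise ValueError(f"3D/2D label sets differ; unmatched: {sorted(missing)}")
    return p3d.sorted_by_label(), p2d.sorted_by_label()
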