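"""Closed-loop synthetic experiments emulating the physical validation study.

Each function builds its inputs with the phantom generator, runs the method
under test end to end, and measures recovery against the known ground
truth.  These are the desk-scale analogues of the physical experiments:
laser-tracker reference positions become exact generator coordinates, and
measured localization scatter becomes the calibrated noise model (95th
percentile of the displacement magnitude: 0.2 mm for 3DCT sphere
localization and small-FoV dots).

Study conditions fixed here (and documented in the methods note):

* frame calibration: three scan ranges centered at 850 / 1000 / 1150 mm
  from the parking position, twelve spheres each, three repeated scans
  averaged per region; ground-truth per-range scalings
  m = (-2e-3, -3e-3, -4e-3), c = (0.3, 0.5, 0.8) mm joined by the unique
  quadratic profile through them;
* validation scans at 984 and 1015.5 mm between the calibrated ranges;
* head-phantom positioning with a displacement of (10, 10, 20) mm
  (lateral, vertical, longitudinal 2 cm) on a 0.98 x 0.98 x 1.0 mm raster;
* topogram geometry: LAT (90 deg) + PA (180 deg), SAD 570 mm, 1 mm
  (small FoV) or 2 mm (large FoV) in-plane resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import (
    CalibrationRegion,
    FrameCalibration,
    calibrate_projection_geometry,
    compute_fre,
    fit_frame_calibration,
    fit_rigid_pointbased,
)
from .drt import ProjectionGeometry, project_point, render_topogram
from .frames import (
    DistortionInterpolant,
    DistortionModel,
    FiducialSet,
    Frame,
    RigidTransform,
)
from .localize import reproducibility_stats
from .phantoms import (
    add_noise,
    inject_distortion,
    make_calibration_phantom,
    make_head_phantom,
    make_dot_field,
    make_validation_phantom,
    rasterize,
)
from .register import register_2d3d, register_3d3d_translation

__all__ = [
    "CALIBRATION_CENTERS",
    "VALIDATION_CENTERS",
    "TRUE_SLOPES",
    "TRUE_INTERCEPTS",
    "true_distortion_profile",
    "default_room_transform",
    "FrameCalibrationExperiment",
    "run_frame_calibration",
    "run_validation_fre",
    "run_fre_improvement_trial",
    "run_registration_3d3d",
    "run_registration_2d3d",
    "run_projection_calibration",
    "nominal_geometry",
]

CALIBRATION_CENTERS = (850.0, 1000.0, 1150.0)
VALIDATION_CENTERS = (984.0, 1015.5)
TRUE_SLOPES = (-2e-3, -3e-3, -4e-3)
TRUE_INTERCEPTS = (0.3, 0.5, 0.8)

HEAD_DISPLACEMENT = (10.0, 10.0, 20.0)
CT_SPACING = (0.98, 0.98, 1.0)
SAD = 570.0
NOISE_P95_3D = 0.2
NOISE_P95_2D = 0.2
N_REPEATS = 3


def true_distortion_profile() -> DistortionInterpolant:
    """Ground-truth smooth (m, c) vs scan-range-center profile: the unique
    quadratics through the three per-range anchor values."""
    return DistortionInterpolant.fit(CALIBRATION_CENTERS, TRUE_SLOPES, TRUE_INTERCEPTS)


def default_room_transform() -> RigidTransform:
    """A plausible CT -> f_IMA transform: rails offset plus small residual tilt."""
    return RigidTransform.from_euler_zxy(
        (0.15, -0.10, 0.20), (1.5, -1200.0, -2.5), Frame.CT, Frame.F_IMA
    )


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(int(seed) % (2**31))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class FrameCalibrationExperiment:
    calib: FrameCalibration
    room_transform: RigidTransform
    profile: DistortionInterpolant


def _simulate_region(center_y: float, model: DistortionModel, T_room, noise_p95, n_repeats, seeds):
    _, truth = make_calibration_phantom(center_y)
    reference = T_room.apply(truth)
    distorted = inject_distortion(truth, model)
    repeats = [add_noise(distorted, noise_p95, s) for s in seeds]
    imaging = reproducibility_stats(repeats).mean
    return CalibrationRegion(imaging=imaging, reference=reference, center_y=center_y)


def run_frame_calibration(
    seed: int = 0,
    noise_p95: float = NOISE_P95_3D,
    n_repeats: int = N_REPEATS,
) -> FrameCalibrationExperiment:
    """Calibrate on synthetic 3-range, 12-sphere data with injected distortion."""
    T_room = default_room_transform()
    profile = true_distortion_profile()
    seeds = _child_seeds(seed, len(CALIBRATION_CENTERS) * n_repeats)
    regions = {}
    for i, center in enumerate(CALIBRATION_CENTERS):
        model = profile.at(center)
        regions[f"R{i + 1}"] = _simulate_region(
            center, model, T_room, noise_p95, n_repeats, seeds[i * n_repeats : (i + 1) * n_repeats]
        )
    calib = fit_frame_calibration(regions)
    return FrameCalibrationExperiment(calib=calib, room_transform=T_room, profile=profile)


def run_validation_fre(
    exp: FrameCalibrationExperiment,
    seed: int = 1,
    n_replicates: int = 50,
    noise_p95: float = NOISE_P95_3D,
    centers=VALIDATION_CENTERS,
) -> float:
    """Mean FRE RMSE of the two-sphere validation phantom between ranges.

    Each replicate images the validation phantom at both centers with fresh
    localization noise, applies the interpolated distortion correction and
    the calibrated transform, and measures residuals against the reference
    positions; returns the mean RMSE over replicates (mm).
    """
    seeds = _child_seeds(seed + 104729, n_replicates * len(centers))
    rmses = []
    k = 0
    for _ in range(n_replicates):
        errors = []
        for center in centers:
            _, truth = make_validation_phantom(center)
            reference = exp.room_transform.apply(truth)
            distorted = inject_distortion(truth, exp.profile.at(center))
            observed = add_noise(distorted, noise_p95, seeds[k])
            k += 1
            model = exp.calib.interpolant.at(center)
            fre = compute_fre(observed, reference, exp.calib.transform, model)
            errors.extend(fre.per_point_error)
        rmses.append(float(np.sqrt(np.mean(np.square(errors)))))
    return float(np.mean(rmses))


def run_fre_improvement_trial(seed: int, noise_p95: float = NOISE_P95_3D) -> tuple:
    """(uncorrected, corrected) calibration FRE RMSE for one noise draw.

    Uncorrected: rigid-only fit on the pooled distorted coordinates.
    Corrected: the joint fit with per-range scalings.
    """
    exp = run_frame_calibration(seed, noise_p95=noise_p95)
    before = [r.per_point_error for r in exp.calib.fre_before.values()]
    after = [r.per_point_error for r in exp.calib.fre_after.values()]
    rms = lambda e: float(np.sqrt(np.mean(np.square(np.concatenate(e)))))
    return rms(before), rms(after)


# ---------------------------------------------------------------------------
# positioning experiments (head phantom)
# ---------------------------------------------------------------------------


def _head_volume(displacement=None, spacing=CT_SPACING, supersample: int = 1):
    from .phantoms import add_texture

    spec, iso = make_head_phantom()
    shift = (0.0, 0.0, 0.0) if displacement is None else displacement
    if displacement is not None:
        spec = spec.translated(displacement)
    grid = spec.default_grid(spacing=spacing, margin=20.0)
    vol = rasterize(spec, grid, supersample=supersample)
    # anatomical-texture stand-in, anchored to the phantom
    return add_texture(vol, phase_origin=shift), iso


def run_registration_3d3d(
    seed: int = 0,
    displacement=HEAD_DISPLACEMENT,
    spacing=CT_SPACING,
) -> dict:
    """3D/3D translation recovery: fixed head phantom vs resampled shifted copy."""
    import SimpleITK as sitk

    fixed, _ = _head_volume(spacing=spacing)
    img = fixed.to_sitk()
    shift = tuple(float(v) for v in displacement)
    tx = sitk.TranslationTransform(3, tuple(-v for v in shift))
    moved = sitk.Resample(img, img, tx, sitk.sitkLinear, -1000.0)
    from .images import CTVolume

    moving = CTVolume.from_sitk(moved)
    recovered = register_3d3d_translation(fixed, moving)
    err = np.abs(recovered - np.asarray(displacement))
    return {
        "recovered": recovered,
        "true": np.asarray(displacement, dtype=float),
        "per_axis_error": err,
        "max_error": float(err.max()),
        "n_voxels": int(np.prod(fixed.shape)),
    }


def run_registration_2d3d(
    seed: int = 0,
    displacement=HEAD_DISPLACEMENT,
    resolution: float = 1.0,
    spacing=CT_SPACING,
) -> dict:
    """2D/3D recovery: LAT+PA topograms of the displaced phantom vs the
    undisplaced volume, at the given topogram in-plane resolution (mm)."""
    displaced, _ = _head_volume(displacement=displacement, spacing=spacing)
    fixed, _ = _head_volume(spacing=spacing)
    topos = []
    for alpha in (90.0, 180.0):
        geom = ProjectionGeometry.for_volume(displaced, alpha, resolution=resolution, sad=SAD, margin=15.0)
        topos.append(render_topogram(displaced, geom))
    recovered = register_2d3d(topos, fixed, init=(0.0, 0.0, 0.0))
    err = np.abs(recovered - np.asarray(displacement))
    return {
        "recovered": recovered,
        "true": np.asarray(displacement, dtype=float),
        "per_axis_error": err,
        "max_error": float(err.max()),
        "n_pixels": int(sum(t.pixels.size for t in topos)),
    }


# ---------------------------------------------------------------------------
# projection-geometry calibration experiment
# ---------------------------------------------------------------------------


def nominal_geometry(
    alpha_deg: float = 90.0,
    resolution: float = 1.0,
    sad: float = SAD,
    fov: float = 250.0,
    y_extent: float = 320.0,
) -> ProjectionGeometry:
    n_cols = int(np.ceil(fov / resolution)) + 1
    n_rows = int(np.ceil(y_extent / resolution)) + 1
    return ProjectionGeometry(
        alpha_deg=alpha_deg,
        sad=sad,
        col_origin=-resolution * (n_cols - 1) / 2.0,
        col_spacing=resolution,
        row_origin=-y_extent / 2.0,
        row_spacing=resolution,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def run_projection_calibration(
    seed: int = 0,
    n_seeds: int = 20,
    noise_p95: float = NOISE_P95_2D,
    n_repeats: int = N_REPEATS,
    alpha_perturb: float = 0.5,
    sad_perturb: float = 5.0,
    resolution: float = 1.0,
) -> dict:
    """Fan-beam geometry calibration from 13 dots with localization noise.

    The true geometry projects the dot field; per-dot 2D localizations are
    averaged over ``n_repeats`` repeated acquisitions (as in the physical
    protocol); the nominal starting geometry is perturbed in source angle
    and SAD; the residual RMSE (RMS of 2D residual distances) is averaged
    over ``n_seeds`` independent experiments.
    """
    from dataclasses import replace

    true_geom = nominal_geometry(alpha_deg=90.0, resolution=resolution)
    nominal = replace(true_geom, alpha_deg=true_geom.alpha_deg + alpha_perturb, sad=true_geom.sad + sad_perturb)
    seeds = _child_seeds(seed + 15485863, 2 * n_seeds)
    rmses = []
    alpha_errors = []
    for i in range(n_seeds):
        dots = make_dot_field(13, fov=240.0, y_extent=280.0, seed=seeds[2 * i])
        p2d_true = np.array([project_point(true_geom, c).coords for c in dots.coords])
        truth2d = FiducialSet(dots.labels, p2d_true, Frame.TOPO2D)
        repeats = [
            add_noise(truth2d, noise_p95, seeds[2 * i + 1] + r) for r in range(n_repeats)
        ]
        observed = reproducibility_stats(repeats).mean
        result = calibrate_projection_geometry(dots, observed, nominal)
        rmses.append(result.residual_rmse)
        alpha_errors.append(abs(result.geometry.alpha_deg - true_geom.alpha_deg))
    return {
        "mean_residual_rmse": float(np.mean(rmses)),
        "rmses": np.asarray(rmses),
        "mean_alpha_error_deg": float(np.mean(alpha_errors)),
        "n_seeds": n_seeds,
    }
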