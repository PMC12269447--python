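"""Calibration fits: rigid point registration, FRE, the joint frame +
distortion fit, robust topogram regression, projection-geometry recovery."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.spatial.transform import Rotation

from roomct.calibrate import (
    CalibrationRegion,
    calibrate_projection_geometry,
    compute_fre,
    fit_frame_calibration,
    fit_rigid_pointbased,
    fit_topogram_distortion,
)
from roomct.drt import ProjectionGeometry, project_point
from roomct.frames import DistortionModel, FiducialSet, Frame, RigidTransform
from roomct.phantoms import inject_distortion, make_calibration_phantom, make_dot_field


def random_rigid(rng, from_frame=Frame.CT, to_frame=Frame.F_IMA):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return RigidTransform(
        Rotation.from_quat(q).as_matrix(), rng.normal(0, 300, 3), from_frame, to_frame
    )


class TestRigidPointFit:
    def test_identical_sets_give_identity(self):
        _, fids = make_calibration_phantom(0.0)
        T = fit_rigid_pointbased(fids, fids)
        assert np.allclose(T.matrix(), np.eye(4), atol=1e-9)

    def test_exact_recovery_of_random_transforms(self, rng):
        _, fids = make_calibration_phantom(0.0)
        for _ in range(100):
            T = random_rigid(rng)
            That = fit_rigid_pointbased(fids, T.apply(fids))
            assert np.abs(That.rotation - T.rotation).max() < 1e-9
            assert np.abs(That.translation - T.translation).max() < 1e-9

    def test_two_points_rejected(self):
        fs = FiducialSet(("a", "b"), [[0, 0, 0], [1, 0, 0]], Frame.CT)
        with pytest.raises(ValueError, match=">= 3"):
            fit_rigid_pointbased(fs, fs)

    def test_collinear_rejected(self):
        fs = FiducialSet(("a", "b", "c"), [[0, 0, 0], [1, 0, 0], [2, 0, 0]], Frame.CT)
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_pointbased(fs, fs)


class TestFRE:
    def test_perfect_data_zero(self):
        _, fids = make_calibration_phantom(0.0)
        T = RigidTransform.identity(Frame.CT)
        assert compute_fre(fids, fids, T).rmse == 0.0

    def test_uniform_offset_is_exact(self):
        _, fids = make_calibration_phantom(0.0)
        d = np.array([0.3, -0.4, 1.2])
        shifted = fids.with_coords(fids.coords + d)
        rep = compute_fre(fids, shifted, RigidTransform.identity(Frame.CT))
        assert rep.rmse == pytest.approx(np.linalg.norm(d), abs=1e-12)
        assert rep.rmse**2 == pytest.approx(np.mean(rep.per_point_error**2))

    def test_true_model_improves_fre_on_distorted_data(self, rng):
        _, fids = make_calibration_phantom(1000.0)
        model = DistortionModel(m=-3e-3, c=0.5)
        distorted = inject_distortion(fids, model)
        T = RigidTransform.identity(Frame.CT)
        without = compute_fre(distorted, fids, T).rmse
        with_model = compute_fre(distorted, fids, T, model).rmse
        assert with_model < without


def _regions(T_room, models, centers=(850.0, 1000.0, 1150.0), noise=None, seeds=None):
    from roomct.phantoms import add_noise

    out = {}
    for i, (center, model) in enumerate(zip(centers, models)):
        _, fids = make_calibration_phantom(center)
        img = inject_distortion(fids, model)
        if noise:
            img = add_noise(img, noise, seeds[i])
        out[f"R{i + 1}"] = CalibrationRegion(img, T_room.apply(fids), center)
    return out


class TestFrameCalibration:
    MODELS = tuple(DistortionModel(m, c) for m, c in
                   zip((-2e-3, -3e-3, -4e-3), (0.3, 0.5, 0.8)))

    def test_noiseless_exact_recovery(self, rng):
        """Slopes exactly; intercepts up to the common translation gauge;
        the composed correction+transform maps points exactly."""
        T_room = random_rigid(rng)
        regions = _regions(T_room, self.MODELS)
        calib = fit_frame_calibration(regions)
        fitted = [calib.per_region[f"R{i + 1}"][0] for i in range(3)]
        for fit, true in zip(fitted, self.MODELS):
            assert abs(fit.m - true.m) < 1e-6
        gauge = np.array([f.c - t.c for f, t in zip(fitted, self.MODELS)])
        assert np.ptp(gauge) < 1e-6  # common offset only
        for rid, reg in regions.items():
            model, _ = calib.per_region[rid]
            mapped = calib.transform.apply(model.correct_set(reg.imaging).coords)
            assert np.abs(mapped - reg.reference.coords).max() < 1e-6

    def test_zero_distortion_recovers_transform(self, rng):
        T_room = random_rigid(rng)
        regions = _regions(T_room, (DistortionModel(0, 0),) * 3)
        calib = fit_frame_calibration(regions)
        _, fids = make_calibration_phantom(1000.0)
        err = np.abs(calib.transform.apply(fids.coords) - T_room.apply(fids.coords))
        assert err.max() < 0.05
        for model, _ in calib.per_region.values():
            assert abs(model.m) < 1e-6

    def test_interpolant_reproduces_fitted_values(self, rng):
        calib = fit_frame_calibration(_regions(random_rigid(rng), self.MODELS))
        assert calib.interpolant.fit_rmse_m < 1e-5
        assert calib.interpolant.fit_rmse_c < 1e-5
        for model, center in calib.per_region.values():
            at = calib.interpolant.at(center)
            assert abs(at.m - model.m) < 1e-9 and abs(at.c - model.c) < 1e-9

    def test_relabeling_invariance(self, rng):
        T_room = random_rigid(rng)
        regions = _regions(T_room, self.MODELS)
        shuffled = {}
        for rid, reg in regions.items():
            order = rng.permutation(len(reg.imaging))
            img = FiducialSet(
                tuple(reg.imaging.labels[i] for i in order), reg.imaging.coords[order], Frame.CT
            )
            shuffled[rid] = CalibrationRegion(img, reg.reference, reg.center_y)
        a = fit_frame_calibration(regions)
        b = fit_frame_calibration(shuffled)
        assert np.allclose(a.transform.matrix(), b.transform.matrix(), atol=1e-8)

    def test_global_prerotation_invariance(self, rng):
        """Rotating both point sets together changes the fitted transform but
        not the fitted distortion slopes or the residual."""
        T_room = random_rigid(rng)
        regions = _regions(T_room, self.MODELS)
        R_pre = RigidTransform.from_euler_zxy((10.0, 0, 0), (0, 0, 0), Frame.F_IMA, Frame.F_IMA)
        rotated = {
            rid: CalibrationRegion(reg.imaging, R_pre.apply(reg.reference), reg.center_y)
            for rid, reg in regions.items()
        }
        a = fit_frame_calibration(regions)
        b = fit_frame_calibration(rotated)
        for rid in regions:
            assert abs(a.per_region[rid][0].m - b.per_region[rid][0].m) < 1e-6
        assert abs(a.residual - b.residual) < 1e-6

    def test_fewer_than_three_regions_no_interpolant(self, rng):
        T_room = random_rigid(rng)
        regions = _regions(T_room, self.MODELS[:2], centers=(900.0, 1100.0))
        with pytest.warns(UserWarning, match="interpolant refused"):
            calib = fit_frame_calibration(regions)
        assert calib.interpolant is None
        assert len(calib.per_region) == 2

    def test_corrected_fre_beats_uncorrected_with_noise(self):
        from roomct.experiments import run_fre_improvement_trial

        before, after = run_fre_improvement_trial(seed=11)
        assert after < before


class TestTopogramDistortion:
    def test_zero_error_gives_identity_model(self):
        y = np.linspace(200.0, 1500.0, 40)
        fit = fit_topogram_distortion(y, y)
        assert fit.model.m == pytest.approx(0.0, abs=1e-12)
        assert fit.model.c == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_without_outliers(self, rng):
        y_ref = np.linspace(100.0, 1600.0, 60)
        m_true, c_true = 2.4e-3, -0.35
        y_topo = y_ref + m_true * y_ref + c_true + rng.normal(0, 0.05, y_ref.size)
        fit = fit_topogram_distortion(y_topo, y_ref, lam=0.0)
        slope_ols, inter_ols = np.polyfit(y_ref, y_topo - y_ref, 1)
        assert fit.slope == pytest.approx(slope_ols, abs=1e-9)
        assert fit.intercept == pytest.approx(inter_ols, abs=1e-9)

    def test_correction_maps_topogram_to_reference(self):
        y_ref = np.linspace(100.0, 1600.0, 30)
        y_topo = y_ref + 3e-3 * y_ref + 0.4  # exact linear error
        fit = fit_topogram_distortion(y_topo, y_ref)
        assert np.allclose(fit.model.correct_y(y_topo), y_ref, atol=1e-6)

    def test_huber_resists_gross_outliers(self, rng):
        """One-sided 10 mm gross errors on 10% of the points at moderate
        leverage: bounded Huber influence keeps the slope while OLS drifts."""
        y_ref = np.linspace(100.0, 1600.0, 100)
        m_true = 3e-3
        err = m_true * y_ref + 0.2 + rng.normal(0, 0.05, y_ref.size)
        y_topo_clean = y_ref + err
        contaminated = err.copy()
        idx = np.argsort(np.abs(y_ref - (y_ref.mean() + 200.0)))[:10]
        contaminated[idx] += 10.0
        y_topo_out = y_ref + contaminated

        clean = fit_topogram_distortion(y_topo_clean, y_ref)
        robust = fit_topogram_distortion(y_topo_out, y_ref)
        ols_slope = np.polyfit(y_ref, y_topo_out - y_ref, 1)[0]
        assert abs(robust.slope - clean.slope) / abs(clean.slope) < 0.05
        assert abs(ols_slope - clean.slope) / abs(clean.slope) > 0.20

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_topogram_distortion([100.0], [100.0])


def _nominal(alpha=90.0, sad=570.0):
    return ProjectionGeometry(alpha, sad, -128.0, 1.0, -150.0, 1.0, 301, 257)


def _observed(geom, dots):
    coords = np.array([project_point(geom, c).coords for c in dots.coords])
    return FiducialSet(dots.labels, coords, Frame.TOPO2D)


class TestProjectionCalibration:
    def test_noiseless_self_consistent_recovery(self):
        true_geom = _nominal()
        dots = make_dot_field(13, seed=5)
        result = calibrate_projection_geometry(dots, _observed(true_geom, dots), true_geom)
        assert result.residual_rmse < 1e-6
        assert abs(result.geometry.alpha_deg - 90.0) < 1e-3
        assert abs(result.geometry.sad - 570.0) < 1e-2

    def test_basin_of_attraction_from_perturbed_nominal(self):
        true_geom = _nominal()
        dots = make_dot_field(13, seed=6)
        nominal = replace(true_geom, alpha_deg=90.8)
        result = calibrate_projection_geometry(dots, _observed(true_geom, dots), nominal)
        assert abs(result.geometry.alpha_deg - 90.0) < 0.05

    def test_parallel_data_drives_sad_up(self):
        dots = make_dot_field(13, seed=7)
        # orthographic observation: column = lateral offset, no magnification
        v = _nominal().v_col
        coords = np.column_stack([dots.coords @ v, dots.coords[:, 1]])
        obs = FiducialSet(dots.labels, coords, Frame.TOPO2D)
        nominal = _nominal()
        result = calibrate_projection_geometry(dots, obs, nominal)
        init_res = np.sqrt(
            np.mean(
                np.sum((np.array([project_point(nominal, c).coords for c in dots.coords]) - coords) ** 2, axis=1)
            )
        )
        assert result.geometry.sad > nominal.sad
        assert result.residual_rmse < init_res

    def test_central_plane_degeneracy_rejected(self):
        geom = _nominal(alpha=90.0)
        pts = np.array([[0.0, y, z] for y, z in [(-50, -40), (0, 10), (50, 30), (80, -20)]])
        dots = FiducialSet(("a", "b", "c", "d"), pts, Frame.CT)  # x=0: on the axis plane
        with pytest.raises(ValueError, match="unobservable"):
            calibrate_projection_geometry(dots, _observed(geom, dots), geom)

    def test_fewer_than_four_pairs_rejected(self):
        geom = _nominal()
        pts = np.array([[10.0, 0.0, 5.0], [-20.0, 10.0, 30.0], [5.0, -40.0, -25.0]])
        dots = FiducialSet(("a", "b", "c"), pts, Frame.CT)
        with pytest.raises(ValueError, match=">= 4"):
            calibrate_projection_geometry(dots, _observed(geom, dots), geom)
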