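"""Fast invariant checks runnable from the CLI (``roomct selftest``)."""

from __future__ import annotations

import numpy as np


def run() -> list:
    """Run the invariant suite; return a list of failure descriptions."""
    from .calibrate import fit_rigid_pointbased
    from .drt import ProjectionGeometry, project_point, render_topogram
    from .frames import DistortionModel, FiducialSet, Frame, Point3, RigidTransform, compose
    from .images import CTVolume
    from .phantoms import inject_distortion, make_calibration_phantom

    failures = []
    rng = np.random.default_rng(0)

    def check(name, ok):
        if not ok:
            failures.append(name)

    # rigid algebra: distance preservation and inverse composition
    for _ in range(20):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        from scipy.spatial.transform import Rotation

        T = RigidTransform(Rotation.from_quat(q).as_matrix(), rng.normal(0, 50, 3), Frame.CT, Frame.F_IMA)
        p1, p2 = rng.normal(0, 100, 3), rng.normal(0, 100, 3)
        d0 = np.linalg.norm(p1 - p2)
        d1 = np.linalg.norm(T.apply(p1) - T.apply(p2))
        check("rigid distance preservation", abs(d0 - d1) < 1e-9)
        I = compose(T.inverse(), T)
        check("compose(inv, T) identity", np.allclose(I.matrix(), np.eye(4), atol=1e-9))

    # distortion round trip
    model = DistortionModel(m=-3e-3, c=0.5)
    p = Point3((5.0, 1000.0, -3.0), Frame.CT)
    rt = model.correct_point(inject_distortion(p, model))
    check("inject/correct identity", np.allclose(rt.coords, p.coords, atol=1e-9))

    # rigid recovery on the 12-sphere layout
    _, fids = make_calibration_phantom(1000.0)
    T = RigidTransform.from_euler_zxy((0.3, -0.2, 0.1), (5.0, -800.0, 3.0), Frame.CT, Frame.F_IMA)
    That = fit_rigid_pointbased(fids, T.apply(fids))
    check("rigid point fit recovery", np.allclose(That.matrix(), T.matrix(), atol=1e-9))

    # projector/renderer consistency on a point object
    vol = CTVolume(np.full((41, 41, 41), -1000.0, dtype=np.float32), (-20.0, -20.0, -20.0), (1.0, 1.0, 1.0))
    vol.values[30, 20, 10] = 5000.0
    geom = ProjectionGeometry(90.0, 570.0, -30.0, 1.0, -20.0, 1.0, 41, 61)
    topo = render_topogram(vol, geom)
    r, c = np.unravel_index(np.argmax(topo.pixels), topo.pixels.shape)
    pt = project_point(geom, vol.index_to_physical((30, 20, 10)))
    check(
        "projector/renderer argmax",
        abs(geom.row_coords()[r] - pt.row_y) <= 0.75 and abs(geom.col_coords()[c] - pt.col) <= 0.75,
    )
    return failures
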