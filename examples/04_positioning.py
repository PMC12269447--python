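"""End-to-end daily positioning: displaced head phantom to table correction.

Renders LAT + PA topograms of a displaced head phantom, registers them to
the planning volume (2D/3D Mattes MI + Nelder-Mead), then maps the plan
isocenter through the distortion correction and the calibrated frame
transform to obtain the table correction.
"""

import numpy as np

from roomct.experiments import run_frame_calibration, run_registration_2d3d
from roomct.frames import Frame, Point3
from roomct.position import compute_table_position

displacement = (10.0, 10.0, 20.0)  # lateral / vertical 1 cm, longitudinal 2 cm
print("true displacement (mm):", displacement)

reg = run_registration_2d3d(seed=1, displacement=displacement, resolution=2.0,
                            spacing=(1.5, 1.5, 1.5))
print("2D/3D registration recovered (mm):", np.round(reg["recovered"], 3))
print("per-axis error (mm):", np.round(reg["per_axis_error"], 3))

calib = run_frame_calibration(seed=1).calib
plan_iso = Point3((5.0, 1000.0, 12.0), Frame.PCT, "ISO")
result = compute_table_position(plan_iso, reg["recovered"], calib, scan_center_y=1000.0)
print("\nplan isocenter (pCT, mm)     :", plan_iso.coords)
print("isocenter in CT (raw, mm)    :", np.round(result.iso_ct.coords, 3))
print("after distortion correction  :", np.round(result.iso_ct_corrected.coords, 3))
print("in room frame f_IMA (mm)     :", np.round(result.iso_fima.coords, 3))
print("table correction (mm)        :", np.round(result.table_correction, 3))
print(
    "\nThe registration recovers the displacement to a fraction of a\n"
    "millimetre; the correction is the translation that brings the imaged\n"
    "isocenter to its nominal room-frame target."
)
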