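"""Scanner-to-room frame calibration with per-range distortion correction.

Simulates the 12-sphere phantom imaged at three scan ranges (three repeated
scans each, localization noise at the measured 0.2 mm reproducibility
level), jointly fits the CT -> f_IMA rigid transform plus one longitudinal
scaling (m, c) per range, and interpolates the scalings quadratically over
the scan-range center.
"""

import numpy as np

from roomct.experiments import (
    CALIBRATION_CENTERS,
    run_frame_calibration,
    run_validation_fre,
)

exp = run_frame_calibration(seed=1)
calib = exp.calib

print("per-range fiducial registration error (RMSE, mm):")
for rid in calib.per_region:
    print(
        f"  {rid}: raw {calib.fre_before[rid].rmse:.3f} -> "
        f"corrected {calib.fre_after[rid].rmse:.3f}"
    )
print("\nfitted per-range corrections (slope m, intercept c):")
for rid, (model, center) in calib.per_region.items():
    print(f"  {rid} @ {center:6.1f} mm: m = {model.m:+.2e}, c = {model.c:+.3f} mm")

fre = run_validation_fre(exp, seed=1, n_replicates=50)
print(f"\ntwo-sphere validation phantom between ranges (984 / 1015.5 mm):")
print(f"  mean FRE RMSE over 50 replicates: {fre:.3f} mm")
print(
    "\nThe raw FRE reflects the injected longitudinal distortion; after the\n"
    "jointly fitted correction the residual drops to the localization-noise\n"
    "level, and the interpolated correction keeps validation scans between\n"
    "the calibrated ranges below the 0.2 mm reproducibility bound."
)
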