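"""From daily images to the treatment-table correction.

The pipeline is pure algebra once the registration translation is known:
the plan isocenter is carried into the in-room scanner frame by the
(translation-only) patient registration, corrected for the modality's
longitudinal distortion, mapped to the room frame at the imaging position
by the calibrated transform, and differenced against the nominal target to
give the table correction:

    iso_CT        = iso_pCT + t_registration
    iso_CT'       = K_modality(iso_CT)          (Y-scaling correction)
    iso_fIMA      = T_CT->fIMA * iso_CT'
    correction    = target_fIMA - iso_fIMA

For 3DCT the correction model is interpolated at the scan-range center; for
topograms a single global scaling model is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import FrameCalibration
from .frames import Frame, Point3, distortion_at_center

__all__ = ["PositioningResult", "compute_table_position"]


@dataclass(frozen=True)
class PositioningResult:
    """All intermediate points of the positioning chain, for audit."""

    iso_ct: Point3  # raw, after patient registration (CT frame)
    iso_ct_corrected: Point3  # after distortion correction (CT frame)
    iso_fima: Point3  # in the room frame at imaging position
    table_correction: np.ndarray  # mm, f_IMA axes
    registration_translation: np.ndarray  # mm
    modality: str
    scan_center_y: float

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "scan_center_y_mm": self.scan_center_y,
            "registration_translation_mm": list(self.registration_translation),
            "iso_ct_mm": list(self.iso_ct.coords),
            "iso_ct_corrected_mm": list(self.iso_ct_corrected.coords),
            "iso_fima_mm": list(self.iso_fima.coords),
            "table_correction_mm": list(self.table_correction),
        }


def compute_table_position(
    plan_iso: Point3,
    registration_t,
    calib: FrameCalibration,
    scan_center_y: float,
    modality: str = "ct3d",
    target_fima=(0.0, 0.0, 0.0),
) -> PositioningResult:
    """Map the plan isocenter through daily imaging to a table correction.

    ``plan_iso`` is in the planning-CT frame; ``registration_t`` is the
    translation-only patient registration (plan -> daily image, mm);
    ``modality`` selects the distortion model: ``"ct3d"`` interpolates the
    frame calibration at ``scan_center_y``, ``"topogram"`` uses the single
    topogram scaling model; ``target_fima`` is the nominal target position
    of the isocenter in the room frame at imaging position.
    """
    if plan_iso.frame != Frame.PCT:
        raise ValueError(f"plan isocenter must be in frame 'pCT', got {plan_iso.frame.value!r}")
    if modality not in ("ct3d", "topogram"):
        raise ValueError(f"modality must be 'ct3d' or 'topogram', got {modality!r}")
    t = np.asarray(registration_t, dtype=float).reshape(3)

    iso_ct = Point3(plan_iso.coords + t, Frame.CT, plan_iso.label)
    if modality == "ct3d":
        if calib.interpolant is None:
            raise ValueError("calibration has no distortion interpolant for modality 'ct3d'")
        model = distortion_at_center(calib.interpolant, scan_center_y)
    else:
        if calib.topogram_model is None:
            raise ValueError("calibration has no topogram distortion model")
        model = calib.topogram_model
    iso_corr = model.correct_point(iso_ct)
    iso_fima = calib.transform.apply(iso_corr)
    correction = np.asarray(target_fima, dtype=float).reshape(3) - iso_fima.coords
    return PositioningResult(
        iso_ct=iso_ct,
        iso_ct_corrected=iso_corr,
        iso_fima=iso_fima,
        table_correction=correction,
        registration_translation=t,
        modality=modality,
        scan_center_y=float(scan_center_y),
    )
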