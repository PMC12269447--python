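"""Readers and writers: volumes, topograms, fiducial tables, transforms,
and calibration bundles.

Volumes round-trip through MetaImage (.mha) and NIfTI (.nii/.nii.gz); a
directory path is read as a DICOM series.  Fiducial tables are strict CSVs
(``label,x_mm,y_mm,z_mm,frame``; ``z_mm`` omitted for 2D sets, where
``x_mm`` is the topogram column and ``y_mm`` the IEC-Y row coordinate).
Transforms serialize as a plain-text 4x4 homogeneous matrix with frame
tags.  All coordinates are physical mm; voxel indices are 0-based with the
origin at the center of voxel (0, 0, 0).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .calibrate import FrameCalibration
from .drt import ProjectionGeometry, Topogram
from .frames import (
    DistortionInterpolant,
    DistortionModel,
    FiducialSet,
    Frame,
    RigidTransform,
)
from .images import CTVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_fiducials",
    "write_fiducials",
    "read_transform",
    "write_transform",
    "read_topogram",
    "write_topogram",
    "save_calibration",
    "load_calibration",
]

_VOLUME_EXTS = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_ext(path: str):
    p = str(path).lower()
    if not any(p.endswith(e) for e in _VOLUME_EXTS):
        raise ValueError(
            f"unknown volume format {path!r}; supported: {', '.join(_VOLUME_EXTS)} "
            "or a DICOM series directory"
        )


def read_volume(path, frame: Frame = Frame.CT) -> CTVolume:
    import SimpleITK as sitk

    path = str(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(path)
        if not files:
            raise ValueError(f"no DICOM series found in directory {path!r}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        _check_ext(path)
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:
            raise IOError(f"could not read volume {path!r}: {exc}") from exc
    return CTVolume.from_sitk(img, frame)


def write_volume(vol: CTVolume, path) -> None:
    import SimpleITK as sitk

    _check_ext(str(path))
    sitk.WriteImage(vol.to_sitk(), str(path), useCompression=False)


_HEADER_3D = ["label", "x_mm", "y_mm", "z_mm", "frame"]
_HEADER_2D = ["label", "x_mm", "y_mm", "frame"]


def read_fiducials(path) -> FiducialSet:
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    cols = list(df.columns)
    if cols == _HEADER_3D:
        ndim = 3
    elif cols == _HEADER_2D:
        ndim = 2
    else:
        raise ValueError(
            f"bad fiducial CSV header {cols}; expected {_HEADER_3D} or {_HEADER_2D}"
        )
    if len(df) == 0:
        return FiducialSet((), np.zeros((0, ndim)), Frame.CT if ndim == 3 else Frame.TOPO2D)
    frames = set(df["frame"])
    if len(frames) != 1:
        raise ValueError(f"fiducial file mixes frames: {sorted(frames)}")
    frame = Frame.coerce(frames.pop())
    coord_cols = ["x_mm", "y_mm", "z_mm"][:ndim]
    return FiducialSet(tuple(df["label"]), df[coord_cols].to_numpy(dtype=float), frame)


def write_fiducials(fs: FiducialSet, path) -> None:
    cols = ["x_mm", "y_mm", "z_mm"][: fs.ndim]
    df = pd.DataFrame(fs.coords, columns=cols)
    df.insert(0, "label", list(fs.labels))
    df["frame"] = fs.frame.value
    df.to_csv(path, index=False, float_format="%.17g")


def write_transform(T: RigidTransform, path) -> None:
    lines = [f"# from: {T.from_frame.value}", f"# to: {T.to_frame.value}"]
    for row in T.matrix():
        lines.append(" ".join(f"{v:.17g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_transform(path) -> RigidTransform:
    frames = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                frames[key.strip()] = value.strip()
            else:
                rows.append([float(v) for v in line.split()])
    M = np.asarray(rows, dtype=float)
    if M.shape != (4, 4):
        raise ValueError(f"transform file {path!r} must contain a 4x4 matrix, got {M.shape}")
    if "from" not in frames or "to" not in frames:
        raise ValueError(f"transform file {path!r} is missing '# from:' / '# to:' frame tags")
    return RigidTransform(M[:3, :3], M[:3, 3], Frame.coerce(frames["from"]), Frame.coerce(frames["to"]))


def write_topogram(topo: Topogram, path_prefix) -> None:
    """Write raster (.mha, 2D) plus a JSON geometry sidecar (.json)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(topo.pixels, dtype=np.float32))
    sitk.WriteImage(img, str(path_prefix) + ".mha", useCompression=False)
    with open(str(path_prefix) + ".json", "w") as fh:
        json.dump(asdict(topo.geometry), fh, indent=2)


def read_topogram(path_prefix) -> Topogram:
    import SimpleITK as sitk

    px = sitk.GetArrayFromImage(sitk.ReadImage(str(path_prefix) + ".mha"))
    with open(str(path_prefix) + ".json") as fh:
        geom = ProjectionGeometry(**json.load(fh))
    return Topogram(px, geom)


def save_calibration(calib: FrameCalibration, directory) -> None:
    """Write a calibration bundle: transform, per-region models, interpolant."""
    os.makedirs(directory, exist_ok=True)
    write_transform(calib.transform, os.path.join(directory, "transform.txt"))
    rows = [
        {"region": rid, "center_y_mm": center, "m": model.m, "c_mm": model.c}
        for rid, (model, center) in calib.per_region.items()
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(directory, "regions.csv"), index=False, float_format="%.17g"
    )
    bundle = {"residual_mm": calib.residual}
    if calib.interpolant is not None:
        bundle["interpolant"] = {
            "coeffs_m": list(calib.interpolant.coeffs_m),
            "coeffs_c": list(calib.interpolant.coeffs_c),
            "valid_range": list(calib.interpolant.valid_range),
        }
    if calib.topogram_model is not None:
        bundle["topogram_model"] = {"m": calib.topogram_model.m, "c": calib.topogram_model.c}
    with open(os.path.join(directory, "calibration.json"), "w") as fh:
        json.dump(bundle, fh, indent=2)


def load_calibration(directory) -> FrameCalibration:
    transform = read_transform(os.path.join(directory, "transform.txt"))
    df = pd.read_csv(os.path.join(directory, "regions.csv"), float_precision="round_trip")
    per_region = {
        str(r["region"]): (DistortionModel(m=r["m"], c=r["c_mm"]), float(r["center_y_mm"]))
        for _, r in df.iterrows()
    }
    with open(os.path.join(directory, "calibration.json")) as fh:
        bundle = json.load(fh)
    interp = None
    if "interpolant" in bundle:
        b = bundle["interpolant"]
        interp = DistortionInterpolant(
            np.asarray(b["coeffs_m"]), np.asarray(b["coeffs_c"]), tuple(b["valid_range"])
        )
    topo_model = None
    if "topogram_model" in bundle:
        topo_model = DistortionModel(**bundle["topogram_model"])
    return FrameCalibration(
        transform=transform,
        per_region=per_region,
        interpolant=interp,
        topogram_model=topo_model,
        residual=float(bundle.get("residual_mm", 0.0)),
    )
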