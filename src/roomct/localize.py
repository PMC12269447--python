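"""Fiducial localization in 3D volumes and 2D topograms.

Automatic analogue of the paper-grade segmentation workflow: Otsu threshold
over the image histogram, connected-component labelling, size filtering,
and an intensity-weighted centroid over a one-voxel-dilated mask for
sub-voxel refinement.  Detected-to-reference matching is mutual nearest
neighbour and must be a perfect matching — ambiguity is an error, never a
silent guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .drt import Topogram
from .frames import FiducialSet, Frame
from .images import CTVolume

__all__ = [
    "LocalizationError",
    "MatchingError",
    "localize_spheres_3d",
    "localize_dots_2d",
    "match_fiducials",
    "reproducibility_stats",
    "ReproducibilityStats",
]


class LocalizationError(RuntimeError):
    pass


class MatchingError(RuntimeError):
    pass


def _weighted_centroids(values, mask, background, min_size, spacing, origin):
    """Centroids (physical units) of connected components above threshold."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    struct = ndimage.generate_binary_structure(values.ndim, 1)
    centroids = []
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        size = int(comp_mask.sum())
        if size < min_size:
            continue
        dil = ndimage.binary_dilation(comp_mask, structure=struct)
        w = np.where(dil, values - background, 0.0)
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if total <= 0:
            continue
        idx = np.array(ndimage.center_of_mass(w))
        centroids.append((size, origin + idx * spacing))
    return centroids


def localize_spheres_3d(
    vol: CTVolume, expected_n: int, min_diameter: float = 10.0
) -> FiducialSet:
    """Locate ``expected_n`` bright spheres; sub-voxel centroids in mm (CT frame).

    Components smaller than a sphere of diameter ``min_diameter / 2`` are
    discarded as debris.  A count mismatch is an error reporting what was
    found and the threshold used.
    """
    values = np.asarray(vol.values, dtype=np.float32)
    if values.max() == values.min():
        raise LocalizationError("volume is constant; nothing to segment")
    thr = float(threshold_otsu(values))
    background = float(np.median(values))
    min_size = (4.0 / 3.0) * np.pi * (min_diameter / 4.0) ** 3 / float(np.prod(vol.spacing))
    found = _weighted_centroids(values, values >= thr, background, min_size, vol.spacing, vol.origin)
    if len(found) != expected_n:
        raise LocalizationError(
            f"expected {expected_n} fiducials, found {len(found)} "
            f"(Otsu threshold {thr:.1f} HU, min component {min_size:.0f} voxels)"
        )
    found.sort(key=lambda sc: (sc[1][1], sc[1][0], sc[1][2]))  # stable order: by Y, X, Z
    labels = tuple(f"F{i + 1:02d}" for i in range(expected_n))
    return FiducialSet(labels, np.array([c for _, c in found]), vol.frame)


def localize_dots_2d(topo: Topogram, expected_n: int, min_diameter: float = 1.0) -> FiducialSet:
    """Locate ``expected_n`` dots in a topogram.

    Returns 2D fiducials with coordinates (column mm at the axis plane,
    IEC-Y mm).  Dots merging into one connected component (closer than the
    resolution limit) surface as a count mismatch error.
    """
    px = np.asarray(topo.pixels, dtype=np.float32)
    if px.max() == px.min():
        raise LocalizationError("topogram is constant; nothing to segment")
    thr = float(threshold_otsu(px))
    background = float(np.median(px))
    g = topo.geometry
    spacing = np.array([g.row_spacing, g.col_spacing])
    origin = np.array([g.row_origin, g.col_origin])
    min_size = np.pi * (min_diameter / 4.0) ** 2 / float(spacing.prod())
    found = _weighted_centroids(px, px >= thr, background, max(1.0, min_size), spacing, origin)
    if len(found) != expected_n:
        raise LocalizationError(
            f"expected {expected_n} dots, found {len(found)} (Otsu threshold {thr:.2f})"
        )
    # centroids come back as (row_y, col); emit (col, row_y)
    coords = np.array([[c[1], c[0]] for _, c in found])
    order = np.lexsort((coords[:, 0], coords[:, 1]))
    labels = tuple(f"F{i + 1:02d}" for i in range(expected_n))
    return FiducialSet(labels, coords[order], Frame.TOPO2D)


def match_fiducials(detected: FiducialSet, reference: FiducialSet) -> FiducialSet:
    """Relabel ``detected`` with reference labels by mutual nearest neighbour.

    The matching must be perfect (a bijection); anything else raises
    :class:`MatchingError`.
    """
    if len(detected) != len(reference):
        raise MatchingError(f"{len(detected)} detections for {len(reference)} references")
    if detected.ndim != reference.ndim:
        raise MatchingError("dimensionality mismatch between detected and reference sets")
    td = cKDTree(detected.coords)
    tr = cKDTree(reference.coords)
    _, d2r = tr.query(detected.coords)  # nearest reference for each detection
    _, r2d = td.query(reference.coords)  # nearest detection for each reference
    pairs = {}
    for i_det, i_ref in enumerate(d2r):
        if r2d[i_ref] != i_det:
            raise MatchingError(
                f"ambiguous match: detection {i_det} and reference "
                f"{reference.labels[i_ref]!r} are not mutual nearest neighbours"
            )
        pairs[i_ref] = i_det
    if len(pairs) != len(reference):
        raise MatchingError("matching is not a bijection")
    order = [pairs[i] for i in range(len(reference))]
    return FiducialSet(reference.labels, detected.coords[order], detected.frame)


@dataclass(frozen=True)
class ReproducibilityStats:
    """Per-fiducial mean positions and scatter across repeated scans."""

    mean: FiducialSet
    distances: np.ndarray  # (n_repeats, n_fiducials) distance from mean, mm
    pooled_p95: float

    @property
    def per_fiducial_p95(self) -> np.ndarray:
        return np.percentile(self.distances, 95, axis=0)


def reproducibility_stats(repeats) -> ReproducibilityStats:
    """Summarize repeated localizations of the same fiducials.

    The mean set (per-fiducial average across repeats) is the quantity used
    downstream for calibration; scatter is reported as distances from the
    mean with a pooled 95th percentile.
    """
    repeats = list(repeats)
    if not repeats:
        raise ValueError("need at least one repeat")
    base = repeats[0].sorted_by_label()
    aligned = [base]
    for r in repeats[1:]:
        _, other = base.aligned_with(r)
        aligned.append(other)
    stack = np.stack([r.coords for r in aligned])  # (R, N, k)
    mean_coords = stack.mean(axis=0)
    dist = np.linalg.norm(stack - mean_coords[None], axis=2)
    pooled = float(np.percentile(dist, 95)) if dist.size else 0.0
    return ReproducibilityStats(
        mean=FiducialSet(base.labels, mean_coords, base.frame),
        distances=dist,
        pooled_p95=pooled,
    )
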