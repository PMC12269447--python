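"""Intensity-based registration: Mattes mutual information, translation-only
3D/3D, and 2D/3D topogram-to-volume registration.

The 2D/3D method maximizes the summed Mattes MI between measured topograms
and DRTs re-rendered from the candidate-shifted volume, driven by a
Nelder-Mead simplex (initial edge 2 mm, parameter tolerance 0.1 mm by
default) — a coarse pass on 2 mm rasters is followed by one refinement at
full resolution.  Only translations are estimated throughout, matching the
table's control capabilities.

3D/3D translation registration uses the same metric through SimpleITK's
registration framework (Mattes MI, Nelder-Mead/Amoeba optimizer,
multi-resolution), which is the standard equivalent of the commercial rigid
registration step it replaces.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize

from .drt import ProjectionGeometry, Topogram, render_topogram
from .images import CTVolume, block_downsample

__all__ = [
    "RegistrationError",
    "mattes_mi",
    "register_3d3d_translation",
    "register_2d3d",
]


class RegistrationError(RuntimeError):
    pass


def _cubic_bspline(s: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |s| < 2, partition of unity."""
    a = np.abs(s)
    out = np.zeros_like(a)
    m1 = a < 1
    m2 = (a >= 1) & (a < 2)
    out[m1] = (4.0 - 6.0 * a[m1] ** 2 + 3.0 * a[m1] ** 3) / 6.0
    out[m2] = (2.0 - a[m2]) ** 3 / 6.0
    return out


def mattes_mi(a, b, bins: int = 50, mask=None) -> float:
    """Mattes-style mutual information between two images, in bits.

    The joint histogram uses zero-order binning for the first image and a
    cubic B-spline Parzen window for the second, following the Mattes
    formulation.  ``mask`` (same shape, nonzero = excluded) restricts the
    overlap region.  Higher values mean more similar images.
    """
    a = np.asarray(a.pixels if isinstance(a, Topogram) else a, dtype=np.float64)
    b = np.asarray(b.pixels if isinstance(b, Topogram) else b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask) == 0
    af = a[keep].ravel()
    bf = b[keep].ravel()
    if af.size == 0:
        raise ValueError("empty overlap region")
    if af.max() == af.min() or bf.max() == bf.min():
        raise ValueError("image is constant over the overlap region")

    xa = (af - af.min()) / (af.max() - af.min()) * (bins - 1)
    xb = (bf - bf.min()) / (bf.max() - bf.min()) * (bins - 1)
    ia = np.clip(np.floor(xa).astype(np.int64), 0, bins - 1)
    j0 = np.floor(xb).astype(np.int64)
    H = np.zeros(bins * bins, dtype=np.float64)
    for k in range(-1, 3):
        j = j0 + k
        w = _cubic_bspline(xb - j)
        jc = np.clip(j, 0, bins - 1)
        H += np.bincount(ia * bins + jc, weights=w, minlength=bins * bins)
    P = H.reshape(bins, bins)
    P /= P.sum()
    pa = P.sum(axis=1)
    pb = P.sum(axis=0)
    nz = P > 0
    return float(np.sum(P[nz] * np.log2(P[nz] / np.outer(pa, pb)[nz])))


def register_3d3d_translation(
    fixed: CTVolume,
    moving: CTVolume,
    init=(0.0, 0.0, 0.0),
    bins: int = 50,
    simplex_delta: float = 2.0,
    tolerance: float = 0.02,
    max_iterations: int = 300,
    shrink_factors=(4, 2),
    smoothing_sigmas=None,
) -> np.ndarray:
    """Translation (mm) of the moving image's content relative to the fixed.

    Maximizes Mattes MI (dense sampling, deterministic) with a Nelder-Mead
    simplex over the three translation parameters in a multi-resolution
    pyramid.  ``smoothing_sigmas`` defaults to (2, 1) voxels in physical
    units: keeping a finest-level smoothing of about one voxel suppresses
    the grid-aligned interpolation artifact of histogram metrics.  Raises
    :class:`RegistrationError` with the optimization trace on
    non-convergence.
    """
    import SimpleITK as sitk

    if smoothing_sigmas is None:
        s = float(np.max(fixed.spacing))
        smoothing_sigmas = tuple(s * f for f in (2.0, 1.0)[: len(shrink_factors)])

    f = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    m = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsAmoeba(
        simplexDelta=simplex_delta,
        numberOfIterations=max_iterations,
        parametersConvergenceTolerance=tolerance,
        functionConvergenceTolerance=1e-9,
        withRestarts=False,
    )
    tx = sitk.TranslationTransform(3, tuple(float(v) for v in init))
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    trace = []
    reg.AddCommand(
        sitk.sitkIterationEvent,
        lambda: trace.append((reg.GetOptimizerIteration(), reg.GetMetricValue())),
    )
    out = reg.Execute(f, m)
    stop = reg.GetOptimizerStopConditionDescription()
    if "Maximum number of iterations" in stop and len(trace) >= max_iterations:
        raise RegistrationError(
            f"3D/3D registration did not converge ({stop}); trace tail: {trace[-5:]}"
        )
    return np.asarray(sitk.TranslationTransform(out).GetParameters(), dtype=float)


def _as_pairs(topos):
    pairs = []
    for item in topos:
        if isinstance(item, Topogram):
            pairs.append((item, item.geometry))
        else:
            topo, geom = item
            pairs.append((topo, geom))
    return pairs


def _nelder_mead(fun, x0, delta, xatol, max_iter):
    x0 = np.asarray(x0, dtype=float)
    simplex = np.vstack([x0] + [x0 + delta * e for e in np.eye(x0.size)])
    res = optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": xatol,
            "fatol": 1e-4,
            "maxiter": max_iter,
            "maxfev": 4 * max_iter,
        },
    )
    if not res.success and "maximum number" in (res.message or "").lower():
        raise RegistrationError(f"2D/3D registration did not converge: {res.message}")
    return res.x


def register_2d3d(
    topos,
    vol: CTVolume,
    init=(0.0, 0.0, 0.0),
    masks=None,
    bins: int = 50,
    simplex_delta: float = 2.0,
    tolerance: float = 0.1,
    coarse_resolution: float = 2.0,
    max_iterations: int = 400,
) -> np.ndarray:
    """Translation (mm) aligning the volume's DRTs to measured topograms.

    ``topos`` is a list of Topograms (or (Topogram, geometry) pairs); two
    orthogonal projections (LAT + PA) are required for full 3-axis
    observability.  ``masks`` optionally excludes regions (nonzero pixels)
    of each topogram — e.g. an isocenter marker — from the metric.
    """
    pairs = _as_pairs(topos)
    if not pairs:
        raise ValueError("need at least one topogram")
    if len(pairs) == 1:
        g = pairs[0][1]
        warnings.warn(
            f"single projection (alpha={g.alpha_deg} deg): motion along the "
            "source-axis direction is essentially unobservable"
        )
    if masks is not None and len(masks) != len(pairs):
        raise ValueError("one mask per topogram required")

    def stage(topo_list, mask_list, volume, x0, delta, xatol):
        def neg_mi(t):
            total = 0.0
            for (topo, geom), msk in zip(topo_list, mask_list):
                drt = render_topogram(volume, geom, volume_shift=t)
                total += mattes_mi(topo.pixels, drt.pixels, bins=bins, mask=msk)
            return -total

        return _nelder_mead(neg_mi, x0, delta, xatol, max_iterations)

    mask_list = list(masks) if masks is not None else [None] * len(pairs)

    # coarse pass on ~coarse_resolution rasters
    x = np.asarray(init, dtype=float)
    f_img = max(1, int(round(coarse_resolution / float(np.min(vol.spacing)))))
    coarse_pairs = []
    coarse_masks = []
    for (topo, geom), msk in zip(pairs, mask_list):
        f_t = max(1, int(round(coarse_resolution / geom.row_spacing)))
        if f_t > 1:
            tds = topo.block_downsample(f_t)
            coarse_pairs.append((tds, tds.geometry))
            if msk is not None:
                nr, nc = tds.pixels.shape
                m = np.asarray(msk)[: nr * f_t, : nc * f_t]
                m = m.reshape(nr, f_t, nc, f_t).max(axis=(1, 3))
                coarse_masks.append(m)
            else:
                coarse_masks.append(None)
        else:
            coarse_pairs.append((topo, geom))
            coarse_masks.append(msk)
    coarse_vol = block_downsample(vol, f_img) if f_img > 1 else vol
    if any(f > 1 for f in [f_img]) or coarse_pairs is not pairs:
        x = stage(coarse_pairs, coarse_masks, coarse_vol, x, simplex_delta, max(tolerance, 0.2))

    # one refinement at full resolution
    x = stage(pairs, mask_list, vol, x, max(2.0 * tolerance, 0.5), tolerance)
    return x
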